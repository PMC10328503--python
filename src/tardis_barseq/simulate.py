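"""Generative model of the TARDIS barcode experiment.

The simulator reproduces, stage by stage, the statistical structure of the
barcode quantification experiment:

1. **Library synthesis** — molecules drawn uniformly from a degenerate
   oligo template space (:func:`sample_library`).
2. **Complexing PCR** — per-template amplification efficiencies drawn from
   a Beta distribution, compounded over binomial doubling cycles; the
   variance of the efficiency distribution is what produces "jackpotted"
   sequences with far higher representation than expected
   (:func:`simulate_pcr`).
3. **Array formation** — an extrachromosomal array is founded by ``m``
   distinct molecules sampled proportionally to their frequency in the
   injection mix; each founder is amplified to a copy number drawn from a
   zero-truncated Poisson, optionally with rare log-normal jackpot
   amplification (:func:`form_array`).
4. **Integration** — F1 integrants are multinomial draws proportional to
   array frequency, with optional per-barcode bias multipliers
   (:func:`draw_integrants`).
5. **Sequencing** — UMI-tagged 87 bp amplicon reads with substitution
   errors, PCR duplicates and a configurable quality model, written as
   Phred+33 FASTQ with a ground-truth sidecar table
   (:func:`generate_reads`).

All stages take an explicit seed (or :class:`numpy.random.Generator`);
identical parameters and seed give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fastq import ReadRecord, write_fastq
from .template import BASES, BarcodeTemplate

STAGES = ("library", "injection_mix", "array", "integrants")

# Constant 3' filler downstream of the barcode, standing in for the vector
# backbone / homology arm sequence of the amplicon.  Long enough to pad the
# default layout (31 bases of flank+UMI+flank+barcode) out to 87 bp.
DEFAULT_SUFFIX = (
    "TGGAGCTCCACCGCGGTGGCGGCCGCTCTAGAACTAGTGGATCCCCCGGGCTGCAGGAATTCGAT"
)


def as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class MoleculePool:
    """Barcode sequence → abundance at one generative stage.

    Abundances are molecule-equivalents (positive reals; integral at the
    library and integrant stages).  ``frequencies`` normalizes to a
    probability vector.
    """

    entries: dict[str, float]
    stage_label: str = "library"

    def __post_init__(self) -> None:
        if self.stage_label not in STAGES:
            raise ValueError(f"unknown stage label {self.stage_label!r}")
        if any(v <= 0 for v in self.entries.values()):
            raise ValueError("all pool abundances must be > 0")
        lengths = {len(b) for b in self.entries}
        if len(lengths) > 1:
            raise ValueError(f"pool holds barcodes of mixed lengths {sorted(lengths)}")

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    def frequencies(self) -> dict[str, float]:
        total = self.total
        return {b: a / total for b, a in self.entries.items()}

    def barcodes(self) -> list[str]:
        return list(self.entries)

    def to_frame(self) -> pd.DataFrame:
        total = self.total
        df = pd.DataFrame(
            {
                "barcode": list(self.entries),
                "abundance": list(self.entries.values()),
            }
        )
        df["frequency"] = df["abundance"] / total
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, stage_label: str = "library") -> "MoleculePool":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["barcode"], df["abundance"].astype(float))), stage_label)


@dataclass
class GenerativeParams:
    """Parameters of the full generative model, with study-condition defaults.

    ``n_library_molecules`` is the number of template molecules entering the
    complexing PCR; ``pcr_efficiency_beta`` the (a, b) shape of the
    per-template duplication probability; ``n_founders`` the array founder
    count m (observed arrays ranged from 91 to 3001 unique barcodes);
    ``copy_lambda`` the zero-truncated Poisson rate of founder copy numbers;
    ``jackpot_prob``/``jackpot_factor_log_sd`` the rare multiplicative
    amplification during array formation; ``n_integrants`` the number of F1
    integration events drawn from the array.
    """

    n_library_molecules: int = 1_000_000
    pcr_cycles: int = 10
    pcr_efficiency_beta: tuple[float, float] = (8.0, 2.0)
    n_founders: int = 1000
    copy_lambda: float = 3.0
    jackpot_prob: float = 0.05
    jackpot_factor_log_sd: float = 1.0
    n_integrants: int = 50_000
    integration_bias: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jackpot_prob <= 1.0:
            raise ValueError("jackpot_prob must be in [0, 1]")
        if self.copy_lambda < 0:
            raise ValueError("copy_lambda must be >= 0")


@dataclass
class AmpliconLayout:
    """Structure of the sequenced amplicon and the read noise model.

    Layout: ``prefix + umi_flank_5 + UMI + umi_flank_3 + barcode + suffix``
    cropped to ``read_length``.  With the defaults the UMI occupies 0-based
    read positions 3..12 and the barcode 16..30.  ``quality_model`` is
    (mean Q, sd Q, probability of a low-quality 3' tail).
    """

    prefix: str = ""
    umi_flank_5: str = "CAC"
    umi_length: int = 10
    umi_flank_3: str = "GAC"
    suffix: str = DEFAULT_SUFFIX
    read_length: int = 87
    error_rate: float = 0.0
    indel_rate: float = 0.0
    duplicate_rate: float = 0.0
    quality_model: tuple[float, float, float] = (36.0, 3.0, 0.0)

    def fixed_length(self, barcode_length: int) -> int:
        return (
            len(self.prefix)
            + len(self.umi_flank_5)
            + self.umi_length
            + len(self.umi_flank_3)
            + barcode_length
        )

    def validate(self, barcode_length: int) -> None:
        if self.fixed_length(barcode_length) > self.read_length:
            raise ValueError(
                f"layout ({self.fixed_length(barcode_length)} bases) exceeds "
                f"read length {self.read_length}"
            )


# ---------------------------------------------------------------------------
# stage 1: library synthesis


def sample_library(
    template: BarcodeTemplate,
    n_molecules: int,
    seed: int | np.random.Generator = 0,
) -> MoleculePool:
    """Draw ``n_molecules`` uniformly from the template space.

    Fixed positions are respected exactly; abundances are integer molecule
    counts summing to ``n_molecules``.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = as_rng(seed)
    free = template.free_positions
    draws = rng.integers(0, 4, size=(n_molecules, len(free)))
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    chars = np.empty((n_molecules, template.length), dtype="S1")
    for i, b in enumerate(template.pattern):
        if b != "N":
            chars[:, i] = b.encode()
    for j, pos in enumerate(free):
        chars[:, pos] = base_arr[draws[:, j]]
    seqs = chars.view(f"S{template.length}").ravel()
    uniq, counts = np.unique(seqs, return_counts=True)
    entries = {s.decode(): int(c) for s, c in zip(uniq, counts)}
    return MoleculePool(entries, "library")


# ---------------------------------------------------------------------------
# stage 2: PCR with per-template efficiency


def simulate_pcr(
    pool: MoleculePool,
    cycles: int,
    efficiency_beta: tuple[float, float] | None = (8.0, 2.0),
    efficiency: float | Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> MoleculePool:
    """Amplify a pool through ``cycles`` binomial doubling rounds.

    Each barcode i receives a per-template duplication probability e_i,
    drawn once from Beta(a, b) (or fixed via ``efficiency``); in each cycle
    its molecule count n grows by Binomial(n, e_i).  Heterogeneity in e_i
    compounds geometrically over cycles, producing the heavy-tailed
    "jackpotting" seen in real complexing PCR.  A deterministic efficiency
    of 1.0 doubles every barcode exactly and leaves frequencies unchanged.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    rng = as_rng(seed)
    barcodes = list(pool.entries)
    counts = np.array([pool.entries[b] for b in barcodes], dtype=np.int64)

    if efficiency is not None:
        if isinstance(efficiency, Mapping):
            eff = np.array([float(efficiency[b]) for b in barcodes])
        else:
            eff = np.full(len(barcodes), float(efficiency))
    else:
        a, b = efficiency_beta
        eff = rng.beta(a, b, size=len(barcodes))
    if np.any((eff < 0) | (eff > 1)):
        raise ValueError("efficiencies must be in [0, 1]")

    deterministic = np.isin(eff, (0.0, 1.0))
    for _ in range(cycles):
        growth = np.where(
            deterministic,
            (counts * eff).astype(np.int64),
            rng.binomial(counts, eff),
        )
        counts = counts + growth
    entries = {b: int(c) for b, c in zip(barcodes, counts) if c > 0}
    return MoleculePool(entries, "injection_mix")


# ---------------------------------------------------------------------------
# stage 3: array formation


def sample_zt_poisson(
    lam: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-truncated Poisson(lam) draws; collapses to all-ones as lam → 0."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    out = np.ones(size, dtype=np.int64)
    if lam < 1e-9:
        return out
    out = rng.poisson(lam, size=size)
    zero = out == 0
    # resample zeros until none remain; expected passes = 1/(1-e^-lam)
    while np.any(zero):
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def form_array(
    pool: MoleculePool,
    m: int,
    copy_lambda: float = 3.0,
    jackpot_prob: float = 0.0,
    jackpot_factor_log_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> MoleculePool:
    """Found an extrachromosomal array from an injection-mix pool.

    ``m`` distinct founders are sampled without replacement with
    probability proportional to pool frequency; each receives a
    zero-truncated Poisson(``copy_lambda``) copy number.  Independently,
    with probability ``jackpot_prob``, a founder's copy number is further
    multiplied by ``exp(Normal(0, jackpot_factor_log_sd))`` (rounded up) —
    the rare early-amplification events that dominate low-diversity arrays.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > pool.n_unique:
        raise ValueError(
            f"cannot sample {m} distinct founders from {pool.n_unique} barcodes"
        )
    rng = as_rng(seed)
    barcodes = np.array(pool.barcodes())
    freqs = np.array([pool.entries[b] for b in barcodes], dtype=float)
    freqs /= freqs.sum()
    founders = rng.choice(barcodes, size=m, replace=False, p=freqs)
    copies = sample_zt_poisson(copy_lambda, m, rng).astype(float)
    if jackpot_prob > 0:
        hit = rng.random(m) < jackpot_prob
        factors = np.exp(rng.normal(0.0, jackpot_factor_log_sd, size=m))
        copies = np.where(hit, np.ceil(copies * factors), copies)
    entries = {str(b): float(c) for b, c in zip(founders, copies)}
    return MoleculePool(entries, "array")


# ---------------------------------------------------------------------------
# stage 4: integration


def draw_integrants(
    array: MoleculePool,
    n_integrants: int,
    bias: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> MoleculePool:
    """Multinomial integrant draws proportional to array frequency × bias.

    ``bias`` maps barcode → positive multiplier (default 1 everywhere);
    output abundances are integers summing exactly to ``n_integrants``.
    Barcodes drawn zero times are absent from the output pool.
    """
    if n_integrants < 1:
        raise ValueError("n_integrants must be >= 1")
    rng = as_rng(seed)
    barcodes = array.barcodes()
    p = np.array([array.entries[b] for b in barcodes], dtype=float)
    if bias:
        mult = np.array([float(bias.get(b, 1.0)) for b in barcodes])
        if np.any(mult < 0):
            raise ValueError("bias multipliers must be >= 0")
        p = p * mult
    p /= p.sum()
    counts = rng.multinomial(n_integrants, p)
    entries = {b: int(c) for b, c in zip(barcodes, counts) if c > 0}
    return MoleculePool(entries, "integrants")


# ---------------------------------------------------------------------------
# stage 5: sequencing


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _apply_substitutions(
    bases: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return bases
    n = len(bases)
    mask = rng.random(n) < rate
    if not mask.any():
        return bases
    chars = list(bases)
    for i in np.flatnonzero(mask):
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _apply_indels(bases: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return bases
    chars: list[str] = []
    for ch in bases:
        r = rng.random()
        if r < rate / 2:  # deletion
            continue
        if r < rate:  # insertion before this base
            chars.append(BASES[rng.integers(0, 4)])
        chars.append(ch)
    return "".join(chars)


def _qualities(
    n: int, model: tuple[float, float, float], rng: np.random.Generator
) -> list[int]:
    mean, sd, tail_prob = model
    q = rng.normal(mean, sd, size=n)
    if tail_prob > 0 and rng.random() < tail_prob:
        tail = int(rng.integers(10, 31))
        q[-tail:] = rng.normal(10.0, 2.0, size=min(tail, n))
    return list(np.clip(np.rint(q), 2, 41).astype(int))


def simulate_reads(
    pool: MoleculePool,
    layout: AmpliconLayout,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate UMI-tagged amplicon reads from a barcode pool.

    ``depth`` unique molecules are sampled multinomially in proportion to
    pool frequency.  Each molecule gets a uniform random UMI and
    ``1 + Poisson(duplicate_rate)`` reads sharing that UMI; every read is
    built as ``prefix+flank5+UMI+flank3+barcode+suffix`` cropped to
    ``read_length``, then substitution (and optional indel) errors are
    applied independently per read.  Returns the reads and a ground-truth
    sidecar table (molecule_id, barcode, umi, n_reads).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    barcodes = pool.barcodes()
    barcode_length = len(barcodes[0])
    layout.validate(barcode_length)
    rng = as_rng(seed)

    p = np.array([pool.entries[b] for b in barcodes], dtype=float)
    p /= p.sum()
    molecule_barcodes = rng.choice(len(barcodes), size=depth, p=p)

    reads: list[ReadRecord] = []
    sidecar_rows = []
    for mol_id, bc_idx in enumerate(molecule_barcodes):
        barcode = barcodes[bc_idx]
        umi = _random_dna(rng, layout.umi_length)
        n_reads = 1 + (
            rng.poisson(layout.duplicate_rate) if layout.duplicate_rate > 0 else 0
        )
        amplicon = (
            layout.prefix
            + layout.umi_flank_5
            + umi
            + layout.umi_flank_3
            + barcode
            + layout.suffix
        )[: layout.read_length]
        for dup in range(n_reads):
            bases = _apply_indels(amplicon, layout.indel_rate, rng)
            bases = _apply_substitutions(bases, layout.error_rate, rng)
            bases = bases[: layout.read_length]
            quals = _qualities(len(bases), layout.quality_model, rng)
            reads.append(ReadRecord(f"sim_{mol_id:07d}_{dup}", bases, quals))
        sidecar_rows.append((f"sim_{mol_id:07d}", barcode, umi, n_reads))
    sidecar = pd.DataFrame(
        sidecar_rows, columns=["molecule_id", "barcode", "umi", "n_reads"]
    )
    return reads, sidecar


def generate_reads(
    pool: MoleculePool,
    layout: AmpliconLayout,
    depth: int,
    fastq_path: str | Path,
    sidecar_path: str | Path,
    seed: int | np.random.Generator = 0,
) -> int:
    """Simulate reads and write FASTQ plus the truth sidecar TSV.

    Returns the number of reads written (== sum of sidecar n_reads).
    """
    reads, sidecar = simulate_reads(pool, layout, depth, seed)
    n = write_fastq(reads, fastq_path)
    sidecar.to_csv(sidecar_path, sep="\t", index=False)
    assert n == int(sidecar["n_reads"].sum())
    return n


def stage_rngs(seed: int, n: int = 5) -> list[np.random.Generator]:
    """Independent per-stage generators derived from one top-level seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
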