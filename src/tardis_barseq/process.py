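"""Raw FASTQ → deduplicated 15 bp barcode observations.

The stage order mirrors the study's preprocessing: optional two-color
(NextSeq) poly-G-aware 3' trimming, 3' quality trimming at Q30 with the
running-sum minimum algorithm, removal of reads containing N, a maximum
expected-error filter (sum of 10^(-Q/10) <= 1), cropping to 87 bp, UMI
extraction with the CAC + 10 bases + GAC pattern, duplicate collapse on the
(UMI, remainder) key, and trimming of the deduplicated remainder to the
15 bp barcode.

Every stage keeps a conservation tally: reads in == reads kept + sum of
per-reason discards.  Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .fastq import ReadRecord

# precomputed 10^(-q/10) for q 0..93
_ERR_PROB = [10.0 ** (-q / 10.0) for q in range(94)]


@dataclass
class ProcessingParams:
    """Filtering, UMI and trimming parameters (defaults = study settings)."""

    quality_threshold: int = 30
    max_expected_error: float = 1.0
    crop_length: int = 87
    umi_flank_5: str = "CAC"
    umi_length: int = 10
    umi_flank_3: str = "GAC"
    barcode_length: int = 15
    nextseq_mode: bool = False
    quality_filter_mode: str = "trim3_then_ee"  # or "strict_per_base"
    umi_flank_mismatches: int = 0  # 0 or 1 mismatch tolerated across flanks

    @property
    def min_read_length(self) -> int:
        """Shortest read that can still contain flanked UMI + barcode."""
        return (
            len(self.umi_flank_5)
            + self.umi_length
            + len(self.umi_flank_3)
            + self.barcode_length
        )

    def __post_init__(self) -> None:
        if self.quality_filter_mode not in ("trim3_then_ee", "strict_per_base"):
            raise ValueError(f"unknown quality_filter_mode {self.quality_filter_mode!r}")
        if self.crop_length < self.min_read_length:
            raise ValueError(
                f"crop_length {self.crop_length} < minimal layout length "
                f"{self.min_read_length}"
            )


def quality_trim_index(quals: list[int], threshold: int) -> int:
    """3' trim point by the running-sum minimum (BWA/cutadapt) algorithm.

    Walking from the 3' end, accumulate ``threshold - q``; the read is cut
    where the running sum attains its maximum.  Returns the index such that
    ``bases[:index]`` is kept.
    """
    s = 0
    max_s = 0
    cut = len(quals)
    for i in range(len(quals) - 1, -1, -1):
        s += threshold - quals[i]
        if s < 0:
            break
        if s > max_s:
            max_s = s
            cut = i
    return cut


def nextseq_trim_index(bases: str, quals: list[int], threshold: int) -> int:
    """Two-color-chemistry trim: G bases are scored as quality 0.

    On NextSeq-style two-color sequencers a dark cycle reads as a
    high-confidence G, so trailing G runs are treated as no signal.
    """
    adjusted = [0 if b == "G" else q for b, q in zip(bases, quals)]
    return quality_trim_index(adjusted, threshold)


def expected_errors(quals: Iterable[int]) -> float:
    return sum(_ERR_PROB[q] for q in quals)


def filter_and_crop(
    reads: Iterable[ReadRecord], params: ProcessingParams
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Quality-filter, N-filter, EE-filter and crop a read stream.

    Returns the surviving reads (cropped to ``params.crop_length``) and a
    tally of input / kept / per-reason discard counts satisfying
    ``input == kept + sum(discards)``.
    """
    tally: Counter[str] = Counter()
    kept: list[ReadRecord] = []
    for read in reads:
        tally["input"] += 1
        bases, quals = read.bases, read.quals
        if params.quality_filter_mode == "strict_per_base":
            if any(q < params.quality_threshold for q in quals):
                tally["discard_low_quality"] += 1
                continue
        else:
            if params.nextseq_mode:
                cut = nextseq_trim_index(bases, quals, params.quality_threshold)
                bases, quals = bases[:cut], quals[:cut]
            cut = quality_trim_index(quals, params.quality_threshold)
            bases, quals = bases[:cut], quals[:cut]
        if "N" in bases:
            tally["discard_contains_N"] += 1
            continue
        if expected_errors(quals) > params.max_expected_error:
            tally["discard_expected_error"] += 1
            continue
        bases, quals = bases[: params.crop_length], quals[: params.crop_length]
        if len(bases) < params.min_read_length:
            tally["discard_too_short"] += 1
            continue
        kept.append(ReadRecord(read.read_id, bases, quals))
        tally["kept"] += 1
    result = dict(tally)
    assert result.get("input", 0) == result.get("kept", 0) + sum(
        v for k, v in result.items() if k.startswith("discard_")
    )
    return kept, result


def _flank_matches(segment: str, flank: str, budget: int) -> int | None:
    """Mismatches of segment vs flank if within budget, else None."""
    mismatches = 0
    for a, b in zip(segment, flank):
        if a != b:
            mismatches += 1
            if mismatches > budget:
                return None
    return mismatches


def extract_umi(
    read: ReadRecord | str, params: ProcessingParams
) -> tuple[str, str] | None:
    """Locate ``flank5 + UMI + flank3`` and split the read around it.

    Scans 5'→3' for the first occurrence of the flanked UMI block (exact by
    default; ``umi_flank_mismatches`` allows one mismatch across both
    flanks).  Returns ``(umi, remainder)`` where remainder is the read with
    the whole matched block removed (prefix + suffix concatenated), or
    ``None`` when no occurrence exists.
    """
    bases = read if isinstance(read, str) else read.bases
    f5, f3 = params.umi_flank_5, params.umi_flank_3
    block = len(f5) + params.umi_length + len(f3)
    for start in range(0, len(bases) - block + 1):
        m5 = _flank_matches(bases[start : start + len(f5)], f5, params.umi_flank_mismatches)
        if m5 is None:
            continue
        tail_start = start + len(f5) + params.umi_length
        m3 = _flank_matches(
            bases[tail_start : tail_start + len(f3)],
            f3,
            params.umi_flank_mismatches - m5,
        )
        if m3 is None:
            continue
        umi = bases[start + len(f5) : tail_start]
        remainder = bases[:start] + bases[tail_start + len(f3) :]
        return umi, remainder
    return None


def extract_umis(
    reads: Iterable[ReadRecord], params: ProcessingParams
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Apply :func:`extract_umi` to a stream, tallying unmatched reads."""
    tally: Counter[str] = Counter()
    pairs: list[tuple[str, str]] = []
    for read in reads:
        tally["input"] += 1
        hit = extract_umi(read, params)
        if hit is None:
            tally["umi_unmatched"] += 1
        else:
            pairs.append(hit)
            tally["kept"] += 1
    return pairs, dict(tally)


@dataclass
class DedupTable:
    """(UMI, post-UMI sequence) → duplicate read count."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def keys(self):
        return self.counts.keys()


def deduplicate(pairs: Iterable[tuple[str, str]]) -> DedupTable:
    """Collapse PCR duplicates: one representative per (UMI, sequence) key.

    The key deliberately includes the full post-UMI sequence, not the UMI
    alone, so two distinct barcodes that collide on a UMI by chance
    (probability ≈ n / 4^10) are not merged.  Idempotent: deduplicating the
    set of kept representatives again is a no-op.
    """
    counts: Counter[tuple[str, str]] = Counter()
    for umi, remainder in pairs:
        counts[(umi, remainder)] += 1
    return DedupTable(dict(counts))


def trim_to_barcode(
    dedup: DedupTable, barcode_length: int = 15
) -> tuple[Counter, dict[str, int]]:
    """Keep the first ``barcode_length`` bases of each deduplicated sequence.

    Each dedup key contributes one observation; identical barcodes
    aggregate.  Remainders shorter than the barcode are tallied
    ``too_short`` and dropped.
    """
    tally: Counter[str] = Counter()
    barcode_counts: Counter[str] = Counter()
    for (_umi, remainder) in dedup.counts:
        tally["input"] += 1
        if len(remainder) < barcode_length:
            tally["too_short"] += 1
            continue
        barcode_counts[remainder[:barcode_length]] += 1
        tally["kept"] += 1
    return barcode_counts, dict(tally)


def fixed_base_conformity(
    barcode_counts: Counter, template_pattern: str = "NNNCNNTNTNANNNN"
) -> float:
    """QC metric: fraction of observations matching the template's fixed bases.

    Non-conforming barcodes are reported, never filtered — the study
    filtered only on final length.
    """
    from .template import BarcodeTemplate

    template = BarcodeTemplate(template_pattern)
    total = sum(barcode_counts.values())
    if total == 0:
        return float("nan")
    good = sum(c for b, c in barcode_counts.items() if template.matches(b))
    return good / total


def demultiplex(
    reads: Iterable[ReadRecord],
    sample_sheet: dict[str, str],
    index_from: str = "header",
) -> dict[str, list[ReadRecord]]:
    """Assign reads to samples by exact index match.

    ``sample_sheet`` maps index sequence → sample name (indices must be
    unique, which the dict enforces upstream via :func:`read_sample_sheet`).
    ``index_from`` is ``"header"`` (index = token after the last ``:`` of
    the read id) or ``"prefix"`` (index = the read's first bases; the index
    is stripped from assigned reads).  Unmatched reads go to
    ``"undetermined"``.
    """
    if index_from not in ("header", "prefix"):
        raise ValueError(f"unknown index_from {index_from!r}")
    out: dict[str, list[ReadRecord]] = {name: [] for name in sample_sheet.values()}
    out.setdefault("undetermined", [])
    lengths = {len(ix) for ix in sample_sheet}
    for read in reads:
        assigned = None
        if index_from == "header":
            token = read.read_id.rsplit(":", 1)[-1]
            assigned = sample_sheet.get(token)
            if assigned is not None:
                out[assigned].append(read)
        else:
            for ell in sorted(lengths, reverse=True):
                name = sample_sheet.get(read.bases[:ell])
                if name is not None:
                    assigned = name
                    out[name].append(read.trimmed(ell))
                    break
        if assigned is None:
            out["undetermined"].append(read)
    return out


def read_sample_sheet(path) -> dict[str, str]:
    """Load a (sample, index) TSV; duplicate indices are a config error."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df["index"].duplicated().any():
        dupes = df.loc[df["index"].duplicated(), "index"].tolist()
        raise ValueError(f"duplicate indices in sample sheet: {dupes}")
    return dict(zip(df["index"], df["sample"]))
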