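"""Diversity, jackpotting, overlap and array-to-F1 correlation statistics.

This module computes the headline quantities of a barcode-array
experiment:

* a plateau-based read-count threshold separating true barcodes from
  error tail (:func:`select_threshold`);
* per-sample diversity summaries and jackpot reports
  (:func:`summarize_diversity`, :func:`jackpot_report`);
* position probability matrices for sequence logos
  (:func:`position_probabilities`);
* cross-sample membership/containment overlap (:func:`overlap_analysis`);
* a zero-truncated Poisson fit to array copy numbers
  (:func:`fit_zt_poisson`);
* the Pearson correlation between array and F1-integrant barcode
  frequencies with replicated-outlier detection
  (:func:`array_f1_correlation`).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

LOG10E = math.log10(math.e)


@dataclass
class StatsParams:
    """Statistic-stage parameters (defaults mirror the study settings)."""

    threshold_window: int = 3
    threshold_tol: float = 0.01
    default_threshold: int = 5
    jackpot_cutoff: int = 50
    outlier_z: float = 3.0
    outlier_min_replicates: int = 3
    outlier_scale: str = "binomial"  # "binomial" (default), "mad" or "rms"
    correlation_universe: str = "union_zero_fill"  # or "intersection"
    logo_weighting: str = "unique"  # or "read_weighted"

    def __post_init__(self) -> None:
        if self.threshold_window < 1:
            raise ValueError("threshold_window must be >= 1")
        if self.threshold_tol <= 0:
            raise ValueError("threshold_tol must be > 0")
        if self.jackpot_cutoff < 1:
            raise ValueError("jackpot_cutoff must be >= 1")
        if self.outlier_scale not in ("binomial", "mad", "rms"):
            raise ValueError(f"unknown outlier_scale {self.outlier_scale!r}")
        if self.correlation_universe not in ("union_zero_fill", "intersection"):
            raise ValueError(f"unknown universe {self.correlation_universe!r}")


@dataclass
class SampleProfile:
    """Thresholded barcode counts and frequencies for one sample."""

    sample_id: str
    counts: dict[str, int]
    threshold: int = 1

    @classmethod
    def from_counts(
        cls, sample_id: str, counts: Mapping[str, int], threshold: int = 1
    ) -> "SampleProfile":
        kept = {b: int(c) for b, c in counts.items() if c >= threshold}
        if not kept:
            raise ValueError(f"no barcodes at threshold {threshold}")
        return cls(sample_id, kept, threshold)

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> dict[str, float]:
        total = self.n_reads
        return {b: c / total for b, c in self.counts.items()}

    def barcode_set(self) -> set[str]:
        return set(self.counts)


# ---------------------------------------------------------------------------
# plateau threshold


def unique_at_cutoff(counts: Mapping[str, int], c: int) -> int:
    """u(c): number of barcodes with count >= c."""
    return sum(1 for v in counts.values() if v >= c)


def select_threshold(
    counts: Mapping[str, int], params: StatsParams | None = None
) -> tuple[int, bool]:
    """Smallest cutoff where the unique-barcode count has plateaued.

    Let ``u(c)`` be the number of barcodes with count >= c.  Returns the
    smallest ``c >= 1`` with ``(u(c) - u(c + window)) / u(c) < tol`` —
    i.e. raising the cutoff by ``window`` sheds less than ``tol`` of the
    surviving barcodes.  If no plateau appears at or below the
    99th-percentile count, falls back to ``default_threshold`` with the
    warning flag set.  Returns ``(threshold, fallback_used)``.
    """
    params = params or StatsParams()
    if not counts:
        raise ValueError("empty counts")
    values = np.fromiter(counts.values(), dtype=np.int64)
    cmax = int(np.percentile(values, 99))
    for c in range(1, max(cmax, 1) + 1):
        u_c = int((values >= c).sum())
        if u_c == 0:
            break
        u_ck = int((values >= c + params.threshold_window).sum())
        if (u_c - u_ck) / u_c < params.threshold_tol:
            return c, False
    return params.default_threshold, True


# ---------------------------------------------------------------------------
# diversity and jackpots


def summarize_diversity(profile: SampleProfile) -> dict:
    """n_unique, n_reads and frequency spread for a thresholded profile."""
    freqs = np.array(list(profile.frequencies().values()))
    cv = float(freqs.std(ddof=0) / freqs.mean()) if len(freqs) > 1 else 0.0
    return {
        "sample_id": profile.sample_id,
        "threshold": profile.threshold,
        "n_unique": profile.n_unique,
        "n_reads": profile.n_reads,
        "max_frequency": float(freqs.max()),
        "min_frequency": float(freqs.min()),
        "frequency_cv": cv,
    }


def jackpot_report(
    counts: Mapping[str, int], cutoff: int = 50
) -> tuple[set[str], float, float]:
    """Overrepresented barcodes (count > cutoff) in a raw count table.

    Returns the jackpot set, the fraction of all reads they carry, and the
    fraction of unique barcodes they represent.  Applied to raw
    (pre-threshold) counts, as in the injection-mix analysis.
    """
    total_reads = sum(counts.values())
    jackpots = {b for b, c in counts.items() if c > cutoff}
    if not counts:
        return set(), 0.0, 0.0
    reads_fraction = sum(counts[b] for b in jackpots) / total_reads
    unique_fraction = len(jackpots) / len(counts)
    return jackpots, reads_fraction, unique_fraction


# ---------------------------------------------------------------------------
# sequence logos


def position_probabilities(
    counts: Mapping[str, int] | Iterable[str], weighting: str = "unique"
) -> pd.DataFrame:
    """Per-position base probability matrix (rows = 1-based positions).

    ``weighting="unique"`` counts each barcode once; ``"read_weighted"``
    weights by count.  All barcodes must share one length; each row of the
    returned (length x 4) frame sums to 1, columns ordered A, C, G, T.
    """
    if not isinstance(counts, Mapping):
        counts = {b: 1 for b in counts}
    if not counts:
        raise ValueError("empty barcode set")
    lengths = {len(b) for b in counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed barcode lengths {sorted(lengths)}")
    (length,) = lengths
    if weighting not in ("unique", "read_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    matrix = np.zeros((length, 4))
    base_index = {b: i for i, b in enumerate("ACGT")}
    for barcode, count in counts.items():
        w = count if weighting == "read_weighted" else 1
        for pos, base in enumerate(barcode):
            matrix[pos, base_index[base]] += w
    matrix /= matrix.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        matrix, index=pd.RangeIndex(1, length + 1, name="position"),
        columns=list("ACGT"),
    )


# ---------------------------------------------------------------------------
# overlap


def overlap_analysis(
    barcode_sets: Sequence[set[str]], labels: Sequence[str] | None = None
) -> dict:
    """Membership counts and pairwise containment across barcode sets.

    For the union, counts elements present in exactly k of the n sets
    (k = 1..n, with percentages of the union); containment(A, B) =
    |A ∩ B| / |A| for every ordered pair.
    """
    if len(barcode_sets) < 2:
        raise ValueError("need at least two sets")
    labels = list(labels) if labels else [f"set{i + 1}" for i in range(len(barcode_sets))]
    membership: Counter[str] = Counter()
    for s in barcode_sets:
        for b in s:
            membership[b] += 1
    union_size = len(membership)
    exactly = {
        k: sum(1 for v in membership.values() if v == k)
        for k in range(1, len(barcode_sets) + 1)
    }
    containment = {
        (labels[i], labels[j]): (
            len(barcode_sets[i] & barcode_sets[j]) / len(barcode_sets[i])
            if barcode_sets[i]
            else float("nan")
        )
        for i in range(len(barcode_sets))
        for j in range(len(barcode_sets))
    }
    return {
        "union_size": union_size,
        "exactly_k": exactly,
        "exactly_k_pct": {
            k: 100.0 * v / union_size if union_size else 0.0 for k, v in exactly.items()
        },
        "containment": containment,
    }


# ---------------------------------------------------------------------------
# zero-truncated Poisson fit


def zt_poisson_mean(lam: float) -> float:
    """Mean of the zero-truncated Poisson: lam / (1 - exp(-lam))."""
    if lam <= 0:
        return 1.0
    return lam / -math.expm1(-lam)


def zt_poisson_pmf(k: np.ndarray, lam: float) -> np.ndarray:
    return sps.poisson.pmf(k, lam) / -math.expm1(-lam)


def fit_zt_poisson(copy_counts: Iterable[int]) -> dict:
    """Maximum-likelihood zero-truncated Poisson fit with chi-square GOF.

    The ML estimate solves ``lam / (1 - exp(-lam)) = sample mean``; solved
    by bracketed root-finding to 1e-12.  The goodness-of-fit statistic
    merges right-tail bins until every expected count is >= 5.  A sample
    mean <= 1 sits on the lam -> 0 boundary: lam_hat = 0 is reported and
    the GOF is skipped.
    """
    counts = np.asarray(list(copy_counts), dtype=np.int64)
    if len(counts) == 0:
        raise ValueError("empty copy-count sample")
    if np.any(counts < 1):
        raise ValueError("zero-truncated counts must be >= 1")
    mean = float(counts.mean())
    if mean <= 1.0 + 1e-12:
        return {"lambda": 0.0, "boundary": True, "gof_stat": None, "gof_p": None}

    lam_hat = float(
        optimize.brentq(
            lambda lam: zt_poisson_mean(lam) - mean,
            1e-12,
            mean,  # zt mean >= lam, so the root lies below the sample mean
            xtol=1e-12,
        )
    )

    n = len(counts)
    kmax = int(counts.max())
    ks = np.arange(1, kmax + 1)
    expected = n * zt_poisson_pmf(ks, lam_hat)
    expected = np.append(expected, n * (1.0 - expected.sum() / n))  # k > kmax tail
    observed = np.append(np.bincount(counts, minlength=kmax + 1)[1:], 0)
    # merge right-tail bins until each expected >= 5
    obs_list, exp_list = list(observed), list(expected)
    while len(exp_list) > 2 and exp_list[-1] < 5:
        e, o = exp_list.pop(), obs_list.pop()
        exp_list[-1] += e
        obs_list[-1] += o
    while len(exp_list) > 2 and exp_list[0] < 5:
        e, o = exp_list.pop(0), obs_list.pop(0)
        exp_list[0] += e
        obs_list[0] += o
    dof = len(exp_list) - 1 - 1  # one estimated parameter
    if dof < 1:
        return {"lambda": lam_hat, "boundary": False, "gof_stat": None, "gof_p": None}
    obs_arr, exp_arr = np.array(obs_list, dtype=float), np.array(exp_list)
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    stat = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    return {
        "lambda": lam_hat,
        "boundary": False,
        "gof_stat": stat,
        "gof_p": float(sps.chi2.sf(stat, dof)),
        "gof_dof": dof,
    }


# ---------------------------------------------------------------------------
# array vs F1 correlation


def pearson_with_log_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Pearson r with a two-sided p computed in log space.

    Returns ``(r, p, log10_p)``.  For the extreme correlations this assay
    produces (p ~ 1e-150), the Student-t survival function is evaluated on
    the log scale so the report never degrades to an unusable 0.
    """
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points for a correlation")
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt(float((xm**2).sum()) * float((ym**2).sum()))
    if denom == 0:
        raise ValueError("zero variance in correlation input")
    r = float((xm * ym).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, -math.inf
    t = abs(r) * math.sqrt((n - 2) / (1 - r * r))
    log_p = math.log(2.0) + _log_t_sf(t, n - 2)
    return r, math.exp(log_p), log_p * LOG10E


def _log_t_sf(t: float, df: float) -> float:
    """log of the Student-t survival function, accurate in the deep tail.

    scipy's ``t.logsf`` underflows to -inf for the t statistics produced by
    near-perfect correlations at large n; beyond that point the survival
    function is evaluated through the regularized incomplete beta function
    in log space: sf(t) = I_x(df/2, 1/2) / 2 with x = df / (df + t^2) and
    B(x; a, b) = x^a (1-x)^b / a * 2F1(a+b, 1; a+1; x).
    """
    log_sf = float(sps.t.logsf(t, df))
    if math.isfinite(log_sf):
        return log_sf
    a, b = df / 2.0, 0.5
    x = df / (df + t * t)
    log_ix = (
        a * math.log(x)
        + b * math.log1p(-x)
        - math.log(a)
        - float(special.betaln(a, b))
        + math.log(float(special.hyp2f1(a + b, 1.0, a + 1.0, x)))
    )
    return math.log(0.5) + log_ix


def _ls_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _standardized_residuals(
    x: np.ndarray, y: np.ndarray, scale_mode: str, n_total: int | None = None
) -> np.ndarray:
    """Leverage-corrected standardized residuals from a least-squares line.

    Frequencies estimated from N reads have binomial sampling noise
    sqrt(f(1-f)/N), so the residual scale grows with frequency; the
    default ``"binomial"`` mode standardizes each residual by that
    predicted noise (at the fitted value), floored by a robust MAD scale
    so near-zero fitted frequencies cannot hair-trigger.  ``"mad"`` uses
    the robust MAD scale alone; ``"rms"`` is the classical studentized
    residual, whose scale one gross outlier can inflate enough to mask a
    second, smaller one.  One refit excluding first-pass outliers removes
    the fit distortion the outliers themselves cause.
    """
    if scale_mode == "binomial" and n_total is None:
        raise ValueError("binomial scale mode needs the replicate read total")

    def residuals(xs, ys, fit_mask):
        slope, intercept = _ls_fit(xs[fit_mask], ys[fit_mask])
        resid = ys - (intercept + slope * xs)
        xf = xs[fit_mask]
        h = 1 / len(xf) + (xs - xf.mean()) ** 2 / ((xf - xf.mean()) ** 2).sum()
        h = np.clip(h, 0, 0.999)
        rf = resid[fit_mask]
        mad = 1.4826 * float(np.median(np.abs(rf - np.median(rf))))
        if scale_mode == "binomial":
            yhat = np.clip(intercept + slope * xs, 1.0 / (2 * n_total), 1.0)
            scale = np.maximum(np.sqrt(yhat * (1 - yhat) / n_total), mad)
        elif scale_mode == "mad":
            scale = mad
        else:
            dof = max(fit_mask.sum() - 2, 1)
            scale = math.sqrt(float((rf**2).sum()) / dof)
        scale = np.maximum(scale, np.finfo(float).tiny)
        return resid / (scale * np.sqrt(1 - h))

    all_points = np.ones(len(x), dtype=bool)
    t0 = residuals(x, y, all_points)
    keep = np.abs(t0) <= 3.0
    if keep.sum() >= 3 and not keep.all():
        return residuals(x, y, keep)
    return t0


def array_f1_correlation(
    array_profile: SampleProfile,
    f1_profiles: Sequence[SampleProfile],
    params: StatsParams | None = None,
) -> dict:
    """Array-frequency vs F1-integration-frequency correlation and outliers.

    Builds the barcode universe per ``params.correlation_universe``
    (default: union with zero fill), computes per-replicate and pooled
    Pearson r (the pooled y pools integrant counts across replicates), and
    flags replicated outliers: barcodes whose |standardized residual| from
    the per-replicate least-squares fit exceeds ``outlier_z`` in at least
    ``outlier_min_replicates`` replicates, labeled over-/under-integrating
    by residual sign.
    """
    params = params or StatsParams()
    if not f1_profiles:
        raise ValueError("need at least one F1 replicate")
    array_freq = array_profile.frequencies()
    rep_freqs = [p.frequencies() for p in f1_profiles]
    if params.correlation_universe == "intersection":
        universe = set(array_freq)
        for f in rep_freqs:
            universe &= set(f)
    else:
        universe = set(array_freq)
        for f in rep_freqs:
            universe |= set(f)
    universe_list = sorted(universe)
    if len(universe_list) < 3:
        raise ValueError("universe has fewer than 3 barcodes")
    x = np.array([array_freq.get(b, 0.0) for b in universe_list])

    per_replicate = []
    y_columns = []
    flags = np.zeros(len(universe_list), dtype=int)
    residual_signs = np.zeros(len(universe_list))
    for profile, freqs in zip(f1_profiles, rep_freqs):
        y = np.array([freqs.get(b, 0.0) for b in universe_list])
        y_columns.append(y.tolist())
        r, p, log10p = pearson_with_log_p(x, y)
        t = _standardized_residuals(x, y, params.outlier_scale, profile.n_reads)
        outlier_mask = np.abs(t) > params.outlier_z
        flags += outlier_mask
        residual_signs += np.sign(t) * outlier_mask
        per_replicate.append(
            {"sample_id": profile.sample_id, "r": r, "p": p, "log10_p": log10p,
             "n": len(universe_list)}
        )

    pooled_counts: Counter[str] = Counter()
    for profile in f1_profiles:
        pooled_counts.update(profile.counts)
    pooled_total = sum(pooled_counts.values())
    y_pooled = np.array([pooled_counts.get(b, 0) / pooled_total for b in universe_list])
    r, p, log10p = pearson_with_log_p(x, y_pooled)

    outliers = [
        {
            "barcode": universe_list[i],
            "n_replicates_flagged": int(flags[i]),
            "direction": "over" if residual_signs[i] > 0 else "under",
        }
        for i in np.flatnonzero(flags >= params.outlier_min_replicates)
    ]
    return {
        "universe": params.correlation_universe,
        "n_universe": len(universe_list),
        "barcodes": universe_list,
        "x": x.tolist(),
        "y_per_replicate": y_columns,
        "per_replicate": per_replicate,
        "pooled": {"r": r, "p": p, "log10_p": log10p, "n": len(universe_list)},
        "outliers": sorted(outliers, key=lambda o: o["barcode"]),
    }


# ---------------------------------------------------------------------------
# worked promoter-table example


def load_promoter_table() -> pd.DataFrame:
    """The published 13-promoter injection panel with presence flags.

    Columns: promoter, size_bp, in_array (Y/N for the tested array line),
    integrated (Y/N among sequence-confirmed integrant lines).
    """
    with resources.files("tardis_barseq.data").joinpath(
        "table1_promoters.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def promoter_tally(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Presence/integration tallies for the promoter panel.

    A promoter counts as present if it was detected in the array line, and
    as integrated if a sequence-confirmed integrant line carried it.
    """
    if table is None:
        table = load_promoter_table()
    return {
        "n_injected": int(len(table)),
        "n_in_array": int((table["in_array"] == "Y").sum()),
        "n_integrated": int((table["integrated"] == "Y").sum()),
    }
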