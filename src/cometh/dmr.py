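"""Paired de-novo DMR detection by binary segmentation.

Per-site methylation for matched sample pairs (e.g. tumor vs adjacent
normal) is segmented recursively within gap-bounded CpG blocks; candidate
segments are scored with a Wilcoxon signed-rank test on per-patient segment
mean differences (paired mode) or a Mann-Whitney U test on per-sample
segment means (unpaired mode), BH-corrected, filtered on CpG count, mean
difference and q-value, and reduced to a non-overlapping set.

The signed-rank statistic is W = sum sgn(d_i) * R_i with average ranks on
ties; the exact two-sided p-value is obtained from a dynamic program over
the signed-rank null distribution when n <= 25 and |d| are tie-free,
otherwise from a tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

EXACT_N_MAX = 25


class InputError(ValueError):
    """Malformed or inconsistent caller input."""


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


@dataclass(frozen=True)
class SignedRankResult:
    W: float
    n_eff: int  # pairs remaining after zero-difference removal
    p: float
    method: Literal["exact", "normal_approx", "degenerate"]


@functools.lru_cache(maxsize=64)
def _exact_null_counts(n: int) -> np.ndarray:
    """Counts over W+ in 0..n(n+1)/2 of the 2^n equally likely sign vectors.

    Classic dynamic program: each rank 1..n independently joins W+ or not.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[: total + 1 - rank]
        counts = counts + shifted
    return counts


def _exact_two_sided_p(w: float, n: int) -> float:
    """P(|W| >= |w|) under the exact signed-rank null (no ties)."""
    counts = _exact_null_counts(n)
    total = n * (n + 1) // 2
    wplus = np.arange(total + 1)
    wvals = 2 * wplus - total  # W = W+ - W- = 2 W+ - total
    mask = np.abs(wvals) >= abs(w) - 1e-9
    return float(counts[mask].sum() / 2.0**n)


def signed_rank_test(diffs: Sequence[float]) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    NA differences are dropped; zero differences are dropped (standard
    Wilcoxon convention).  With no informative pair left, W = 0 and p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise InputError("signed_rank_test requires >= 1 non-NA difference")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return SignedRankResult(W=0.0, n_eff=0, p=1.0, method="degenerate")
    ranks = sps.rankdata(np.abs(d))  # average ranks on ties
    w = float(np.sum(np.sign(d) * ranks))
    has_ties = np.unique(np.abs(d)).size < n
    if n <= EXACT_N_MAX and not has_ties:
        return SignedRankResult(
            W=w, n_eff=n, p=_exact_two_sided_p(w, n), method="exact"
        )
    # Normal approximation: E[W] = 0, Var[W] = sum R_i^2, which equals
    # n(n+1)(2n+1)/6 minus the usual tie correction under average ranks.
    var = float(np.sum(ranks**2))
    if var == 0.0:
        return SignedRankResult(W=w, n_eff=n, p=1.0, method="degenerate")
    z = (abs(w) - 1.0) / np.sqrt(var) if abs(w) > 1.0 else 0.0
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return SignedRankResult(W=w, n_eff=n, p=max(p, np.finfo(float).tiny),
                            method="normal_approx")


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Paired methylation matrix


@dataclass
class PairedMethMatrix:
    """Per-site methylation for N patients x {tumor, normal}.

    ``tumor`` and ``normal`` are (n_sites, n_patients) float arrays in
    [0, 1] with NaN for missing; rows follow ``positions`` (1-based,
    increasing).
    """

    chrom: str
    positions: np.ndarray
    tumor: np.ndarray
    normal: np.ndarray
    patient_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if self.tumor.shape != self.normal.shape:
            raise InputError(
                f"tumor shape {self.tumor.shape} ≠ normal shape "
                f"{self.normal.shape}: sample sets must match"
            )
        if self.tumor.shape[0] != self.positions.size:
            raise InputError("value rows must match number of positions")
        if np.any(np.diff(self.positions) <= 0):
            raise InputError("positions must be strictly increasing")
        for name, layer in (("tumor", self.tumor), ("normal", self.normal)):
            finite = layer[~np.isnan(layer)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise InputError(f"{name} methylation values outside [0, 1]")
        if not self.patient_ids:
            self.patient_ids = tuple(
                f"p{i + 1}" for i in range(self.tumor.shape[1])
            )

    @property
    def n_patients(self) -> int:
        return self.tumor.shape[1]

    @property
    def n_sites(self) -> int:
        return self.positions.size


@dataclass(frozen=True)
class DMR:
    """A called differentially methylated region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_cpg: int
    mean_diff: float  # tumor - normal
    W: float
    p: float
    q: float
    direction: Literal["hyper", "hypo"]


def presegment(positions: Sequence[int], max_gap: int = 300) -> List[Tuple[int, int]]:
    """Split sorted CpG positions into blocks of inter-site gap <= max_gap.

    Returns (start_index, end_index) half-open index pairs partitioning the
    input.
    """
    pos = np.asarray(positions)
    if pos.size == 0:
        return []
    breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
    bounds = np.concatenate(([0], breaks, [pos.size]))
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


# ---------------------------------------------------------------------------
# Segment scoring and recursive binary segmentation


def _segment_pair_diffs(
    matrix: PairedMethMatrix, lo: int, hi: int, per_site: bool = False
) -> np.ndarray:
    """Paired differences for segment [lo, hi).

    Default: one difference per patient (tumor segment mean minus normal
    segment mean, NA-aware).  ``per_site`` instead flattens to one
    difference per (site, patient) observation.
    """
    t = matrix.tumor[lo:hi]
    n = matrix.normal[lo:hi]
    if per_site:
        d = (t - n).ravel()
    else:
        with np.errstate(invalid="ignore"):
            d = np.nanmean(t, axis=0) - np.nanmean(n, axis=0)
    # round away float jitter so rank ties reflect signal, not arithmetic noise
    d = np.round(d, 12)
    return d[~np.isnan(d)]


def _score_segment(
    matrix: PairedMethMatrix,
    lo: int,
    hi: int,
    mode: str,
    per_site: bool,
) -> Tuple[float, float, float]:
    """(p, W, mean_diff) for segment [lo, hi)."""
    with np.errstate(invalid="ignore"):
        site_d = np.nanmean(matrix.tumor[lo:hi] - matrix.normal[lo:hi], axis=1)
        mean_diff = float(np.round(np.nanmean(site_d), 12))
    if mode == "paired":
        d = _segment_pair_diffs(matrix, lo, hi, per_site=per_site)
        if d.size == 0:
            return 1.0, 0.0, mean_diff
        res = signed_rank_test(d)
        return res.p, res.W, mean_diff
    # unpaired: Mann-Whitney U on per-sample segment means
    with np.errstate(invalid="ignore"):
        t = np.nanmean(matrix.tumor[lo:hi], axis=0)
        n = np.nanmean(matrix.normal[lo:hi], axis=0)
    t, n = t[~np.isnan(t)], n[~np.isnan(n)]
    if t.size == 0 or n.size == 0 or (np.ptp(t) == 0 and np.ptp(n) == 0
                                      and t[0] == n[0]):
        return 1.0, 0.0, mean_diff
    u, p = sps.mannwhitneyu(t, n, alternative="two-sided")
    return float(p), float(u), mean_diff


def _best_breakpoint(site_d: np.ndarray, lo: int, hi: int, min_cpg: int
                     ) -> Optional[int]:
    """Split index k in (lo, hi) maximizing |mean(d[lo:k]) - mean(d[k:hi])|."""
    valid = ~np.isnan(site_d[lo:hi])
    d = np.where(valid, site_d[lo:hi], 0.0)
    csum = np.cumsum(d)
    ccnt = np.cumsum(valid)
    total_sum, total_cnt = csum[-1], ccnt[-1]
    best_k, best_gap = None, -1.0
    for k in range(lo + min_cpg, hi - min_cpg + 1):
        i = k - lo - 1
        nl, nr = ccnt[i], total_cnt - ccnt[i]
        if nl == 0 or nr == 0:
            continue
        gap = abs(csum[i] / nl - (total_sum - csum[i]) / nr)
        if gap > best_gap:
            best_gap, best_k = gap, k
    return best_k


def detect_dmrs(
    matrix: PairedMethMatrix,
    mode: Literal["paired", "unpaired"] = "paired",
    min_cpg: int = 3,
    min_diff: float = 0.1,
    q_thresh: float = 0.05,
    max_gap: int = 300,
    per_site_pairs: bool = False,
) -> List[DMR]:
    """De-novo DMR detection on a paired methylation matrix.

    Within each gap-bounded block, recursive binary segmentation follows the
    per-site mean paired difference signal; every segment with >= min_cpg
    sites encountered during the recursion is a candidate, and recursion
    descends while a child segment attains a lower p-value than its parent.
    Candidates are BH-corrected; survivors must satisfy the CpG-count, mean
    difference and q-value filters and are reduced to a non-overlapping set
    greedily by ascending p (ties: longer region, then leftmost).
    """
    if mode == "paired" and matrix.n_patients < 2:
        raise InputError("paired mode requires >= 2 patients")
    with np.errstate(invalid="ignore"):
        site_d = np.nanmean(matrix.tumor - matrix.normal, axis=1)

    candidates: List[Tuple[int, int, float, float, float]] = []

    # Segments are compared on (p, -|mean_diff|): rank tests saturate, so in
    # low-noise data a diluted parent can tie the planted segment's p exactly
    # and only the mean difference separates them.
    def recurse(lo: int, hi: int) -> None:
        if hi - lo < min_cpg:
            return
        p, w, md = _score_segment(matrix, lo, hi, mode, per_site_pairs)
        candidates.append((lo, hi, p, w, md))
        if hi - lo < 2 * min_cpg:
            return
        k = _best_breakpoint(site_d, lo, hi, min_cpg)
        if k is None:
            return
        pl, _, mdl = _score_segment(matrix, lo, k, mode, per_site_pairs)
        pr, _, mdr = _score_segment(matrix, k, hi, mode, per_site_pairs)
        if min((pl, -abs(mdl)), (pr, -abs(mdr))) < (p, -abs(md)):
            recurse(lo, k)
            recurse(k, hi)

    for blo, bhi in presegment(matrix.positions, max_gap=max_gap):
        recurse(blo, bhi)

    if not candidates:
        return []
    qvals = bh_fdr([c[2] for c in candidates])
    passing = [
        (lo, hi, p, w, md, q)
        for (lo, hi, p, w, md), q in zip(candidates, qvals)
        if q <= q_thresh and abs(md) >= min_diff and md != 0.0
    ]
    # greedy non-overlap: best p first; ties by larger |mean_diff|, then
    # longer region, then leftmost start
    passing.sort(key=lambda c: (c[2], -abs(c[4]), -(c[1] - c[0]), c[0]))
    chosen: List[Tuple[int, int, float, float, float, float]] = []
    for cand in passing:
        if all(cand[1] <= lo or cand[0] >= hi for lo, hi, *_ in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])
    dmrs = []
    for lo, hi, p, w, md, q in chosen:
        dmrs.append(
            DMR(
                chrom=matrix.chrom,
                start=int(matrix.positions[lo]) - 1,
                end=int(matrix.positions[hi - 1]) + 1,
                n_cpg=hi - lo,
                mean_diff=md,
                W=w,
                p=p,
                q=q,
                direction="hyper" if md > 0 else "hypo",
            )
        )
    return dmrs


def merge_dmrs(
    dmrs: Sequence[DMR], max_dist: int = 200, same_direction: bool = True
) -> List[DMR]:
    """Merge coordinate-sorted DMRs closer than ``max_dist`` bp.

    Chains of (same-direction, by default) DMRs with pairwise gap < max_dist
    collapse to their span; CpG counts are summed, the mean difference is
    recomputed as a CpG-count-weighted mean, and the best (smallest) p/q and
    its W are kept.  Idempotent.
    """
    out: List[DMR] = []
    for dmr in sorted(dmrs, key=lambda d: (d.chrom, d.start)):
        prev = out[-1] if out else None
        if (
            prev is not None
            and dmr.chrom == prev.chrom
            and dmr.start - prev.end < max_dist
            and (not same_direction or dmr.direction == prev.direction)
        ):
            n = prev.n_cpg + dmr.n_cpg
            md = (prev.mean_diff * prev.n_cpg + dmr.mean_diff * dmr.n_cpg) / n
            best = prev if prev.p <= dmr.p else dmr
            out[-1] = replace(
                prev,
                end=max(prev.end, dmr.end),
                n_cpg=n,
                mean_diff=md,
                W=best.W,
                p=best.p,
                q=min(prev.q, dmr.q),
            )
        else:
            out.append(dmr)
    return out


# ---------------------------------------------------------------------------
# Tabular I/O


def matrix_from_table(df) -> PairedMethMatrix:
    """Build a matrix from a table with chrom, pos, tumor_<id>, normal_<id>."""
    import pandas as pd  # local: keep pandas optional at import time

    tumor_cols = sorted(c for c in df.columns if c.startswith("tumor_"))
    normal_cols = sorted(c for c in df.columns if c.startswith("normal_"))
    t_ids = [c[len("tumor_"):] for c in tumor_cols]
    n_ids = [c[len("normal_"):] for c in normal_cols]
    if t_ids != n_ids:
        raise InputError(
            f"unmatched sample sets: tumor {t_ids} vs normal {n_ids}"
        )
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise InputError("one chromosome per matrix; split the table first")
    df = df.sort_values("pos")
    return PairedMethMatrix(
        chrom=str(chroms[0]),
        positions=df["pos"].to_numpy(),
        tumor=df[tumor_cols].to_numpy(dtype=float),
        normal=df[normal_cols].to_numpy(dtype=float),
        patient_ids=tuple(t_ids),
    )


def write_dmrs(dmrs: Sequence[DMR], stream) -> None:
    """BED6+ output: chrom start end name score strand n_cpg mean_diff W p q direction."""
    stream.write(
        "#chrom\tstart\tend\tname\tscore\tstrand\tn_cpg\tmean_diff\tW\tp\tq\tdirection\n"
    )
    for i, d in enumerate(dmrs, 1):
        stream.write(
            f"{d.chrom}\t{d.start}\t{d.end}\tDMR{i}\t0\t.\t{d.n_cpg}"
            f"\t{d.mean_diff:.6g}\t{d.W:.6g}\t{d.p:.6g}\t{d.q:.6g}\t{d.direction}\n"
        )
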