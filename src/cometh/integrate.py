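"""Downstream statistics linking methylation to expression and annotation.

Correlation and signal normalization, DMR-to-gene assignment with the
five-way Hyper/Hypo x Up/Down/NS classification, CpG-island context bands,
interval utilities, motif occupancy, TFBM activity scores, and nested
variance-explained regression models.

All interval arguments are 0-based half-open (BED convention); distances
are end-to-start gaps in bp with 0 for overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Literal, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from cometh.dmr import DMR

Interval = Tuple[int, int]


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


# ---------------------------------------------------------------------------
# Correlation and signal normalization


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> Tuple[float, float]:
    """Pearson or Spearman correlation with a t-distribution p-value.

    NA pairs are dropped; requires >= 3 complete pairs and nonzero variance
    in both vectors.  Spearman is Pearson applied to average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined: zero variance in an input vector"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, p


def signal_strength(read_count: float, region_length_bp: float) -> float:
    """log2(read_count / region_length_bp * 1000 + 1)."""
    if region_length_bp <= 0:
        raise ValueError("region length must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return math.log2(read_count / region_length_bp * 1000.0 + 1.0)


# ---------------------------------------------------------------------------
# Genes, promoters, DMR-gene pairs


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: TSS and transcript span (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    span: Interval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or - for {self.gene_id}")
        if not (self.span[0] <= self.tss < self.span[1]):
            raise ValueError(
                f"TSS {self.tss} outside span {self.span} for {self.gene_id}"
            )


Category = Literal["Hyper-Down", "Hyper-Up", "Hypo-Down", "Hypo-Up", "NS"]


@dataclass(frozen=True)
class DMRGenePair:
    dmr: DMR
    gene_id: str
    distance_bp: int
    category: Category = "NS"


def promoter_of(gene: GeneModel, flank: int = 2000) -> Interval:
    """Symmetric promoter window around the TSS, clipped at 0.

    The window is strand-independent: [tss - flank, tss + flank).
    """
    return (max(0, gene.tss - flank), gene.tss + flank)


def interval_gap(a: Interval, b: Interval) -> int:
    """bp gap between half-open intervals; 0 when they overlap or touch."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0] - b[1], b[0] - a[1], 0)


def nearest_feature_distance(
    interval: Interval, features: Sequence[Interval]
) -> Optional[int]:
    """Distance to the nearest feature: 0 if overlapping, NA if none."""
    if not features:
        return None
    return min(interval_gap(interval, f) for f in features)


def assign_dmrs_to_genes(
    dmrs: Sequence[DMR],
    genes: Sequence[GeneModel],
    max_dist: int = 2000,
    anchor: Literal["span", "tss"] = "span",
) -> List[DMRGenePair]:
    """Assign each DMR to its single nearest gene closer than ``max_dist``.

    Distance is the gap between the DMR interval and the gene span (or the
    TSS point, with ``anchor='tss'``); strictly-less-than threshold; ties
    resolved by lexicographically smaller gene_id.  Unassignable DMRs are
    omitted.
    """
    pairs: List[DMRGenePair] = []
    for dmr in dmrs:
        best: Optional[Tuple[int, str]] = None
        for gene in genes:
            if gene.chrom != dmr.chrom:
                continue
            target = gene.span if anchor == "span" else (gene.tss, gene.tss + 1)
            d = interval_gap((dmr.start, dmr.end), target)
            if best is None or (d, gene.gene_id) < best:
                best = (d, gene.gene_id)
        if best is not None and best[0] < max_dist:
            pairs.append(
                DMRGenePair(dmr=dmr, gene_id=best[1], distance_bp=best[0])
            )
    return pairs


def classify_pairs(
    pairs: Sequence[DMRGenePair],
    deg_table: Mapping[str, Tuple[float, float]],
    fdr: float = 0.05,
) -> List[DMRGenePair]:
    """Label DMR-gene pairs with the five-way category.

    ``deg_table`` maps gene_id -> (log2FC, FDR).  A gene is Up when
    FDR < threshold and log2FC > 0, Down when FDR < threshold and
    log2FC < 0, otherwise NS (genes absent from the table included).
    """
    out: List[DMRGenePair] = []
    for pair in pairs:
        entry = deg_table.get(pair.gene_id)
        category: Category = "NS"
        if entry is not None:
            log2fc, gene_fdr = entry
            if gene_fdr < fdr and log2fc != 0:
                reg = "Up" if log2fc > 0 else "Down"
                meth = "Hyper" if pair.dmr.direction == "hyper" else "Hypo"
                category = f"{meth}-{reg}"  # type: ignore[assignment]
        out.append(replace(pair, category=category))
    return out


# ---------------------------------------------------------------------------
# CGI context and motif geometry


def cgi_context(position: int, cgis: Sequence[Interval]) -> str:
    """Band of a position relative to CpG islands.

    Inside an island -> 'CGI'; border distance in (0, 2000) -> 'shore';
    [2000, 4000] -> 'shelf'; beyond -> 'inteCGI'.
    """
    if not cgis:
        return "inteCGI"
    d = nearest_feature_distance((position, position + 1), list(cgis))
    if d == 0:
        return "CGI"
    if d < 2000:
        return "shore"
    if d <= 4000:
        return "shelf"
    return "inteCGI"


def merge_motifs(motif_intervals: Sequence[Interval]) -> List[Interval]:
    """Union of overlapping or bookended intervals on one chromosome."""
    merged: List[List[int]] = []
    for start, end in sorted(motif_intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


def motif_occupancy(
    dmr_interval: Interval, motifs: Sequence[Interval], extend: int = 200
) -> float:
    """Motif occupancy rate of a DMR extended by ``extend`` bp per flank.

    Sum of individual motif lengths clipped to the extended DMR (overlaps
    between motifs counted multiply — "all individual motifs") divided by
    the extended DMR length; can exceed 1 under heavy motif overlap.
    """
    lo = max(0, dmr_interval[0] - extend)
    hi = dmr_interval[1] + extend
    total = sum(
        max(0, min(hi, m_end) - max(lo, m_start)) for m_start, m_end in motifs
    )
    return total / (hi - lo)


# ---------------------------------------------------------------------------
# TFBM activity scores


@dataclass(frozen=True)
class ActivityRecord:
    """Per-gene motif activity: mean over motifs of r x log2(fold change)."""

    gene_id: str
    motif_ids: Tuple[str, ...]
    r_spearman: float  # mean r over retained motifs
    log2_fold_change: float
    activity: float


def activity_score(r: float, fold_change: float) -> float:
    """r x log2(fold change) for one motif."""
    if fold_change <= 0:
        raise UndefinedStatisticError("fold change must be positive")
    return r * math.log2(fold_change)


def gene_activity(
    gene_id: str,
    tfbm_methylation_by_motif: Mapping[str, Sequence[float]],
    expression_by_sample: Sequence[float],
    tumor_mask: Sequence[bool],
    expression_is_log2: bool = True,
) -> Optional[ActivityRecord]:
    """Activity record for one gene over its DMR motifs.

    For each motif, r = Spearman(TFBM methylation, expression) over all
    samples; the fold change is the ratio of mean linear-scale tumor
    expression to mean normal expression (input log2(FPKM+1) values are
    back-converted by default).  Motifs with r >= 0 are dropped (only
    inverse methylation-expression relations are of interest); with no
    motif left, returns None.  Requires >= 3 tumor and >= 3 normal samples.
    """
    expr = np.asarray(expression_by_sample, dtype=float)
    mask = np.asarray(tumor_mask, dtype=bool)
    if mask.shape != expr.shape:
        raise ValueError("tumor_mask must match expression length")
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("need >= 3 tumor and >= 3 normal samples")
    linear = (2.0**expr - 1.0) if expression_is_log2 else expr
    mean_normal = float(np.mean(linear[~mask]))
    mean_tumor = float(np.mean(linear[mask]))
    if mean_normal <= 0 or mean_tumor <= 0:
        raise UndefinedStatisticError(
            f"fold change undefined for {gene_id}: non-positive mean expression"
        )
    fc = mean_tumor / mean_normal
    kept_ids: List[str] = []
    kept_r: List[float] = []
    kept_act: List[float] = []
    for motif_id, meth in tfbm_methylation_by_motif.items():
        r, _ = correlation(meth, expr, method="spearman")
        if r >= 0:
            continue
        kept_ids.append(motif_id)
        kept_r.append(r)
        kept_act.append(activity_score(r, fc))
    if not kept_ids:
        return None
    return ActivityRecord(
        gene_id=gene_id,
        motif_ids=tuple(kept_ids),
        r_spearman=float(np.mean(kept_r)),
        log2_fold_change=math.log2(fc),
        activity=float(np.mean(kept_act)),
    )


def filter_by_activity(
    records: Sequence[ActivityRecord], threshold: float = 1.2
) -> List[ActivityRecord]:
    """Keep records with |activity| above the reporting threshold."""
    return [r for r in records if abs(r.activity) > threshold]


# ---------------------------------------------------------------------------
# Variance-explained regression models


@dataclass(frozen=True)
class VarianceModel:
    gene_id: str
    adj_r2_meth: float
    adj_r2_tf: float
    adj_r2_joint: float
    adj_r2_interaction: float
    raw_r2: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)


def _ols_r2(y: np.ndarray, X: np.ndarray, term_names: Sequence[str]) -> float:
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"collinear design: rank {rank} < {design.shape[1]} "
            f"(terms: intercept, {', '.join(term_names)})"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    return 1.0 - ss_res / ss_tot


def _adjust(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_explained(
    expression_y: Sequence[float],
    tfbm_meth: Sequence[float],
    tf_expression: Sequence[float],
    gene_id: str = "",
) -> VarianceModel:
    """Adjusted R² of four nested OLS models for a target gene's expression.

    Models: methylation only; TF expression only; both; both plus their
    interaction.  Complete cases only; n > 4 required.
    """
    y = np.asarray(expression_y, dtype=float)
    m = np.asarray(tfbm_meth, dtype=float)
    t = np.asarray(tf_expression, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(m) | np.isnan(t))
    y, m, t = y[keep], m[keep], t[keep]
    n = y.size
    if n <= 4:
        raise ValueError(f"need > 4 complete cases, got {n}")
    designs = [
        (m[:, None], ("meth",)),
        (t[:, None], ("tf",)),
        (np.column_stack([m, t]), ("meth", "tf")),
        (np.column_stack([m, t, m * t]), ("meth", "tf", "meth:tf")),
    ]
    raw = [_ols_r2(y, X, names) for X, names in designs]
    adj = [_adjust(r2, n, X.shape[1]) for r2, (X, _) in zip(raw, designs)]
    return VarianceModel(
        gene_id=gene_id,
        adj_r2_meth=adj[0],
        adj_r2_tf=adj[1],
        adj_r2_joint=adj[2],
        adj_r2_interaction=adj[3],
        raw_r2=tuple(raw),  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# DEG table reader


def read_deg_table(df) -> Dict[str, Tuple[float, float]]:
    """Validate and index a DEG table with columns gene_id, log2FC, FDR."""
    required = {"gene_id", "log2FC", "FDR"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    return {
        str(row.gene_id): (float(row.log2FC), float(row.FDR))
        for row in df.itertuples(index=False)
    }
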