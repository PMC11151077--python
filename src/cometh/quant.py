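"""Per-site and per-region methylation quantifiers.

Four quantifiers over a site pileup with n_m methylated reads (>=1 M call),
n_u all-U reads and n_p partially methylated reads unmethylated at the site:

* ``wemics``  A / (A + n_u), where A sums per-read weights m/c — m the
  length of the maximal consecutive-M run containing the site (m = 1 when
  the site's own call is U), c the read's CpG count.
* ``chalm``   n_m / (n_m + n_u)
* ``camda``   n_p / (n_m + n_u)
* ``meanm``   (n_m - n_p) / (n_m + n_u)

All four lie in [0, 1]; meanm + camda == chalm identically and
wemics <= chalm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from cometh.reads import MethRead, SitePileup, build_pileups


class Method(str, enum.Enum):
    WEMICS = "wemics"
    MEANM = "meanm"
    CHALM = "chalm"
    CAMDA = "camda"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_METHODS: Tuple[Method, ...] = (
    Method.WEMICS,
    Method.MEANM,
    Method.CHALM,
    Method.CAMDA,
)


@dataclass(frozen=True)
class RunWeight:
    """Co-methylation run weight of one methylated read at one site."""

    c: int  # CpG count of the read
    m: int  # consecutive-M run length containing the site (1 if call is U)
    w: float  # m / c

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.c):
            raise ValueError(f"run length {self.m} outside [1, {self.c}]")


@dataclass(frozen=True)
class SiteQuant:
    """All four methylation rates of one CpG site."""

    chrom: str
    position: int
    n_m: int
    n_u: int
    n_p: int
    weight_sum: float  # A = sum of run weights over methylated reads
    values: Dict[Method, float]


def run_weight(read: MethRead, position: int) -> RunWeight:
    """Weight of a methylated read at ``position``: m/c.

    m is the length of the maximal run of consecutive M calls (in read CpG
    order) containing the site, or 1 if the site's own call is U.  The read
    must carry at least one M call; all-U reads belong in the unmethylated
    group and are a contract error here.
    """
    if not read.is_methylated:
        raise ValueError(
            f"read {read.read_id!r} has no methylated CpG; route it to n_u"
        )
    idx = read.index_of(position)
    calls = read.calls
    if calls[idx] == "U":
        m = 1
    else:
        lo = idx
        while lo > 0 and calls[lo - 1] == "M":
            lo -= 1
        hi = idx
        while hi < len(calls) - 1 and calls[hi + 1] == "M":
            hi += 1
        m = hi - lo + 1
    c = read.n_cpg
    return RunWeight(c=c, m=m, w=m / c)


def quantify_site(
    pileup: SitePileup, method: Optional[Method] = None
) -> SiteQuant:
    """Quantify one site with all four methods (or report just ``method``).

    Requires coverage >= 1; a zero-coverage site is undefined (missing),
    never 0, and the caller should not construct such a pileup.
    """
    n_m, n_u, n_p = pileup.n_m, pileup.n_u, pileup.n_p
    total = n_m + n_u
    if total < 1:
        raise ValueError(
            f"zero coverage at {pileup.chrom}:{pileup.position}; "
            "value is missing, not 0"
        )
    weight_sum = sum(
        run_weight(r, pileup.position).w for r in pileup.meth_reads
    )
    values = {
        Method.WEMICS: weight_sum / (weight_sum + n_u) if (weight_sum + n_u) else 0.0,
        Method.CHALM: n_m / total,
        Method.CAMDA: n_p / total,
        Method.MEANM: (n_m - n_p) / total,
    }
    if method is not None:
        values = {method: values[method]}
    return SiteQuant(
        chrom=pileup.chrom,
        position=pileup.position,
        n_m=n_m,
        n_u=n_u,
        n_p=n_p,
        weight_sum=weight_sum,
        values=values,
    )


def quantify_sites(
    reads: Iterable[MethRead], min_coverage: int = 1
) -> List[SiteQuant]:
    """Convenience: pileups plus all-method quantification, position-sorted."""
    return [
        quantify_site(p) for p in build_pileups(reads, min_coverage).values()
    ]


def quantify_region(
    reads: Sequence[MethRead],
    region: Tuple[str, int, int],
    method: Method,
    aggregation: str = "mean_of_sites",
    min_site_coverage: int = 5,
) -> Optional[float]:
    """Aggregate a quantifier over a half-open region (1-based start/end).

    ``mean_of_sites`` averages per-site values over CpGs inside the region
    with coverage >= ``min_site_coverage``; ``pooled_reads`` (CHALM/CAMDA
    only) treats the region as one unit over all reads touching it.  Returns
    None when no qualifying site (or read) exists.
    """
    chrom, start, end = region
    if aggregation == "mean_of_sites":
        pileups = build_pileups(
            [r for r in reads if r.chrom == chrom], min_coverage=min_site_coverage
        )
        vals = [
            quantify_site(p, method).values[method]
            for pos, p in pileups.items()
            if start <= pos < end
        ]
        return float(np.mean(vals)) if vals else None
    if aggregation == "pooled_reads":
        if method not in (Method.CHALM, Method.CAMDA):
            raise ValueError(
                f"pooled_reads aggregation is defined for CHALM/CAMDA only, "
                f"not {method.value}"
            )
        covering = [
            r
            for r in reads
            if r.chrom == chrom
            and any(start <= p < end for p in r.cpg_positions)
        ]
        if not covering:
            return None
        n_m = sum(1 for r in covering if r.is_methylated)
        n_u = len(covering) - n_m
        if method is Method.CHALM:
            return n_m / (n_m + n_u)
        # region-level CAMDA: partially methylated reads (>=1 M and >=1 U
        # among in-region calls) over all covering reads
        n_p = 0
        for r in covering:
            in_region = [
                c for p, c in zip(r.cpg_positions, r.calls) if start <= p < end
            ]
            if "M" in r.calls and "U" in in_region:
                n_p += 1
        return n_p / (n_m + n_u)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def subsample_stability(
    reads: Sequence[MethRead],
    fraction: float,
    seed: int,
    pre_cov: int = 10,
    post_cov: int = 5,
    cov_diff: int = 5,
) -> List[Dict]:
    """Per-site before-minus-after deltas under read subsampling.

    Reads are subsampled without replacement at ``fraction``; sites must
    pass three coverage filters (pre-sampling coverage >= ``pre_cov``,
    post-sampling coverage >= ``post_cov``, coverage difference >=
    ``cov_diff``) to be reported.  One record per passing site with a delta
    per method.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    n_keep = int(round(fraction * len(reads)))
    keep_idx = rng.choice(len(reads), size=n_keep, replace=False)
    kept = [reads[i] for i in sorted(keep_idx)]

    before = {q.position: q for q in quantify_sites(reads, min_coverage=1)}
    after = {q.position: q for q in quantify_sites(kept, min_coverage=1)}

    out: List[Dict] = []
    for pos, bq in before.items():
        aq = after.get(pos)
        cov_b = bq.n_m + bq.n_u
        cov_a = (aq.n_m + aq.n_u) if aq is not None else 0
        if cov_b < pre_cov or cov_a < post_cov or (cov_b - cov_a) < cov_diff:
            continue
        rec: Dict = {
            "chrom": bq.chrom,
            "position": pos,
            "coverage_before": cov_b,
            "coverage_after": cov_a,
        }
        for method in ALL_METHODS:
            rec[f"delta_{method.value}"] = (
                bq.values[method] - aq.values[method]
            )
        out.append(rec)
    return out
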