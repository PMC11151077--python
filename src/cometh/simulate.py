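"""Synthetic paired bisulfite read sets with controlled co-methylation.

Reads are drawn from a two-state Markov chain over a region's CpG sites:
stationary methylation probability ``theta`` and persistence ``rho`` blended
so that P(M -> M) = rho + (1 - rho) * theta and P(U -> M) = (1 - rho) * theta
— the stationary distribution stays ``theta`` for every persistence level.
A paired cohort plants tumor-vs-normal shifts in chosen regions and records
the ground truth; an expression layer with a target methylation correlation
completes the end-to-end test bed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Mapping, Optional, Sequence, Tuple

if TYPE_CHECKING:  # pragma: no cover
    from cometh.dmr import PairedMethMatrix
    from cometh.quant import Method

import numpy as np

from cometh.reads import MethRead


@dataclass(frozen=True)
class SimRegionSpec:
    """Generative parameters for one genomic region."""

    chrom: str
    cpg_positions: Tuple[int, ...]
    theta_normal: float
    delta: float = 0.0  # planted tumor shift
    rho: float = 0.0  # within-read methylation persistence
    coverage_lambda: float = 30.0  # target mean reads per site
    cpgs_per_read_mean: float = 5.0
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.cpg_positions) < 1:
            raise ValueError("region needs >= 1 CpG position")
        if not (0.0 <= self.theta_normal <= 1.0):
            raise ValueError("theta_normal must be in [0, 1]")
        if not (0.0 <= self.theta_normal + self.delta <= 1.0):
            raise ValueError("theta_normal + delta must stay in [0, 1]")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))


@dataclass(frozen=True)
class TruthRecord:
    region: str
    chrom: str
    start_pos: int  # first CpG position (1-based)
    end_pos: int  # last CpG position (1-based)
    is_dmr: bool
    delta: float
    direction: str  # hyper / hypo / none


@dataclass
class CohortConfig:
    n_patients: int
    regions: List[SimRegionSpec]
    patient_sd: float = 0.05  # patient-level jitter on theta_normal


def _markov_calls(
    n_reads: int, lengths: np.ndarray, theta: float, rho: float,
    rng: np.random.Generator
) -> List[str]:
    """Vectorized two-state chain: matrix of M/U calls, row i truncated to lengths[i]."""
    lmax = int(lengths.max())
    u = rng.random((n_reads, lmax))
    state = np.zeros((n_reads, lmax), dtype=bool)
    state[:, 0] = u[:, 0] < theta
    p_mm = rho + (1.0 - rho) * theta
    p_um = (1.0 - rho) * theta
    for k in range(1, lmax):
        thresh = np.where(state[:, k - 1], p_mm, p_um)
        state[:, k] = u[:, k] < thresh
    out = []
    for i in range(n_reads):
        li = int(lengths[i])
        out.append("".join("M" if s else "U" for s in state[i, :li]))
    return out


def simulate_reads(
    spec: SimRegionSpec,
    condition: str,
    n_reads: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    read_prefix: str = "r",
) -> List[MethRead]:
    """Draw ``n_reads`` epiallele reads from one region.

    ``condition`` is 'normal' or 'tumor'; tumor adds the planted delta to
    the stationary methylation level.  Each read starts at a uniformly
    chosen CpG and spans 1 + Poisson(mean - 1) sites, truncated at the
    region end.
    """
    if condition not in ("normal", "tumor"):
        raise ValueError(f"condition must be normal or tumor, got {condition!r}")
    theta = spec.theta_normal + (spec.delta if condition == "tumor" else 0.0)
    theta = float(np.clip(theta, 0.0, 1.0))
    if rng is None:
        rng = np.random.default_rng(seed)
    n_cpg = len(spec.cpg_positions)
    if n_reads == 0:
        return []
    starts = rng.integers(0, n_cpg, size=n_reads)
    lengths = 1 + rng.poisson(max(spec.cpgs_per_read_mean - 1.0, 0.0), size=n_reads)
    lengths = np.minimum(lengths, n_cpg - starts)
    calls = _markov_calls(n_reads, lengths, theta, spec.rho, rng)
    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        li = int(lengths[i])
        reads.append(
            MethRead(
                read_id=f"{read_prefix}{i + 1}",
                chrom=spec.chrom,
                cpg_positions=spec.cpg_positions[s : s + li],
                calls=calls[i],
                strand="+",
            )
        )
    return reads


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample stream from a stable hash, so adding a sample never
    reshuffles the others."""
    digest = hashlib.sha256(sample_id.encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng([seed, *words])


def reads_for_coverage(spec: SimRegionSpec) -> int:
    """Read count giving the target mean per-site coverage."""
    n_cpg = len(spec.cpg_positions)
    return max(1, round(spec.coverage_lambda * n_cpg / spec.cpgs_per_read_mean))


def simulate_paired_cohort(
    config: CohortConfig, seed: int
) -> Tuple[Dict[str, List[MethRead]], List[TruthRecord]]:
    """Paired tumor/normal read sets for every patient plus the truth table.

    Per patient and region, the normal methylation level is drawn
    Normal(theta_normal, patient_sd) clipped to a feasible range; the tumor
    level adds the planted delta.  Sample keys are '<patient>_tumor' and
    '<patient>_normal'.
    """
    samples: Dict[str, List[MethRead]] = {}
    clipped = 0
    draws = 0
    for p in range(1, config.n_patients + 1):
        pid = f"p{p:03d}"
        for condition in ("normal", "tumor"):
            key = f"{pid}_{condition}"
            rng = _sample_rng(seed, key)
            all_reads: List[MethRead] = []
            for ridx, spec in enumerate(config.regions):
                # theta stream keyed by (patient, region) only: tumor and
                # normal of one patient share the same baseline draw
                theta_rng = _sample_rng(seed, f"{pid}_theta_{ridx}")
                theta_n = float(
                    theta_rng.normal(spec.theta_normal, config.patient_sd)
                )
                draws += 1
                lo, hi = 0.0, 1.0 - max(spec.delta, 0.0)
                if spec.delta < 0:
                    lo = -spec.delta
                if not (lo <= theta_n <= hi):
                    clipped += 1
                    theta_n = float(np.clip(theta_n, lo, hi))
                patient_spec = SimRegionSpec(
                    chrom=spec.chrom,
                    cpg_positions=spec.cpg_positions,
                    theta_normal=theta_n,
                    delta=spec.delta,
                    rho=spec.rho,
                    coverage_lambda=spec.coverage_lambda,
                    cpgs_per_read_mean=spec.cpgs_per_read_mean,
                    name=spec.name,
                )
                all_reads.extend(
                    simulate_reads(
                        patient_spec,
                        condition,
                        reads_for_coverage(spec),
                        rng=rng,
                        read_prefix=f"{key}_{spec.name or f'reg{ridx}'}_",
                    )
                )
            samples[key] = all_reads
    if draws and clipped / draws > 0.10:
        import warnings

        warnings.warn(
            f"{clipped}/{draws} patient-level theta draws were infeasible and "
            "clipped; consider a smaller patient_sd or delta",
            stacklevel=2,
        )
    truth = [
        TruthRecord(
            region=spec.name or f"{spec.chrom}:{spec.cpg_positions[0]}",
            chrom=spec.chrom,
            start_pos=spec.cpg_positions[0],
            end_pos=spec.cpg_positions[-1],
            is_dmr=spec.delta != 0.0,
            delta=spec.delta,
            direction="hyper" if spec.delta > 0 else
                      ("hypo" if spec.delta < 0 else "none"),
        )
        for spec in config.regions
    ]
    return samples, truth


def cohort_site_matrix(
    samples: Mapping[str, Sequence[MethRead]],
    method: "Method" = None,
    min_coverage: int = 1,
) -> "PairedMethMatrix":
    """Quantify every sample per site and assemble the paired matrix.

    ``samples`` maps '<patient>_tumor' / '<patient>_normal' to read lists on
    one chromosome (as produced by :func:`simulate_paired_cohort`).  Sites
    missing or under-covered in a sample are NaN.
    """
    from cometh.dmr import PairedMethMatrix
    from cometh.quant import Method, quantify_sites

    if method is None:
        method = Method.MEANM
    patients = sorted({k.rsplit("_", 1)[0] for k in samples})
    per_sample: Dict[str, Dict[int, float]] = {}
    chrom = None
    for key, reads in samples.items():
        vals: Dict[int, float] = {}
        for sq in quantify_sites(reads, min_coverage=min_coverage):
            vals[sq.position] = sq.values[method]
            chrom = sq.chrom
        per_sample[key] = vals
    positions = sorted({pos for vals in per_sample.values() for pos in vals})
    n_sites, n_pat = len(positions), len(patients)
    tumor = np.full((n_sites, n_pat), np.nan)
    normal = np.full((n_sites, n_pat), np.nan)
    pos_idx = {p: i for i, p in enumerate(positions)}
    for j, pid in enumerate(patients):
        for layer, cond in ((tumor, "tumor"), (normal, "normal")):
            for pos, v in per_sample.get(f"{pid}_{cond}", {}).items():
                layer[pos_idx[pos], j] = v
    return PairedMethMatrix(
        chrom=chrom or "chrSim",
        positions=np.asarray(positions, dtype=np.int64),
        tumor=tumor,
        normal=normal,
        patient_ids=tuple(patients),
    )


def simulate_expression(
    promoter_methylation_by_sample: Sequence[float],
    r_target: float,
    seed: int,
    baseline: float = 5.0,
    scale: float = 2.0,
) -> np.ndarray:
    """Expression values with a planted methylation correlation.

    The population Pearson correlation with the methylation vector equals
    ``r_target`` (open interval (-1, 1); the endpoints would require zero
    noise).  Output is on a log2(FPKM+1)-like scale, clipped at 0.
    """
    if not (-1.0 < r_target < 1.0):
        raise ValueError("r_target must lie in the open interval (-1, 1)")
    meth = np.asarray(promoter_methylation_by_sample, dtype=float)
    if meth.size < 3 or np.ptp(meth) == 0:
        raise ValueError("methylation vector must have variance and n >= 3")
    rng = np.random.default_rng(seed)
    z = (meth - meth.mean()) / meth.std()
    noise = rng.standard_normal(meth.size)
    raw = r_target * z + np.sqrt(1.0 - r_target**2) * noise
    return np.maximum(0.0, baseline + scale * raw)
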