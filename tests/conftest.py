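"""Shared fixtures: random pileup generation and a naive rational oracle.

The oracle computes all four quantifiers directly from the call strings with
exact Fraction arithmetic and deliberately shares no code with the
production path.
"""

from __future__ import annotations

import random
from fractions import Fraction
from typing import Dict, List, Tuple

import pytest

from cometh.reads import MethRead, SitePileup


# ---------------------------------------------------------------------------
# Naive direct-from-definition oracle (exact rational arithmetic)


def oracle_run_length(calls: str, idx: int) -> int:
    """Maximal consecutive-M run containing idx, by brute-force expansion."""
    if calls[idx] != "M":
        return 1
    best = 0
    for lo in range(idx + 1):
        for hi in range(idx, len(calls)):
            if all(c == "M" for c in calls[lo : hi + 1]):
                best = max(best, hi - lo + 1)
    return best


def oracle_quantify(
    reads_calls: List[Tuple[Tuple[int, ...], str]], position: int
) -> Dict[str, Fraction]:
    """All four quantifiers at ``position`` from (positions, calls) pairs."""
    covering = [(p, c) for p, c in reads_calls if position in p]
    meth = [(p, c) for p, c in covering if "M" in c]
    unmeth = [(p, c) for p, c in covering if "M" not in c]
    n_m, n_u = len(meth), len(unmeth)
    n_p = sum(1 for p, c in meth if c[p.index(position)] == "U")
    assert n_m + n_u >= 1
    A = Fraction(0)
    for p, c in meth:
        idx = p.index(position)
        m = oracle_run_length(c, idx)
        A += Fraction(m, len(c))
    total = n_m + n_u
    return {
        "wemics": A / (A + n_u),
        "chalm": Fraction(n_m, total),
        "camda": Fraction(n_p, total),
        "meanm": Fraction(n_m - n_p, total),
    }


# ---------------------------------------------------------------------------
# Random pileup generation


def random_pileup(
    rng: random.Random, position: int = 500, chrom: str = "chrT"
) -> Tuple[SitePileup, List[Tuple[Tuple[int, ...], str]]]:
    """A random pileup at ``position`` plus its raw (positions, calls) pairs."""
    n_reads = rng.randint(1, 12)
    raw: List[Tuple[Tuple[int, ...], str]] = []
    pileup = SitePileup(chrom=chrom, position=position)
    for i in range(n_reads):
        c = rng.randint(1, 8)
        offset = rng.randint(0, c - 1)
        positions = tuple(position + (k - offset) * 10 for k in range(c))
        calls = "".join(rng.choice("MU") for _ in range(c))
        raw.append((positions, calls))
        pileup.add(
            MethRead(
                read_id=f"r{i}",
                chrom=chrom,
                cpg_positions=positions,
                calls=calls,
            )
        )
    return pileup, raw


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)


@pytest.fixture
def two_read_pileup() -> SitePileup:
    """The worked two-read example: MMUM and UUUU over the same 4 CpGs."""
    positions = (100, 105, 110, 120)
    p = SitePileup(chrom="chr1", position=100)
    p.add(MethRead("r1", "chr1", positions, "MMUM"))
    p.add(MethRead("r2", "chr1", positions, "UUUU"))
    return p
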