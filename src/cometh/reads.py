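"""Core read-level domain types: per-read CpG calls and per-site pileups.

Coordinates are 1-based positions of the forward-strand C of each CpG
throughout the in-memory model; on-disk BED/bedGraph output converts to
0-based half-open intervals at write time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

VALID_CALLS = frozenset("MU")


class FormatError(ValueError):
    """Malformed input record (bad fixture line, inconsistent fields)."""


@dataclass(frozen=True)
class MethRead:
    """One sequenced read's ordered CpG methylation calls.

    ``calls`` is a string over {M, U}, one character per entry of
    ``cpg_positions`` (strictly increasing, 1-based forward-strand C
    coordinates).
    """

    read_id: str
    chrom: str
    cpg_positions: Tuple[int, ...]
    calls: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise FormatError("chrom must be non-empty")
        if len(self.calls) != len(self.cpg_positions):
            raise FormatError(
                f"call length {len(self.calls)} ≠ "
                f"{len(self.cpg_positions)} positions (read {self.read_id!r})"
            )
        if len(self.cpg_positions) < 1:
            raise FormatError(f"read {self.read_id!r} has no CpG calls")
        if any(b <= a for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise FormatError(
                f"positions not strictly increasing (read {self.read_id!r})"
            )
        bad = set(self.calls) - VALID_CALLS
        if bad:
            raise FormatError(
                f"invalid call characters {sorted(bad)} (read {self.read_id!r})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or - (read {self.read_id!r})")
        object.__setattr__(self, "cpg_positions", tuple(self.cpg_positions))

    @property
    def n_cpg(self) -> int:
        """Number of CpG sites on the read (the c of the run weight)."""
        return len(self.cpg_positions)

    @property
    def is_methylated(self) -> bool:
        """True if the read carries at least one methylated CpG call."""
        return "M" in self.calls

    def index_of(self, position: int) -> int:
        """Index of ``position`` on this read, or KeyError if not covered."""
        try:
            return self.cpg_positions.index(position)
        except ValueError:
            raise KeyError(
                f"position {position} not covered by read {self.read_id!r}"
            ) from None

    def call_at(self, position: int) -> str:
        return self.calls[self.index_of(position)]


@dataclass
class SitePileup:
    """All reads covering one CpG site, split by read-level methylation.

    ``meth_reads`` hold at least one M call anywhere on the read,
    ``unmeth_reads`` are all-U.  ``n_p`` counts members of ``meth_reads``
    whose call at *this* site is U (partially methylated reads that are
    unmethylated here).
    """

    chrom: str
    position: int
    meth_reads: List[MethRead] = field(default_factory=list)
    unmeth_reads: List[MethRead] = field(default_factory=list)

    @property
    def n_m(self) -> int:
        return len(self.meth_reads)

    @property
    def n_u(self) -> int:
        return len(self.unmeth_reads)

    @property
    def n_p(self) -> int:
        return sum(1 for r in self.meth_reads if r.call_at(self.position) == "U")

    @property
    def coverage(self) -> int:
        return self.n_m + self.n_u

    def add(self, read: MethRead) -> None:
        if self.position not in read.cpg_positions:
            raise ValueError(
                f"read {read.read_id!r} does not cover position {self.position}"
            )
        (self.meth_reads if read.is_methylated else self.unmeth_reads).append(read)


def build_pileups(
    reads: Iterable[MethRead], min_coverage: int = 1
) -> Dict[int, SitePileup]:
    """Group reads by covered CpG position into :class:`SitePileup` objects.

    All reads must share one chromosome.  Sites covered by fewer than
    ``min_coverage`` reads are dropped.  Returns a position-sorted mapping.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    pileups: Dict[int, SitePileup] = {}
    chrom: str | None = None
    for read in reads:
        if chrom is None:
            chrom = read.chrom
        elif read.chrom != chrom:
            raise ValueError(
                f"build_pileups expects one chromosome, got {chrom!r} and "
                f"{read.chrom!r}"
            )
        for pos in read.cpg_positions:
            pileup = pileups.get(pos)
            if pileup is None:
                pileup = pileups[pos] = SitePileup(chrom=read.chrom, position=pos)
            pileup.add(read)
    return {
        pos: p
        for pos, p in sorted(pileups.items())
        if p.coverage >= min_coverage
    }
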