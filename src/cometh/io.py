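"""Parsing and serialization of read-level methylation calls.

Two input dialects are supported:

* READPAT — a deterministic tab-separated text fixture format, one read per
  line: ``read_id  chrom  strand  pos1,pos2,...  CALLS`` with calls over
  {M, U} and 1-based forward-strand C coordinates.  ``#`` lines are comments.
* SAM/BAM with a per-base methylation call string tag (default ``XM``) using
  the Bismark alphabet: ``Z`` methylated CpG, ``z`` unmethylated CpG; all
  other characters (x/X/h/H/u/U/.) are non-CpG context and ignored.

Per-site output is written as bedGraph (0-based half-open CpG dinucleotide
intervals) or TSV.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import IO, Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from cometh.reads import FormatError, MethRead

# ---------------------------------------------------------------------------
# READPAT fixture format


def parse_readpat(stream: IO[str] | Iterable[str]) -> List[MethRead]:
    """Parse the READPAT text format into :class:`MethRead` records.

    Raises :class:`FormatError` naming the offending line on any
    inconsistency (call/position length mismatch, non-increasing positions,
    characters outside {M, U}).
    """
    reads: List[MethRead] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(
                f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        read_id, chrom, strand, pos_field, calls = fields
        try:
            positions = tuple(int(p) for p in pos_field.split(","))
        except ValueError as exc:
            raise FormatError(f"line {lineno}: bad position list: {exc}") from None
        if len(calls) != len(positions):
            raise FormatError(
                f"line {lineno}: call length {len(calls)} ≠ "
                f"{len(positions)} positions"
            )
        try:
            reads.append(
                MethRead(
                    read_id=read_id,
                    chrom=chrom,
                    cpg_positions=positions,
                    calls=calls,
                    strand=strand,
                )
            )
        except FormatError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return reads


def write_readpat(reads: Iterable[MethRead], stream: IO[str]) -> None:
    """Serialize reads to READPAT; round-trips exactly with parse_readpat."""
    for read in reads:
        stream.write(
            "\t".join(
                (
                    read.read_id,
                    read.chrom,
                    read.strand,
                    ",".join(str(p) for p in read.cpg_positions),
                    read.calls,
                )
            )
            + "\n"
        )


# ---------------------------------------------------------------------------
# SAM/BAM with Bismark-dialect methylation call tag

_CALL_FOR = {"Z": "M", "z": "U"}
_UNSUPPORTED_CIGAR = {3, 5, 6}  # N, H, P


@dataclass
class AlignmentStats:
    """Counters accumulated while reading an alignment file."""

    parsed: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_supplementary: int = 0
    skipped_duplicate: int = 0
    skipped_no_tag: int = 0
    skipped_bad_record: int = 0
    skipped_no_cpg: int = 0
    errors: List[str] = field(default_factory=list)


def parse_bisulfite_alignments(
    path: str,
    region: Optional[Tuple[str, int, int]] = None,
    tag: str = "XM",
    strict: bool = False,
    keep_duplicates: bool = False,
    clip_mate_overlap: bool = True,
    stats: Optional[AlignmentStats] = None,
) -> List[MethRead]:
    """Extract per-read CpG calls from a SAM/BAM file carrying a call-string tag.

    Forward-strand alignments map each Z/z to its reference coordinate
    (1-based); reverse-strand alignments carry the call on the G of the CpG,
    so positions are shifted by -1 onto the forward-strand C — both strands
    address the same CpG unit.  Unmapped, secondary, supplementary and (by
    default) duplicate-flagged records are skipped.  Records whose tag length
    disagrees with the query length are skipped and counted, or abort the
    parse under ``strict``.

    ``region`` is (chrom, start, end) in 0-based half-open reference
    coordinates, as accepted by :func:`pysam.AlignmentFile.fetch`.

    Paired-end mates sharing a read name have overlapping CpG positions
    clipped from the later mate by default (each mate still yields its own
    record for the non-overlapping part), so one fragment never counts a
    CpG twice; disable with ``clip_mate_overlap=False``.
    """
    import pysam

    if stats is None:
        stats = AlignmentStats()
    reads: List[MethRead] = []
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        if region is not None:
            it = af.fetch(region[0], region[1], region[2])
        else:
            it = af.fetch(until_eof=True)
        for aln in it:
            if aln.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if aln.is_secondary:
                stats.skipped_secondary += 1
                continue
            if aln.is_supplementary:
                stats.skipped_supplementary += 1
                continue
            if aln.is_duplicate and not keep_duplicates:
                stats.skipped_duplicate += 1
                continue
            if not aln.has_tag(tag):
                stats.skipped_no_tag += 1
                continue
            bad_ops = {op for op, _ in (aln.cigartuples or ())} & _UNSUPPORTED_CIGAR
            if bad_ops:
                msg = (
                    f"record {aln.query_name!r}: unsupported CIGAR op(s) "
                    f"{sorted(bad_ops)}"
                )
                if strict:
                    raise FormatError(msg)
                stats.skipped_bad_record += 1
                stats.errors.append(msg)
                continue
            call_string = str(aln.get_tag(tag))
            if len(call_string) != aln.query_length:
                msg = (
                    f"record {aln.query_name!r}: tag length {len(call_string)} ≠ "
                    f"query length {aln.query_length}"
                )
                if strict:
                    raise FormatError(msg)
                stats.skipped_bad_record += 1
                stats.errors.append(msg)
                continue
            shift = -1 if aln.is_reverse else 0
            sites: List[Tuple[int, str]] = []
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                call = _CALL_FOR.get(call_string[qpos])
                if call is not None:
                    # rpos is 0-based; +1 to 1-based, then strand shift
                    sites.append((rpos + 1 + shift, call))
            if not sites:
                stats.skipped_no_cpg += 1
                continue
            sites.sort()
            reads.append(
                MethRead(
                    read_id=aln.query_name or "",
                    chrom=af.get_reference_name(aln.reference_id),
                    cpg_positions=tuple(p for p, _ in sites),
                    calls="".join(c for _, c in sites),
                    strand="-" if aln.is_reverse else "+",
                )
            )
            stats.parsed += 1
    if clip_mate_overlap:
        reads = _clip_mate_overlap(reads)
    return reads


def _clip_mate_overlap(reads: List[MethRead]) -> List[MethRead]:
    """Drop CpG positions a later mate shares with an earlier same-name mate."""
    seen: Dict[Tuple[str, str], set] = {}
    out: List[MethRead] = []
    for read in reads:
        key = (read.read_id, read.chrom)
        covered = seen.setdefault(key, set())
        if covered & set(read.cpg_positions):
            kept = [
                (p, c)
                for p, c in zip(read.cpg_positions, read.calls)
                if p not in covered
            ]
            if not kept:
                continue
            read = MethRead(
                read_id=read.read_id,
                chrom=read.chrom,
                cpg_positions=tuple(p for p, _ in kept),
                calls="".join(c for _, c in kept),
                strand=read.strand,
            )
        covered.update(read.cpg_positions)
        out.append(read)
    return out


# ---------------------------------------------------------------------------
# Per-site output tables


def write_site_table(
    results: Sequence[Dict],
    stream: IO[str] = sys.stdout,
    format: str = "tsv",
) -> None:
    """Write per-site quantification records as bedGraph or TSV.

    Each record is a mapping with keys ``chrom``, ``position`` (1-based C),
    ``value``, and for TSV additionally ``n_m``, ``n_u``, ``n_p``,
    ``method``.  bedGraph intervals span the CpG dinucleotide: 0-based
    half-open ``[position-1, position+1)``.  Values outside [0, 1] are
    refused — they signal an upstream bug.
    """
    if format not in ("bedGraph", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    for rec in results:
        v = rec["value"]
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError(
                f"methylation value {v} outside [0, 1] at "
                f"{rec['chrom']}:{rec['position']}"
            )
    if format == "bedGraph":
        for rec in results:
            if rec["value"] is None:
                continue
            stream.write(
                f"{rec['chrom']}\t{rec['position'] - 1}\t{rec['position'] + 1}"
                f"\t{_fmt(rec['value'])}\n"
            )
    else:
        stream.write("chrom\tposition\tmethod\tvalue\tn_m\tn_u\tn_p\n")
        for rec in results:
            value = "NA" if rec["value"] is None else _fmt(rec["value"])
            stream.write(
                f"{rec['chrom']}\t{rec['position']}\t{rec.get('method', 'NA')}"
                f"\t{value}\t{rec.get('n_m', 'NA')}\t{rec.get('n_u', 'NA')}"
                f"\t{rec.get('n_p', 'NA')}\n"
            )


def _fmt(x: float) -> str:
    return f"{x:.6g}"
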