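"""Sequence and alignment I/O with a single coordinate convention.

All coordinates inside the package are 0-based, half-open, on both reads
and references — the PAF convention. SAM input is converted on the fly;
BED6 is emitted natively. Any 1-based coordinate in human-readable output
is labelled as such where it is written.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence with explicit topology.

    Bacterial chromosomes and most plasmids are circular; donor contigs
    may be linear. Topology decides whether flank extraction and window
    arithmetic may wrap the origin.
    """

    id: str
    seq: str
    topology: str = "circular"  # {"circular", "linear"}

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"GenomeRecord {self.id!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"invalid topology {self.topology!r}")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"GenomeRecord {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin on circular records.

        ``start`` may be negative and ``end`` may exceed the length on a
        circular record; on a linear record any overrun is an error.
        """
        n = len(self.seq)
        if end <= start:
            raise ValueError("fetch requires end > start")
        length = end - start
        if length > n:
            raise ValueError("window longer than the sequence")
        if self.topology == "linear":
            if start < 0 or end > n:
                raise ValueError(
                    f"window [{start}, {end}) overruns linear record {self.id!r}"
                )
            return self.seq[start:end]
        start %= n
        if start + length <= n:
            return self.seq[start : start + length]
        return self.seq[start:] + self.seq[: start + length - n]


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a named reference, optionally stranded."""

    ref_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment, PAF-style coordinates on read and reference."""

    read_id: str
    ref_id: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    matches: int
    block_len: int
    mapq: int = 0
    ref_len: int = 0  # 0 when unknown; used to wrap circular coordinates

    def __post_init__(self) -> None:
        if not self.read_start < self.read_end:
            raise ValueError("read_start must be < read_end")
        if not self.ref_start < self.ref_end:
            raise ValueError("ref_start must be < ref_end")
        if self.matches > self.block_len:
            raise ValueError("matches cannot exceed block_len")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


def read_fasta(path: str | os.PathLike, topology: str = "circular") -> list[GenomeRecord]:
    """Load FASTA records in file order, uppercased and validated.

    Lowercase (masked) bases are folded to uppercase; characters outside
    {A,C,G,T,N} and duplicate ids are rejected. An empty file is an error.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, str(rec.seq).upper(), topology))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _parse_paf_line(line: str, lineno: int) -> AlignmentRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ValueError(f"PAF line {lineno}: expected >=12 columns, got {len(fields)}")
    try:
        return AlignmentRecord(
            read_id=fields[0],
            ref_id=fields[5],
            read_start=int(fields[2]),
            read_end=int(fields[3]),
            strand=fields[4],
            ref_start=int(fields[7]),
            ref_end=int(fields[8]),
            matches=int(fields[9]),
            block_len=int(fields[10]),
            mapq=int(fields[11]),
            ref_len=int(fields[6]),
        )
    except (ValueError, IndexError) as exc:
        raise ValueError(f"PAF line {lineno}: {exc}") from exc


def _sam_to_record(aln: pysam.AlignedSegment) -> AlignmentRecord | None:
    """Convert one SAM record to PAF-contract coordinates.

    Unmapped and secondary records are dropped; supplementary alignments
    are kept because split reads carry junction halves in them. Hard and
    soft clips are both treated as unaligned read sequence, so read
    coordinates always refer to the original (pre-clipping) read strand.
    """
    if aln.is_unmapped or aln.is_secondary:
        return None
    cigar = aln.cigartuples
    if not cigar:
        return None
    # leading/trailing clip lengths (S=4, H=5)
    lead = cigar[0][1] if cigar[0][0] in (4, 5) else 0
    trail = cigar[-1][1] if cigar[-1][0] in (4, 5) else 0
    aligned_read = sum(n for op, n in cigar if op in (0, 1, 7, 8))  # M,I,=,X
    read_len = lead + aligned_read + trail
    if aln.is_reverse:
        read_start, read_end = trail, trail + aligned_read
    else:
        read_start, read_end = lead, lead + aligned_read
    block_len = sum(n for op, n in cigar if op in (0, 1, 2, 7, 8))
    eq = sum(n for op, n in cigar if op == 7)
    if eq > 0 or any(op == 8 for op, _ in cigar):
        matches = eq
    elif aln.has_tag("NM"):
        matches = block_len - aln.get_tag("NM")
    else:
        matches = sum(n for op, n in cigar if op in (0, 7))
    _ = read_len
    return AlignmentRecord(
        read_id=aln.query_name,
        ref_id=aln.reference_name,
        read_start=read_start,
        read_end=read_end,
        ref_start=aln.reference_start,
        ref_end=aln.reference_end,
        strand="-" if aln.is_reverse else "+",
        matches=max(0, matches),
        block_len=block_len,
        mapq=aln.mapping_quality,
        ref_len=aln.header.get_reference_length(aln.reference_name) if aln.header else 0,
    )


def read_alignments(path: str | os.PathLike, dialect: str = "paf") -> list[AlignmentRecord]:
    """Read PAF or SAM alignments into the shared coordinate contract."""
    if dialect == "paf":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.strip():
                    records.append(_parse_paf_line(line, lineno))
        return records
    if dialect == "sam":
        records = []
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
            for aln in fh:
                rec = _sam_to_record(aln)
                if rec is not None:
                    records.append(rec)
        return records
    raise ValueError(f"unknown dialect {dialect!r}")


def write_paf(
    records: Sequence[AlignmentRecord],
    path: str | os.PathLike,
    read_lengths: dict[str, int] | None = None,
) -> None:
    """Write alignments as minimal 12-column PAF.

    Read lengths are not part of AlignmentRecord; pass ``read_lengths``
    to fill column 2, otherwise the aligned end is used as a lower bound.
    """
    with open(path, "w") as fh:
        for a in records:
            rlen = (read_lengths or {}).get(a.read_id, a.read_end)
            fh.write(
                f"{a.read_id}\t{rlen}\t{a.read_start}\t{a.read_end}\t{a.strand}"
                f"\t{a.ref_id}\t{a.ref_len}\t{a.ref_start}\t{a.ref_end}"
                f"\t{a.matches}\t{a.block_len}\t{a.mapq}\n"
            )


def write_bed(sites: Sequence, path: str | os.PathLike) -> None:
    """Write BED6 (0-based half-open), sorted by coordinate then strand.

    ``sites`` are objects exposing ``ref_id``/``start``/``end``/``name``/
    ``score``/``strand`` attributes or equivalent 6-tuples. At equal
    coordinates ``+`` sorts before ``-``.
    """
    rows = []
    for s in sites:
        if isinstance(s, (tuple, list)):
            rows.append(tuple(s))
        else:
            rows.append((s.ref_id, s.start, s.end, s.name, s.score, s.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2], 0 if r[5] == "+" else 1))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple]:
    """Read BED6 rows back as (ref_id, start, end, name, score, strand)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
    return rows


def write_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)
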