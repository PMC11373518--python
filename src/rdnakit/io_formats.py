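"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open on the forward strand;
conversion to/from the 1-based inclusive conventions of BLAST tabular,
RepeatMasker ``.out`` and GFF3 happens only here, at the I/O boundary.
Soft-masked (lowercase) bases are preserved on read and interpreted
downstream by the feature search, never stripped.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

IUPAC = set("ACGTURYSWKMBDHVN")


class FormatError(ValueError):
    """Raised when an input file violates its stated dialect."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally with Phred qualities."""

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length must match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TabularHit:
    """One row of 12-column BLAST tabular output (outfmt 6/7).

    The subject is the long read/contig and the query is the rDNA
    feature, matching ``blastn -query rDNA -db reads``. Subject
    start > end signals minus orientation and is preserved as written.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class RMRecord:
    """One RepeatMasker ``.out`` annotation, minus-strand consensus
    coordinates normalized so ``repeat_begin <= repeat_end``."""

    sw_score: int
    percent_divergence: float
    percent_deleted: float
    percent_inserted: float
    query_id: str
    query_begin: int
    query_end: int
    orientation: str  # "plus" | "minus"
    repeat_name: str
    repeat_class_family: str
    repeat_begin: int
    repeat_end: int
    element_id: int


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Parse a (optionally gzipped) FASTA file, preserving lowercase."""
    records: list[SeqRecord] = []
    header: str | None = None
    chunks: list[str] = []
    header_line = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append(SeqRecord(header, "".join(chunks)))
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: sequence before any header at line {lineno}"
                    )
                bad = set(line.upper()) - IUPAC
                if bad:
                    raise FormatError(
                        f"{path}: non-IUPAC characters {sorted(bad)} at line {lineno}"
                    )
                chunks.append(line)
    if header is not None:
        records.append(SeqRecord(header, "".join(chunks)))
    elif chunks:  # pragma: no cover - unreachable by construction
        raise FormatError(f"{path}: trailing sequence without header near line {header_line}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Parse FASTQ; qualities are retained for provenance only."""
    records: list[SeqRecord] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: FASTQ line count not a multiple of 4")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise FormatError(f"{path}: malformed FASTQ record at line {i + 1}")
        if len(qual) != len(seq):
            raise FormatError(f"{path}: quality/sequence length mismatch at line {i + 1}")
        records.append(
            SeqRecord(head[1:].split()[0], seq, [ord(c) - 33 for c in qual])
        )
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [30] * len(rec.sequence)
            fh.write(
                f"@{rec.id}\n{rec.sequence}\n+\n"
                + "".join(chr(q + 33) for q in qual)
                + "\n"
            )


def parse_blast_tabular(path: str | Path, dialect: str = "outfmt7") -> list[TabularHit]:
    """Parse 12-column BLAST tabular output.

    ``outfmt7`` permits '#'-prefixed comment lines; ``outfmt6`` has none.
    """
    if dialect not in ("outfmt6", "outfmt7"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[TabularHit] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if dialect == "outfmt7":
                    continue
                raise FormatError(f"{path}: comment line {lineno} in outfmt6 input")
            fields = line.split("\t")
            if len(fields) != 12:
                fields = line.split()
            if len(fields) != 12:
                raise FormatError(
                    f"{path}: expected 12 columns, got {len(fields)} at line {lineno}"
                )
            try:
                hits.append(
                    TabularHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        query_start=int(fields[6]),
                        query_end=int(fields[7]),
                        subject_start=int(fields[8]),
                        subject_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: bad numeric field at line {lineno}: {exc}")
    return hits


def write_blast_tabular(hits: Iterable[TabularHit], path: str | Path,
                        dialect: str = "outfmt6") -> None:
    with open(path, "w") as fh:
        if dialect == "outfmt7":
            fh.write("# BLASTN\n# 12 fields\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.percent_identity,
                        h.alignment_length, h.mismatches, h.gap_opens,
                        h.query_start, h.query_end, h.subject_start,
                        h.subject_end, h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


def parse_repeatmasker_out(path: str | Path) -> list[RMRecord]:
    """Parse a standard RepeatMasker ``.out`` file.

    Layout: up to 3 header lines, then whitespace-delimited records.
    'C' in the strand column denotes minus orientation, in which case the
    consensus coordinate triple is printed as ``(left) end begin``; it is
    normalized here to ``repeat_begin <= repeat_end``.
    """
    records: list[RMRecord] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            low = line.lower()
            if low.startswith(("sw", "score", "there were no")):
                continue
            fields = line.split()
            if len(fields) < 15:
                raise FormatError(
                    f"{path}: expected >=15 fields, got {len(fields)} at line {lineno}"
                )
            try:
                strand = fields[8]
                if strand in ("+",):
                    orientation = "plus"
                    r_begin = int(fields[11])
                    r_end = int(fields[12])
                elif strand in ("C", "-"):
                    orientation = "minus"
                    if fields[11].startswith("("):
                        # standard minus layout: (left) end begin
                        r_end = int(fields[12])
                        r_begin = int(fields[13])
                    else:  # tolerate a plus-like begin end (left) layout
                        r_begin = int(fields[11])
                        r_end = int(fields[12])
                    if r_begin > r_end:
                        r_begin, r_end = r_end, r_begin
                else:
                    raise ValueError(f"unknown strand token {strand!r}")
                records.append(
                    RMRecord(
                        sw_score=int(fields[0]),
                        percent_divergence=float(fields[1]),
                        percent_deleted=float(fields[2]),
                        percent_inserted=float(fields[3]),
                        query_id=fields[4],
                        query_begin=int(fields[5]),
                        query_end=int(fields[6]),
                        orientation=orientation,
                        repeat_name=fields[9],
                        repeat_class_family=fields[10],
                        repeat_begin=r_begin,
                        repeat_end=r_end,
                        element_id=int(fields[14].rstrip("*")),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: unparseable record at line {lineno}: {exc}")
    return records


def to_internal_interval(one_based_start: int, one_based_end: int) -> tuple[int, int, str]:
    """Convert 1-based inclusive coordinates (swapped => minus strand)
    to internal 0-based half-open forward-strand coordinates."""
    if one_based_start < 1 or one_based_end < 1:
        raise ValueError("1-based positions must be >= 1")
    if one_based_start <= one_based_end:
        return one_based_start - 1, one_based_end, "plus"
    return one_based_end - 1, one_based_start, "minus"


def to_one_based(start0: int, end0: int, strand: str = "plus") -> tuple[int, int]:
    """Inverse of :func:`to_internal_interval`."""
    if start0 < 0 or end0 <= start0:
        raise ValueError("need 0 <= start0 < end0")
    if strand == "plus":
        return start0 + 1, end0
    return end0, start0 + 1


@dataclass(frozen=True)
class GffFeature:
    """One annotation row, held in internal coordinates."""

    seqid: str
    type: str
    start0: int
    end0: int
    strand: str = "plus"
    feature_id: str = ""
    source: str = "rdnakit"
    attributes: tuple[tuple[str, str], ...] = field(default_factory=tuple)


def write_gff3(annotations: Sequence[GffFeature], path: str | Path) -> None:
    """Write GFF3 (1-based inclusive on disk). Duplicate non-empty IDs
    are rejected."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            if ann.feature_id:
                if ann.feature_id in seen:
                    raise ValueError(f"duplicate feature ID {ann.feature_id!r}")
                seen.add(ann.feature_id)
            start1, end1 = ann.start0 + 1, ann.end0
            attrs = []
            if ann.feature_id:
                attrs.append(f"ID={ann.feature_id}")
            attrs.extend(f"{k}={v}" for k, v in ann.attributes)
            fh.write(
                "\t".join(
                    (
                        ann.seqid, ann.source, ann.type, str(start1), str(end1),
                        ".", "+" if ann.strand == "plus" else "-", ".",
                        ";".join(attrs) or ".",
                    )
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GffFeature]:
    feats: list[GffFeature] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: expected 9 columns at line {lineno}")
            start1, end1 = int(fields[3]), int(fields[4])
            attrs = []
            feature_id = ""
            if fields[8] != ".":
                for pair in fields[8].split(";"):
                    k, _, v = pair.partition("=")
                    if k == "ID":
                        feature_id = v
                    else:
                        attrs.append((k, v))
            feats.append(
                GffFeature(
                    seqid=fields[0],
                    source=fields[1],
                    type=fields[2],
                    start0=start1 - 1,
                    end0=end1,
                    strand="plus" if fields[6] != "-" else "minus",
                    feature_id=feature_id,
                    attributes=tuple(attrs),
                )
            )
    return feats


_COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVNacgturyswkmbdhvn",
                            "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn")


def reverse_complement(sequence: str) -> str:
    """Reverse complement preserving case (soft-mask flags)."""
    return sequence.translate(_COMPLEMENT)[::-1]
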