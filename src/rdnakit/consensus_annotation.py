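"""Extract unit copies, build a majority-rule consensus, annotate regions.

Unit copies are cut from multi-unit reads between consecutive 18S anchor
starts and rotated so every unit begins at the 18S. The consensus is a
star alignment: the medoid unit (minimal summed edit distance) is the
centre, every other unit is pairwise-aligned to it (edlib), and each
centre column is called by majority vote with the gap treated as a
symbol; gap-majority columns are deleted. Ties go to the alphabetically
earliest base, with a base preferred over a gap.

The IGS is operationally defined as 28S-end to the next 18S-start, so it
includes both external transcribed spacers: rRNA transcription start
sites cannot be determined from DNA sequence alone.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .feature_search import FeatureHit
from .io_formats import GffFeature, SeqRecord, reverse_complement
from .unit_sizing import ANCHOR_COVERAGE, MAX_ANCHOR_TRUNCATION

CODING_FEATURES = ("18S", "5.8S", "28S")
REGION_ORDER = ("18S", "ITS1", "5.8S", "ITS2", "28S", "IGS")
MIN_ANNOTATION_IDENTITY = 0.60


class AnnotationError(ValueError):
    """Raised when a coding region cannot be located on a consensus."""


@dataclass(frozen=True)
class RotatedUnit:
    """One unit copy, oriented plus and starting at its 18S start."""

    source_id: str
    sequence: str
    source_start: int
    source_end: int
    strand: str
    anchor_span: int  # bp of 18S anchor support (selection tie-break)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("unit sequence must be non-empty")


@dataclass(frozen=True)
class UnitAnnotation:
    """Region intervals of one unit; they partition [0, total)."""

    intervals: tuple[tuple[str, int, int], ...]  # (name, start0, end0)
    total: int

    @property
    def lengths(self) -> dict[str, int]:
        return {name: e - s for name, s, e in self.intervals}

    def interval(self, name: str) -> tuple[int, int]:
        for nm, s, e in self.intervals:
            if nm == name:
                return s, e
        raise KeyError(name)


def extract_rotated_units(read: SeqRecord, hits: Sequence[FeatureHit],
                          anchor_feature: str = "18S",
                          min_coverage: float = ANCHOR_COVERAGE,
                          ) -> list[RotatedUnit]:
    """Cut one unit per adjacent 18S-anchor pair, rotated to plus strand."""
    units: list[RotatedUnit] = []
    for strand in ("plus", "minus"):
        anchors = sorted(
            (h for h in hits
             if h.read_id == read.id and h.feature == anchor_feature
             and h.strand == strand and h.feature_coverage >= min_coverage
             and h.feature_start <= MAX_ANCHOR_TRUNCATION),
            key=lambda h: h.start)
        if len(anchors) < 2:
            continue
        seq = read.sequence
        if strand == "minus":
            # mirror to the unit-forward representation
            n = len(seq)
            seq = reverse_complement(seq)
            anchors = sorted(
                (type(h)(read_id=h.read_id, feature=h.feature,
                         start=n - h.end, end=n - h.start, strand="plus",
                         identity=h.identity,
                         feature_coverage=h.feature_coverage,
                         feature_start=h.feature_start,
                         feature_end=h.feature_end, ref_length=h.ref_length,
                         source=h.source, chain_members=h.chain_members)
                 for h in anchors),
                key=lambda h: h.start)
        for left, right in zip(anchors, anchors[1:]):
            # cut at the projected 18S origins so truncated anchors do
            # not shift the rotation point
            lo = left.start - left.feature_start
            ro = right.start - right.feature_start
            if lo < 0 or ro > len(seq) or ro <= lo:
                continue
            units.append(RotatedUnit(
                source_id=read.id, sequence=seq[lo:ro],
                source_start=lo, source_end=ro, strand=strand,
                anchor_span=min(left.end - left.start, right.end - right.start)))
    return units


def select_units(candidates: Iterable[RotatedUnit], max_units: int = 15,
                 ) -> list[RotatedUnit]:
    """Deterministic sample: longest anchors first, then lexical read id."""
    ranked = sorted(candidates,
                    key=lambda u: (-u.anchor_span, u.source_id, u.source_start))
    return ranked[:max_units]


def _pairwise_columns(centre: str, other: str) -> list[str]:
    """Symbol of ``other`` at each centre position ('-' for deletion)."""
    res = edlib.align(other, centre, mode="NW", task="path")
    cols = ["-"] * len(centre)
    ci = oi = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            for _ in range(n):
                cols[ci] = other[oi]
                ci += 1
                oi += 1
        elif ch == "D":  # centre has extra bases -> gaps in other
            ci += n
        elif ch == "I":  # other has extra bases; not representable in
            oi += n      # centre columns, dropped (insertions are rare
                         # independent errors and never reach majority)
    return cols


_SYMBOL_ORDER = {b: i for i, b in enumerate("ACGT-")}


def build_consensus(units: Sequence[RotatedUnit | SeqRecord | str],
                    ) -> tuple[SeqRecord, bool]:
    """Star-alignment majority consensus; returns (record, single_flag).

    The flag is True when only one unit was supplied (returned unchanged).
    """
    seqs = [(u if isinstance(u, str) else u.sequence).upper() for u in units]
    if not seqs:
        raise ValueError("need at least one unit")
    if len(seqs) == 1:
        return SeqRecord("consensus", seqs[0]), True
    # medoid: minimal summed edit distance; first on ties
    dists = [[0] * len(seqs) for _ in seqs]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")["editDistance"]
            dists[i][j] = dists[j][i] = d
    sums = [sum(row) for row in dists]
    centre_idx = min(range(len(seqs)), key=lambda i: (sums[i], i))
    centre = seqs[centre_idx]

    votes: list[Counter] = [Counter() for _ in range(len(centre))]
    for i, s in enumerate(seqs):
        cols = list(centre) if i == centre_idx else _pairwise_columns(centre, s)
        for pos, sym in enumerate(cols):
            votes[pos][sym] += 1
    out: list[str] = []
    for counter in votes:
        best = max(counter.items(),
                   key=lambda kv: (kv[1], -_SYMBOL_ORDER.get(kv[0], 9)))
        if best[0] != "-":
            out.append(best[0])
    return SeqRecord("consensus", "".join(out)), False


def annotate_unit(consensus: SeqRecord, reference_features: Mapping[str, str],
                  min_identity: float = MIN_ANNOTATION_IDENTITY,
                  ) -> UnitAnnotation:
    """Locate 18S/5.8S/28S by alignment; derive ITS1/ITS2/IGS by position.

    The unit is expected to begin at the 18S start; the IGS runs from the
    28S end to the unit end. A coding region that cannot be aligned at
    ``min_identity`` raises :class:`AnnotationError` naming the feature.
    """
    seq = consensus.sequence.upper()
    located: dict[str, tuple[int, int]] = {}
    for name in CODING_FEATURES:
        if name not in reference_features:
            raise ValueError(f"reference for {name} missing")
        ref = reference_features[name].upper()
        res = edlib.align(ref, seq, mode="HW", task="locations")
        identity = 1.0 - res["editDistance"] / max(len(ref), 1)
        if res["editDistance"] < 0 or identity < min_identity:
            raise AnnotationError(f"{name} not found (best identity "
                                  f"{max(identity, 0.0):.2f} < {min_identity})")
        loc0, loc1 = res["locations"][0]
        located[name] = (loc0, loc1 + 1)
    s18, e18 = located["18S"]
    s58, e58 = located["5.8S"]
    s28, e28 = located["28S"]
    if not (e18 <= s58 and e58 <= s28):
        raise AnnotationError("coding regions out of order on the unit")
    intervals = (
        ("18S", 0, e18),
        ("ITS1", e18, s58),
        ("5.8S", s58, e58),
        ("ITS2", e58, s28),
        ("28S", s28, e28),
        ("IGS", e28, len(seq)),
    )
    return UnitAnnotation(intervals=intervals, total=len(seq))


def annotation_to_gff(annotation: UnitAnnotation, seqid: str) -> list[GffFeature]:
    return [GffFeature(seqid=seqid, type=name, start0=s, end0=e,
                       feature_id=f"{seqid}_{name}")
            for name, s, e in annotation.intervals if e > s]


def annotation_from_gff(features: Sequence[GffFeature]) -> UnitAnnotation:
    by_name = {f.type: (f.start0, f.end0) for f in features}
    intervals = tuple((name, *by_name[name]) for name in REGION_ORDER
                      if name in by_name)
    total = max(e for _, _, e in intervals)
    return UnitAnnotation(intervals=intervals, total=total)


def region_length_report(annotations: Mapping[str, UnitAnnotation]) -> list[dict]:
    """One row per annotated unit: species/sample and region lengths."""
    rows = []
    for name in sorted(annotations):
        ann = annotations[name]
        row = {"sample": name, "total": ann.total}
        lengths = ann.lengths
        for region in REGION_ORDER:
            row[region] = lengths.get(region, 0)
        rows.append(row)
    return rows


def write_region_report_tsv(rows: Sequence[dict], path) -> None:
    cols = ["sample", "total", *REGION_ORDER]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
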