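"""Reconstruct logical transposable elements from RepeatMasker records
and match putatively orthologous TEs between two IGSs.

RepeatMasker splits a TE interrupted by a nested insertion into multiple
fragments; fragments of the same repeat with the same orientation whose
consensus coordinates are co-linear, and whose gap on the query is
occupied by other annotated elements, are rejoined into one logical TE
with the interveners as nested children. Elements shorter than 50 bp
are discarded.

Orthology between two IGSs is the maximum-cardinality order-preserving
matching of TEs with identical family and orientation (an LCS over
(family, orientation) tokens); among maximum-cardinality matchings the
one maximizing the summed min(length_A, length_B) over pairs is chosen,
making the result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import RMRecord

MIN_TE_LENGTH = 50
NON_TE_CLASSES = ("Simple_repeat", "Low_complexity", "Satellite",
                  "rRNA", "tRNA", "snRNA", "srpRNA", "scRNA")


@dataclass
class TERecord:
    """A logical transposable element on an IGS."""

    family: str  # RepeatMasker class/family token, e.g. "SINE/Alu"
    name: str
    orientation: str  # "plus" | "minus"
    start: int  # 0-based half-open on the IGS
    end: int
    nested_children: list["TERecord"] = field(default_factory=list)
    fragment_ids: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def token(self) -> tuple[str, str]:
        return (self.family, self.orientation)


@dataclass(frozen=True)
class OrthologyMatching:
    pairs: tuple[tuple[int, int], ...]
    count: int
    matched_length_a: int
    matched_length_b: int


def _from_rm(rec: RMRecord) -> TERecord:
    return TERecord(
        family=rec.repeat_class_family, name=rec.repeat_name,
        orientation=rec.orientation,
        start=rec.query_begin - 1, end=rec.query_end,
        fragment_ids=[rec.element_id],
        # consensus extent retained on the instance for join decisions
    )


def _consensus_range(rec: RMRecord) -> tuple[int, int]:
    return rec.repeat_begin, rec.repeat_end


def filter_and_reconstruct(rm_records: Sequence[RMRecord],
                           min_length: int = MIN_TE_LENGTH,
                           join_tolerance: int = 50,
                           gap_covered_fraction: float = 0.8,
                           ) -> list[TERecord]:
    """Drop short records, rejoin split fragments, nest interveners.

    Two same-name, same-orientation fragments are joined when their
    consensus coordinates continue co-linearly (within ``join_tolerance``)
    and the query gap between them is >= ``gap_covered_fraction`` covered
    by other annotated elements (which become nested children).
    """
    recs = sorted(rm_records, key=lambda r: r.query_begin)
    tes = [_from_rm(r) for r in recs]
    cons = [_consensus_range(r) for r in recs]
    used = [False] * len(tes)
    logical: list[TERecord] = []

    for i in range(len(tes)):
        if used[i]:
            continue
        used[i] = True
        current = tes[i]
        cur_cons = cons[i]
        children: list[TERecord] = []
        j = i + 1
        while j < len(tes):
            cand_idx = None
            interveners: list[int] = []
            for j2 in range(j, len(tes)):
                if used[j2]:
                    continue
                if (tes[j2].name == current.name
                        and tes[j2].orientation == current.orientation
                        and _colinear_consensus(cur_cons, cons[j2],
                                                current.orientation,
                                                join_tolerance)):
                    cand_idx = j2
                    break
                interveners.append(j2)
            if cand_idx is None:
                break
            gap_start, gap_end = current.end, tes[cand_idx].start
            gap = gap_end - gap_start
            covered = _coverage(gap_start, gap_end,
                                [(tes[x].start, tes[x].end) for x in interveners])
            if gap > 0 and covered < gap_covered_fraction * gap:
                break
            for x in interveners:
                used[x] = True
                children.append(tes[x])
            used[cand_idx] = True
            current = TERecord(
                family=current.family, name=current.name,
                orientation=current.orientation,
                start=current.start, end=tes[cand_idx].end,
                fragment_ids=current.fragment_ids + tes[cand_idx].fragment_ids,
            )
            cur_cons = _merge_cons(cur_cons, cons[cand_idx])
            j = cand_idx + 1
        current.nested_children = children
        logical.append(current)

    out = [t for t in logical if t.length >= min_length]
    out.sort(key=lambda t: t.start)
    return out


def _colinear_consensus(prev: tuple[int, int], nxt: tuple[int, int],
                        orientation: str, tolerance: int) -> bool:
    if orientation == "plus":
        return nxt[0] >= prev[1] - tolerance
    # minus strand: consensus coordinates decrease along the query
    return nxt[1] <= prev[0] + tolerance


def _merge_cons(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    return min(a[0], b[0]), max(a[1], b[1])


def _coverage(start: int, end: int, intervals: Sequence[tuple[int, int]]) -> int:
    if end <= start:
        return 0
    clipped = sorted((max(s, start), min(e, end)) for s, e in intervals
                     if min(e, end) > max(s, start))
    covered = 0
    cursor = start
    for s, e in clipped:
        if e > cursor:
            covered += e - max(s, cursor)
            cursor = max(cursor, e)
    return covered


def is_te(record: TERecord) -> bool:
    """Non-TE annotations (simple repeats, pseudogenes, ...) are carried
    through reports but excluded from orthology matching."""
    fam = record.family
    return not (fam in NON_TE_CLASSES or fam.startswith("Simple")
                or fam.lower().startswith("pseudogene")
                or fam == "Unknown/pseudogene")


def match_orthologous_tes(tes_a: Sequence[TERecord], tes_b: Sequence[TERecord],
                          by_name: bool = False) -> OrthologyMatching:
    """Maximum order-preserving matching on (family, orientation) tokens.

    Dynamic programming over prefixes: value = (#pairs, summed
    min(len_A, len_B)), maximized lexicographically. ``by_name`` switches
    token equality to the strict repeat-name level.
    """
    A = [t for t in tes_a if is_te(t)]
    B = [t for t in tes_b if is_te(t)]
    idx_a = [i for i, t in enumerate(tes_a) if is_te(t)]
    idx_b = [i for i, t in enumerate(tes_b) if is_te(t)]

    def token(t: TERecord):
        return (t.name, t.orientation) if by_name else t.token

    n, m = len(A), len(B)
    # dp[i][j]: best (count, minlen_sum) for A[:i] vs B[:j]
    dp = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = dp[i - 1][j] if dp[i - 1][j] >= dp[i][j - 1] else dp[i][j - 1]
            if token(A[i - 1]) == token(B[j - 1]):
                c, s = dp[i - 1][j - 1]
                cand = (c + 1, s + min(A[i - 1].length, B[j - 1].length))
                if cand > best:
                    best = cand
            dp[i][j] = best
    # traceback
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if dp[i][j] == dp[i - 1][j]:
            i -= 1
        elif dp[i][j] == dp[i][j - 1]:
            j -= 1
        else:
            pairs.append((idx_a[i - 1], idx_b[j - 1]))
            i -= 1
            j -= 1
    pairs.reverse()
    matched_a = sum(tes_a[i].length for i, _ in pairs)
    matched_b = sum(tes_b[j].length for _, j in pairs)
    return OrthologyMatching(tuple(pairs), len(pairs), matched_a, matched_b)


def orthology_report(matching: OrthologyMatching, tes_a: Sequence[TERecord],
                     tes_b: Sequence[TERecord], igs_length_a: int,
                     igs_length_b: int) -> dict:
    """Fig-4-style totals: IGS lengths, TE bp, orthologous TE bp, counts."""
    return {
        "igs_length_a": igs_length_a,
        "igs_length_b": igs_length_b,
        "n_te_a": sum(1 for t in tes_a if is_te(t)),
        "n_te_b": sum(1 for t in tes_b if is_te(t)),
        "te_bp_a": sum(t.length for t in tes_a if is_te(t)),
        "te_bp_b": sum(t.length for t in tes_b if is_te(t)),
        "n_orthologous": matching.count,
        "orthologous_bp_a": matching.matched_length_a,
        "orthologous_bp_b": matching.matched_length_b,
    }


def write_orthology_tsv(report: dict, matching: OrthologyMatching,
                        tes_a: Sequence[TERecord], tes_b: Sequence[TERecord],
                        report_path, pairs_path) -> None:
    with open(report_path, "w") as fh:
        keys = list(report)
        fh.write("\t".join(keys) + "\n")
        fh.write("\t".join(str(report[k]) for k in keys) + "\n")
    with open(pairs_path, "w") as fh:
        fh.write("index_a\tindex_b\tfamily\torientation\tlen_a\tlen_b\n")
        for i, j in matching.pairs:
            a, b = tes_a[i], tes_b[j]
            fh.write(f"{i}\t{j}\t{a.family}\t{a.orientation}\t"
                     f"{a.length}\t{b.length}\n")
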