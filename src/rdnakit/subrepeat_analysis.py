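"""Detect tandem sub-repeat arrays inside an rDNA unit and quantify how
much unit-length variation sub-repeat copy number explains.

Detection works from the unit's k-mer self-match map (the dotplot): a
tandem array of period p produces off-diagonal matches at offsets that
are multiples of p. Candidate array spans are the merged regions covered
by short-offset self-matches; the period is the smallest offset whose
multiples explain >=80% of a span's match offsets (so a p-periodic array
is never reported as 2p). Arrays with period <10 bp are microsatellites
and are excluded from sub-repeat accounting; arrays whose adjacent
copies align below a 70% identity threshold are classed degenerate.

Variance attribution: with S_i the total sub-repeat length physically
contained in unit i of length L_i, the fraction of length variance
explained by sub-repeat copy number is 1 - Var(L - S)/Var(L) (sample
variances, clamped to [0, 1]).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

from .consensus_annotation import UnitAnnotation

MICROSATELLITE_MAX_PERIOD = 9  # "<10 bp" rule
DEGENERATE_IDENTITY = 0.70


@dataclass(frozen=True)
class SubRepeatArray:
    """A detected tandem array within a unit."""

    start: int
    end: int
    period: int
    copy_number: float
    mean_adjacent_identity: float
    klass: str  # "subrepeat" | "microsatellite" | "degenerate"
    location_label: str = "other"

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class VarianceAttribution:
    n_units: int
    var_total: float
    var_residual: float
    fraction_explained: float | None  # None when Var(L) == 0


def self_match_map(sequence: str, k: int = 12,
                   max_offset: int | None = None) -> list[tuple[int, int]]:
    """All off-diagonal exact k-mer self-matches (i, j) with i < j.

    ``max_offset`` bounds j - i (None = unbounded); bounding keeps the
    map small on units containing long-range duplications.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < k:
        return []
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(n - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        positions[kmer].append(i)
    pairs: list[tuple[int, int]] = []
    for pos in positions.values():
        if len(pos) < 2:
            continue
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                if max_offset is not None and pos[b] - pos[a] > max_offset:
                    break
                pairs.append((pos[a], pos[b]))
    pairs.sort()
    return pairs


def _pick_period(offsets: Counter, explain: float = 0.8,
                 tolerance: int = 2) -> int | None:
    """Smallest observed offset whose multiples explain >=80% of offsets."""
    total = sum(offsets.values())
    if total == 0:
        return None
    for cand in sorted(offsets):
        covered = 0
        for off, cnt in offsets.items():
            m = round(off / cand)
            if m >= 1 and abs(off - m * cand) <= max(tolerance, 0.02 * cand):
                covered += cnt
        if covered >= explain * total:
            return cand
    return None


def _chunk_identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _grow_span(seq: str, start: int, end: int, period: int,
               min_identity: float = 0.60) -> tuple[int, int]:
    """Extend a candidate span outward one period at a time while the
    new chunk still aligns to its inner neighbour at ``min_identity``."""
    n = len(seq)
    while start - period >= 0 and _chunk_identity(
            seq[start - period:start], seq[start:start + period]) >= min_identity:
        start -= period
    while end + period <= n and _chunk_identity(
            seq[end:end + period], seq[end - period:end]) >= min_identity:
        end += period
    return start, end


def _adjacent_identity(seq: str, start: int, end: int, period: int) -> float:
    """Mean identity between consecutive period-sized chunks (edlib)."""
    chunks = [seq[p:p + period] for p in range(start, end - period + 1, period)]
    if len(chunks) < 2:
        return 1.0
    idents = []
    for a, b in zip(chunks, chunks[1:]):
        d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        idents.append(1.0 - d / max(len(a), len(b)))
    return float(np.mean(idents))


def detect_tandem_arrays(sequence: str, k: int = 12, min_period: int = 1,
                         min_copies: float = 2.0, max_period: int = 1_000,
                         merge_gap: int = 100,
                         degenerate_identity: float = DEGENERATE_IDENTITY,
                         annotation: UnitAnnotation | None = None,
                         ) -> list[SubRepeatArray]:
    """Find tandem arrays from the self-match map of ``sequence``.

    Overlapping candidates are resolved by keeping the larger span, then
    the larger period. If ``annotation`` is given, each array gets the
    label of the region containing its midpoint.
    """
    seq = sequence.upper()
    pairs = self_match_map(seq, k=k, max_offset=max_period)
    n = len(seq)
    if not pairs:
        return []
    # positions covered by any short-offset self-match (both endpoints)
    covered = np.zeros(n + 1, dtype=bool)
    for i, j in pairs:
        covered[i:i + k] = True
        covered[j:j + k] = True
    # merge covered runs, tolerating short gaps where divergence removed
    # every exact k-mer; the gap must stay well below typical inter-array
    # spacing or distinct arrays would fuse
    runs: list[list[int]] = []
    idx = np.flatnonzero(covered)
    for p in idx:
        if runs and p <= runs[-1][1] + merge_gap:
            runs[-1][1] = p + 1
        else:
            runs.append([p, p + 1])

    arrays: list[SubRepeatArray] = []
    for start, end in runs:
        local = [(i, j) for i, j in pairs if i >= start and j <= end]
        if not local:
            continue
        offsets = Counter(j - i for i, j in local if j - i >= min_period)
        period = _pick_period(offsets)
        if period is None or period < min_period:
            continue
        # divergence fragments the exact-match coverage; recover the full
        # array by growing the span while adjacent copies still align
        start, end = _grow_span(seq, start, end, period)
        copy_number = (end - start) / period
        if copy_number < min_copies:
            continue
        ident = _adjacent_identity(seq, start, end, period)
        if period <= MICROSATELLITE_MAX_PERIOD:
            klass = "microsatellite"
        elif ident < degenerate_identity:
            klass = "degenerate"
        else:
            klass = "subrepeat"
        label = "other"
        if annotation is not None:
            mid = (start + end) // 2
            for name, s, e in annotation.intervals:
                if s <= mid < e:
                    label = name if name in ("IGS", "ITS1", "ITS2") else "other"
                    break
        arrays.append(SubRepeatArray(
            start=int(start), end=int(end), period=int(period),
            copy_number=round(float(copy_number), 3),
            mean_adjacent_identity=round(ident, 4), klass=klass,
            location_label=label))

    # resolve overlaps: larger span wins, then larger period
    arrays.sort(key=lambda a: (-(a.span_length), -a.period, a.start))
    kept: list[SubRepeatArray] = []
    for arr in arrays:
        if all(arr.end <= other.start or arr.start >= other.end for other in kept):
            kept.append(arr)
    kept.sort(key=lambda a: a.start)
    return kept


def subrepeat_totals(unit_annotation: UnitAnnotation,
                     arrays: Sequence[SubRepeatArray],
                     ) -> tuple[int, int, float]:
    """(total sub-repeat bp, bp inside the IGS, fraction of IGS occupied).

    Microsatellites (and degenerate arrays) are excluded; an array
    straddling the IGS boundary contributes only its overlapping part.
    """
    igs_start, igs_end = unit_annotation.interval("IGS")
    igs_len = igs_end - igs_start
    total = 0
    igs_bp = 0
    for arr in arrays:
        if arr.klass != "subrepeat":
            continue
        total += arr.span_length
        overlap = min(arr.end, igs_end) - max(arr.start, igs_start)
        if overlap > 0:
            igs_bp += overlap
    proportion = igs_bp / igs_len if igs_len > 0 else 0.0
    return total, igs_bp, proportion


def variance_explained_by_subrepeats(unit_lengths: Sequence[float],
                                     subrepeat_totals_per_unit: Sequence[float],
                                     ) -> VarianceAttribution:
    """1 - Var(L - S)/Var(L), clamped to [0, 1]; None when Var(L) = 0."""
    L = np.asarray(unit_lengths, dtype=float)
    S = np.asarray(subrepeat_totals_per_unit, dtype=float)
    if len(L) != len(S):
        raise ValueError("unit lengths and sub-repeat totals must be paired")
    if len(L) < 3:
        raise ValueError("need >= 3 units with matched measurements")
    var_total = float(np.var(L, ddof=1))
    var_residual = float(np.var(L - S, ddof=1))
    if var_total == 0.0:
        return VarianceAttribution(len(L), var_total, var_residual, None)
    frac = min(max(1.0 - var_residual / var_total, 0.0), 1.0)
    return VarianceAttribution(len(L), var_total, var_residual, frac)


ARRAY_COLUMNS = ("start", "end", "period", "copy_number",
                 "mean_adjacent_identity", "klass", "location_label")


def write_arrays_tsv(arrays: Iterable[SubRepeatArray], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ARRAY_COLUMNS) + "\n")
        for a in arrays:
            fh.write("\t".join(str(getattr(a, c)) for c in ARRAY_COLUMNS) + "\n")


def write_dotplot_tsv(pairs: Iterable[tuple[int, int]], path) -> None:
    """Self-match coordinates for external dotplot rendering."""
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for i, j in pairs:
            fh.write(f"{i}\t{j}\n")
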