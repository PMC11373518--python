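"""Measure rDNA repeat-unit sizes from multi-unit long reads.

A read spanning two or more occurrences of the same rDNA feature (e.g.
the 18S gene) yields direct unit-length observations: the start-to-start
distance between consecutive same-feature, same-strand anchors.
Start-to-start cancels anchor-internal length errors to first order, so
substitution-only sequencing errors never change a measured length.

Summaries follow the conventions of R's ``density()``/``mean``/``sd``:
sample SD (n-1), Gaussian KDE on a 512-point grid spanning the data
range extended by 3 bandwidths, and the bw.nrd0 rule-of-thumb bandwidth
0.9 * min(sd, IQR/1.34) * n^(-1/5). The mode of the KDE is the "peak"
unit size; a secondary peak is the restricted-range mode after excluding
the primary peak's side of a stated bound.

Size classes: "normal" = 8-20 kb, "large" = >30 kb; lengths between are
"intermediate", below 8 kb "out_of_range".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .feature_search import FeatureHit

ANCHOR_COVERAGE = 0.8
# anchors missing more than this many bases of the feature's start are
# excluded: their projected origin is an extrapolation whose error grows
# with the truncation, which would corrupt start-to-start distances
MAX_ANCHOR_TRUNCATION = 25
NORMAL_RANGE = (8_000, 20_000)
LARGE_MIN = 30_000


@dataclass(frozen=True)
class UnitObservation:
    """One measured unit length from a pair of consecutive anchors."""

    read_id: str
    anchor_feature: str
    left_start: int
    right_start: int
    strand: str

    @property
    def length(self) -> int:
        return self.right_start - self.left_start

    def __post_init__(self) -> None:
        if self.right_start <= self.left_start:
            raise ValueError("observation length must be > 0")


@dataclass(frozen=True)
class SizeSummary:
    n: int
    mean: float
    sd: float
    primary_peak: float
    bandwidth: float
    secondary_peak: float | None = None
    size_class: str = ""


def anchor_origin(hit: FeatureHit) -> int:
    """Read coordinate of the feature's position 0 implied by the hit.

    Anchors truncated at a read edge still cover >=80% of the feature
    but miss its first bases; projecting every anchor to the feature
    origin keeps start-to-start distances exact regardless of truncation.
    """
    if hit.strand == "plus":
        return hit.start - hit.feature_start
    return hit.end + hit.feature_start


def _anchors(hits: Iterable[FeatureHit], feature: str,
             min_coverage: float = ANCHOR_COVERAGE) -> dict[str, list[FeatureHit]]:
    """Anchor-quality hits of ``feature`` grouped by (read, strand)."""
    grouped: dict[str, list[FeatureHit]] = defaultdict(list)
    for h in hits:
        if (h.feature == feature and h.feature_coverage >= min_coverage
                and h.feature_start <= MAX_ANCHOR_TRUNCATION):
            grouped[f"{h.read_id}\t{h.strand}"].append(h)
    return grouped


def find_multiunit_reads(hits: Iterable[FeatureHit], anchor_feature: str = "18S",
                         min_coverage: float = ANCHOR_COVERAGE) -> list[str]:
    """Reads with >=2 same-strand anchor-quality hits of the feature."""
    grouped = _anchors(hits, anchor_feature, min_coverage)
    return sorted({key.split("\t")[0] for key, g in grouped.items() if len(g) >= 2})


def measure_unit_lengths(hits_of_read: Sequence[FeatureHit], anchor_feature: str,
                         min_coverage: float = ANCHOR_COVERAGE,
                         ) -> list[UnitObservation]:
    """One observation per adjacent same-feature same-strand anchor pair."""
    obs: list[UnitObservation] = []
    grouped = _anchors(hits_of_read, anchor_feature, min_coverage)
    for key, anchors in sorted(grouped.items()):
        read_id, strand = key.split("\t")
        origins = sorted(anchor_origin(h) for h in anchors)
        for left, right in zip(origins, origins[1:]):
            obs.append(UnitObservation(
                read_id=read_id, anchor_feature=anchor_feature,
                left_start=left, right_start=right, strand=strand))
    return obs


def bw_nrd0(values: Sequence[float]) -> float:
    """R's bw.nrd0 rule-of-thumb bandwidth, with a 1 bp degeneracy floor.

    When the data carry no spread at all (sd = IQR = 0) the bandwidth is
    floored at 1 bp rather than following R's abs(x[1]) fallback, so the
    KDE mode of constant observations is the observed value itself.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 1:
        raise ValueError("no observations")
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    lo = min(sd, iqr / 1.34)
    if lo == 0.0:
        lo = sd or 1.0
    return max(0.9 * lo * n ** (-0.2), 1e-9)


def kde_grid(values: Sequence[float], bandwidth: float | None = None,
             n_grid: int = 512) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian KDE on a grid spanning [min-3bw, max+3bw]."""
    x = np.asarray(values, dtype=float)
    bw = bandwidth if bandwidth is not None else bw_nrd0(x)
    if bw <= 0:
        bw = 1.0
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (len(x) * bw * np.sqrt(2 * np.pi))
    return grid, dens, bw


def classify_unit_size(length_bp: float) -> str:
    """Normal 8-20 kb; large >30 kb; the gap between is intermediate."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if NORMAL_RANGE[0] <= length_bp <= NORMAL_RANGE[1]:
        return "normal"
    if length_bp > LARGE_MIN:
        return "large"
    if length_bp < NORMAL_RANGE[0]:
        return "out_of_range"
    return "intermediate"


def summarize_sizes(observations: Sequence[UnitObservation | float],
                    bandwidth: float | None = None) -> SizeSummary:
    """Mean, sample SD, KDE primary peak and size class of the lengths."""
    lengths = np.asarray(
        [o.length if isinstance(o, UnitObservation) else float(o)
         for o in observations], dtype=float)
    if len(lengths) == 0:
        raise ValueError("no observations")
    mean = float(lengths.mean())
    sd = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0
    grid, dens, bw = kde_grid(lengths, bandwidth)
    peak = float(grid[int(np.argmax(dens))])
    return SizeSummary(
        n=len(lengths), mean=mean, sd=sd, primary_peak=peak, bandwidth=bw,
        size_class=classify_unit_size(mean))


def find_secondary_peak(observations: Sequence[UnitObservation | float],
                        exclusion_bound: float, side: str,
                        bandwidth: float | None = None) -> float:
    """Mode of the same KDE restricted to one side of the bound."""
    if side not in ("below", "above"):
        raise ValueError("side must be 'below' or 'above'")
    lengths = np.asarray(
        [o.length if isinstance(o, UnitObservation) else float(o)
         for o in observations], dtype=float)
    grid, dens, _ = kde_grid(lengths, bandwidth)
    keep = grid < exclusion_bound if side == "below" else grid > exclusion_bound
    if not keep.any():
        raise ValueError("no density grid points on the requested side of the bound")
    grid, dens = grid[keep], dens[keep]
    return float(grid[int(np.argmax(dens))])


# ---------------------------------------------------------------------------
# TSV externalization

OBS_COLUMNS = ("read_id", "anchor_feature", "left_start", "right_start",
               "strand", "length")


def write_observations_tsv(observations: Iterable[UnitObservation], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(OBS_COLUMNS) + "\n")
        for o in observations:
            fh.write(f"{o.read_id}\t{o.anchor_feature}\t{o.left_start}\t"
                     f"{o.right_start}\t{o.strand}\t{o.length}\n")


def write_summary_tsv(summary: SizeSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("n\tmean\tsd\tprimary_peak\tsecondary_peak\tbandwidth\tsize_class\n")
        sec = "" if summary.secondary_peak is None else f"{summary.secondary_peak:.1f}"
        fh.write(f"{summary.n}\t{summary.mean:.1f}\t{summary.sd:.1f}\t"
                 f"{summary.primary_peak:.1f}\t{sec}\t{summary.bandwidth:.2f}\t"
                 f"{summary.size_class}\n")
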