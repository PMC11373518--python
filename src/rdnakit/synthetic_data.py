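"""Simulate tandem rDNA arrays and long reads over them, with full truth.

The generator emulates the structure the analysis assumes: a locus of
head-to-tail repeat units (18S - ITS1 - 5.8S - ITS2 - 28S - IGS, each unit
beginning at the 18S start), per-unit copy-number variation of planted
IGS/ITS1 sub-repeat arrays, transposable-element and microsatellite
insertions, and ONT-like substitution/indel read errors. Every planted
feature is recorded in a :class:`Truth` object so downstream measurements
can be scored exactly.

Coding-region default lengths (18S 1,800 bp; 5.8S 150 bp; 28S 4,500 bp)
mimic vertebrate magnitudes; only the relative layout matters to the
pipeline. All randomness flows from one explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import SeqRecord, reverse_complement

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SubRepeatSpec:
    """A tandem sub-repeat array planted once per unit.

    ``copy_number`` per unit is drawn uniformly from
    ``{cn_low, ..., cn_high}``; each copy is independently mutated from a
    master copy at ``divergence`` substitutions per base. ``location`` is
    the spacer the array sits in (IGS or ITS1, as seen in platypus).
    """

    period: int
    cn_low: int
    cn_high: int
    divergence: float = 0.0
    location: str = "IGS"  # "IGS" | "ITS1"
    offset: float = 0.3  # fractional position within the host spacer core

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if self.cn_low > self.cn_high or self.cn_low < 0:
            raise ValueError("need 0 <= cn_low <= cn_high")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0,1]")
        if self.location not in ("IGS", "ITS1"):
            raise ValueError("location must be IGS or ITS1")


@dataclass(frozen=True)
class TEInsertion:
    """A transposable-element insertion planted in the IGS core."""

    family: str
    orientation: str  # "plus" | "minus"
    length: int
    offset: float  # fractional position within the IGS core


@dataclass(frozen=True)
class MicrosatelliteSpec:
    """A short-motif (<10 bp) tandem insertion in the IGS core."""

    motif: str
    copies: int
    offset: float


@dataclass(frozen=True)
class UnitArchitecture:
    """Lengths and planted contents of one rDNA repeat unit."""

    len_18s: int = 1_800
    len_its1: int = 1_000
    len_5_8s: int = 150
    len_its2: int = 1_000
    len_28s: int = 4_500
    len_igs_core: int = 6_550
    subrepeats: tuple[SubRepeatSpec, ...] = ()
    tes: tuple[TEInsertion, ...] = ()
    microsatellites: tuple[MicrosatelliteSpec, ...] = ()

    def __post_init__(self) -> None:
        for name in ("len_18s", "len_its1", "len_5_8s", "len_its2",
                     "len_28s", "len_igs_core"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def base_length(self) -> int:
        """Unit length before sub-repeat/TE/microsatellite insertions."""
        return (self.len_18s + self.len_its1 + self.len_5_8s
                + self.len_its2 + self.len_28s + self.len_igs_core)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base independent read errors and a read-length law.

    ``read_length`` is the fixed length, or a ``(mean, sigma)`` pair for a
    lognormal law when ``lognormal`` is True. Indels are single-base
    events; there is no homopolymer bias.
    """

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    read_length: int | tuple[float, float] = 40_000
    lognormal: bool = False

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(not 0.0 <= r < 1.0 for r in rates):
            raise ValueError("error rates must be in [0,1)")
        if sum(rates) >= 1.0:
            raise ValueError("error rates must sum to < 1")


@dataclass
class PlantedInterval:
    """A planted feature located on the simulated genome."""

    name: str
    start: int
    end: int
    orientation: str = "plus"
    unit_index: int = -1


@dataclass
class ReadProvenance:
    read_id: str
    start: int
    end: int
    strand: str


@dataclass
class Truth:
    """Ground truth for one simulated locus (and its reads)."""

    genome_id: str
    seed: int
    unit_bounds: list[tuple[int, int]] = field(default_factory=list)
    unit_lengths: list[int] = field(default_factory=list)
    subrepeat_copy_numbers: list[dict[int, int]] = field(default_factory=list)
    subrepeat_spans: list[PlantedInterval] = field(default_factory=list)
    subrepeat_totals: list[int] = field(default_factory=list)
    te_placements: list[PlantedInterval] = field(default_factory=list)
    feature_spans: list[PlantedInterval] = field(default_factory=list)
    reads: list[ReadProvenance] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        # substitute with a uniformly random *different* base
        shifts = rng.integers(1, 4, size=n)
        idx = np.where(hit)[0]
        lookup = {b: i for i, b in enumerate("ACGT")}
        cur = np.array([lookup[b] for b in arr[idx]])
        arr[idx] = BASES[(cur + shifts) % 4]
    return "".join(arr)


def plant_te_library(families: Sequence[str], lengths: Sequence[int],
                     seed: int) -> dict[str, str]:
    """Reproducible random sequences labelled by family, for insertion."""
    if not families:
        raise ValueError("families must be non-empty")
    if len(families) != len(lengths):
        raise ValueError("families and lengths must have equal length")
    rng = np.random.default_rng(seed)
    return {fam: _random_seq(rng, ln) for fam, ln in zip(families, lengths)}


def simulate_locus(architecture: UnitArchitecture, n_units: int,
                   flank_length: int = 2_000, seed: int = 0,
                   te_library: dict[str, str] | None = None,
                   genome_id: str = "synthetic_locus") -> tuple[SeqRecord, Truth]:
    """Build flank + ``n_units`` tandem units + flank, recording truth.

    The base sequence of every region, the sub-repeat master copies, TE
    sequences and microsatellites are drawn once per locus (mimicking
    concerted evolution); only sub-repeat copy numbers (and their per-copy
    substitutions) vary between units.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    arch = architecture
    rng = np.random.default_rng(seed)

    base = {
        "18S": _random_seq(rng, arch.len_18s),
        "ITS1": _random_seq(rng, arch.len_its1),
        "5.8S": _random_seq(rng, arch.len_5_8s),
        "ITS2": _random_seq(rng, arch.len_its2),
        "28S": _random_seq(rng, arch.len_28s),
        "IGS": _random_seq(rng, arch.len_igs_core),
    }
    masters = [_random_seq(rng, s.period) for s in arch.subrepeats]
    if te_library is None and arch.tes:
        te_library = plant_te_library(
            [t.family for t in arch.tes], [t.length for t in arch.tes],
            seed=int(rng.integers(0, 2**31)))

    truth = Truth(genome_id=genome_id, seed=seed)
    parts: list[str] = []
    left_flank = _random_seq(rng, flank_length)
    parts.append(left_flank)
    pos = flank_length

    for u in range(n_units):
        unit_start = pos
        cn_draws: dict[int, int] = {}
        sub_total = 0

        # spacer insertions, grouped per host region
        def build_region(name: str, region_seq: str) -> str:
            nonlocal pos, sub_total
            inserts: list[tuple[int, str, str, str]] = []  # (point, seq, kind, label)
            for si, spec in enumerate(arch.subrepeats):
                if spec.location != name:
                    continue
                cn = int(rng.integers(spec.cn_low, spec.cn_high + 1))
                cn_draws[si] = cn
                copies = [_mutate(rng, masters[si], spec.divergence)
                          for _ in range(cn)]
                arr_seq = "".join(copies)
                point = int(spec.offset * len(region_seq))
                inserts.append((point, arr_seq, "subrepeat", f"SR{si}_p{spec.period}"))
                sub_total += len(arr_seq)
            if name == "IGS":
                for te in arch.tes:
                    seq = te_library[te.family]  # type: ignore[index]
                    if te.orientation == "minus":
                        seq = reverse_complement(seq)
                    inserts.append((int(te.offset * len(region_seq)), seq,
                                    "te", f"{te.family}:{te.orientation}"))
                for ms in arch.microsatellites:
                    inserts.append((int(ms.offset * len(region_seq)),
                                    ms.motif * ms.copies, "microsatellite",
                                    f"MS_{ms.motif}"))
            inserts.sort(key=lambda t: t[0])
            out: list[str] = []
            cursor = 0
            region_start = pos
            offset_in_built = 0
            for point, ins_seq, kind, label in inserts:
                out.append(region_seq[cursor:point])
                offset_in_built += point - cursor
                start = region_start + offset_in_built
                end = start + len(ins_seq)
                interval = PlantedInterval(label, start, end, unit_index=u)
                if kind == "subrepeat":
                    truth.subrepeat_spans.append(interval)
                elif kind == "te":
                    fam, _, ori = label.partition(":")
                    truth.te_placements.append(
                        PlantedInterval(fam, start, end, orientation=ori,
                                        unit_index=u))
                out.append(ins_seq)
                offset_in_built += len(ins_seq)
                cursor = point
            out.append(region_seq[cursor:])
            built = "".join(out)
            truth.feature_spans.append(
                PlantedInterval(name, pos, pos + len(built), unit_index=u))
            pos += len(built)
            return built

        for name in ("18S", "ITS1", "5.8S", "ITS2", "28S", "IGS"):
            parts.append(build_region(name, base[name]))

        truth.unit_bounds.append((unit_start, pos))
        truth.unit_lengths.append(pos - unit_start)
        truth.subrepeat_copy_numbers.append(cn_draws)
        truth.subrepeat_totals.append(sub_total)

    parts.append(_random_seq(rng, flank_length))
    genome = SeqRecord(genome_id, "".join(parts))
    return genome, truth


def _draw_length(rng: np.random.Generator, model: ErrorModel, genome_len: int) -> int:
    if model.lognormal:
        mean, sigma = model.read_length  # type: ignore[misc]
        mu = float(np.log(mean) - 0.5 * sigma**2)
        length = int(rng.lognormal(mu, sigma))
    else:
        length = int(model.read_length)  # type: ignore[arg-type]
    if length > genome_len:
        raise ValueError("requested read length exceeds genome length")
    return max(length, 1)


def _apply_errors(rng: np.random.Generator, seq: str, model: ErrorModel) -> str:
    s, i, d = (model.substitution_rate, model.insertion_rate,
               model.deletion_rate)
    if s == i == d == 0.0:
        return seq
    out: list[str] = []
    u = rng.random(len(seq))
    v = rng.random(len(seq))
    lookup = {b: k for k, b in enumerate("ACGT")}
    sub_shift = rng.integers(1, 4, size=len(seq))
    ins_base = rng.integers(0, 4, size=len(seq))
    for j, b in enumerate(seq):
        if u[j] < d:
            pass  # deletion
        elif u[j] < d + s:
            out.append("ACGT"[(lookup.get(b.upper(), 0) + sub_shift[j]) % 4])
        else:
            out.append(b)
        if v[j] < i:
            out.append("ACGT"[ins_base[j]])
    return "".join(out)


def simulate_reads(genome: SeqRecord, truth: Truth, error_model: ErrorModel,
                   n_reads: int, seed: int = 0,
                   read_prefix: str = "read") -> tuple[list[SeqRecord], Truth]:
    """Draw reads uniformly by start position, fair-coin strand, apply
    per-base errors, and record each read's error-free source interval.

    The input ``truth`` is not mutated; the returned copy carries the
    appended read provenance.
    """
    rng = np.random.default_rng(seed)
    glen = len(genome.sequence)
    truth = replace(truth, reads=list(truth.reads))
    reads: list[SeqRecord] = []
    for r in range(n_reads):
        length = _draw_length(rng, error_model, glen)
        start = int(rng.integers(0, max(glen - 1, 1)))
        end = min(start + length, glen)
        source = genome.sequence[start:end]
        strand = "plus" if rng.random() < 0.5 else "minus"
        if strand == "minus":
            source = reverse_complement(source)
        seq = _apply_errors(rng, source, error_model)
        read_id = f"{read_prefix}_{r:05d}"
        reads.append(SeqRecord(read_id, seq))
        truth.reads.append(ReadProvenance(read_id, start, end, strand))
    return reads, truth


def default_feature_references(architecture: UnitArchitecture, seed: int,
                               ) -> dict[str, str]:
    """Error-free reference sequences for 18S/5.8S/28S and the whole base
    unit, as drawn by :func:`simulate_locus` for the same seed."""
    rng = np.random.default_rng(seed)
    refs = {
        "18S": _random_seq(rng, architecture.len_18s),
        "ITS1": _random_seq(rng, architecture.len_its1),
        "5.8S": _random_seq(rng, architecture.len_5_8s),
        "ITS2": _random_seq(rng, architecture.len_its2),
        "28S": _random_seq(rng, architecture.len_28s),
        "IGS": _random_seq(rng, architecture.len_igs_core),
    }
    refs["UNIT"] = (refs["18S"] + refs["ITS1"] + refs["5.8S"] + refs["ITS2"]
                    + refs["28S"] + refs["IGS"])
    return refs
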