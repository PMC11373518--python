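"""Orchestrate the full analysis: simulate -> scan -> size -> consensus
-> subrepeats -> te-ortho, from one flat key=value config, with a
checksummed output manifest. Identical config + seed gives identical
manifest checksums.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

from . import consensus_annotation as ca
from . import feature_search as fs
from . import subrepeat_analysis as sa
from . import synthetic_data as syn
from . import te_orthology as te
from . import unit_sizing as us
from .io_formats import GffFeature, write_fasta, write_gff3


@dataclass
class PipelineConfig:
    """Every tunable of the simulated end-to-end run, with defaults."""

    out_dir: str = "rdnakit_out"
    seed: int = 0
    # simulated locus
    n_units: int = 6
    flank_length: int = 2000
    unit_18s: int = 1800
    unit_its1: int = 1000
    unit_5_8s: int = 150
    unit_its2: int = 1000
    unit_28s: int = 4500
    unit_igs_core: int = 6550
    subrepeat_period: int = 105
    subrepeat_cn_low: int = 5
    subrepeat_cn_high: int = 12
    subrepeat_divergence: float = 0.02
    # reads
    n_reads: int = 40
    read_length: int = 40000
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    # analysis thresholds
    anchor_feature: str = "18S"
    anchor_coverage: float = 0.8
    min_identity: float = 0.75
    min_feature_coverage: float = 0.5
    seed_k: int = 15
    selfmatch_k: int = 12
    degenerate_identity: float = 0.7
    size_normal_low: int = 8000
    size_normal_high: int = 20000
    size_large_min: int = 30000
    max_consensus_units: int = 15
    bandwidth: float = 0.0  # 0 = automatic (bw.nrd0)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of violations (empty iff the config is valid)."""
    v: list[str] = []
    c = config
    for name in ("anchor_coverage", "min_identity", "min_feature_coverage",
                 "degenerate_identity"):
        val = getattr(c, name)
        if not 0.0 <= val <= 1.0:
            v.append(f"{name} not in [0,1]: {val}")
    for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
        val = getattr(c, name)
        if not 0.0 <= val < 1.0:
            v.append(f"{name} not in [0,1): {val}")
    if c.substitution_rate + c.insertion_rate + c.deletion_rate >= 1.0:
        v.append("error rates sum to >= 1")
    if not (0 < c.size_normal_low < c.size_normal_high <= c.size_large_min):
        v.append("size class bounds unordered: need 0 < normal_low < "
                 "normal_high <= large_min")
    if c.seed_k < 8:
        v.append(f"seed_k < 8: {c.seed_k}")
    if c.n_units < 1:
        v.append("n_units < 1")
    if c.n_reads < 1:
        v.append("n_reads < 1")
    for name in ("unit_18s", "unit_its1", "unit_5_8s", "unit_its2",
                 "unit_28s", "unit_igs_core", "read_length", "flank_length"):
        if getattr(c, name) <= 0 and name != "flank_length":
            v.append(f"{name} must be > 0")
    if c.anchor_feature not in ("18S", "5.8S", "28S", "UNIT"):
        v.append(f"unknown anchor_feature {c.anchor_feature!r}")
    return v


def load_config(path: str | Path, overrides: dict[str, str] | None = None,
                ) -> PipelineConfig:
    """Read a flat ``key = value`` config file, then apply overrides."""
    values: dict[str, str] = {}
    text = Path(path).read_text() if path else ""
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno} is not key=value")
        k, _, val = line.partition("=")
        values[k.strip()] = val.strip()
    if overrides:
        values.update(overrides)
    cfg = PipelineConfig()
    types = {f.name: f.type for f in fields(PipelineConfig)}
    for k, val in values.items():
        if k not in types:
            raise ValueError(f"unknown config key {k!r}")
        current = getattr(cfg, k)
        if isinstance(current, int) and not isinstance(current, bool):
            setattr(cfg, k, int(val))
        elif isinstance(current, float):
            setattr(cfg, k, float(val))
        else:
            setattr(cfg, k, val)
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, log=print) -> dict[str, str]:
    """Run all six stages on a simulated locus; returns the manifest
    mapping output file names to sha256 prefixes."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    c = config

    def stage(name: str, t0: float) -> None:
        log(f"[{name}] done in {time.perf_counter() - t0:.2f}s")

    # --- simulate ---------------------------------------------------------
    t0 = time.perf_counter()
    arch = syn.UnitArchitecture(
        len_18s=c.unit_18s, len_its1=c.unit_its1, len_5_8s=c.unit_5_8s,
        len_its2=c.unit_its2, len_28s=c.unit_28s, len_igs_core=c.unit_igs_core,
        subrepeats=(syn.SubRepeatSpec(
            period=c.subrepeat_period, cn_low=c.subrepeat_cn_low,
            cn_high=c.subrepeat_cn_high, divergence=c.subrepeat_divergence),),
        tes=(syn.TEInsertion("LINE/L1", "plus", 600, 0.55),
             syn.TEInsertion("SINE/Alu", "minus", 300, 0.8)),
    )
    genome, truth = syn.simulate_locus(arch, c.n_units,
                                       flank_length=c.flank_length, seed=c.seed)
    model = syn.ErrorModel(substitution_rate=c.substitution_rate,
                           insertion_rate=c.insertion_rate,
                           deletion_rate=c.deletion_rate,
                           read_length=min(c.read_length, len(genome.sequence)))
    reads, truth = syn.simulate_reads(genome, truth, model, c.n_reads,
                                      seed=c.seed + 1)
    write_fasta([genome], out / "genome.fasta")
    write_fasta(reads, out / "reads.fasta")
    truth_feats = [GffFeature(seqid=genome.id, type=p.name, start0=p.start,
                              end0=p.end, feature_id=f"truth_{i}")
                   for i, p in enumerate(truth.feature_spans)]
    write_gff3(truth_feats, out / "truth.gff3")
    stage("simulate", t0)

    # --- scan -------------------------------------------------------------
    t0 = time.perf_counter()
    refs = syn.default_feature_references(arch, seed=c.seed)
    feature_refs = {k: refs[k] for k in ("18S", "5.8S", "28S")}
    hits: list[fs.FeatureHit] = []
    for read in reads:
        hits.extend(fs.find_feature_hits(
            read, feature_refs, k=c.seed_k, min_identity=c.min_identity,
            min_feature_coverage=c.min_feature_coverage))
    fs.write_hits_tsv(hits, out / "hits.tsv")
    stage("scan", t0)

    # --- size -------------------------------------------------------------
    t0 = time.perf_counter()
    observations = us.measure_unit_lengths(hits, c.anchor_feature,
                                           min_coverage=c.anchor_coverage)
    us.write_observations_tsv(observations, out / "unit_observations.tsv")
    if observations:
        summary = us.summarize_sizes(
            observations, bandwidth=c.bandwidth or None)
        us.write_summary_tsv(summary, out / "size_summary.tsv")
    stage("size", t0)

    # --- consensus --------------------------------------------------------
    t0 = time.perf_counter()
    candidates: list[ca.RotatedUnit] = []
    for read in reads:
        read_hits = [h for h in hits if h.read_id == read.id]
        candidates.extend(ca.extract_rotated_units(
            read, read_hits, min_coverage=c.anchor_coverage))
    selected = ca.select_units(candidates, c.max_consensus_units)
    annotation = None
    if selected:
        consensus, _single = ca.build_consensus(selected)
        write_fasta([consensus], out / "consensus.fasta")
        annotation = ca.annotate_unit(consensus, feature_refs)
        write_gff3(ca.annotation_to_gff(annotation, consensus.id),
                   out / "consensus_annotation.gff3")
        rows = ca.region_length_report({"simulated": annotation})
        ca.write_region_report_tsv(rows, out / "region_lengths.tsv")
    stage("consensus", t0)

    # --- subrepeats -------------------------------------------------------
    t0 = time.perf_counter()
    if selected and annotation is not None:
        consensus_seq = consensus.sequence
        arrays = sa.detect_tandem_arrays(
            consensus_seq, k=c.selfmatch_k,
            degenerate_identity=c.degenerate_identity, annotation=annotation)
        sa.write_arrays_tsv(arrays, out / "subrepeat_arrays.tsv")
        # per-unit variance attribution from the simulator truth
        att = sa.variance_explained_by_subrepeats(
            truth.unit_lengths, truth.subrepeat_totals)
        with open(out / "variance_attribution.tsv", "w") as fh:
            fh.write("n_units\tvar_total\tvar_residual\tfraction_explained\n")
            frac = ("NA" if att.fraction_explained is None
                    else f"{att.fraction_explained:.4f}")
            fh.write(f"{att.n_units}\t{att.var_total:.1f}\t"
                     f"{att.var_residual:.1f}\t{frac}\n")
    stage("subrepeats", t0)

    # --- te-ortho ---------------------------------------------------------
    # the two simulated IGSs to compare: the planted TE layouts of the
    # first two units (every unit carries the same planted TEs, so this
    # exercises the matcher on a fully-matched instance)
    t0 = time.perf_counter()
    def unit_tes(u: int) -> list[te.TERecord]:
        out_list = []
        for p in truth.te_placements:
            if p.unit_index == u:
                out_list.append(te.TERecord(
                    family=p.name, name=p.name, orientation=p.orientation,
                    start=p.start, end=p.end))
        return sorted(out_list, key=lambda t: t.start)
    if c.n_units >= 2:
        tes_a, tes_b = unit_tes(0), unit_tes(1)
        matching = te.match_orthologous_tes(tes_a, tes_b)
        igs_a = next(p for p in truth.feature_spans
                     if p.name == "IGS" and p.unit_index == 0)
        igs_b = next(p for p in truth.feature_spans
                     if p.name == "IGS" and p.unit_index == 1)
        report = te.orthology_report(matching, tes_a, tes_b,
                                     igs_a.end - igs_a.start,
                                     igs_b.end - igs_b.start)
        te.write_orthology_tsv(report, matching, tes_a, tes_b,
                               out / "te_orthology.tsv",
                               out / "te_orthology_pairs.tsv")
    stage("te-ortho", t0)

    for path in sorted(out.iterdir()):
        if path.is_file():
            manifest[path.name] = _checksum(path)
    with open(out / "MANIFEST.tsv", "w") as fh:
        fh.write("file\tsha256_16\n")
        for name, digest in manifest.items():
            fh.write(f"{name}\t{digest}\n")
    return manifest
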