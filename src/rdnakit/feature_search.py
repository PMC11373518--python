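"""Locate rDNA features (18S/5.8S/28S or a whole unit) on long reads.

The internal matcher is a classic seed-and-extend: exact k-mer seeds
(default k=15) outside DUST-masked and soft-masked intervals, clustered
by diagonal, then a banded edit-distance alignment (edlib) of the feature
against the implied read window. ONT errors fragment a single feature
occurrence into several local matches, so hits are chained when
co-linear. An adapter converts external BLAST tabular hits into the same
FeatureHit shape so either source feeds the sizing stage.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import edlib

from .io_formats import SeqRecord, TabularHit, reverse_complement, to_internal_interval

FEATURE_LABELS = ("18S", "5.8S", "28S", "UNIT")


@dataclass(frozen=True)
class FeatureHit:
    """One located occurrence of an rDNA feature on a read/contig.

    ``start``/``end`` are 0-based half-open on the read's forward
    representation; ``feature_start``/``feature_end`` locate the covered
    part of the feature reference (forward feature coordinates).
    """

    read_id: str
    feature: str
    start: int
    end: int
    strand: str  # "plus" | "minus"
    identity: float
    feature_coverage: float
    feature_start: int
    feature_end: int
    ref_length: int
    source: str = "internal"  # "internal" | "blast_adapter"
    chain_members: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit interval must be non-empty")
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.feature_coverage <= 1.0):
            raise ValueError("identity and coverage must be in [0,1]")


# ---------------------------------------------------------------------------
# DUST low-complexity masking


def dust_mask(sequence: str, window: int = 64, threshold: float = 20.0,
              ) -> list[tuple[int, int]]:
    """Classic DUST: mask windows whose triplet score exceeds threshold.

    Score of a window = 10 * sum_t c_t(c_t-1)/2 / (n_triplets - 1), where
    c_t counts occurrences of triplet t among the window's overlapping
    triplets — the scaling used by the classic masker, under which random
    DNA scores ~5 and the default threshold of 20 flags only genuinely
    low-complexity runs. High-scoring sliding windows are unioned into
    intervals.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 3:
        return []
    trips = [seq[i:i + 3] for i in range(n - 2)]
    w = min(window, n)
    ntrip_in_window = w - 2
    counts: dict[str, int] = defaultdict(int)
    score = 0  # running sum of c_t(c_t-1)/2
    masked: list[tuple[int, int]] = []

    def push(t: str) -> None:
        nonlocal score
        score += counts[t]
        counts[t] += 1

    def pop(t: str) -> None:
        nonlocal score
        counts[t] -= 1
        score -= counts[t]

    scale = 10.0 / max(ntrip_in_window - 1, 1)
    for i in range(ntrip_in_window):
        push(trips[i])
    for start in range(0, n - w + 1):
        if score * scale > threshold:
            masked.append((start, start + w))
        last = start + ntrip_in_window
        if last < len(trips):
            pop(trips[start])
            push(trips[last])
    if not masked:
        return []
    merged = [list(masked[0])]
    for s, e in masked[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


# ---------------------------------------------------------------------------
# internal seed-and-extend matcher


def _kmer_index(seq: str, k: int, blocked: Sequence[bool] | None) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        if blocked is not None and blocked[i]:
            continue
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        index[kmer].append(i)
    return index


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    """Return (aligned_query_bases, insertions, deletions, columns)."""
    aligned = ins = dele = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch in "=X":
                aligned += n
            elif ch == "I":
                ins += n
            elif ch == "D":
                dele += n
    return aligned, ins, dele, cols


def _seed_clusters(seeds: list[tuple[int, int]], band: int, max_gap: int,
                   ) -> list[list[tuple[int, int]]]:
    """Group (read_pos, feat_pos) seeds into co-linear clusters."""
    clusters: list[dict] = []
    for rpos, fpos in sorted(seeds):
        diag = rpos - fpos
        placed = False
        for cl in clusters:
            if (abs(diag - cl["diag"]) <= band
                    and rpos - cl["last_r"] <= max_gap
                    and fpos >= cl["last_f"] - band):
                cl["seeds"].append((rpos, fpos))
                cl["last_r"] = rpos
                cl["last_f"] = max(cl["last_f"], fpos)
                cl["diag"] = 0.8 * cl["diag"] + 0.2 * diag
                placed = True
                break
        if not placed:
            clusters.append({"seeds": [(rpos, fpos)], "diag": float(diag),
                             "last_r": rpos, "last_f": fpos})
    return [cl["seeds"] for cl in clusters]


def _extend_cluster(read_seq: str, feature_seq: str, cluster: list[tuple[int, int]],
                    k: int, band: int) -> dict | None:
    flen = len(feature_seq)
    rmin = min(r for r, _ in cluster)
    rmax = max(r for r, _ in cluster)
    fmin = min(f for _, f in cluster)
    fmax = max(f for _, f in cluster) + k
    win_start = max(0, rmin - fmin - band)
    win_end = min(len(read_seq), rmax + k + (flen - fmax) + band)
    window = read_seq[win_start:win_end].upper()
    if not window:
        return None
    res = edlib.align(feature_seq, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("locations"):
        return None
    loc0, loc1 = res["locations"][0]
    aligned, ins, dele, cols = _cigar_stats(res["cigar"])
    # feature bases unaligned at the window edges ("I" runs there) are
    # sequence falling off the read: they reduce coverage, and identity is
    # computed over the interior (actually aligned) columns only
    lead_ins, trail_ins = _edge_insertions(res["cigar"])
    interior_cols = max(cols - lead_ins - trail_ins, 1)
    interior_err = max(res["editDistance"] - lead_ins - trail_ins, 0)
    identity = max(0.0, 1.0 - interior_err / interior_cols)
    coverage = aligned / flen
    feature_start = lead_ins
    feature_end = flen - trail_ins
    # a hit abutting a read boundary may be a truncated feature whose
    # missing part the aligner absorbed as scattered gaps instead of an
    # edge run; the seed evidence bounds what is genuinely present
    start = win_start + loc0
    end = win_start + loc1 + 1
    if start == 0:
        feature_start = max(feature_start, fmin)
    if end == len(read_seq):
        feature_end = min(feature_end, fmax)
    if feature_end <= feature_start:
        return None
    coverage = min(coverage, (feature_end - feature_start) / flen)
    return {
        "start": start,
        "end": end,
        "identity": identity,
        "coverage": coverage,
        "feature_start": feature_start,
        "feature_end": feature_end,
    }


def _edge_insertions(cigar: str) -> tuple[int, int]:
    ops: list[tuple[int, str]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    lead = ops[0][0] if ops and ops[0][1] == "I" else 0
    trail = ops[-1][0] if len(ops) > 1 and ops[-1][1] == "I" else 0
    return lead, trail


def find_feature_hits(read: SeqRecord, feature_refs: Mapping[str, str],
                      k: int = 15, min_identity: float = 0.75,
                      min_feature_coverage: float = 0.5,
                      mask: bool = True) -> list[FeatureHit]:
    """Search both strands of ``read`` for each labelled feature reference.

    Seeds are exact k-mers of the read outside DUST-masked and lowercase
    (soft-masked) intervals; co-linear seed clusters are extended with a
    banded edit-distance alignment. Hits below ``min_identity`` or
    ``min_feature_coverage`` are discarded. Hits are reported in forward
    read coordinates; minus-strand hits come from matching the reverse
    complement of the feature.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    seq = read.sequence
    n = len(seq)
    if n < k:
        return []
    blocked = [False] * (n - k + 1)
    if mask:
        intervals = dust_mask(seq)
        for s, e in intervals:
            for i in range(max(0, s), min(n - k + 1, e)):
                blocked[i] = True
        for i in range(n - k + 1):  # soft-mask: seed must be fully uppercase
            if not blocked[i] and not seq[i:i + k].isupper():
                blocked[i] = True
    read_index = _kmer_index(seq.upper(), k, blocked)

    hits: list[FeatureHit] = []
    for label, ref in feature_refs.items():
        flen = len(ref)
        band = max(16, int(0.2 * flen))
        for strand in ("plus", "minus"):
            fseq = ref.upper() if strand == "plus" else reverse_complement(ref.upper())
            seeds: list[tuple[int, int]] = []
            for fpos in range(flen - k + 1):
                kmer = fseq[fpos:fpos + k]
                for rpos in read_index.get(kmer, ()):
                    seeds.append((rpos, fpos))
            if not seeds:
                continue
            for cluster in _seed_clusters(seeds, band=band, max_gap=2_000):
                if len(cluster) * k < 0.05 * flen:  # spurious
                    continue
                ext = _extend_cluster(seq, fseq, cluster, k, band)
                if ext is None:
                    continue
                if ext["identity"] < min_identity or ext["coverage"] < min_feature_coverage:
                    continue
                fs, fe = ext["feature_start"], ext["feature_end"]
                if strand == "minus":  # report in forward feature coords
                    fs, fe = flen - fe, flen - fs
                hits.append(FeatureHit(
                    read_id=read.id, feature=label,
                    start=ext["start"], end=ext["end"], strand=strand,
                    identity=round(ext["identity"], 6),
                    feature_coverage=round(min(ext["coverage"], 1.0), 6),
                    feature_start=fs, feature_end=fe, ref_length=flen,
                ))
    hits.sort(key=lambda h: (h.feature, h.strand, h.start))
    return chain_hits(hits)


# ---------------------------------------------------------------------------
# chaining


def _colinear(prev: FeatureHit, nxt: FeatureHit, max_gap: int, tol: int = 100) -> bool:
    if nxt.start - prev.end > max_gap:
        return False
    if prev.strand == "plus":
        return nxt.feature_start >= prev.feature_end - tol
    return nxt.feature_end <= prev.feature_start + tol


def _merge(prev: FeatureHit, nxt: FeatureHit) -> FeatureHit:
    w1 = prev.feature_end - prev.feature_start
    w2 = nxt.feature_end - nxt.feature_start
    identity = (prev.identity * w1 + nxt.identity * w2) / max(w1 + w2, 1)
    fs = min(prev.feature_start, nxt.feature_start)
    fe = max(prev.feature_end, nxt.feature_end)
    return replace(
        prev,
        start=min(prev.start, nxt.start),
        end=max(prev.end, nxt.end),
        identity=round(identity, 6),
        feature_start=fs,
        feature_end=fe,
        feature_coverage=round(min((fe - fs) / prev.ref_length, 1.0), 6),
        chain_members=prev.chain_members + nxt.chain_members,
    )


def chain_hits(hits: Sequence[FeatureHit], same_feature_max_gap: int = 2_000,
               ) -> list[FeatureHit]:
    """Merge co-linear same-feature same-strand fragments.

    Overlapping same-feature same-strand hits are always merged so the
    output satisfies the no-overlap invariant; chaining is idempotent.
    """
    by_key: dict[tuple[str, str, str], list[FeatureHit]] = defaultdict(list)
    for h in hits:
        by_key[(h.read_id, h.feature, h.strand)].append(h)
    out: list[FeatureHit] = []
    for key, group in by_key.items():
        group.sort(key=lambda h: h.start)
        chained = [group[0]]
        for h in group[1:]:
            prev = chained[-1]
            if h.start < prev.end or _colinear(prev, h, same_feature_max_gap):
                chained[-1] = _merge(prev, h)
            else:
                chained.append(h)
        out.extend(chained)
    out.sort(key=lambda h: (h.read_id, h.start, h.feature, h.strand))
    return out


# ---------------------------------------------------------------------------
# BLAST adapter


def adapt_blast_hits(tabular_hits: Iterable[TabularHit],
                     feature_label_map: Mapping[str, str],
                     reference_lengths: Mapping[str, int],
                     query_is_read: bool = False) -> list[FeatureHit]:
    """Convert BLAST tabular hits (query = rDNA feature, subject = read,
    unless ``query_is_read``) into FeatureHits in internal coordinates."""
    unmapped = sorted({
        (h.subject_id if query_is_read else h.query_id)
        for h in tabular_hits
        if (h.subject_id if query_is_read else h.query_id) not in feature_label_map
    })
    if unmapped:
        raise ValueError(f"unmapped feature query ids: {unmapped}")
    out: list[FeatureHit] = []
    for h in tabular_hits:
        if query_is_read:
            read_id = h.query_id
            label = feature_label_map[h.subject_id]
            r1, r2 = h.query_start, h.query_end
            f1, f2 = h.subject_start, h.subject_end
        else:
            read_id = h.subject_id
            label = feature_label_map[h.query_id]
            r1, r2 = h.subject_start, h.subject_end
            f1, f2 = h.query_start, h.query_end
        start0, end0, strand_r = to_internal_interval(r1, r2)
        fstart0, fend0, strand_f = to_internal_interval(f1, f2)
        strand = "plus" if strand_r == strand_f else "minus"
        ref_len = reference_lengths[label]
        out.append(FeatureHit(
            read_id=read_id, feature=label, start=start0, end=end0,
            strand=strand, identity=h.percent_identity / 100.0,
            feature_coverage=round(min(h.alignment_length / ref_len, 1.0), 6),
            feature_start=fstart0, feature_end=fend0, ref_length=ref_len,
            source="blast_adapter",
        ))
    out.sort(key=lambda x: (x.read_id, x.start, x.feature, x.strand))
    return out


# ---------------------------------------------------------------------------
# TSV externalization (consumed by the sizing stage / CLI)

HIT_COLUMNS = ("read_id", "feature", "start", "end", "strand", "identity",
               "feature_coverage", "feature_start", "feature_end",
               "ref_length", "source", "chain_members")


def write_hits_tsv(hits: Iterable[FeatureHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write("\t".join(str(getattr(h, c)) for c in HIT_COLUMNS) + "\n")


def read_hits_tsv(path) -> list[FeatureHit]:
    hits: list[FeatureHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != HIT_COLUMNS:
            raise ValueError(f"{path}: unexpected hits TSV header")
        for line in fh:
            v = dict(zip(HIT_COLUMNS, line.rstrip("\n").split("\t")))
            hits.append(FeatureHit(
                read_id=v["read_id"], feature=v["feature"],
                start=int(v["start"]), end=int(v["end"]), strand=v["strand"],
                identity=float(v["identity"]),
                feature_coverage=float(v["feature_coverage"]),
                feature_start=int(v["feature_start"]),
                feature_end=int(v["feature_end"]),
                ref_length=int(v["ref_length"]), source=v["source"],
                chain_members=int(v["chain_members"]),
            ))
    return hits
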