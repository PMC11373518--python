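"""Feature location: DUST masking against a brute-force oracle, the
seed-and-extend matcher on planted copies, chaining, and the BLAST
adapter."""

import numpy as np
import pytest

from rdnakit import feature_search as fs
from rdnakit.io_formats import SeqRecord, TabularHit, reverse_complement


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def dust_oracle(sequence, window=64, threshold=20.0):
    """Brute-force DUST: score every window independently from scratch."""
    seq = sequence.upper()
    n = len(seq)
    out = set()
    w = min(window, n)
    if n < 3:
        return []
    for start in range(0, n - w + 1):
        trips = [seq[i:i + 3] for i in range(start, start + w - 2)]
        counts = {}
        for t in trips:
            counts[t] = counts.get(t, 0) + 1
        raw = sum(c * (c - 1) // 2 for c in counts.values())
        if 10.0 * raw / max(len(trips) - 1, 1) > threshold:
            out.update(range(start, start + w))
    # merge into intervals
    intervals = []
    for p in sorted(out):
        if intervals and p == intervals[-1][1]:
            intervals[-1][1] = p + 1
        else:
            intervals.append([p, p + 1])
    return [(s, e) for s, e in intervals]


class TestDustMask:
    def test_homopolymer_masked(self, rng):
        seq = random_seq(rng, 150) + "A" * 200 + random_seq(rng, 150)
        got = fs.dust_mask(seq)
        expect = dust_oracle(seq)
        assert got == expect
        # one interval covering (nearly) the whole run
        assert len(got) == 1
        s, e = got[0]
        assert s <= 160 and e >= 340

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_on_random_and_dirty_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = (random_seq(rng, 300) + "AT" * 60 + random_seq(rng, 200)
               + "CAG" * 40 + random_seq(rng, 100))
        assert fs.dust_mask(seq) == dust_oracle(seq)

    def test_random_sequence_unmasked(self, rng):
        assert fs.dust_mask(random_seq(rng, 2000)) == []

    def test_empty_and_short(self):
        assert fs.dust_mask("") == []
        assert fs.dust_mask("AC") == []


class TestFindFeatureHits:
    def make_read(self, rng, ref, mutate=None):
        planted = ref if mutate is None else mutate(ref)
        left, right = random_seq(rng, 500), random_seq(rng, 500)
        return SeqRecord("read1", left + planted + right), (500, 500 + len(planted))

    def test_exact_planted_copy(self, rng):
        ref = random_seq(rng, 1800)
        read, (s, e) = self.make_read(rng, ref)
        (hit,) = fs.find_feature_hits(read, {"18S": ref})
        assert (hit.start, hit.end) == (s, e)
        assert hit.strand == "plus"
        assert hit.identity == 1.0 and hit.feature_coverage == 1.0

    def test_reverse_complement_mirrored(self, rng):
        ref = random_seq(rng, 1800)
        read, (s, e) = self.make_read(rng, ref)
        rc = SeqRecord("read1", reverse_complement(read.sequence))
        (hit,) = fs.find_feature_hits(rc, {"18S": ref})
        n = len(read.sequence)
        assert hit.strand == "minus"
        assert (hit.start, hit.end) == (n - e, n - s)
        assert hit.identity == 1.0

    def test_five_percent_substitutions_identity(self, rng):
        ref = random_seq(rng, 1800)

        def mutate(seq):
            arr = list(seq)
            pos = rng.choice(len(arr), size=int(0.05 * len(arr)), replace=False)
            for p in pos:
                arr[p] = "ACGT"[("ACGT".index(arr[p]) + 1 + rng.integers(0, 3)) % 4]
            return "".join(arr)

        read, _ = self.make_read(rng, ref, mutate)
        hits = fs.find_feature_hits(read, {"18S": ref})
        assert len(hits) == 1
        # <=5% of bases differ (some substitutions may re-draw the base)
        assert hits[0].identity == pytest.approx(0.95, abs=0.02)

    def test_read_shorter_than_k_empty(self):
        assert fs.find_feature_hits(SeqRecord("r", "ACGT"), {"18S": "A" * 100}) == []

    def test_strand_symmetry_property(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            ref = random_seq(rng, 600)
            read = SeqRecord(
                "r", random_seq(rng, 300) + ref + random_seq(rng, 200)
                + reverse_complement(ref) + random_seq(rng, 300))
            fwd = fs.find_feature_hits(read, {"F": ref})
            rc_read = SeqRecord("r", reverse_complement(read.sequence))
            rev = fs.find_feature_hits(rc_read, {"F": ref})
            n = len(read.sequence)
            mirrored = sorted((n - h.end, n - h.start,
                               "plus" if h.strand == "minus" else "minus")
                              for h in rev)
            assert mirrored == sorted((h.start, h.end, h.strand) for h in fwd)

    def test_every_planted_instance_found_once(self, clean_locus):
        genome, truth, refs = clean_locus
        from rdnakit import synthetic_data as syn
        model = syn.ErrorModel(read_length=40_000)
        reads, truth = syn.simulate_reads(genome, truth, model, 12, seed=21)
        for read, prov in zip(reads, truth.reads):
            hits = fs.find_feature_hits(read, {"18S": refs["18S"]})
            contained = [
                f for f in truth.feature_spans
                if f.name == "18S" and f.start >= prov.start and f.end <= prov.end
            ]
            full = [h for h in hits if h.feature_coverage == 1.0]
            assert len(full) == len(contained)
            assert all(h.identity == 1.0 for h in full)


def mk_hit(start, end, fstart, fend, feature="28S", strand="plus",
           identity=0.9, ref_length=4500, read_id="r"):
    return fs.FeatureHit(
        read_id=read_id, feature=feature, start=start, end=end, strand=strand,
        identity=identity, feature_coverage=(fend - fstart) / ref_length,
        feature_start=fstart, feature_end=fend, ref_length=ref_length)


class TestChaining:
    def test_colinear_fragments_merged(self):
        h1 = mk_hit(1000, 3000, 0, 2000)
        h2 = mk_hit(3150, 5550, 2100, 4500)
        (merged,) = fs.chain_hits([h1, h2])
        assert merged.chain_members == 2
        assert (merged.start, merged.end) == (1000, 5550)
        assert merged.feature_coverage == pytest.approx(1.0)

    def test_anti_colinear_not_merged(self):
        h1 = mk_hit(1000, 3000, 2100, 4100)
        h2 = mk_hit(3300, 5300, 0, 2000)
        assert len(fs.chain_hits([h1, h2])) == 2

    def test_opposite_strand_middle_fragment(self):
        h1 = mk_hit(1000, 2000, 0, 1000)
        h2 = mk_hit(2100, 3100, 1000, 2000, strand="minus")
        h3 = mk_hit(3200, 4200, 1100, 2100)
        out = fs.chain_hits([h1, h2, h3])
        assert len(out) == 2  # plus-strand pair merges, minus stays alone
        members = sorted(h.chain_members for h in out)
        assert members == [1, 2]

    def test_idempotent(self):
        hits = [mk_hit(1000, 3000, 0, 2000), mk_hit(3150, 5550, 2100, 4500),
                mk_hit(9000, 9900, 0, 900, feature="18S", ref_length=1800)]
        once = fs.chain_hits(hits)
        assert fs.chain_hits(once) == once

    def test_no_overlaps_after_chaining(self):
        hits = [mk_hit(1000, 3000, 0, 2000), mk_hit(2500, 4500, 1500, 3500),
                mk_hit(4400, 5500, 3400, 4500)]
        out = fs.chain_hits(hits)
        by_key = {}
        for h in out:
            by_key.setdefault((h.feature, h.strand), []).append(h)
        for group in by_key.values():
            group.sort(key=lambda h: h.start)
            for a, b in zip(group, group[1:]):
                assert a.end <= b.start


class TestBlastAdapter:
    def test_plus_hit_converted(self):
        th = TabularHit("18S", "read1", 95.0, 1800, 80, 5, 1, 1800, 100, 1899,
                        0.0, 3000.0)
        (hit,) = fs.adapt_blast_hits([th], {"18S": "18S"}, {"18S": 1800})
        assert (hit.start, hit.end, hit.strand) == (99, 1899, "plus")
        assert hit.identity == pytest.approx(0.95)
        assert hit.feature_coverage == pytest.approx(1.0)
        assert hit.source == "blast_adapter"

    def test_swapped_subject_coords_minus(self):
        th = TabularHit("18S", "read1", 95.0, 1800, 80, 5, 1, 1800, 1899, 100,
                        0.0, 3000.0)
        (hit,) = fs.adapt_blast_hits([th], {"18S": "18S"}, {"18S": 1800})
        assert (hit.start, hit.end, hit.strand) == (99, 1899, "minus")

    def test_unknown_query_label(self):
        th = TabularHit("mystery", "read1", 95.0, 100, 5, 0, 1, 100, 1, 100,
                        0.0, 100.0)
        with pytest.raises(ValueError, match="mystery"):
            fs.adapt_blast_hits([th], {"18S": "18S"}, {"18S": 1800})

    def test_adapter_agrees_with_internal_matcher_on_exact_copy(self, rng):
        ref = random_seq(rng, 1200)
        read = SeqRecord("read9", random_seq(rng, 400) + ref + random_seq(rng, 400))
        (internal,) = fs.find_feature_hits(read, {"18S": ref})
        th = TabularHit("18S", "read9", 100.0, 1200, 0, 0, 1, 1200,
                        internal.start + 1, internal.end, 0.0, 2000.0)
        (adapted,) = fs.adapt_blast_hits([th], {"18S": "18S"}, {"18S": 1200})
        assert (adapted.start, adapted.end, adapted.strand) == (
            internal.start, internal.end, internal.strand)
        assert adapted.identity == internal.identity
        assert adapted.feature_coverage == internal.feature_coverage


class TestHitsTsv:
    def test_round_trip(self, tmp_path):
        hits = [mk_hit(10, 500, 0, 490), mk_hit(900, 1500, 100, 700, strand="minus")]
        p = tmp_path / "hits.tsv"
        fs.write_hits_tsv(hits, p)
        assert fs.read_hits_tsv(p) == hits
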