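"""Tandem-array detection from self-match maps, the microsatellite rule,
and variance attribution."""

import numpy as np
import pytest

from rdnakit import subrepeat_analysis as sa
from rdnakit import synthetic_data as syn
from rdnakit.consensus_annotation import UnitAnnotation


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def mutated_copies(rng, master, n, rate):
    out = []
    for _ in range(n):
        arr = list(master)
        for p in range(len(arr)):
            if rng.random() < rate:
                arr[p] = "ACGT"[("ACGT".index(arr[p]) + 1 + rng.integers(0, 3)) % 4]
        out.append("".join(arr))
    return "".join(out)


class TestSelfMatchMap:
    def test_random_sequence_nearly_empty(self, rng):
        pairs = sa.self_match_map(random_seq(rng, 5_000), k=12)
        # expected duplicate-12-mer count ~ n^2 / 4^12 << 1 per 5 kb
        assert len(pairs) <= 2

    def test_tandem_copies_offsets_are_period_multiples(self, rng):
        seq = random_seq(rng, 100) * 10
        pairs = sa.self_match_map(seq, k=12)
        assert pairs
        assert all((j - i) % 100 == 0 for i, j in pairs)

    def test_strictly_upper_triangular(self, rng):
        seq = random_seq(rng, 60) * 5
        assert all(i < j for i, j in sa.self_match_map(seq, k=12))


class TestDetectTandemArrays:
    def test_exact_105bp_array(self, rng):
        master = random_seq(rng, 105)
        seq = random_seq(rng, 2_000) + master * 10 + random_seq(rng, 2_000)
        (arr,) = sa.detect_tandem_arrays(seq)
        assert abs(arr.period - 105) <= 1
        assert arr.copy_number == pytest.approx(10, abs=0.2)
        assert arr.klass == "subrepeat"
        assert arr.start >= 1_900 and arr.end <= 3_150

    def test_microsatellite_rule(self, rng):
        seq = random_seq(rng, 1_000) + "AT" * 50 + random_seq(rng, 1_000)
        (arr,) = sa.detect_tandem_arrays(seq)
        assert arr.period == 2 and arr.klass == "microsatellite"

    def test_diverged_585bp_array(self):
        rng = np.random.default_rng(17)
        master = random_seq(rng, 585)
        body = mutated_copies(rng, master, 8, 0.12)
        seq = random_seq(rng, 1_500) + body + random_seq(rng, 1_500)
        arrays = sa.detect_tandem_arrays(seq)
        assert len(arrays) == 1
        assert abs(arrays[0].period - 585) <= 5
        # span covers >=90% of the planted array
        overlap = min(arrays[0].end, 1_500 + len(body)) - max(arrays[0].start, 1_500)
        assert overlap >= 0.9 * len(body)

    @pytest.mark.parametrize("period,copies", [(10, 30), (50, 12), (220, 9),
                                               (700, 4)])
    def test_planted_period_recovery(self, period, copies):
        rng = np.random.default_rng(period)
        master = random_seq(rng, period)
        body = mutated_copies(rng, master, copies, 0.05)
        seq = random_seq(rng, 1_000) + body + random_seq(rng, 1_000)
        arrays = sa.detect_tandem_arrays(seq)
        assert arrays, f"period {period} not detected"
        best = max(arrays, key=lambda a: a.span_length)
        # the detected period is p (or a divisor consistent with structure)
        assert best.period <= period + 5
        assert min(best.period % period, -best.period % period) <= 5 or \
            period % best.period <= 5

    def test_degeneracy_threshold_is_a_knob(self, rng):
        master = random_seq(rng, 150)
        body = mutated_copies(rng, master, 10, 0.08)
        seq = random_seq(rng, 800) + body + random_seq(rng, 800)
        (normal,) = sa.detect_tandem_arrays(seq)
        assert normal.klass == "subrepeat"
        (strict,) = sa.detect_tandem_arrays(seq, degenerate_identity=0.95)
        assert strict.klass == "degenerate"
        assert strict.mean_adjacent_identity < 0.95

    def test_no_overlapping_arrays(self, rng):
        m1, m2 = random_seq(rng, 105), random_seq(rng, 40)
        seq = (random_seq(rng, 1_500) + m1 * 8 + random_seq(rng, 1_500)
               + m2 * 12 + random_seq(rng, 1_500))
        arrays = sa.detect_tandem_arrays(seq)
        assert len(arrays) >= 2
        arrays.sort(key=lambda a: a.start)
        for a, b in zip(arrays, arrays[1:]):
            assert a.end <= b.start

    def test_location_label_from_annotation(self, rng):
        ann = UnitAnnotation(intervals=(("18S", 0, 1_000), ("ITS1", 1_000, 2_000),
                                        ("5.8S", 2_000, 2_100),
                                        ("ITS2", 2_100, 2_600),
                                        ("28S", 2_600, 4_000),
                                        ("IGS", 4_000, 9_000)), total=9_000)
        master = random_seq(rng, 100)
        seq = random_seq(rng, 5_000) + master * 8 + random_seq(rng, 3_200)
        (arr,) = sa.detect_tandem_arrays(seq, annotation=ann)
        assert arr.location_label == "IGS"


def annotation_with_igs(igs_start, igs_end, total):
    return UnitAnnotation(intervals=(("18S", 0, 100), ("ITS1", 100, 200),
                                     ("5.8S", 200, 300), ("ITS2", 300, 400),
                                     ("28S", 400, igs_start),
                                     ("IGS", igs_start, igs_end)), total=total)


class TestSubrepeatTotals:
    def test_no_arrays(self):
        ann = annotation_with_igs(1_000, 21_000, 21_000)
        assert sa.subrepeat_totals(ann, []) == (0, 0, 0.0)

    def test_array_inside_igs(self):
        ann = annotation_with_igs(1_000, 21_000, 21_000)
        arr = sa.SubRepeatArray(start=5_000, end=6_000, period=100,
                                copy_number=10, mean_adjacent_identity=0.95,
                                klass="subrepeat")
        total, igs_bp, prop = sa.subrepeat_totals(ann, [arr])
        assert (total, igs_bp) == (1_000, 1_000)
        assert prop == pytest.approx(0.05)

    def test_boundary_straddling_array_counts_overlap_only(self):
        ann = annotation_with_igs(1_000, 21_000, 21_000)
        arr = sa.SubRepeatArray(start=500, end=1_500, period=100,
                                copy_number=10, mean_adjacent_identity=0.95,
                                klass="subrepeat")
        # brute-force base count oracle
        igs_bases = set(range(1_000, 21_000))
        expected = len(igs_bases & set(range(500, 1_500)))
        _, igs_bp, _ = sa.subrepeat_totals(ann, [arr])
        assert igs_bp == expected == 500

    def test_microsatellites_never_counted(self):
        ann = annotation_with_igs(1_000, 21_000, 21_000)
        ms = sa.SubRepeatArray(start=5_000, end=5_200, period=2,
                               copy_number=100, mean_adjacent_identity=1.0,
                               klass="microsatellite")
        assert sa.subrepeat_totals(ann, [ms]) == (0, 0, 0.0)


class TestVarianceAttribution:
    def test_pure_copy_number_variation_gives_one(self):
        arch = syn.UnitArchitecture(subrepeats=(
            syn.SubRepeatSpec(period=105, cn_low=3, cn_high=12),))
        _, truth = syn.simulate_locus(arch, 10, seed=2)
        att = sa.variance_explained_by_subrepeats(truth.unit_lengths,
                                                  truth.subrepeat_totals)
        assert att.fraction_explained == 1.0
        assert att.var_residual == 0.0

    def test_constant_subrepeats_give_zero(self):
        L = [15_000, 15_040, 14_980, 15_020, 15_010]
        S = [900] * 5
        att = sa.variance_explained_by_subrepeats(L, S)
        assert att.fraction_explained == 0.0

    def test_planted_variance_share(self):
        # Var(S) = 9 * Var(other): fraction ~ 0.9 within Monte-Carlo CI
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            S = rng.normal(3_000, 300, size=40)
            other = rng.normal(0, 100, size=40)
            L = 12_000 + S + other
            att = sa.variance_explained_by_subrepeats(L, S)
            fracs.append(att.fraction_explained)
        assert np.mean(fracs) == pytest.approx(0.9, abs=0.03)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        S = rng.normal(2_000, 250, size=10)
        L = 13_000 + S + rng.normal(0, 80, size=10)
        a1 = sa.variance_explained_by_subrepeats(L, S)
        a2 = sa.variance_explained_by_subrepeats(L + 5_000, S)
        assert a1.fraction_explained == pytest.approx(a2.fraction_explained)

    def test_zero_variance_is_na(self):
        att = sa.variance_explained_by_subrepeats([100.0] * 5, [10.0] * 5)
        assert att.fraction_explained is None

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            sa.variance_explained_by_subrepeats([1.0, 2.0], [0.5, 0.5])
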