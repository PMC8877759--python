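import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imufatigue.core import PhysicalTraits, ValidationError
from imufatigue import similarity as sim
from imufatigue.similarity import (
    CrowdMember,
    MinMaxNormalizer,
    SimilarityParams,
    fit_minmax,
    physical_distance,
    rank_crowd,
    signal_distance,
    similarity_from_distance,
    total_similarity,
)

unit_floats = st.floats(0.0, 1.0, allow_nan=False)
vec4 = st.tuples(*[unit_floats] * 4).map(np.array)


class TestParams:
    def test_alpha_beta_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SimilarityParams(alpha=0.5, beta=0.6)

    def test_cross_subject_sentinel_allowed(self):
        p = SimilarityParams.cross_subject()
        assert p.is_cross_subject

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValidationError):
            SimilarityParams(gamma=-1)


class TestMinMax:
    def test_midpoint(self):
        norm = fit_minmax(np.array([[20.0], [46.0]]))
        assert norm.transform(np.array([33.0]))[0] == pytest.approx(0.5)

    def test_query_clipped(self):
        norm = fit_minmax(np.array([[20.0], [46.0]]))
        assert norm.transform(np.array([50.0]))[0] == 1.0
        assert norm.transform(np.array([10.0]))[0] == 0.0

    def test_constant_dimension_maps_to_zero(self):
        norm = fit_minmax(np.array([[3.0], [3.0]]))
        assert norm.transform(np.array([3.0]))[0] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            fit_minmax(np.empty((0, 4)))

    def test_training_rows_land_in_unit_interval(self, rng):
        X = rng.normal(0, 100, (20, 6))
        norm = fit_minmax(X)
        T = np.apply_along_axis(norm.transform, 1, X)
        assert T.min() >= 0.0 and T.max() <= 1.0


class TestPhysicalDistance:
    def test_identical_zero(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        assert physical_distance(v, v) == 0.0

    def test_worked_example(self):
        d = physical_distance(np.array([0.2, 0.4, 0.1, 0.3]),
                              np.array([0.5, 0.1, 0.2, 0.6]))
        assert d == pytest.approx(1.0)

    def test_wrong_length(self):
        with pytest.raises(ValidationError):
            physical_distance(np.zeros(3), np.zeros(4))

    @given(vec4, vec4)
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, a, b):
        assert physical_distance(a, b) == pytest.approx(physical_distance(b, a))

    @given(vec4, vec4, vec4)
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, a, b, c):
        dab = physical_distance(a, b)
        assert dab >= 0
        assert physical_distance(a, a) == 0
        assert dab <= physical_distance(a, c) + physical_distance(c, b) + 1e-12


class TestSignalDistance:
    def test_identical_blocks_zero(self, rng):
        f = rng.uniform(0, 1, (5, 11))
        assert signal_distance(f, f) == 0.0

    def test_uniform_offset_single_rep(self):
        fq = np.full((1, 11), 0.5)
        fp = np.full((1, 11), 0.4)
        assert signal_distance(fq, fp) == pytest.approx(1.1)

    def test_truncation_to_shorter(self, rng):
        fq = rng.uniform(0, 1, (4, 11))
        fp = rng.uniform(0, 1, (4, 11))
        base = signal_distance(fq, fp)
        extended = np.vstack([fp, rng.uniform(0, 1, (3, 11))])
        assert signal_distance(fq, extended) == pytest.approx(base)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            signal_distance(np.empty((0, 11)), np.ones((1, 11)))

    def test_wrong_width_rejected(self):
        with pytest.raises(ValidationError):
            signal_distance(np.ones((1, 10)), np.ones((1, 10)))


class TestExponentialSimilarity:
    def test_gamma_zero_gives_one(self):
        for d in (0.0, 0.5, 100.0):
            assert similarity_from_distance(d, 0.0) == 1.0

    def test_distance_zero_gives_one(self):
        for g in (0.0, 1.0, 14.0):
            assert similarity_from_distance(0.0, g) == 1.0

    def test_reference_value(self):
        assert similarity_from_distance(1.0, 14.0) == pytest.approx(8.3153e-7, rel=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            similarity_from_distance(-0.1, 1.0)

    def test_strictly_decreasing_in_distance_and_gamma(self):
        ds = np.linspace(0.1, 5, 25)
        sims = [similarity_from_distance(d, 2.0) for d in ds]
        assert all(b < a for a, b in zip(sims, sims[1:]))
        gs = np.linspace(0.1, 30, 25)
        sims = [similarity_from_distance(0.7, g) for g in gs]
        assert all(b < a for a, b in zip(sims, sims[1:]))


class TestTotalSimilarity:
    def test_equal_inputs_fixed_point(self):
        for alpha in (0.0, 0.3, 1.0):
            p = SimilarityParams(alpha=alpha, beta=1 - alpha, gamma=1)
            assert total_similarity(0.42, 0.42, p) == pytest.approx(0.42)

    def test_worked_example(self):
        p = SimilarityParams(alpha=0.4, beta=0.6, gamma=1)
        assert total_similarity(0.5, 1.0, p) == pytest.approx(0.8)

    def test_alpha_one_endpoint(self):
        p = SimilarityParams(alpha=1.0, beta=0.0, gamma=1)
        assert total_similarity(0.37, 0.99, p) == pytest.approx(0.37)

    @given(unit_floats, unit_floats, st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_inputs(self, sp, ss, alpha):
        p = SimilarityParams(alpha=alpha, beta=1 - alpha, gamma=1)
        t = total_similarity(sp, ss, p)
        assert min(sp, ss) - 1e-12 <= t <= max(sp, ss) + 1e-12


def _make_member(rng, subject_id, traits=None, block=None):
    traits = traits or PhysicalTraits.from_measurements(
        age=float(rng.integers(20, 47)), height=float(rng.uniform(165, 190)),
        weight=float(rng.uniform(69, 127)))
    block = block if block is not None else rng.uniform(0, 1, (5, 11))
    return CrowdMember(subject_id, traits, block)


class TestRankCrowd:
    def test_clones_all_similarity_one_ordered_by_id(self, rng):
        traits = PhysicalTraits.from_measurements(30, 180, 80)
        block = rng.uniform(0, 1, (5, 11))
        crowd = [CrowdMember(f"s{i:02d}", traits, block.copy()) for i in (3, 1, 2)]
        scores = rank_crowd("q", traits, block, crowd, SimilarityParams())
        assert [s.other_subject for s in scores] == ["s01", "s02", "s03"]
        assert all(s.sim_total == pytest.approx(1.0) for s in scores)

    def test_planted_near_duplicate_ranks_first(self, rng):
        q_traits = PhysicalTraits.from_measurements(30, 180, 80)
        q_block = rng.uniform(0.4, 0.6, (5, 11))
        near = CrowdMember("near", PhysicalTraits.from_measurements(31, 179, 81),
                           q_block + rng.normal(0, 0.01, q_block.shape).clip(-0.02, 0.02))
        others = [_make_member(rng, f"far{i}") for i in range(6)]
        for gamma in (1.0, 5.0, 14.0, 30.0):
            p = SimilarityParams(gamma=gamma)
            scores = rank_crowd("q", q_traits, q_block, [near] + others, p)
            assert scores[0].other_subject == "near", gamma

    def test_endpoint_rankings_follow_raw_distances(self, rng):
        q = _make_member(rng, "q")
        crowd = [_make_member(rng, f"s{i}") for i in range(8)]
        phys = rank_crowd("q", q.traits, q.signal_features, crowd,
                          SimilarityParams(alpha=1.0, beta=0.0, gamma=5.0))
        assert [s.other_subject for s in phys] == [
            s.other_subject for s in sorted(phys, key=lambda s: (s.d_phy, s.other_subject))]
        sig = rank_crowd("q", q.traits, q.signal_features, crowd,
                         SimilarityParams(alpha=0.0, beta=1.0, gamma=5.0))
        assert [s.other_subject for s in sig] == [
            s.other_subject for s in sorted(sig, key=lambda s: (s.d_sig, s.other_subject))]

    def test_permutation_invariance(self, rng):
        q = _make_member(rng, "q")
        crowd = [_make_member(rng, f"s{i}") for i in range(6)]
        a = rank_crowd("q", q.traits, q.signal_features, crowd, SimilarityParams())
        shuffled = list(crowd)
        np.random.default_rng(1).shuffle(shuffled)
        b = rank_crowd("q", q.traits, q.signal_features, shuffled, SimilarityParams())
        assert [s.other_subject for s in a] == [s.other_subject for s in b]

    def test_leakage_guard(self, rng):
        q = _make_member(rng, "q")
        with pytest.raises(ValidationError):
            rank_crowd("q", q.traits, q.signal_features, [q], SimilarityParams())

    def test_empty_crowd(self, rng):
        q = _make_member(rng, "q")
        with pytest.raises(ValidationError):
            rank_crowd("q", q.traits, q.signal_features, [], SimilarityParams())

    def test_sim_total_blend_identity(self, rng):
        q = _make_member(rng, "q")
        crowd = [_make_member(rng, f"s{i}") for i in range(5)]
        p = SimilarityParams(alpha=0.4, beta=0.6, gamma=3.0)
        for s in rank_crowd("q", q.traits, q.signal_features, crowd, p):
            assert s.sim_total == pytest.approx(0.4 * s.sim_phy + 0.6 * s.sim_sig, abs=1e-12)
            assert 0 < s.sim_phy <= 1 and 0 < s.sim_sig <= 1
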