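"""Temporal-interference planning: MEM, exposure metrics, Pareto, steering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nibsim.ti import (StimConfig, enumerate_configs, exposure_map,
                       exposure_metrics, mem_bruteforce, mem_closed_form,
                       pareto_front, steer_currents, weighted_rank)

vec3 = st.lists(st.floats(-3.0, 3.0, allow_nan=False), min_size=3, max_size=3)


class TestMEM:
    @pytest.mark.parametrize("e1,e2,expected", [
        ((1, 0, 0), (1, 0, 0), 2.0),      # parallel equal: 2 min
        ((1, 0, 0), (0, 0, 0), 0.0),      # no second channel field
        ((1, 0, 0), (-1, 0, 0), 2.0),     # antiparallel: sign flip
        ((1, 0, 0), (0, 1, 0), np.sqrt(2.0)),  # orthogonal equal
    ])
    def test_analytic_cases(self, e1, e2, expected):
        assert mem_closed_form(e1, e2) == pytest.approx(expected, abs=1e-12)
        assert mem_bruteforce(e1, e2, n_directions=4000) \
            == pytest.approx(expected, rel=1e-3, abs=1e-9)

    def test_closed_form_matches_bruteforce_on_1000_pairs(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            e1 = rng.standard_normal(3) * rng.uniform(0.2, 2.0)
            e2 = rng.standard_normal(3) * rng.uniform(0.2, 2.0)
            bf = mem_bruteforce(e1, e2, n_directions=2000)
            worst = max(worst, abs(mem_closed_form(e1, e2) - bf) / max(bf, 1e-12))
        assert worst < 1e-3

    @given(vec3, vec3)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_symmetry_and_sign_invariance(self, e1, e2):
        m = mem_closed_form(e1, e2)
        assert m == pytest.approx(mem_closed_form(e2, e1), rel=1e-12, abs=1e-12)
        assert m == pytest.approx(mem_closed_form(-np.asarray(e1), e2),
                                  rel=1e-12, abs=1e-12)

    @given(vec3, vec3)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_upper_bound_two_min(self, e1, e2):
        m = mem_closed_form(e1, e2)
        bound = 2.0 * min(np.linalg.norm(e1), np.linalg.norm(e2))
        assert m <= bound + 1e-9

    def test_orthogonal_monotone_in_smaller_field(self):
        vals = [mem_bruteforce((1, 0, 0), (0, a, 0), n_directions=3000)
                for a in np.linspace(0.05, 1.0, 8)]
        assert np.all(np.diff(vals) > 0)


class TestExposureMap:
    def test_homogeneity_and_channel_swap(self, small_basis):
        c1 = StimConfig(("C3", "C4"), 1.0, 2000.0, ("T7", "T8"), 1.0, 2010.0)
        c2 = StimConfig(("C3", "C4"), 2.0, 2000.0, ("T7", "T8"), 2.0, 2010.0)
        m1 = exposure_map(small_basis, c1)
        m2 = exposure_map(small_basis, c2)
        assert np.allclose(m2, 2.0 * m1)
        swapped = StimConfig(("T7", "T8"), 1.0, 2000.0, ("C3", "C4"), 1.0, 2010.0)
        assert np.allclose(exposure_map(small_basis, swapped), m1)

    def test_single_channel_tacs_uses_field_magnitude(self, small_basis):
        c = StimConfig(("C3", "C4"), 2.0, 8.0)
        m = exposure_map(small_basis, c, quantity="|E|")
        f = small_basis.pair_field("C3", "C4", 2.0)
        assert np.allclose(m, np.linalg.norm(f, axis=0))

    def test_missing_electrode_raises(self, small_basis):
        c = StimConfig(("C3", "F9"), 1.0, 2000.0, ("T7", "T8"), 1.0, 2010.0)
        with pytest.raises(KeyError, match="F9"):
            exposure_map(small_basis, c)

    def test_shared_electrode_rejected(self):
        with pytest.raises(ValueError, match="share"):
            StimConfig(("C3", "C4"), 1.0, 2000.0, ("C4", "T8"), 1.0, 2010.0)


class TestMetrics:
    def test_worked_examples(self):
        qoi = np.array([1.0, 2.0, 3.0, 4.0, 1.0, 3.0, 3.0, 5.0])
        target = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
        brain = np.ones(8, bool)
        m = exposure_metrics(qoi, target, brain, p=50, threshold=2.5)
        assert m.m1 == pytest.approx(2.5)          # median of 1,2,3,4
        assert m.m2 == pytest.approx(2.5 / 3.0)    # mean 2.5 over mean 3
        assert m.m3 == pytest.approx(0.75)         # {3,3,5} of {1,3,3,5} > 2.5

    def test_mean_ratio_and_auto_threshold(self):
        qoi = np.array([2.0, 2.0, 1.0, 1.0])
        target = np.array([1, 1, 0, 0], bool)
        m = exposure_metrics(qoi, target, np.ones(4, bool))
        assert m.m2 == pytest.approx(2.0)
        assert m.threshold == m.m1                  # auto mode

    def test_scaling_invariance(self, rng):
        qoi = rng.random(100) + 0.1
        target = np.zeros(100, bool)
        target[:20] = True
        brain = np.ones(100, bool)
        a = exposure_metrics(qoi, target, brain)
        b = exposure_metrics(3.0 * qoi, target, brain)
        assert b.m1 == pytest.approx(3.0 * a.m1)
        assert b.m2 == pytest.approx(a.m2)
        assert b.m3 == pytest.approx(a.m3)          # auto threshold scales along

    def test_zero_offtarget_mean_warns_inf(self):
        qoi = np.array([1.0, 1.0, 0.0, 0.0])
        target = np.array([1, 1, 0, 0], bool)
        with pytest.warns(UserWarning, match="inf"):
            m = exposure_metrics(qoi, target, np.ones(4, bool))
        assert np.isinf(m.m2)


class TestEnumerate:
    def test_four_electrodes_fixed_split(self):
        cfgs = enumerate_configs(["A", "B", "C", "D"], ratios=(0.5,))
        assert len(cfgs) == 3  # {AB|CD, AC|BD, AD|BC}
        for c in cfgs:
            assert not set(c.pair1) & set(c.pair2)

    def test_ratio_grid_multiplies_count(self):
        base = enumerate_configs(["A", "B", "C", "D"], ratios=(0.5,))
        five = enumerate_configs(["A", "B", "C", "D"],
                                 ratios=(0.1, 0.3, 0.5, 0.7, 0.9))
        assert len(five) == 5 * len(base)


class TestPareto:
    def test_strict_dominance(self):
        res = pareto_front([(1.0, 1.0, 1.0), (2.0, 2.0, 0.5)])
        assert list(res.pareto_flags) == [False, True]

    def test_matches_bruteforce_on_200_random_triples(self, rng):
        triples = [tuple(t) for t in rng.random((200, 3))]
        res = pareto_front(triples)
        brute = []
        for t in triples:
            dominated = any(
                (o[0] >= t[0] and o[1] >= t[1] and o[2] <= t[2]) and
                (o[0] > t[0] or o[1] > t[1] or o[2] < t[2])
                for o in triples)
            brute.append(not dominated)
        assert list(res.pareto_flags) == brute

    def test_identical_triples_all_kept(self):
        res = pareto_front([(1, 1, 1)] * 4)
        assert res.pareto_flags.all()

    def test_front_of_front_is_front(self, rng):
        triples = [tuple(t) for t in rng.random((60, 3))]
        res = pareto_front(triples)
        front = [t for t, f in zip(triples, res.pareto_flags) if f]
        again = pareto_front(front)
        assert again.pareto_flags.all()


class TestRanking:
    def test_pure_strength_weighting(self, rng):
        triples = [tuple(t) for t in rng.random((50, 3))]
        res = weighted_rank(pareto_front(triples), (1.0, 0.0, 0.0))
        top = res.ranking[0]
        front_m1 = [t[0] for t, f in zip(triples, res.pareto_flags) if f]
        assert triples[top][0] == max(front_m1)

    def test_front_always_precedes_dominated(self, rng):
        triples = [tuple(t) for t in rng.random((80, 3))]
        base = pareto_front(triples)
        for w in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0.2, 0.5, 0.3)]:
            res = weighted_rank(base, w)
            n_front = int(res.pareto_flags.sum())
            assert res.pareto_flags[res.ranking[:n_front]].all()

    def test_ties_keep_input_order(self):
        res = weighted_rank(pareto_front([(1, 1, 1)] * 3), (1, 1, 1))
        assert list(res.ranking) == [0, 1, 2]


@pytest.fixture(scope="module")
def masks(small_phantom):
    """Centered deep spherical target inside the brain compartment."""
    labels = small_phantom.labels
    brain = (labels == small_phantom.label_of("gm")) \
        | (labels == small_phantom.label_of("wm"))
    idx = np.argwhere(brain)
    pos = small_phantom.origin + idx * small_phantom.spacing
    target = np.zeros_like(brain)
    target[tuple(idx[np.linalg.norm(pos, axis=1) <= 12.0].T)] = True
    return target, brain


class TestSteering:

    def test_symmetric_setup_prefers_even_split(self, small_basis, masks):
        """Mirror-image channel pairs + centered target: score is symmetric
        in the split, so the optimum sits at the even split."""
        target, brain = masks
        ratios = np.round(np.arange(0.1, 0.91, 0.1), 10)
        best, _, res = steer_currents(small_basis, ("C3", "T7"), ("C4", "T8"),
                                      target, brain, ratios=ratios)
        r_best = best.current1_mA / (best.current1_mA + best.current2_mA)
        assert abs(r_best - 0.5) <= 0.1 + 1e-9

    def test_never_worse_than_even_split(self, small_basis, masks):
        target, brain = masks
        best, _, res = steer_currents(small_basis, ("C3", "Oz"), ("T7", "T8"),
                                      target, brain,
                                      ratios=(0.2, 0.35, 0.5, 0.65, 0.8))
        half = res.meta["ratios"].index(0.5)
        assert res.scores[int(res.ranking[0])] >= res.scores[half] - 1e-12
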