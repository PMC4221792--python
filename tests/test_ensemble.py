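import math

import pytest
from hypothesis import given, settings, strategies as st

from distilseq import (
    CommunityProfile,
    Parameters,
    brute_force_ensemble,
    cost,
    ensemble_analysis,
    enumerate_divisions,
    expected_cost_curve,
    simulate_ordering,
)


class TestDivisions:
    def test_hand_enumerated_weights(self):
        # p = (2, 1): the 3 equally likely 2-subsets give (2,0) w.p. 1/3
        divs = {d.v: d.pi for d in enumerate_divisions((2, 1))}
        assert divs == {
            (2, 0): pytest.approx(1 / 3),
            (1, 1): pytest.approx(2 / 3),
        }

    def test_forced_split(self):
        divs = enumerate_divisions((2, 0))
        assert len(divs) == 1
        assert divs[0].v == (1, 0) and divs[0].pi == pytest.approx(1.0)

    def test_indivisible_rejected(self):
        with pytest.raises(ValueError):
            enumerate_divisions((1, 0))

    @settings(max_examples=60, derandomize=True)
    @given(
        p=st.lists(st.integers(0, 7), min_size=1, max_size=4).filter(
            lambda xs: sum(xs) >= 2
        )
    )
    def test_hypergeometric_normalisation(self, p):
        divs = enumerate_divisions(p)
        assert math.fsum(d.pi for d in divs) == pytest.approx(1.0, abs=1e-12)
        half = (sum(p) + 1) // 2
        for d in divs:
            assert sum(d.v) == half
            assert tuple(a + b for a, b in zip(d.v, d.w)) == tuple(p)


class TestCostRecursion:
    def test_leaf_always_captured(self, params):
        e_t, P = cost((1,), 0, 12e6, (12e6,), params)
        assert P.P == pytest.approx((0.0, 1.0))
        assert e_t > 0

    def test_all_zero_pool_rejected(self, params):
        with pytest.raises(ValueError):
            cost((0, 0), 0, 1e6, (1e6, 1e6), params)

    def test_normalisation(self, params):
        for p in [(3, 2), (2, 2, 2), (4, 1, 1)]:
            g = [4e6 * (j + 1) for j in range(len(p))]
            for mask in range(2 ** len(p)):
                _, P = cost(p, mask, 8e6, g, params)
                assert P.total() == pytest.approx(1.0, abs=1e-9)

    def test_memoisation_transparent(self, params):
        p, g = (3, 2, 1), (4e6, 12e6, 2e6)
        e1, P1 = cost(p, 0, 12e6, g, params, memoize=True)
        e2, P2 = cost(p, 0, 12e6, g, params, memoize=False)
        assert e1 == pytest.approx(e2, rel=1e-12)
        assert P1.P == pytest.approx(P2.P, abs=1e-12)


class TestAgainstBruteForce:
    """The module's central correctness property: the dynamic program equals
    explicit enumeration over all cell orderings on small communities."""

    @pytest.mark.parametrize("tau", [0.0, 0.2, 0.4])
    @pytest.mark.parametrize(
        "p,g_mbp",
        [
            ((2,), (4,)),
            ((1, 1), (4, 2)),
            ((3, 1), (4, 2)),
            ((2, 2), (4, 4)),
            ((2, 2, 2), (4, 12, 2)),
            ((3, 2, 1), (12, 2, 1)),
            ((4, 2), (12, 1)),
        ],
    )
    def test_dp_equals_enumeration(self, p, g_mbp, tau):
        prof = CommunityProfile(p, [x * 1e6 for x in g_mbp])
        params = Parameters(tau=tau)
        res = ensemble_analysis(prof, params)
        bf_t, bf_P = brute_force_ensemble(prof, params)
        assert res.expected_total == pytest.approx(bf_t, rel=1e-9)
        assert res.capture.P == pytest.approx(bf_P.P, abs=1e-9)

    def test_single_ordering_exact(self, params):
        prof = CommunityProfile((2,), (4e6,))
        res = ensemble_analysis(prof, params)
        bf_t, _ = brute_force_ensemble(prof, params)
        assert res.expected_total == bf_t

    def test_guard(self, params):
        with pytest.raises(ValueError):
            brute_force_ensemble(CommunityProfile((9,), (4e6,)), params)


class TestCaptureBehaviour:
    def test_tau_zero_certain_capture(self):
        params = Parameters(tau=0.0)
        for p, g in [((3, 2, 3), (4e6, 12e6, 2e6)), ((2, 5), (4e6, 1e6))]:
            res = ensemble_analysis(CommunityProfile(p, g), params)
            assert res.capture.P[-1] == pytest.approx(1.0, abs=1e-9)

    def test_marginals_consistent_with_joint(self, profile_323, params):
        res = ensemble_analysis(profile_323, params)
        s = profile_323.s
        for j, marg in enumerate(res.per_genome_capture):
            total = math.fsum(
                q for m, q in enumerate(res.capture.P) if (m >> j) & 1
            )
            assert marg == pytest.approx(total, abs=1e-12)

    def test_capture_monotone_in_tau(self):
        # raising the dissimilarity tolerance can only lose genomes
        prof = CommunityProfile((5, 5, 10, 20), (4e6, 12e6, 2e6, 1e6))
        taus = [0.0, 0.1, 0.2, 0.4]
        margs = [
            ensemble_analysis(prof, Parameters(tau=t)).per_genome_capture
            for t in taus
        ]
        for lo, hi in zip(margs, margs[1:]):
            for a, b in zip(lo, hi):
                assert b <= a + 1e-9

    def test_cost_covers_represented_genomes(self):
        # with tau=0 every represented genome is assembled at least once
        params = Parameters(tau=0.0)
        prof = CommunityProfile((3, 2, 3), (4e6, 12e6, 2e6))
        res = ensemble_analysis(prof, params)
        assert res.expected_total >= params.m_upper * sum(prof.g)


class TestOrderingWalk:
    def test_deterministic(self, params):
        labels = (1, 2, 1, 3, 3, 1, 2, 1)
        g = (4e6, 12e6, 2e6)
        a = simulate_ordering(labels, g, params)
        b = simulate_ordering(labels, g, params)
        assert a == b

    def test_single_cell_charged(self, params):
        total, mask = simulate_ordering((1,), (4e6,), params)
        assert mask == 1
        assert total >= params.m_upper * 4e6


class TestCostCurve:
    def test_scaling_and_fit_attrs(self, params):
        frame = expected_cost_curve(
            (3, 2, 3), (4e6, 12e6, 2e6), [8, 16, 32], params
        )
        assert list(frame["n"]) == [8, 16, 32]
        assert frame["naive_bp"].tolist() == [480e6, 960e6, 1920e6]
        assert "rss_log" in frame.attrs and "rss_linear" in frame.attrs
        assert (frame["expected_total_bp"].diff().dropna() > 0).all()

    def test_non_integral_scaling_rejected(self, params):
        with pytest.raises(ValueError):
            expected_cost_curve((3, 2, 3), (4e6, 12e6, 2e6), [12], params)
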