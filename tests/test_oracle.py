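import math

import pytest
from hypothesis import given, settings, strategies as st

from distilseq import (
    AssemblyProfile,
    Parameters,
    RoundContext,
    allocate_sequence_assemble,
    assembly_size,
    d_tau,
    resource_allocate,
    subsumed,
    subsumed_ensemble,
)

P = Parameters()


class TestAssemblySize:
    @pytest.mark.parametrize(
        "c,g,expected",
        [
            (2.5, 4e6, 2e6),   # linear ramp
            (5.0, 4e6, 4e6),   # boundary: both branches agree
            (50.0, 4e6, 4e6),  # saturates at the genome size
            (0.0, 4e6, 0.0),
        ],
    )
    def test_ramp(self, c, g, expected):
        assert assembly_size(c, g, P) == pytest.approx(expected)

    def test_negative_coverage_rejected(self):
        with pytest.raises(ValueError):
            assembly_size(-1.0, 4e6, P)

    @settings(max_examples=100, derandomize=True)
    @given(
        c1=st.floats(0, 20), c2=st.floats(0, 20),
        g=st.floats(1e5, 2e7),
    )
    def test_nondecreasing_and_complete_above_mu(self, c1, c2, g):
        lo, hi = sorted((c1, c2))
        assert assembly_size(lo, g, P) <= assembly_size(hi, g, P) + 1e-9
        if lo >= P.m_upper:
            assert assembly_size(lo, g, P) == g


class TestResourceAllocate:
    def test_identity_when_child_equals_parent(self):
        ctx = RoundContext(t_parent=100e6, a_parent=10e6, c_parent=5.0)
        assert resource_allocate(ctx, 10e6, params=P) == pytest.approx(100e6)

    def test_formula(self):
        ctx = RoundContext(t_parent=100e6, a_parent=10e6, c_parent=10.0)
        assert resource_allocate(ctx, 5e6, params=P) == pytest.approx(25e6)

    def test_error_free_reduction(self):
        # when t_parent = c_parent * a_parent the rule reduces to M_u * a'
        ctx = RoundContext(t_parent=35e6, a_parent=7e6, c_parent=5.0)
        assert resource_allocate(ctx, 3e6, params=P) == pytest.approx(
            P.m_upper * 3e6
        )

    def test_zero_parent_rejected(self):
        with pytest.raises(ValueError):
            resource_allocate(
                RoundContext(t_parent=1e6, a_parent=0.0, c_parent=5.0), 1e6, params=P
            )


class TestAllocateSequenceAssemble:
    def test_worked_pool(self):
        # 4 cells, two genomes, parent assembly 6 Mbp: t = 2*5*6 = 60 Mbp
        res = allocate_sequence_assemble((2, 2), (4e6, 2e6), 6e6, P)
        assert res.t == pytest.approx(60e6)
        assert res.t_pc == pytest.approx(15e6)
        assert res.t_pdg == pytest.approx((30e6, 30e6))
        assert res.coverages == pytest.approx((7.5, 15.0))
        assert res.assembly.a_bar == pytest.approx((4e6, 2e6))

    def test_absent_genome_contributes_nothing(self):
        res = allocate_sequence_assemble((0, 3), (4e6, 2e6), 6e6, P)
        assert res.assembly.a_bar[0] == 0.0
        assert res.coverages[0] == 0.0

    def test_single_cell_deep_coverage(self):
        # one cell with a complete parent assembly reaches 2*M_u coverage
        res = allocate_sequence_assemble((1,), (12e6,), 12e6, P)
        assert res.assembly.c == pytest.approx(2 * P.m_upper)
        assert res.assembly.a_bar == pytest.approx((12e6,))

    @settings(max_examples=60, derandomize=True)
    @given(
        p=st.lists(st.integers(0, 9), min_size=1, max_size=4).filter(
            lambda xs: sum(xs) >= 1
        ),
        a_parent=st.floats(1e5, 3e7),
    )
    def test_conserves_nucleotides(self, p, a_parent):
        g = [1e6 * (j + 2) for j in range(len(p))]
        res = allocate_sequence_assemble(p, g, a_parent, P)
        assert math.fsum(res.t_pdg) == pytest.approx(res.t, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            allocate_sequence_assemble((0,), (4e6,), 1e6, P)
        with pytest.raises(ValueError):
            allocate_sequence_assemble((1,), (4e6,), 0.0, P)


class TestSubsumption:
    @pytest.mark.parametrize(
        "exclusive,total,expected",
        [
            (0.0, 10e6, 0.2),    # no exclusive content
            (3e6, 10e6, -0.1),   # 30% novel: not subsumed
            (2e6, 10e6, 0.0),    # boundary counts as subsumed
        ],
    )
    def test_d_tau(self, exclusive, total, expected):
        assert d_tau(exclusive, total, P) == pytest.approx(expected)

    def test_d_tau_empty_rejected(self):
        with pytest.raises(ValueError):
            d_tau(0.0, 0.0, P)

    def test_low_coverage_never_subsumed(self):
        new = AssemblyProfile((4e6, 0, 2e6), 0.2)
        ref = AssemblyProfile((4e6, 12e6, 2e6), 10.0)
        assert not subsumed(new, ref, 0.2, P)  # c <= M_l = 0.3

    def test_contained_assembly_subsumed(self):
        new = AssemblyProfile((4e6, 0, 2e6), 10.0)
        ref = AssemblyProfile((4e6, 12e6, 2e6), 10.0)
        assert subsumed(new, ref, 10.0, P)

    def test_small_novel_genome_slips_through(self):
        # 2 Mbp of novel content in an 18 Mbp assembly: 2/18 < tau = 0.2,
        # the mechanism by which the smallest genome can be missed
        new = AssemblyProfile((4e6, 12e6, 2e6), 10.0)
        ref = AssemblyProfile((4e6, 12e6, 0), 10.0)
        assert subsumed(new, ref, 10.0, P)

    def test_ensemble_all_captured(self):
        a = AssemblyProfile((4e6, 12e6, 2e6), 10.0)
        assert subsumed_ensemble(a, 10.0, 0b111, P)

    def test_ensemble_large_exclusive_blocks(self):
        a = AssemblyProfile((4e6, 2e6), 10.0)
        # genome 2 uncaptured: 2/6 = 0.333 > 0.2
        assert not subsumed_ensemble(a, 10.0, 0b01, P)

    def test_ensemble_small_genome_silently_missed(self):
        a = AssemblyProfile((4e6, 12e6, 2e6), 10.0)
        # genome 3 uncaptured: 2/18 = 0.111 <= 0.2
        assert subsumed_ensemble(a, 10.0, 0b011, P)

    @settings(max_examples=80, derandomize=True)
    @given(
        a=st.lists(st.floats(0, 1e7), min_size=1, max_size=4).filter(
            lambda xs: sum(xs) > 0
        ),
        mask=st.integers(0, 15),
        tau1=st.floats(0, 0.9),
        tau2=st.floats(0, 0.9),
    )
    def test_monotone_in_tau(self, a, mask, tau1, tau2):
        lo, hi = sorted((tau1, tau2))
        prof = AssemblyProfile(a, 10.0)
        if subsumed_ensemble(prof, 10.0, mask, Parameters(tau=lo)):
            assert subsumed_ensemble(prof, 10.0, mask, Parameters(tau=hi))

    @settings(max_examples=80, derandomize=True)
    @given(
        a=st.lists(
            st.just(0.0) | st.floats(1.0, 1e7), min_size=1, max_size=4
        ).filter(lambda xs: sum(xs) > 0),
        mask=st.integers(0, 15),
    )
    def test_tau_zero_requires_empty_exclusive(self, a, mask):
        prof = AssemblyProfile(a, 10.0)
        expected = all(
            (mask >> j) & 1 or aj == 0.0 for j, aj in enumerate(a)
        )
        assert subsumed_ensemble(prof, 10.0, mask, Parameters(tau=0.0)) == expected
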