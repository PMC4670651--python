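"""Unit and property tests for the aggregate--BCR cross-linking engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggimmuno import crosslink as cx
from aggimmuno.constants import N_AVOGADRO


def closed_form_bound_n1(Ka, A0, B0):
    """Equilibrium of A + B <-> AB from the quadratic Ka = x/((A0-x)(B0-x)).

    Uses the cancellation-free root 2c / (-b + sqrt(b^2 - 4ac)), stable
    when the bound fraction is tiny.
    """
    a, b, c = Ka, -(Ka * (A0 + B0) + 1.0), Ka * A0 * B0
    return 2.0 * c / (-b + np.sqrt(b * b - 4 * a * c))


class TestInitialConcentrations:
    @pytest.mark.parametrize(
        "ag_total, p, n, expected",
        [
            (1e5, 0.15, 10, 1500.0),   # 40 mg mAb dose, heavy aggregation
            (500.0, 0.02, 100, 0.1),   # 30 ug dose, light aggregation
            (0.0, 0.1, 50, 0.0),
        ],
    )
    def test_aggregate_formula(self, ag_total, p, n, expected):
        assert cx.initial_aggregate_conc(ag_total, p, n) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "args", [(-1.0, 0.1, 10), (1.0, 1.5, 10), (1.0, -0.1, 10), (1.0, 0.1, 0)]
    )
    def test_aggregate_formula_rejects_bad_inputs(self, args):
        with pytest.raises(cx.CrosslinkError):
            cx.initial_aggregate_conc(*args)

    def test_bcr_concentration_from_repertoire(self):
        # 1e5 receptors/cell x 1e8 cells/L = 1e13 receptors/L = 16.6 pM
        full = cx.bcr_initial_conc(1e5, 1e8, 1.0)
        assert full == pytest.approx(1e13 / N_AVOGADRO / 1e-12, rel=1e-12)
        assert full == pytest.approx(16.606, rel=1e-3)
        assert cx.bcr_initial_conc(1e5, 1e8, 0.01) == pytest.approx(full / 100)
        assert cx.bcr_initial_conc(1e5, 1e8, 0.0) == 0.0

    def test_bcr_concentration_rejects_fraction_above_one(self):
        with pytest.raises(cx.CrosslinkError):
            cx.bcr_initial_conc(1e5, 1e8, 1.5)


class TestRateSchedule:
    def test_dissociation_decays_geometrically(self):
        k, k_off = cx.rate_schedule(8.64e-3, 1e-5, 0.5, 4)
        assert np.all(k == 8.64e-3)
        assert k_off[0] == pytest.approx(864.0)   # k_on / Ka
        assert k_off[1] == pytest.approx(432.0)
        assert np.allclose(k_off[1:] / k_off[:-1], 0.5)

    def test_no_decay_when_base_is_one(self):
        _, k_off = cx.rate_schedule(8.64e-3, 1e-5, 1.0, 5)
        assert np.allclose(k_off, k_off[0])

    def test_rejects_bad_base(self):
        with pytest.raises(cx.CrosslinkError):
            cx.rate_schedule(1.0, 1.0, 1.5, 3)


class TestMassActionRhs:
    def test_empty_system_is_static(self):
        p = cx.CrosslinkParams(n=3, Aga0=0.0, BCR0=0.0)
        state = cx.SpeciesState(0.0, 0.0, np.zeros(3))
        assert np.all(cx.mass_action_rhs(state, p) == 0.0)

    def test_single_step_bimolecular_flux(self):
        # n=1, 1 pM each, nothing bound: d[AB]/dt = k_on * A * B
        p = cx.CrosslinkParams(n=1, k_on=8.64e-3, Ka=1e-5, Aga0=1.0, BCR0=1.0)
        state = cx.SpeciesState(1.0, 1.0, np.zeros(1))
        dy = cx.mass_action_rhs(state, p)
        assert dy[2] == pytest.approx(8.64e-3)
        assert dy[0] == pytest.approx(-8.64e-3)
        assert dy[1] == pytest.approx(-8.64e-3)

    def test_dimension_mismatch_raises(self):
        p = cx.CrosslinkParams(n=4)
        state = cx.SpeciesState(1.0, 1.0, np.zeros(3))
        with pytest.raises(cx.CrosslinkError):
            cx.mass_action_rhs(state, p)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        n=st.integers(1, 12),
        seed=st.integers(0, 2**31 - 1),
        log_ka=st.floats(-7, -3),
    )
    def test_conservation_built_into_rhs(self, n, seed, log_ka):
        """Aggregate and BCR-site totals have exactly zero time derivative."""
        rng = np.random.default_rng(seed)
        p = cx.CrosslinkParams(n=n, Ka=10.0 ** log_ka, Aga0=10.0, BCR0=5.0)
        state = cx.SpeciesState(
            float(rng.uniform(0, 10)), float(rng.uniform(0, 10)),
            rng.uniform(0, 1, size=n),
        )
        dy = cx.mass_action_rhs(state, p)
        d_aggregate = dy[0] + np.sum(dy[2:])
        d_bcr_sites = dy[1] + np.dot(np.arange(1, n + 1), dy[2:])
        scale = np.max(np.abs(dy)) + 1e-30
        assert abs(d_aggregate) / scale < 1e-12
        assert abs(d_bcr_sites) / scale < 1e-12


class TestSimulate:
    @pytest.mark.parametrize("Ka", [1e-7, 1e-5, 1e-3])
    @pytest.mark.parametrize("Aga0", [0.1, 12.0, 1500.0])
    def test_monovalent_matches_quadratic_equilibrium(self, Ka, Aga0):
        p = cx.CrosslinkParams(n=1, Ka=Ka, Aga0=Aga0, BCR0=1.66)
        res = cx.simulate(p, rel_tol=1e-10, abs_tol=1e-16)
        expected = closed_form_bound_n1(Ka, Aga0, p.BCR0)
        assert res.final_state.bound[0] == pytest.approx(expected, rel=1e-6)

    def test_zero_aggregate_stays_empty(self):
        p = cx.CrosslinkParams(n=5, Aga0=0.0, BCR0=1.0)
        res = cx.simulate(p, t_end=10.0)
        assert np.all(res.y[:, 2:] == 0.0)

    @pytest.mark.parametrize(
        "params",
        [
            cx.CrosslinkParams(n=10, Ka=1e-3, Aga0=12.0, BCR0=0.166),
            cx.CrosslinkParams(n=100, Ka=1e-3, Aga0=1500.0, BCR0=1.66e-3),
            cx.CrosslinkParams(n=100, Ka=1e-7, Aga0=0.1, BCR0=0.166),
        ],
    )
    def test_conservation_and_nonnegativity_along_trajectory(self, params):
        res = cx.simulate(params)
        totals_ag = res.y[:, 0] + res.y[:, 2:].sum(axis=1)
        weights = np.arange(1, params.n + 1)
        totals_bcr = res.y[:, 1] + res.y[:, 2:] @ weights
        assert np.allclose(totals_ag, params.Aga0, rtol=1e-6)
        assert np.allclose(totals_bcr, params.BCR0, rtol=1e-6)
        assert res.y.min() >= -1e-12

    def test_rejects_nonpositive_horizon(self):
        with pytest.raises(cx.CrosslinkError):
            cx.simulate(cx.CrosslinkParams(n=2), t_end=0.0)


class TestStc:
    def test_partial_sum_arithmetic(self):
        state = cx.SpeciesState(0.0, 0.0, np.array([1.0, 2.0, 3.0]))
        cells = 1e8
        assert cx.stc(state, 2, cells).stc_conc == pytest.approx(5.0)
        assert cx.stc(state, 1, cells).stc_conc == pytest.approx(6.0)
        assert cx.stc(state, 3, cells).stc_conc == pytest.approx(3.0)

    def test_fully_bound_species_counts_for_every_threshold(self):
        state = cx.SpeciesState(0.0, 0.0, np.array([0.0, 0.0, 0.7]))
        for s in (1, 2, 3):
            assert cx.stc(state, s, 1e8).stc_conc == pytest.approx(0.7)

    def test_per_cell_conversion(self):
        # 1 pM of complexes over 6.02214076e11 cells/L -> ~1 per cell
        state = cx.SpeciesState(0.0, 0.0, np.array([1.0]))
        r = cx.stc(state, 1, 6.02214076e11)
        assert r.stc_per_cell == pytest.approx(1.0)

    def test_bad_threshold_or_cells_raise(self):
        state = cx.SpeciesState(0.0, 0.0, np.array([1.0, 2.0]))
        with pytest.raises(cx.CrosslinkError):
            cx.stc(state, 0, 1e8)
        with pytest.raises(cx.CrosslinkError):
            cx.stc(state, 3, 1e8)
        with pytest.raises(cx.CrosslinkError):
            cx.stc(state, 1, 0.0)


class TestSweepAndThreshold:
    def test_sweep_shape_and_determinism(self):
        kwargs = dict(
            ka_levels=[1e-5], aga0_levels=[0.1, 12.0],
            fraction_levels=[1e-4, 1e-3], s_values=[2, 5], n=10,
        )
        df1 = cx.sweep(**kwargs)
        df2 = cx.sweep(**kwargs)
        assert list(df1.columns) == [
            "Ka_pM_inv", "Aga0_pM", "specific_fraction", "s",
            "stc_conc_pM", "stc_per_cell", "status",
        ]
        assert len(df1) == 1 * 2 * 2 * 2
        assert df1.equals(df2)

    def test_threshold_zero_target_returns_lower_bound(self):
        r = cx.fraction_threshold(Ka=1e-5, Aga0=12.0, n=10, s=2, target_count=0.0)
        assert r.attained and r.fraction == pytest.approx(1e-7)

    def test_threshold_not_attained_at_low_affinity(self):
        r = cx.fraction_threshold(Ka=1e-7, Aga0=12.0, n=100, s=2)
        assert not r.attained
        assert r.fraction is None

    def test_threshold_bisection_brackets_target(self):
        r = cx.fraction_threshold(Ka=1e-3, Aga0=12.0, n=100, s=2)
        assert r.attained
        # readout at the returned fraction reaches the target...
        assert r.stc_per_cell >= 1.0
        # ...and just below it does not
        below = cx.CrosslinkParams.from_fraction(
            n=100, Ka=1e-3, Aga0=12.0, specific_fraction=r.fraction * 0.98)
        res = cx.simulate(below)
        assert cx.stc(res.final_state, 2,
                      below.bcell_specific_conc).stc_per_cell < 1.0
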