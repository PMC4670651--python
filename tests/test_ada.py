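"""Tests of the multiscale T-cell-dependent ADA model."""

import dataclasses

import numpy as np
import pytest

from aggimmuno import ada


@pytest.fixture(scope="module")
def short_regimen():
    return ada.Regimen(dose_mg=40.0, interval_days=14.0, n_doses=2)


class TestParameterValidation:
    def test_regimen_rejects_negative_dose_and_zero_interval(self):
        with pytest.raises(ada.AdaModelError):
            ada.Regimen(dose_mg=-1.0)
        with pytest.raises(ada.AdaModelError):
            ada.Regimen(dose_mg=1.0, interval_days=0.0)

    def test_dose_conversion_to_pmol(self):
        # 40 mg of a 150 kg/mol IgG = 40e-3 g / 150e3 g/mol = 2.667e-7 mol
        reg = ada.Regimen(dose_mg=40.0)
        assert reg.dose_pmol == pytest.approx(40.0 / 150_000.0 * 1e9)

    def test_epitope_requires_positive_kd(self):
        with pytest.raises(ada.AdaModelError):
            ada.Epitope(kd_mhc_nM=0.0)

    def test_ladder_must_have_17_strictly_decreasing_rungs(self):
        with pytest.raises(ada.AdaModelError, match="17"):
            ada.CellularParams(kd_ladder_pM=tuple(np.geomspace(1e6, 1e2, 12)))
        bad = list(ada.default_kd_ladder())
        bad[5] = bad[4]  # tie breaks strict decrease
        with pytest.raises(ada.AdaModelError, match="decreasing"):
            ada.CellularParams(kd_ladder_pM=tuple(bad))

    def test_subcellular_rejects_nonpositive_rates(self):
        with pytest.raises(ada.AdaModelError):
            ada.SubcellularParams(internalization_rate=0.0)


class TestPharmacokinetics:
    def test_zero_dose_gives_zero_plasma(self):
        df = ada.simulate_pk(ada.Regimen(dose_mg=0.0, n_doses=2))
        assert np.all(df.plasma_pM == 0.0)

    def test_terminal_slope_equals_slow_eigenvalue(self):
        pk = ada.PkParams()
        df = ada.simulate_pk(ada.Regimen(dose_mg=40.0, n_doses=1), pk,
                             t_end=120.0)
        mask = (df.t_day >= 80) & (df.t_day <= 115)
        slope = np.polyfit(df.t_day[mask], np.log(df.plasma_pM[mask]), 1)[0]
        system = np.array([[-(pk.k_el + pk.k_cp), pk.k_pc],
                           [pk.k_cp, -pk.k_pc]])
        lam_slow = np.max(np.linalg.eigvals(system).real)
        assert slope == pytest.approx(lam_slow, rel=1e-3)

    def test_ada_mediated_clearance_reduces_exposure(self):
        reg = ada.Regimen(dose_mg=40.0, n_doses=1)
        clean = ada.simulate_pk(reg, t_end=60.0)
        loaded = ada.simulate_pk(reg, ada_total=1e6, t_end=60.0)
        auc0 = np.trapezoid(clean.plasma_pM, clean.t_day)
        auc1 = np.trapezoid(loaded.plasma_pM, loaded.t_day)
        assert auc1 < auc0


class TestSubcellular:
    def test_endosome_scales_linearly_with_internalization(self):
        base = ada.SubcellularParams()
        fast = dataclasses.replace(base, internalization_rate=16.6 * ada.IR0)
        e0 = ada.subcellular_steady_state(50.0, base).endosomal_antigen
        e1 = ada.subcellular_steady_state(50.0, fast).endosomal_antigen
        assert e1 / e0 == pytest.approx(16.6, rel=1e-12)

    def test_faster_degradation_empties_endosome_but_not_peptide(self):
        base = ada.SubcellularParams()
        fast = dataclasses.replace(base, degradation_rate=16.6 * ada.DR0)
        s0 = ada.subcellular_steady_state(50.0, base)
        s1 = ada.subcellular_steady_state(50.0, fast)
        assert s0.endosomal_antigen / s1.endosomal_antigen == pytest.approx(
            16.6, rel=1e-12)
        assert s1.peptides == pytest.approx(s0.peptides, rel=1e-12)

    def test_numeric_integration_matches_analytic_steady_state(self):
        sub = ada.SubcellularParams()
        df = ada.simulate_subcellular(50.0, sub, t_end=10.0)
        ss = ada.subcellular_steady_state(50.0, sub)
        assert df["endosomal_antigen"].iloc[-1] == pytest.approx(
            ss.endosomal_antigen, rel=1e-6)
        assert df["peptide_1"].iloc[-1] == pytest.approx(ss.peptides[0], rel=1e-6)
        assert df["mhc_complex_1"].iloc[-1] == pytest.approx(
            ss.surface_complexes[0], rel=1e-6)
        assert df["mhc_complex_2"].iloc[-1] == pytest.approx(
            ss.surface_complexes[1], rel=1e-6)

    def test_higher_affinity_epitope_presents_more_complexes(self):
        sub = ada.SubcellularParams(
            epitopes=(ada.Epitope(123.0), ada.Epitope(850.0)))
        ss = ada.subcellular_steady_state(50.0, sub)
        assert ss.surface_complexes[0] > ss.surface_complexes[1]

    def test_presentation_insensitive_to_internalization_when_saturated(self):
        base = ada.SubcellularParams()
        fast = dataclasses.replace(base, internalization_rate=16.6 * ada.IR0)
        m0 = ada.subcellular_steady_state(50.0, base).surface_complexes
        m1 = ada.subcellular_steady_state(50.0, fast).surface_complexes
        assert m1 == pytest.approx(m0, rel=1e-3)


class TestCellularAndScenario:
    def test_no_danger_signal_means_no_ada(self, short_regimen):
        scn = ada.AdaScenario(
            name="no-danger", regimen=short_regimen,
            cellular=ada.CellularParams(danger_signal_ng=0.0))
        res = ada.run_scenario(scn)
        assert np.all(res.trajectory.ada_total == 0.0)

    def test_ada_total_is_the_subgroup_sum(self, short_regimen):
        res = ada.run_scenario(ada.AdaScenario(name="base", regimen=short_regimen))
        total = res.trajectory.ada_subgroups.sum(axis=1)
        assert np.allclose(res.trajectory.ada_total, total, rtol=0, atol=0)

    def test_state_nonnegative_and_mhc_capacity_respected(self, short_regimen):
        res = ada.run_scenario(ada.AdaScenario(name="base", regimen=short_regimen))
        tr = res.trajectory
        assert tr.plasma_drug_pM.min() >= -1e-9
        assert tr.endosomal_antigen.min() >= -1e-9
        assert tr.surface_complexes.min() >= -1e-9
        cap = ada.SubcellularParams().mhc_total
        assert tr.surface_complexes.sum(axis=1).max() <= cap * (1 + 1e-9)

    def test_ada_monotone_in_danger_signal(self, short_regimen):
        cums = []
        for ds in (70.0, 350.0, 1750.0):
            scn = ada.AdaScenario(
                name=f"ds{ds}", regimen=short_regimen,
                cellular=ada.CellularParams(danger_signal_ng=ds))
            cums.append(ada.run_scenario(scn).cumulative_ada)
        assert cums[0] < cums[1] < cums[2]

    def test_mean_ada_affinity_matures_over_time(self, short_regimen):
        scn = ada.AdaScenario(name="base", regimen=short_regimen)
        res = ada.run_scenario(scn)
        ml = res.trajectory.mean_log10_affinity(scn.cellular.kd_ladder_pM)
        t = res.trajectory.t
        onset = np.where(res.trajectory.ada_total > 1e-3)[0][0]
        samples = [ml[np.searchsorted(t, d)]
                   for d in (t[onset], 28.0, 42.0, t[-1])]
        assert all(a < b for a, b in zip(samples, samples[1:]))

    def test_fold_change_against_itself_is_one(self, short_regimen):
        scn = ada.AdaScenario(name="base", regimen=short_regimen)
        res = ada.run_scenario(scn, reference=scn)
        assert res.fold_change == pytest.approx(1.0, rel=1e-12)

    def test_named_but_missing_reference_raises(self, short_regimen):
        scn = ada.AdaScenario(name="x", regimen=short_regimen, reference="y")
        with pytest.raises(ada.AdaModelError, match="reference"):
            ada.run_scenario(scn)

    def test_cellular_module_standalone_tracks_presentation(self):
        quiet = ada.simulate_cellular(np.array([10.0]), 1e4, t_end=30.0)
        loud = ada.simulate_cellular(np.array([8000.0]), 1e4, t_end=30.0)
        assert loud["ada_total_pM"].iloc[-1] > quiet["ada_total_pM"].iloc[-1]
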