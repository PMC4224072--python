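import numpy as np
import pandas as pd
import pytest

from biletox.compounds import CompoundModel, DoseRegimen, load_compound
from biletox.pbpk import PKCurve, auc, fit_pk, simulate_pk
from biletox.physiology import SpeciesPhysiology
from biletox.synthetic_data import NoiseModel, gen_plasma_pk


def one_compartment_compound(renal_cl=3.0, ka=0.7, v_central=0.3):
    """No hepatic uptake/passive exchange: kinetics collapse to oral 1-cpt."""
    return CompoundModel(
        name="onecpt",
        molecular_weight_g_per_mol=400.0,
        ka_per_h=ka,
        f_abs=1.0,
        uptake_vmax_umol_per_h_kg075=0.0,
        uptake_km_um=20.0,
        passive_cl_l_per_h=0.0,
        biliary_cl_ml_per_h_kg075=0.0,
        renal_cl_l_per_h=renal_cl,
        v_central_l_per_kg=v_central,
        v_peripheral_l_per_kg=1e-6,
        q_peripheral_l_per_h=0.0,
    )


def passthrough_physiology():
    """Liver/portal shrunk to pass-through so the lumped model matches the
    closed-form oral one-compartment (Bateman) solution."""
    return SpeciesPhysiology(
        species="human",
        bodyweight_kg=70.0,
        liver_volume_l=1e-4,
        blood_volume_l=5.4,
        portal_volume_l=1e-4,
        q_portal_l_per_h=600.0,
        q_hepatic_artery_l_per_h=300.0,
        ba_synthesis_rate_umol_per_h=12.0,
        toxic_pool_fraction=0.45,
        lca_hydroxylation_cl_l_per_h=0.0,
        gut_conversion_k_per_h=0.02,
        conjugation_k_per_h=5.0,
        sulfation_k_per_h=0.5,
        gut_transit_k_per_h=0.25,
        fecal_loss_fraction=0.05,
        lca_fecal_loss_fraction=0.3,
        gallbladder_empty_fraction=0.75,
    )


@pytest.fixture(scope="module")
def bosentan_3day_curve(human):
    phys, _ = human
    c = load_compound("bosentan")
    reg = DoseRegimen(amount_mg=500.0, interval_h=12.0, n_doses=6)
    return simulate_pk(c, reg, phys, follow_up_h=24.0)


class TestSimulatePK:
    def test_matches_bateman_closed_form(self):
        """Single oral dose with linear clearance reproduces the ka/ke
        Bateman solution to 0.1%."""
        c = one_compartment_compound()
        phys = passthrough_physiology()
        reg = DoseRegimen(amount_mg=100.0, interval_h=24.0, n_doses=1)
        curve = simulate_pk(c, reg, phys, dt_out_h=0.05, follow_up_h=24.0)
        v = c.v_central_l_per_kg * phys.bodyweight_kg
        ke = c.renal_cl_l_per_h / v
        ka = c.ka_per_h
        dose = reg.dose_umol(c, phys.bodyweight_kg)
        t = curve.times_h
        expected = dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        sim = curve.plasma_um["onecpt"]
        mask = t > 0.5  # skip the near-zero start where relative error is ill-posed
        rel = np.abs(sim[mask] - expected[mask]) / expected[mask].max()
        assert rel.max() < 1e-3

    def test_zero_dose_gives_identically_zero_concentrations(self, human):
        phys, _ = human
        c = load_compound("telmisartan")
        reg = DoseRegimen(amount_mg=0.0, interval_h=24.0, n_doses=3)
        curve = simulate_pk(c, reg, phys, follow_up_h=12.0)
        for sp in curve.species:
            assert np.all(curve.plasma_um[sp] == 0.0)
            assert np.all(curve.liver_um[sp] == 0.0)

    def test_mass_balance_with_metabolites_and_induction(self, bosentan_3day_curve):
        assert bosentan_3day_curve.mass_balance_error() < 1e-6

    def test_concentrations_nonnegative(self, bosentan_3day_curve):
        for sp in bosentan_3day_curve.species:
            assert bosentan_3day_curve.plasma_um[sp].min() >= 0.0

    def test_superposition_in_linear_regime(self, human):
        """Doubling the dose doubles the AUC when uptake runs far below Km."""
        phys, _ = human
        c = load_compound("telmisartan")
        c.uptake_km_um = 1e6  # force the linear uptake regime
        auc_by_dose = {}
        for dose in (10.0, 20.0):
            reg = DoseRegimen(amount_mg=dose, interval_h=24.0, n_doses=1)
            curve = simulate_pk(c, reg, phys, follow_up_h=48.0)
            auc_by_dose[dose] = auc(curve, "telmisartan", 0.0, 72.0)
        assert auc_by_dose[20.0] == pytest.approx(2 * auc_by_dose[10.0], rel=0.01)

    def test_autoinduction_lowers_steady_state_trough(self, human):
        """Bosentan induces its own uptake and metabolism: the day-28 trough
        must not exceed the day-1 trough."""
        phys, _ = human
        c = load_compound("bosentan")
        reg = DoseRegimen(amount_mg=500.0, interval_h=12.0, n_doses=56)
        curve = simulate_pk(c, reg, phys, dt_out_h=0.25)
        t = curve.times_h
        conc = curve.plasma_um["bosentan"]
        trough_d1 = conc[np.searchsorted(t, 12.0) - 1]
        trough_d28 = conc[np.searchsorted(t, 28 * 24.0) - 1]
        assert trough_d28 <= trough_d1

    def test_allometric_biliary_clearance_scaling(self):
        """Stated per-kg^0.75 units: for a fixed IV dose eliminated only by
        biliary clearance, AUC = dose/CL scales as bodyweight^-0.75."""
        c = one_compartment_compound(renal_cl=0.0)
        c.biliary_cl_ml_per_h_kg075 = 100.0
        c.passive_cl_l_per_h = 200.0  # liver equilibrates with blood
        reg = DoseRegimen(amount_mg=100.0, interval_h=24.0, n_doses=1, route="iv")
        aucs = {}
        for bw in (70.0, 35.0):
            phys = passthrough_physiology()
            phys.bodyweight_kg = bw
            phys.liver_volume_l = 1.0
            curve = simulate_pk(c, reg, phys, follow_up_h=30 * 24.0)
            # plasma AUC to infinity = dose / clearance, independent of volume
            aucs[bw] = auc(curve, "onecpt", 0.0, curve.times_h[-1])
        assert aucs[35.0] / aucs[70.0] == pytest.approx(2 ** 0.75, rel=0.02)


class TestAUC:
    def make_curve(self, times, conc):
        z = np.zeros_like(np.asarray(times, dtype=float))
        return PKCurve(
            times_h=np.asarray(times, dtype=float),
            plasma_um={"x": np.asarray(conc, dtype=float)},
            liver_um={"x": z},
        )

    def test_constant_concentration(self):
        curve = self.make_curve(np.linspace(0, 24, 25), np.full(25, 2.0))
        assert auc(curve, "x", 0.0, 24.0) == pytest.approx(48.0)

    def test_zero_curve(self):
        curve = self.make_curve(np.linspace(0, 24, 25), np.zeros(25))
        assert auc(curve, "x", 0.0, 24.0) == 0.0

    def test_triangle(self):
        curve = self.make_curve([0.0, 12.0, 24.0], [0.0, 10.0, 0.0])
        assert auc(curve, "x", 0.0, 24.0) == pytest.approx(120.0)

    def test_partial_window_interpolates_endpoints(self):
        curve = self.make_curve([0.0, 12.0, 24.0], [0.0, 10.0, 0.0])
        # trapezoid with interpolated endpoints: conc 5 at t=6 and t=18
        assert auc(curve, "x", 6.0, 18.0) == pytest.approx(90.0)

    def test_unknown_species_rejected(self):
        curve = self.make_curve([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(KeyError):
            auc(curve, "ghost", 0.0, 1.0)

    def test_invalid_window_rejected(self):
        curve = self.make_curve([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            auc(curve, "x", 1.0, 0.5)


class TestFitPK:
    BOUNDS = {"ka": (0.05, 5.0), "renal_cl": (0.1, 50.0)}

    def _observed(self, cv, seed=7):
        c = one_compartment_compound()
        phys = passthrough_physiology()
        reg = DoseRegimen(amount_mg=100.0, interval_h=24.0, n_doses=1)
        times = np.array([0.5, 1, 2, 3, 4, 6, 8, 10, 12, 16, 20, 24.0])
        noise = NoiseModel(kind="proportional", cv=cv, seed=seed)
        obs, truth = gen_plasma_pk(c, reg, phys, times, noise)
        return obs, c, reg, phys

    def test_recovers_parameters_from_noisy_data(self):
        obs, c_true, reg, phys = self._observed(cv=0.05)
        template = one_compartment_compound(renal_cl=1.5, ka=1.5)
        fit = fit_pk(obs, template, ["ka", "renal_cl"], self.BOUNDS, reg, phys)
        assert fit.converged
        assert fit.params["ka"] == pytest.approx(c_true.ka_per_h, rel=0.15)
        assert fit.params["renal_cl"] == pytest.approx(
            c_true.renal_cl_l_per_h, rel=0.15
        )

    def test_noise_free_self_consistency(self):
        obs, c_true, reg, phys = self._observed(cv=0.0)
        template = one_compartment_compound(renal_cl=2.0, ka=1.2)
        fit = fit_pk(obs, template, ["ka", "renal_cl"], self.BOUNDS, reg, phys)
        assert fit.converged
        assert fit.params["ka"] == pytest.approx(c_true.ka_per_h, rel=1e-3)
        assert fit.params["renal_cl"] == pytest.approx(
            c_true.renal_cl_l_per_h, rel=1e-3
        )

    def test_all_zero_observations_flagged_not_silent(self):
        obs, _, reg, phys = self._observed(cv=0.0)
        obs["conc_uM"] = 0.0
        template = one_compartment_compound(renal_cl=2.0, ka=1.2)
        fit = fit_pk(obs, template, ["ka", "renal_cl"], self.BOUNDS, reg, phys)
        assert not fit.converged  # boundary or failure flag raised

    def test_underdetermined_design_rejected(self):
        obs, _, reg, phys = self._observed(cv=0.0)
        with pytest.raises(ValueError):
            fit_pk(
                obs.head(3),
                one_compartment_compound(),
                ["ka", "renal_cl"],
                self.BOUNDS,
                reg,
                phys,
            )


class TestCurveIO:
    def test_tidy_csv_round_trip(self, tmp_path):
        t = np.linspace(0, 24, 25)
        curve = PKCurve(
            times_h=t,
            plasma_um={"a": np.sin(t / 8.0) ** 2, "b": np.full(25, 2.0)},
            liver_um={"a": np.cos(t / 8.0) ** 2, "b": np.full(25, 5.0)},
        )
        path = tmp_path / "curve.csv"
        curve.to_frame().to_csv(path, index=False)
        back = PKCurve.from_frame(pd.read_csv(path))
        for sp in ("a", "b"):
            assert np.allclose(back.plasma_um[sp], curve.plasma_um[sp])
            assert np.allclose(back.liver_um[sp], curve.liver_um[sp])
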