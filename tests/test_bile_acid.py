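import numpy as np
import pytest

from biletox import engine
from biletox.bile_acid import (
    BA_SPECIES,
    COMPARTMENT_INDEX,
    BileAcidState,
    ba_fluxes,
    gallbladder_empty,
    solve_baseline,
    toxicity_class,
)
from biletox.compounds import InhibitionSpec


class TestSpeciesEnumeration:
    def test_conjugates_inherit_parent_toxicity_class(self):
        assert toxicity_class("CDCA") == "CDCA"
        assert toxicity_class("CDCA_amide") == "CDCA"
        assert toxicity_class("LCA") == "LCA"
        assert toxicity_class("LCA_amide") == "LCA"
        assert toxicity_class("LCA_sulfate") == "LCA"

    def test_negative_amounts_rejected(self):
        bad = np.zeros((5, 5))
        bad[0, 0] = -1.0
        with pytest.raises(ValueError):
            BileAcidState(bad)


class TestGallbladderEmpty:
    def test_configured_fraction_transfer(self, human):
        phys, _ = human
        state = BileAcidState()
        gb = COMPARTMENT_INDEX["gallbladder"]
        state.amounts_umol[:, gb] = 100.0
        out = gallbladder_empty(state, phys)
        gut = COMPARTMENT_INDEX["gut_lumen"]
        frac = phys.gallbladder_empty_fraction
        assert np.allclose(out.amounts_umol[:, gb], 100.0 * (1 - frac))
        assert np.allclose(out.amounts_umol[:, gut], 100.0 * frac)
        # exact mole conservation
        assert out.total_umol() == pytest.approx(state.total_umol(), abs=1e-12)

    def test_zero_fraction_is_identity(self, human):
        phys, _ = human
        phys = phys.copy()
        phys.gallbladder_empty_fraction = 0.0
        state = BileAcidState()
        state.amounts_umol[:, 1] = 50.0
        out = gallbladder_empty(state, phys)
        assert np.array_equal(out.amounts_umol, state.amounts_umol)

    def test_empty_gallbladder_is_identity(self, human):
        phys, _ = human
        state = BileAcidState()
        state.amounts_umol[:, 0] = 10.0
        out = gallbladder_empty(state, phys)
        assert np.array_equal(out.amounts_umol, state.amounts_umol)


class TestBaFluxes:
    def test_zero_state_has_only_synthesis(self, human, human_tox, human_injury):
        phys, tr = human
        deriv, sinks = ba_fluxes(BileAcidState(), tr, phys)
        # CDCA synthesized into the liver; nothing else moves
        assert deriv[0, 0] == pytest.approx(phys.ba_synthesis_rate_umol_per_h)
        deriv[0, 0] = 0.0
        assert np.allclose(deriv, 0.0)
        assert sinks["fecal_umol_per_h"] == 0.0
        assert sinks["hydroxylation_umol_per_h"] == 0.0

    def test_matches_independent_flux_arithmetic(self, human):
        """Cross-check the compiled kernel against a direct evaluation of the
        stated flux laws for one nontrivial state."""
        phys, tr = human
        rng = np.random.default_rng(3)
        state = BileAcidState(rng.uniform(0.5, 50.0, size=(5, 5)))
        deriv, sinks = ba_fluxes(state, tr, phys)

        a = state.amounts_umol
        for s, name in enumerate(BA_SPECIES):
            cliv = a[s, 0] / phys.liver_volume_l
            cpor = a[s, 3] / phys.portal_volume_l
            csys = a[s, 4] / phys.blood_volume_l
            jb = tr.vmax_umol_per_h["BSEP"][s] * cliv / (tr.km_um["BSEP"][s] + cliv)
            jn = tr.vmax_umol_per_h["NTCP"][s] * cpor / (tr.km_um["NTCP"][s] + cpor)
            jba = (
                tr.vmax_umol_per_h["BASOLATERAL"][s]
                * cliv
                / (tr.km_um["BASOLATERAL"][s] + cliv)
            )
            expected_gb = jb
            assert deriv[s, 1] == pytest.approx(expected_gb, rel=1e-12)
            # liver: uptake - export - efflux + chemistry
            chem = 0.0
            if name == "CDCA":
                chem = phys.ba_synthesis_rate_umol_per_h - phys.conjugation_k_per_h * a[s, 0]
            elif name == "CDCA_amide":
                chem = phys.conjugation_k_per_h * a[0, 0]
            elif name == "LCA":
                chem = -(phys.conjugation_k_per_h + phys.sulfation_k_per_h) * a[s, 0]
            elif name == "LCA_amide":
                chem = phys.conjugation_k_per_h * a[2, 0]
            elif name == "LCA_sulfate":
                chem = phys.sulfation_k_per_h * a[2, 0]
            assert deriv[s, 0] == pytest.approx(jn - jb - jba + chem, rel=1e-10)
            # systemic: basolateral + portal spill - splanchnic return
            spill = phys.q_portal_l_per_h * cpor
            ret = phys.q_portal_l_per_h * csys
            assert deriv[s, 4] == pytest.approx(jba + spill - ret, rel=1e-10)

    def test_total_moles_change_only_via_named_sources_and_sinks(self, human):
        phys, tr = human
        rng = np.random.default_rng(4)
        state = BileAcidState(rng.uniform(0.0, 80.0, size=(5, 5)))
        deriv, sinks = ba_fluxes(state, tr, phys)
        net = (
            sinks["synthesis_umol_per_h"]
            - sinks["fecal_umol_per_h"]
            - sinks["hydroxylation_umol_per_h"]
        )
        assert deriv.sum() == pytest.approx(net, rel=1e-10, abs=1e-10)

    def test_bsep_loss_strictly_increases_liver_accumulation(self, human):
        phys, tr = human
        rng = np.random.default_rng(5)
        state = BileAcidState(rng.uniform(1.0, 30.0, size=(5, 5)))
        base, _ = ba_fluxes(state, tr, phys)
        tr0 = tr.scaled("BSEP", 0.0)
        knocked, _ = ba_fluxes(state, tr0, phys)
        assert np.all(knocked[:, 0] > base[:, 0])

    def test_drug_inhibition_reduces_bsep_flux(self, human):
        phys, tr = human
        state = BileAcidState(np.full((5, 5), 10.0))
        spec = [InhibitionSpec(transporter="BSEP", ki_um=12.0, mode="noncompetitive")]
        base, _ = ba_fluxes(state, tr, phys)
        inhib, _ = ba_fluxes(
            state, tr, phys,
            inhibitor_liver_conc_um=[12.0],
            inhibitor_plasma_conc_um=[1.0],
            inhibition_specs=[spec],
        )
        # gallbladder influx (pure BSEP) halves when liver drug conc == Ki
        assert np.allclose(inhib[:, 1], base[:, 1] / 2.0, rtol=1e-9)


class TestSolveBaseline:
    def test_human_baseline_is_positive_and_periodic(self, human_baseline):
        trace = human_baseline["baseline_trace"]
        assert trace.is_periodic()
        state = trace.final_state()
        # every compartment participates in the circulation
        assert np.all(state.amounts_umol.sum(axis=0) > 0.0)
        assert trace.mole_balance_error() < 1e-6

    def test_time_averaged_net_flux_vanishes_at_steady_state(self, human_baseline):
        """Periodic steady state: day-averaged net change of each compartment
        is a negligible share of the circulating pool."""
        trace = human_baseline["baseline_trace"]
        daily = trace.daily_compartment_totals()
        pool = daily[-1].sum()
        assert np.all(np.abs(daily[-1] - daily[-2]) / pool < 0.005)

    def test_washout_without_synthesis(self, human, human_tox, human_injury):
        phys, tr = human
        phys = phys.copy()
        phys.ba_synthesis_rate_umol_per_h = 0.0
        state = BileAcidState(np.full((5, 5), 20.0))
        trace = engine.simulate_exposure(
            tr, phys, human_tox, human_injury, duration_h=60 * 24.0,
            initial_state=state,
        )
        totals = trace.states[:, :25].sum(axis=1)
        assert totals[-1] < 0.05 * totals[0]

    def test_rat_liver_toxic_exposure_below_human(self, human_baseline, rat_baseline):
        """The rat's toxic bile acid pool is the documented protective factor:
        its baseline liver CDCA/LCA-class concentration sits below the human's."""
        h = human_baseline["baseline_trace"]
        r = rat_baseline["baseline_trace"]
        mask_h = h.times_h >= h.times_h[-1] - 24
        mask_r = r.times_h >= r.times_h[-1] - 24
        assert (
            r.liver_toxic_conc_um()[mask_r].mean()
            < h.liver_toxic_conc_um()[mask_h].mean()
        )


class TestJacobianConsistency:
    def test_analytic_jacobian_matches_finite_differences(self, human):
        phys, tr = human
        rng = np.random.default_rng(11)
        state = BileAcidState(rng.uniform(0.5, 40.0, size=(5, 5)))
        y0 = engine.state_to_vector(state, atp_mm=3.0)
        y0[engine.IDX_DELAY : engine.IDX_DELAY + 5] = rng.uniform(1.0, 30.0, 5)
        y0[engine.IDX_VIABLE] = 0.9
        p = engine.pack_params(tr, phys)
        tg = np.array([0.0])
        empty = np.zeros((0, 1))
        J = engine.jac(0.0, y0, p, tg, empty, empty)
        f0 = engine.rhs(0.0, y0, p, tg, empty, empty)
        for i in range(engine.NSTATE_BASE):
            h = max(1e-6 * abs(y0[i]), 1e-8)
            yp = y0.copy()
            yp[i] += h
            col = (engine.rhs(0.0, yp, p, tg, empty, empty) - f0) / h
            assert np.allclose(J[:, i], col, rtol=5e-3, atol=1e-4)
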