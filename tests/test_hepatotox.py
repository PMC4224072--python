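import numpy as np
import pytest
from scipy.integrate import solve_ivp

from biletox.hepatotox import (
    ClassToxParams,
    InjuryParams,
    ToxParams,
    atp_dynamics,
    delay_update,
    fit_tox_params,
    injury_dynamics,
    normalized_lft,
    simulate_invitro_atp,
    synthesis_signal,
)
from biletox.synthetic_data import NoiseModel, gen_invitro_atp

CLS = ClassToxParams(vmax_s=3.0, km_s_um=40.0, hill=2.5, tau_per_h=0.4)


def tox_params(baseline=4.2):
    return ToxParams(
        classes={"CDCA": CLS, "LCA": ClassToxParams(4.0, 25.0, 3.0, 0.3)},
        k_synth_mm_per_h=baseline,
        k_usage_mm_per_h=baseline,
        baseline_atp_mm=baseline,
    )


class TestDelay:
    def test_fixed_point(self):
        assert delay_update(10.0, 10.0, 0.5) == 0.0

    def test_exponential_relaxation_closes_63_percent_at_one_tau(self):
        tau = 0.7
        sol = solve_ivp(
            lambda t, y: delay_update(20.0, y, tau),
            (0.0, 1.0 / tau),
            [0.0],
            rtol=1e-10,
            atol=1e-12,
        )
        assert sol.y[0, -1] / 20.0 == pytest.approx(1 - np.exp(-1), rel=1e-6)

    def test_large_tau_tracks_input(self):
        tau = 1e4
        sol = solve_ivp(
            lambda t, y: delay_update(5.0, y, tau), (0.0, 0.1), [0.0],
            rtol=1e-10, atol=1e-12, method="LSODA",
        )
        assert sol.y[0, -1] == pytest.approx(5.0, rel=1e-4)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            delay_update(1.0, 0.0, 0.0)


class TestSynthesisSignal:
    def test_zero_exposure_gives_unity(self):
        assert synthesis_signal({"CDCA": 0.0, "LCA": 0.0}, tox_params()) == 1.0

    def test_half_saturation_value(self):
        s = synthesis_signal({"CDCA": CLS.km_s_um, "LCA": 0.0}, tox_params())
        assert s == pytest.approx(1.0 / (1.0 + CLS.vmax_s / 2.0))

    def test_saturating_limit(self):
        s = synthesis_signal({"CDCA": 1e9, "LCA": 0.0}, tox_params())
        assert s == pytest.approx(1.0 / (1.0 + CLS.vmax_s), rel=1e-6)

    def test_classes_combine_multiplicatively(self):
        p = tox_params()
        s_both = synthesis_signal({"CDCA": 30.0, "LCA": 15.0}, p)
        s_c = synthesis_signal({"CDCA": 30.0}, p)
        s_l = synthesis_signal({"LCA": 15.0}, p)
        assert s_both == pytest.approx(s_c * s_l)

    @pytest.mark.parametrize("conc", [0.0, 1.0, 40.0, 1e4])
    def test_bounded_in_unit_interval(self, conc):
        p = tox_params()
        s = synthesis_signal({"CDCA": conc, "LCA": conc}, p)
        lower = 1.0 / ((1 + p.classes["CDCA"].vmax_s) * (1 + p.classes["LCA"].vmax_s))
        assert lower - 1e-12 <= s <= 1.0


class TestAtpDynamics:
    def test_baseline_is_fixed_point(self):
        p = tox_params()
        assert atp_dynamics(p.baseline_atp_mm, 1.0, 1.0, p) == pytest.approx(0.0)

    def test_half_signal_halves_steady_state(self):
        p = tox_params()
        ss = 0.5 * p.baseline_atp_mm
        assert atp_dynamics(ss, 0.5, 1.0, p) == pytest.approx(0.0)

    def test_etc_factor_acts_like_signal(self):
        p = tox_params()
        assert atp_dynamics(2.1, 1.0, 0.5, p) == atp_dynamics(2.1, 0.5, 1.0, p)

    def test_out_of_range_signal_rejected(self):
        p = tox_params()
        with pytest.raises(ValueError):
            atp_dynamics(4.2, 0.0, 1.0, p)
        with pytest.raises(ValueError):
            atp_dynamics(4.2, 1.0, 1.5, p)

    def test_imbalanced_turnover_constants_rejected(self):
        with pytest.raises(ValueError):
            ToxParams(
                classes={"CDCA": CLS, "LCA": CLS},
                k_synth_mm_per_h=4.2,
                k_usage_mm_per_h=2.0,
                baseline_atp_mm=4.2,
            )


class TestInjuryDynamics:
    PARAMS = InjuryParams(
        atp_death_threshold_mm=2.31,
        k_necrosis_max_per_h=0.04,
        necrosis_hill=2.0,
        alt_release_fold_per_fraction=300.0,
        k_alt_clear_per_h=0.015,
        k_bili_clear_per_h=0.05,
        k_regen_per_h=0.005,
    )

    def test_no_injury_above_threshold(self):
        d_v, d_alt, d_bili = injury_dynamics(3.0, 1.0, 1.0, 1.0, self.PARAMS)
        assert d_v == 0.0 and d_alt == 0.0 and d_bili == 0.0

    def test_alt_impulse_decays_with_clearance_time_constant(self):
        """After a 1% necrosis step the serum ALT excess decays exponentially
        with 1/k_alt_clear."""
        p = self.PARAMS
        alt0 = 1.0 + 0.01 * p.alt_release_fold_per_fraction

        def rhs(t, y):
            return [injury_dynamics(4.2, 0.99, y[0], 1.0, p)[1]]

        t_c = 1.0 / p.k_alt_clear_per_h
        sol = solve_ivp(rhs, (0, t_c), [alt0], rtol=1e-10, atol=1e-12)
        excess0 = alt0 - 1.0
        assert (sol.y[0, -1] - 1.0) / excess0 == pytest.approx(np.exp(-1), rel=1e-6)

    def test_sustained_atp_collapse_monotonically_kills(self):
        p = self.PARAMS

        def rhs(t, y):
            return [injury_dynamics(0.0, y[0], 1.0, 1.0, p)[0] - p.k_regen_per_h * (1 - y[0])]

        sol = solve_ivp(rhs, (0, 100.0), [1.0], rtol=1e-9, atol=1e-12)
        assert np.all(np.diff(sol.y[0]) < 1e-12)

    def test_bilirubin_tracks_inverse_viable_fraction(self):
        p = self.PARAMS
        d_bili = injury_dynamics(4.2, 0.5, 1.0, 2.0, p)[2]
        assert d_bili == pytest.approx(0.0)


class TestNormalizedLFT:
    @pytest.mark.parametrize(
        "alt, bili, expected",
        [(5.0, 3.0, 1.0), (15.0, 1.0, 3.0), (0.0, 0.0, 0.0), (1.0, 1.0, 1.0 / 3.0)],
    )
    def test_printed_formula(self, alt, bili, expected):
        assert normalized_lft(alt, bili) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            normalized_lft(-0.1, 1.0)


class TestFitToxParams:
    TRUE = ClassToxParams(vmax_s=2.5, km_s_um=35.0, hill=2.0, tau_per_h=0.35)
    EXPOSURES = [5.0, 15.0, 30.0, 60.0, 120.0, 250.0]
    TIMES = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 18.0, 24.0])

    def _fit(self, cv, seed=42):
        data, _ = gen_invitro_atp(
            self.TRUE, "CDCA", self.EXPOSURES, self.TIMES,
            NoiseModel(kind="proportional", cv=cv, seed=seed),
        )
        guess = ClassToxParams(vmax_s=1.5, km_s_um=20.0, hill=1.5, tau_per_h=0.5)
        return fit_tox_params(data, initial_guess=guess)

    def test_recovery_from_noisy_data(self):
        fit = self._fit(cv=0.05)
        assert fit.success and fit.identifiable
        assert fit.params.vmax_s == pytest.approx(self.TRUE.vmax_s, rel=0.2)
        assert fit.params.km_s_um == pytest.approx(self.TRUE.km_s_um, rel=0.2)
        assert fit.params.hill == pytest.approx(self.TRUE.hill, rel=0.2)
        assert fit.params.tau_per_h == pytest.approx(self.TRUE.tau_per_h, rel=0.2)

    def test_noise_free_exact_recovery(self):
        fit = self._fit(cv=0.0)
        assert fit.params.vmax_s == pytest.approx(self.TRUE.vmax_s, rel=1e-3)
        assert fit.params.km_s_um == pytest.approx(self.TRUE.km_s_um, rel=1e-3)
        assert fit.params.hill == pytest.approx(self.TRUE.hill, rel=1e-3)
        assert fit.params.tau_per_h == pytest.approx(self.TRUE.tau_per_h, rel=1e-3)

    def test_null_signal_yields_near_zero_vmax(self):
        import pandas as pd

        rows = []
        for e in self.EXPOSURES:
            rows.append(
                pd.DataFrame(
                    {"exposure_um": e, "time_h": self.TIMES, "atp_pct": 100.0}
                )
            )
        flat = pd.concat(rows, ignore_index=True)
        fit = fit_tox_params(flat)
        assert fit.params.vmax_s < 0.05

    def test_single_exposure_flagged_non_identifiable(self):
        data, _ = gen_invitro_atp(
            self.TRUE, "CDCA", [30.0, 30.0], self.TIMES,
            NoiseModel(cv=0.0, seed=1),
        )
        fit = fit_tox_params(data[data["exposure_um"] == 30.0])
        assert not fit.identifiable


class TestInvitroModel:
    def test_plateau_matches_closed_form_limit(self):
        """At saturating exposure the ATP floor is baseline/(1+Vmax_S)."""
        pct = simulate_invitro_atp(CLS, 1e6, np.array([100.0]))
        assert pct[0] == pytest.approx(100.0 / (1.0 + CLS.vmax_s), rel=1e-3)

    def test_zero_exposure_flat_at_control(self):
        pct = simulate_invitro_atp(CLS, 0.0, np.array([1.0, 10.0, 24.0]))
        assert np.allclose(pct, 100.0)
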