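import numpy as np
import pandas as pd
import pytest

from biletox import vpop
from biletox.compounds import DoseRegimen, load_compound
from biletox.scenarios import Scenario, baseline_context
from biletox.vpop import (
    PK_PATHS,
    VariabilitySpec,
    add_pk_variability,
    generate_simpops,
    incidence,
    run_population,
)


def specs(scale=0.3):
    return [
        VariabilitySpec("bsep_vmax", "lognormal", 1.0, scale, 0.3, 3.0),
        VariabilitySpec("ba_synthesis", "lognormal", 1.0, scale, 0.4, 2.5),
    ]


WIDE_RANGES = {"liver_toxic_ba_um": (0.0, 1e3), "systemic_toxic_ba_um": (0.0, 1e3)}


@pytest.fixture(scope="module")
def small_pop(human_baseline):
    ctx = human_baseline
    return generate_simpops(
        n=4,
        specs=specs(),
        transporters=ctx["transporters"],
        physiology=ctx["physiology"],
        seed=77,
        acceptance_ranges=WIDE_RANGES,
        tox=ctx["tox"],
        injury=ctx["injury"],
    )


class TestGenerateSimpops:
    def test_seeded_determinism_bit_equal(self, human_baseline, small_pop):
        ctx = human_baseline
        again = generate_simpops(
            n=4, specs=specs(), transporters=ctx["transporters"],
            physiology=ctx["physiology"], seed=77,
            acceptance_ranges=WIDE_RANGES, tox=ctx["tox"], injury=ctx["injury"],
        )
        for a, b in zip(small_pop.individuals, again.individuals):
            assert a.overrides == b.overrides  # bit-equal floats

    def test_degenerate_spec_reproduces_baseline(self, human_baseline):
        ctx = human_baseline
        tiny = [
            VariabilitySpec("bsep_vmax", "lognormal", 1.0, 1e-12, 0.9, 1.1),
        ]
        pop = generate_simpops(
            n=2, specs=tiny, transporters=ctx["transporters"],
            physiology=ctx["physiology"], seed=5,
            acceptance_ranges=WIDE_RANGES, tox=ctx["tox"], injury=ctx["injury"],
        )
        ref = pop.individuals[0].baseline_summary
        for ind in pop.individuals[1:]:
            assert ind.baseline_summary["liver_toxic_ba_um"] == pytest.approx(
                ref["liver_toxic_ba_um"], rel=1e-6
            )
        assert ref["baseline_atp_mm"] == pytest.approx(
            ctx["physiology"].baseline_atp_mm, rel=0.01
        )

    def test_impossible_acceptance_range_aborts(self, human_baseline):
        ctx = human_baseline
        with pytest.raises(RuntimeError, match="acceptance rate"):
            generate_simpops(
                n=3, specs=specs(), transporters=ctx["transporters"],
                physiology=ctx["physiology"], seed=9,
                acceptance_ranges={"liver_toxic_ba_um": (1e6, 2e6)},
                tox=ctx["tox"], injury=ctx["injury"],
            )

    def test_invalid_inputs_rejected(self, human_baseline):
        ctx = human_baseline
        with pytest.raises(ValueError):
            generate_simpops(
                n=0, specs=specs(), transporters=ctx["transporters"],
                physiology=ctx["physiology"], seed=1, acceptance_ranges=WIDE_RANGES,
            )
        with pytest.raises(ValueError):
            generate_simpops(
                n=1, specs=[], transporters=ctx["transporters"],
                physiology=ctx["physiology"], seed=1, acceptance_ranges=WIDE_RANGES,
            )


class TestRunPopulation:
    def test_drug_free_min_atp_stays_at_baseline(self, small_pop):
        scenario = Scenario(
            name="drug_free", species="human", compound=None, regimen=None
        )
        res = run_population(small_pop, scenario)
        assert (res["error"] == "").all()
        for _, row in res.iterrows():
            assert row["min_atp_mm"] == pytest.approx(4.2, rel=0.01)

    def test_duplicated_individuals_give_identical_results(self, small_pop):
        import copy

        dup = copy.deepcopy(small_pop)
        dup.individuals = [small_pop.individuals[0], small_pop.individuals[0]]
        scenario = Scenario(
            name="short_bosentan",
            species="human",
            compound=load_compound("bosentan"),
            regimen=DoseRegimen(amount_mg=500.0, interval_h=12.0, n_doses=4),
            follow_up_h=24.0,
        )
        res = run_population(dup, scenario)
        assert res.iloc[0]["peak_alt_fold"] == res.iloc[1]["peak_alt_fold"]
        assert res.iloc[0]["min_atp_mm"] == res.iloc[1]["min_atp_mm"]


class TestIncidence:
    def make(self, n, k):
        return pd.DataFrame({"peak_alt_fold": [4.0] * k + [1.0] * (n - k)})

    def test_one_of_331(self):
        count, pct = incidence(self.make(331, 1))
        assert count == 1
        assert pct == pytest.approx(0.302, abs=0.001)

    def test_eight_of_331(self):
        count, pct = incidence(self.make(331, 8))
        assert count == 8
        assert pct == pytest.approx(2.42, abs=0.01)

    def test_zero_incidence(self):
        count, pct = incidence(self.make(100, 0))
        assert count == 0 and pct == 0.0

    def test_threshold_is_strict(self):
        res = pd.DataFrame({"peak_alt_fold": [3.0, 3.0001]})
        count, _ = incidence(res)
        assert count == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            incidence(pd.DataFrame({"peak_alt_fold": []}))


class TestPKVariability:
    def pk_specs(self, scale=0.2):
        return [
            VariabilitySpec(p, "normal", 1.0, scale, 0.3, 2.0) for p in PK_PATHS
        ]

    def test_wrong_parameter_set_rejected(self, small_pop):
        bad = self.pk_specs()[:3]
        with pytest.raises(ValueError, match="pk_specs"):
            add_pk_variability(small_pop, bad, seed=1)

    def test_seeded_and_layered_on_transport_overrides(self, small_pop):
        pop1 = add_pk_variability(small_pop, self.pk_specs(), seed=3)
        pop2 = add_pk_variability(small_pop, self.pk_specs(), seed=3)
        for a, b in zip(pop1.individuals, pop2.individuals):
            assert a.overrides == b.overrides
            assert set(PK_PATHS) <= set(a.overrides)
            assert "bsep_vmax" in a.overrides  # transport overrides kept

    def test_pk_variability_widens_outcome_spread(self, human_baseline):
        """On a transport-homogeneous population, adding PK variability must
        strictly increase the spread of peak liver bile acid exposure under a
        fixed short bosentan regimen."""
        ctx = human_baseline
        tiny = [VariabilitySpec("bsep_vmax", "lognormal", 1.0, 1e-9, 0.9, 1.1)]
        pop = generate_simpops(
            n=3, specs=tiny, transporters=ctx["transporters"],
            physiology=ctx["physiology"], seed=8,
            acceptance_ranges=WIDE_RANGES, tox=ctx["tox"], injury=ctx["injury"],
        )
        scenario = Scenario(
            name="short_bosentan",
            species="human",
            compound=load_compound("bosentan"),
            regimen=DoseRegimen(amount_mg=500.0, interval_h=12.0, n_doses=4),
            follow_up_h=24.0,
        )
        base = run_population(pop, scenario)
        pkpop = add_pk_variability(pop, self.pk_specs(scale=0.4), seed=11)
        withpk = run_population(pkpop, scenario)
        assert (
            withpk["peak_liver_toxic_ba_um"].std()
            > base["peak_liver_toxic_ba_um"].std()
        )


class TestVariabilitySpec:
    def test_bounds_enforced_by_rejection(self, rng):
        s = VariabilitySpec("bsep_vmax", "lognormal", 1.0, 0.5, 0.8, 1.2)
        draws = [s.sample(rng) for _ in range(200)]
        assert all(0.8 <= d <= 1.2 for d in draws)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            VariabilitySpec("x", "uniform", 1.0, 0.1, 0.5, 2.0)
        with pytest.raises(ValueError):
            VariabilitySpec("x", "normal", 1.0, 0.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            VariabilitySpec("x", "normal", 1.0, 0.1, 2.0, 0.5)
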