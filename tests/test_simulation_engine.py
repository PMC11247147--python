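"""Annual update loop: null dynamics, conservation, absorbing states,
event sampling, KRT, and engine recovery of known ground truths."""
import numpy as np
import pytest

from ckdsim import advance_year, run_projection, sample_event, synthesize
from ckdsim.input_model import KrtParameters
from ckdsim.population_synthesis import Individual
from ckdsim.simulation_engine import (krt_update, outputs_to_frame,
                                      update_diagnosis)
from ckdsim.synthetic_data import (generate_bundle,
                                   generate_ground_truth_scenario)


class TestSampleEvent:
    def test_zero_probability_never_fires(self):
        rng = np.random.default_rng(0)
        assert not any(sample_event(0.0, 5.0, rng) for _ in range(100))

    def test_probability_capped_at_one(self):
        rng = np.random.default_rng(0)
        assert all(sample_event(0.4, 5.0, rng) for _ in range(100))

    def test_relative_risk_doubles_empirical_rate(self):
        n, p = 100_000, 0.01
        hits_rr2 = sum(sample_event(p, 2.0, np.random.default_rng([1, i]))
                       for i in range(n))
        hits_rr1 = sum(sample_event(p, 1.0, np.random.default_rng([2, i]))
                       for i in range(n))
        ratio = hits_rr2 / hits_rr1
        se = np.sqrt(1 / hits_rr2 + 1 / hits_rr1)  # log-scale SE
        assert abs(np.log(ratio) - np.log(2.0)) <= 3 * se

    def test_invalid_inputs_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_event(1.5, 1.0, rng)
        with pytest.raises(ValueError):
            sample_event(0.5, -1.0, rng)


class TestScalarUpdates:
    def _ckd_individual(self, **kw):
        defaults = dict(id=0, age=60, sex="M", egfr=40.0, acr=50.0,
                        is_ckd=True)
        defaults.update(kw)
        return Individual(**defaults)

    def test_diagnosis_rate_one_diagnoses(self):
        ind = self._ckd_individual()
        update_diagnosis(ind, {"G3b": 1.0}, np.random.default_rng(0))
        assert ind.diagnosed

    def test_diagnosis_rate_zero_stays_undiagnosed(self):
        ind = self._ckd_individual()
        update_diagnosis(ind, {"G3b": 0.0}, np.random.default_rng(0))
        assert not ind.diagnosed

    def test_diagnosis_is_absorbing(self):
        ind = self._ckd_individual(diagnosed=True)
        update_diagnosis(ind, {"G3b": 0.0}, np.random.default_rng(0))
        assert ind.diagnosed

    def test_diagnosis_requires_ckd(self):
        ind = Individual(id=0, age=60, sex="M", egfr=95.0, acr=5.0)
        with pytest.raises(ValueError):
            update_diagnosis(ind, {}, np.random.default_rng(0))

    def test_krt_initiation_below_threshold(self):
        krt = KrtParameters(egfr_initiation_threshold=10,
                            access_probability=1.0,
                            modality_shares={"HD": 1.0})
        ind = self._ckd_individual(egfr=8.0)
        krt_update(ind, krt, np.random.default_rng(0), year=2022)
        assert ind.krt == "HD" and ind.krt_start_year == 2022

    def test_no_initiation_above_threshold(self):
        krt = KrtParameters(egfr_initiation_threshold=10,
                            access_probability=1.0,
                            modality_shares={"HD": 1.0})
        ind = self._ckd_individual(egfr=20.0)
        krt_update(ind, krt, np.random.default_rng(0))
        assert ind.krt == "none"

    def test_access_probability_governs_initiation_fraction(self):
        krt0 = KrtParameters(egfr_initiation_threshold=10,
                             access_probability=0.0,
                             modality_shares={"HD": 1.0})
        krt5 = KrtParameters(egfr_initiation_threshold=10,
                             access_probability=0.5,
                             modality_shares={"HD": 1.0})
        n = 10_000
        started = 0
        for i in range(n):
            ind = self._ckd_individual(egfr=8.0)
            krt_update(ind, krt0, np.random.default_rng([3, i]))
            assert ind.krt == "none"
            ind = self._ckd_individual(egfr=8.0)
            krt_update(ind, krt5, np.random.default_rng([4, i]))
            started += ind.krt != "none"
        p = started / n
        assert abs(p - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_dead_individual_rejected(self):
        krt = KrtParameters(egfr_initiation_threshold=10,
                            access_probability=1.0,
                            modality_shares={"HD": 1.0})
        ind = self._ckd_individual(alive=False)
        with pytest.raises(ValueError):
            krt_update(ind, krt, np.random.default_rng(0))


class TestAdvanceYear:
    def test_null_dynamics_only_ages(self, degenerate_bundle):
        coh = synthesize(degenerate_bundle, 5000, seed=1)
        before = coh.to_frame()
        advance_year(coh, degenerate_bundle, 2022, seed=1)
        after = coh.to_frame()
        assert (after["age"] == before["age"] + 1).all()
        for col in ("alive", "egfr", "acr", "is_ckd", "diagnosed", "krt"):
            assert (after[col] == before[col]).all(), col

    def test_certain_death_tallied_once(self, degenerate_bundle):
        bundle, _ = generate_ground_truth_scenario("constant_hazard")
        payload = bundle.model_dump()
        for band in payload["mortality_base"]:
            payload["mortality_base"][band] = {"F": 1.0, "M": 1.0}
        from ckdsim.input_model import CountryInputBundle
        certain = CountryInputBundle.model_validate(payload)
        coh = synthesize(certain, 1, seed=0)
        _, out = advance_year(coh, certain, 2022, seed=0)
        assert out.deaths == 1 and out.n_alive_end == 0
        assert coh.death_year[0] == 2022 and not coh.alive[0]

    def test_year_outside_horizon_rejected(self, degenerate_bundle):
        coh = synthesize(degenerate_bundle, 10, seed=0)
        with pytest.raises(ValueError):
            advance_year(coh, degenerate_bundle, 2030, seed=0)

    def test_determinism_and_conservation(self, small_aged_bundle):
        frames = []
        for _ in range(2):
            _, outs = run_projection(small_aged_bundle, 30_000, seed=9)
            frames.append(outputs_to_frame(outs))
        assert frames[0].equals(frames[1])
        f = frames[0]
        assert len(f) == 6
        # closed cohort: alive(t) = alive(t+1) + deaths(t+1), every year
        assert (f["n_alive_end"] + f["deaths"] == f["n_alive_start"]).all()
        assert (f["n_alive_start"].iloc[1:].values
                == f["n_alive_end"].iloc[:-1].values).all()

    def test_absorbing_states_never_revert(self, small_aged_bundle):
        coh = synthesize(small_aged_bundle, 30_000, seed=10)
        prev_dead = ~coh.alive
        prev_diag = coh.diagnosed.copy()
        prev_krt = coh.krt > 0
        for year in range(2022, 2028):
            advance_year(coh, small_aged_bundle, year, seed=10)
            assert not (prev_dead & coh.alive).any()
            assert not (prev_diag & ~coh.diagnosed).any()
            assert not (prev_krt & (coh.krt == 0)).any()
            prev_dead = ~coh.alive
            prev_diag = coh.diagnosed.copy()
            prev_krt = coh.krt > 0

    def test_stage_counts_sum_to_ckd_count(self, small_aged_bundle):
        _, outs = run_projection(small_aged_bundle, 30_000, seed=12)
        coh, _ = run_projection(small_aged_bundle, 30_000, seed=12)
        for out in outs:
            assert out.ckd_total == sum(out.ckd_diagnosed_by_stage.values()) \
                + sum(out.ckd_undiagnosed_by_stage.values())
        final = outs[-1]
        assert final.ckd_total == int((coh.alive & coh.is_ckd).sum())

    def test_event_counts_monotone_across_risk_categories(self):
        """With non-decreasing grid rr, worse KDIGO cells see more events."""
        from ckdsim.input_model import CountryInputBundle
        bundle = generate_bundle("degenerate", 0)
        payload = bundle.model_dump()
        cells = {"none": 0.25, "G2/A2": 0.25, "G3a/A2": 0.25, "G4/A2": 0.25}
        for band in payload["stage_distribution"]:
            if band == "0-17":
                continue
            payload["stage_distribution"][band] = {
                "F": dict(cells), "M": dict(cells)}
        for band in payload["cv_base_rates"]["heart_failure"]:
            payload["cv_base_rates"]["heart_failure"][band] = {
                "F": 0.02, "M": 0.02}
        bundle = CountryInputBundle.model_validate(payload)
        coh = synthesize(bundle, 200_000, seed=14)
        cat = np.select(
            [~coh.is_ckd, coh.g_index == 1, coh.g_index == 2],
            [0, 1, 2], default=3)  # none, moderate(G2/A2), high, very_high
        advance_year(coh, bundle, 2022, seed=14)
        rates = [coh.cv_hf[cat == k].mean() for k in range(4)]
        assert rates[1] < rates[2] < rates[3]  # rr 1.5 < 2.5 < 4.0
        assert rates[0] < rates[1]


class TestGroundTruthRecovery:
    def test_constant_hazard_survival(self):
        bundle, expected = generate_ground_truth_scenario("constant_hazard",
                                                          seed=21)
        n = 100_000
        coh = synthesize(bundle, n, seed=21)
        for year in range(2022, 2027):
            advance_year(coh, bundle, year, seed=21)
        p = expected["alive_fraction_after_5_years"]
        assert p == pytest.approx(0.59049)
        assert abs(coh.alive.mean() - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_linear_slope_recovery(self):
        bundle, expected = generate_ground_truth_scenario("slope_recovery",
                                                          seed=22)
        coh = synthesize(bundle, 50_000, seed=22)
        assert coh.egfr.mean() == pytest.approx(
            expected["mean_egfr_baseline"], abs=0.2)
        for year in range(2022, 2027):
            advance_year(coh, bundle, year, seed=22)
        assert coh.egfr.mean() == pytest.approx(
            expected["mean_egfr_after_5_years"], abs=0.2)

    def test_known_mortality_rr_recovered_within_3se(self):
        bundle, expected = generate_ground_truth_scenario("rr_recovery",
                                                          seed=23)
        n = 100_000
        coh = synthesize(bundle, n, seed=23)
        ckd0 = coh.is_ckd.copy()
        deaths = np.zeros(2)
        person_years = np.zeros(2)
        for year in range(2022, 2027):
            at_risk = coh.alive.copy()
            advance_year(coh, bundle, year, seed=23)
            died = at_risk & ~coh.alive
            for k, grp in enumerate((~ckd0, ckd0)):
                person_years[k] += (at_risk & grp).sum()
                deaths[k] += (died & grp).sum()
        rates = deaths / person_years
        ratio = rates[1] / rates[0]
        se_log = np.sqrt(1 / deaths[0] + 1 / deaths[1])
        assert abs(np.log(ratio) - np.log(expected["death_rr"])) <= 3 * se_log

    def test_per_100k_outputs_stable_across_cohort_sizes(
            self, small_aged_bundle):
        """Per-100k prevalences at n=1e5 and n=1e6 agree within combined MC error."""
        results = {}
        for n in (100_000, 1_000_000):
            _, outs = run_projection(small_aged_bundle, n, seed=30)
            final = outs[-1]
            results[n] = (final.ckd_total / final.n_alive_end * 1e5, n)
        (r1, n1), (r2, n2) = results[100_000], results[1_000_000]
        p = r2 / 1e5
        se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2)) * 1e5
        assert abs(r1 - r2) <= 3 * se
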