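"""Synthetic drydown generator tests: trajectory anchors, thresholds,
determinism and zero-noise closure with the downstream estimators."""

import numpy as np
import pandas as pd
import pytest

from leafgm import (DrydownScenario, NoiseModel, generate_observations,
                    simulate_conductances, simulate_water_status)
from leafgm.pipeline import estimate_gm_table


class TestWaterStatus:
    def test_drought_rswc_endpoints(self, zero_noise_tables):
        ws = zero_noise_tables["water_status"]
        drought = ws[ws.treatment == "drought"]
        first = drought[drought.day == drought.day.min()]["RSWC"]
        last = drought[drought.day == drought.day.max()]["RSWC"]
        assert np.allclose(first, 82.90)
        assert np.allclose(last, 37.27)

    def test_drought_rswc_monotone_decline(self, zero_noise_tables):
        ws = zero_noise_tables["water_status"]
        daily = (ws[ws.treatment == "drought"]
                 .groupby("day")["RSWC"].mean().to_numpy())
        assert np.all(np.diff(daily) < 0)

    def test_retention_anchors(self, default_scenario):
        assert default_scenario.psi_soil_from_rswc(82.90) == pytest.approx(-0.40)
        assert default_scenario.psi_soil_from_rswc(37.27) == pytest.approx(-1.44)

    def test_control_arm_stationary(self, noisy_tables):
        ws = noisy_tables["water_status"]
        ctrl = ws[ws.treatment == "control"]
        assert ctrl["psi_soil"].mean() == pytest.approx(-0.43, abs=0.05)
        assert ctrl["RSWC"].mean() == pytest.approx(75.13, rel=0.05)

    def test_aba_flat_then_exponential(self, zero_noise_tables):
        ws = zero_noise_tables["water_status"]
        drought = ws[ws.treatment == "drought"]
        sc = DrydownScenario()
        pre = drought[drought.psi_soil >= sc.aba_psi_threshold]
        post = drought[drought.psi_soil < sc.aba_psi_threshold]
        assert np.allclose(pre["ABA"], sc.aba_baseline)
        assert len(post) > 0 and (post["ABA"] > sc.aba_baseline).all()

    def test_final_drought_aba_hits_calibration_anchor(self, zero_noise_tables):
        ws = zero_noise_tables["water_status"]
        drought = ws[ws.treatment == "drought"]
        final = drought[drought.day == drought.day.max()]["ABA"].mean()
        assert final == pytest.approx(97.86, rel=0.01)
        assert final / DrydownScenario().aba_baseline == pytest.approx(300.0, rel=0.01)

    def test_determinism_same_seed_identical_tables(self):
        sc = DrydownScenario(seed=11)
        a = simulate_water_status(sc)
        b = simulate_water_status(sc)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate_water_status(DrydownScenario(seed=1))
        b = simulate_water_status(DrydownScenario(seed=2))
        assert not a["RSWC"].equals(b["RSWC"])

    def test_inverted_day_range_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            DrydownScenario(day_start=33, day_end=27)


class TestConductanceResponses:
    def test_gm_plateau_before_threshold(self, default_scenario):
        _, gm = simulate_conductances(
            {"psi_leaf": -0.8, "ABA": default_scenario.aba_baseline},
            default_scenario)
        assert gm == default_scenario.gm_plateau

    def test_severe_stress_reduces_both(self, default_scenario):
        gs, gm = simulate_conductances(
            {"psi_leaf": -1.6, "ABA": 50.0}, default_scenario)
        assert gm < default_scenario.gm_plateau
        assert gs < default_scenario.gs_ww * 0.9

    def test_aba_lowers_gs_but_not_gm_pre_threshold(self, default_scenario):
        low = simulate_conductances({"psi_leaf": -1.0, "ABA": 1.0},
                                    default_scenario)
        high = simulate_conductances({"psi_leaf": -1.0, "ABA": 10.0},
                                     default_scenario)
        assert high[0] < low[0]
        assert high[1] == low[1]

    def test_gs_declines_at_milder_stress_than_gm(self, default_scenario):
        """Scan psi_leaf: gs leaves its plateau strictly before gm does."""
        psis = np.linspace(-0.72, -1.7, 200)
        base_aba = default_scenario.aba_baseline
        gs_vals, gm_vals = zip(*(
            simulate_conductances({"psi_leaf": p, "ABA": base_aba},
                                  default_scenario)
            for p in psis))
        gs_onset = psis[np.argmax(np.array(gs_vals) < default_scenario.gs_ww * 0.999)]
        gm_onset = psis[np.argmax(np.array(gm_vals) < default_scenario.gm_plateau * 0.999)]
        assert gs_onset > gm_onset  # less negative = milder stress


class TestGeneratedObservations:
    def test_replicate_counts_honoured(self, noisy_tables):
        obs = noisy_tables["observations"]
        per_day = obs.groupby(["day", "treatment"])["plant_id"].nunique()
        assert (per_day.xs("control", level="treatment") == 2).all()
        assert (per_day.xs("drought", level="treatment") == 6).all()

    def test_zero_noise_closure_gm_recovery(self, zero_noise_tables):
        est = estimate_gm_table(zero_noise_tables["observations"])
        truth = zero_noise_tables["truth"]
        merged = est.merge(truth, on=["plant_id", "day", "treatment"])
        assert merged["valid"].all()
        rel = np.abs(merged["gm"] - merged["gm_true"]) / merged["gm_true"]
        assert rel.max() < 1e-6

    def test_observation_table_identical_with_and_without_aci(self, default_scenario):
        with_aci = generate_observations(default_scenario, include_aci=True)
        without = generate_observations(default_scenario, include_aci=False)
        pd.testing.assert_frame_equal(with_aci["observations"],
                                      without["observations"])

    def test_gs_departs_from_control_before_gm(self):
        """Across seeds, the day gs first drops >10% below control precedes
        the day gm does."""
        for seed in range(5):
            tables = generate_observations(DrydownScenario(seed=seed),
                                           include_aci=False)
            truth = tables["truth"]
            piv_gs = truth.pivot_table(index="day", columns="treatment",
                                       values="gs_true")
            piv_gm = truth.pivot_table(index="day", columns="treatment",
                                       values="gm_true")
            gs_day = _departure_day(piv_gs)
            gm_day = _departure_day(piv_gm)
            assert gs_day is not None and gm_day is not None
            assert gs_day < gm_day

    def test_fluorescence_backfill_consistent(self, zero_noise_tables):
        obs = zero_noise_tables["observations"]
        truth = zero_noise_tables["truth"]
        sc = DrydownScenario()
        phi = (obs["Fm_prime"] - obs["Fs"]) / obs["Fm_prime"]
        jf = phi * obs["PPFD"] * sc.kinetics.alpha * sc.kinetics.beta
        assert np.allclose(jf, truth["Jf_true"], rtol=1e-9)

    def test_noise_model_rejects_negative_cv(self):
        with pytest.raises(ValueError):
            NoiseModel(An=-0.1)


def _departure_day(pivot):
    below = pivot["drought"] < 0.9 * pivot["control"]
    days = below[below].index
    return days.min() if len(days) else None
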