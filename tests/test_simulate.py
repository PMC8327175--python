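"""Synthetic cohort generator: closed-form signal checks and determinism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from ventdp import (
    CohortSpec,
    PatientParams,
    VentilatorScenario,
    devine_ibw,
    make_cohort,
    make_patient,
    simulate_eit,
    simulate_vcv,
)
from ventdp.simulate import SEVERITY_EL_RANGES


class TestMakePatient:
    def test_moderate_draw_within_documented_ranges(self):
        p = make_patient(seed=0, severity="moderate")
        lo, hi = SEVERITY_EL_RANGES["moderate"]
        assert lo <= p.el_true <= hi
        assert 15.0 <= p.ers_true <= 45.0  # EL [12,30] + Ecw [5,15]

    def test_same_seed_is_deterministic(self):
        assert make_patient(3, "severe") == make_patient(3, "severe")

    def test_severity_orders_mean_lung_elastance(self):
        mild = np.mean([make_patient(s, "mild").el_true for s in range(100)])
        severe = np.mean([make_patient(s, "severe").el_true for s in range(100)])
        assert severe > mild

    def test_unknown_severity_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            make_patient(0, "catastrophic")

    def test_devine_formula(self):
        assert devine_ibw("male", 152.4) == pytest.approx(50.0)
        assert devine_ibw("female", 162.4) == pytest.approx(45.5 + 9.1)

    def test_roi_fractions_stay_normalized_across_peep(self):
        p = make_patient(5, "moderate")
        for peep in (0.0, 5.0, 10.0, 18.0):
            f = p.roi_fractions_at(peep)
            assert np.all(f >= 0) and np.all(f <= 1)
            assert f.sum() == pytest.approx(1.0, abs=1e-12)


class TestSimulateVcv:
    def test_plateau_matches_equation_of_motion(self, patient, quiet_scenario, analyzed_noiseless):
        # el=18, ecw=9, TV=0.4 L, PEEP=10 -> Pplat = 10 + 27*0.4 = 20.8
        summary, _ = analyzed_noiseless
        assert summary.pplat == pytest.approx(20.8, abs=1e-6)
        assert summary.peep_tot == pytest.approx(10.0, abs=1e-6)

    def test_esophageal_swing_is_chest_wall_share(self, analyzed_noiseless):
        # Peso tidal swing = Ecw*TV = 9*0.4 = 3.6 cmH2O
        summary, breaths = analyzed_noiseless
        swing = np.mean([b.peso_insp - b.peso_exp for b in breaths if b.usable])
        assert swing == pytest.approx(3.6, abs=1e-6)

    def test_flow_conserves_volume_over_cycle(self, patient, quiet_scenario, noiseless_bundle):
        tv = quiet_scenario.tv_per_kg * patient.ibw_kg
        vol = noiseless_bundle.volume
        ann = noiseless_bundle.annotations
        for k in range(1, len(ann)):
            net = vol[ann[k].start] - vol[ann[k - 1].start]
            assert abs(net) < 1e-3 * tv
        assert vol.max() == pytest.approx(tv, rel=1e-9)

    def test_zero_tidal_volume_gives_flat_pressures(self, patient):
        sc = VentilatorScenario(
            peep_set=8.0, tv_per_kg=0.0, noise_sd_paw=0.0, noise_sd_peso=0.0, cardiac_amp=0.0
        )
        b = simulate_vcv(patient, sc)
        assert np.allclose(b.paw, 8.0)
        assert np.allclose(b.peso, patient.pleural_baseline)
        assert np.allclose(b.flow, 0.0)

    def test_infeasible_timing_names_constraint(self, patient):
        sc = VentilatorScenario(peep_set=10.0, resp_rate=40.0, insp_flow=200.0)
        with pytest.raises(ValueError, match="infeasible timing"):
            simulate_vcv(patient, sc)

    def test_scenario_invariants_enforced(self):
        with pytest.raises(ValueError, match="fs_waveform"):
            VentilatorScenario(peep_set=10.0, fs_waveform=50.0, fs_eit=20.0)
        with pytest.raises(ValueError, match="n_breaths"):
            VentilatorScenario(peep_set=10.0, n_breaths=5)


class TestSimulateEit:
    def _volume(self):
        return np.concatenate([np.linspace(0, 400, 50), np.full(50, 400.0), np.linspace(400, 0, 50)])

    def _patient(self, frac):
        return PatientParams(
            "x", "male", 170, 66.7, 18, 9, 10, roi_base=frac, roi_peep_slope=(0, 0, 0, 0)
        )

    def test_uniform_fractions_give_equal_bands(self):
        p = self._patient((0.25, 0.25, 0.25, 0.25))
        bands = simulate_eit(p, self._volume(), peep=10, fs_eit=20, seed=0)
        amp = bands.max(axis=0) - bands.min(axis=0)
        assert np.allclose(100 * amp / amp.sum(), 25.0)

    def test_cohort_median_fractions_round_trip(self):
        p = self._patient((0.19, 0.37, 0.31, 0.13))
        bands = simulate_eit(p, self._volume(), peep=0, fs_eit=20, seed=0)
        amp = bands.max(axis=0) - bands.min(axis=0)
        assert np.allclose(100 * amp / amp.sum(), [19, 37, 31, 13], atol=1e-9)

    def test_volume_scaling_doubles_amplitude_not_fractions(self):
        p = self._patient((0.19, 0.37, 0.31, 0.13))
        b1 = simulate_eit(p, self._volume(), peep=0, fs_eit=20, seed=0)
        b2 = simulate_eit(p, 2 * self._volume(), peep=0, fs_eit=20, seed=0)
        assert np.allclose(b2, 2 * b1)

    def test_image_mode_band_structure(self):
        p = self._patient((0.19, 0.37, 0.31, 0.13))
        frames = simulate_eit(p, self._volume(), peep=0, fs_eit=20, seed=0, as_image=True)
        assert frames.shape[1] == 1024
        band = frames[15].reshape(4, 256).sum(axis=1)  # mid-plateau frame
        assert np.allclose(100 * band / band.sum(), [19, 37, 31, 13], atol=1e-9)


class TestMakeCohort:
    def test_equation_at_cohort_medians(self):
        # IBW 65, Ers 27, roi 19/37/31 -> 16.64 + 0.074683*65 + 0.230941*27
        #   - 0.21449*19 - 0.15974*37 - 0.32996*31 = 7.515352
        spec = CohortSpec(
            n_patients=2,
            dpl_noise_sd=0.0,
            spreads={"ibw": 0.0, "ers": 0.0, "roi1": 0.0, "roi2": 0.0, "roi3": 0.0},
            seed=0,
        )
        cohort = make_cohort(spec)
        assert np.allclose(cohort["dpl"], 7.515352, atol=1e-9)

    def test_panel_shape_and_indexing(self):
        cohort = make_cohort(CohortSpec(n_patients=20, seed=4))
        assert len(cohort) == 60
        assert cohort["patient_id"].nunique() == 20
        assert sorted(cohort["condition"].unique()) == [1, 2, 3]

    def test_identical_seeds_give_bit_identical_cohorts(self):
        spec = CohortSpec(n_patients=5, seed=11)
        a = make_cohort(spec).to_csv(index=False)
        b = make_cohort(dataclasses.replace(spec)).to_csv(index=False)
        assert a == b

    def test_mechanistic_mode_records_ground_truth(self):
        cohort = make_cohort(
            CohortSpec(n_patients=2, generation_mode="mechanistic", seed=2)
        )
        ok = cohort[cohort["quality_ok"]]
        assert len(ok) >= 5
        # measured DP_L tracks the generating EL*TV within noise
        expect = ok["el_true"] * ok["tv_ml"] / 1000.0
        assert np.allclose(ok["dpl"], expect, atol=0.5)

    def test_unknown_mode_rejected(self):
        spec = CohortSpec(n_patients=2)
        with pytest.raises(ValueError, match="generation_mode"):
            make_cohort(dataclasses.replace(spec, generation_mode="oracle"))

    def test_covariates_clamped_to_physiologic_ranges(self):
        spec = CohortSpec(n_patients=50, spreads={"ibw": 40, "ers": 60, "roi1": 40, "roi2": 40, "roi3": 40}, seed=9)
        cohort = make_cohort(spec)
        assert cohort["ers"].between(5, 80).all()
        roi = cohort[[f"roi{i}_pct" for i in range(1, 5)]]
        assert (roi.to_numpy() >= 0).all() and (roi.to_numpy() <= 100).all()
        assert np.allclose(roi.sum(axis=1), 100.0, atol=1e-9)
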