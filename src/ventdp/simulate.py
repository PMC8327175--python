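"""Synthetic ARDS cohort generation.

Virtual patients are single/two-compartment linear respiratory systems
(lung elastance EL and chest-wall elastance Ecw in series, airway
resistance Rrs) ventilated in volume-controlled ventilation (VCV) at
6 ml/kg of ideal body weight, with end-inspiratory and end-expiratory
occlusion pauses in every breath.  Esophageal pressure carries a cardiac
sinusoid artifact; EIT band signals are the regional ventilation
fractions applied to the instantaneous lung volume.

Everything is deterministic given the seed threaded through
``numpy.random.default_rng``; no global RNG state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientParams",
    "VentilatorScenario",
    "SignalBundle",
    "BreathAnnotation",
    "CohortSpec",
    "devine_ibw",
    "make_patient",
    "simulate_vcv",
    "simulate_eit",
    "simulate_measurement",
    "simulate_repeated_measures",
    "make_cohort",
    "SEVERITY_EL_RANGES",
]

# EL strata bracket the cohort EL median of ~18 [14-23] cmH2O/L seen in
# moderate ARDS populations; Ecw is largely severity-independent.
SEVERITY_EL_RANGES = {
    "mild": (8.0, 15.0),
    "moderate": (12.0, 30.0),
    "severe": (25.0, 45.0),
}
ECW_RANGE = (5.0, 15.0)
RRS_RANGE = (8.0, 15.0)  # cmH2O.s/L, typical intubated ARDS
PLEURAL_BASELINE_RANGE = (3.0, 8.0)  # cmH2O end-expiratory pleural pressure

#: cohort-median regional ventilation fractions, ventral -> dorsal
ROI_BASE_DEFAULT = (0.19, 0.37, 0.31, 0.13)
#: per-cmH2O PEEP shift of the fractions (dorsal recruitment with PEEP)
ROI_PEEP_SLOPE_DEFAULT = (-0.004, -0.002, 0.003, 0.003)

CARDIAC_FREQ_HZ = 1.3


def devine_ibw(sex: str, height_cm: float) -> float:
    """Ideal body weight (kg) from the Devine formula."""
    base = 50.0 if sex == "male" else 45.5
    return base + 0.91 * (height_cm - 152.4)


@dataclass(frozen=True)
class PatientParams:
    """Ground-truth respiratory mechanics of one virtual patient.

    Elastances are in cmH2O/L, resistance in cmH2O.s/L, pressures in
    cmH2O.  ``roi_base`` holds the ventral->dorsal ventilation fractions
    at zero PEEP; ``roi_peep_slope`` shifts them linearly with PEEP
    (renormalized afterwards).
    """

    patient_id: str
    sex: Literal["male", "female"]
    height_cm: float
    ibw_kg: float
    el_true: float
    ecw_true: float
    rrs: float
    roi_base: tuple[float, float, float, float] = ROI_BASE_DEFAULT
    roi_peep_slope: tuple[float, float, float, float] = ROI_PEEP_SLOPE_DEFAULT
    pleural_baseline: float = 5.0

    def __post_init__(self) -> None:
        if self.el_true <= 0 or self.ecw_true <= 0 or self.rrs <= 0:
            raise ValueError("el_true, ecw_true and rrs must be positive")
        base = np.asarray(self.roi_base, dtype=float)
        if base.shape != (4,) or np.any(base < 0) or abs(base.sum() - 1.0) > 1e-9:
            raise ValueError("roi_base must be 4 non-negative fractions summing to 1")

    @property
    def ers_true(self) -> float:
        """Respiratory-system elastance Ers = EL + Ecw (cmH2O/L)."""
        return self.el_true + self.ecw_true

    def roi_fractions_at(self, peep: float) -> np.ndarray:
        """Ventilation fractions at a PEEP level (shift, clip, renormalize)."""
        f = np.asarray(self.roi_base) + peep * np.asarray(self.roi_peep_slope)
        f = np.clip(f, 0.0, None)
        total = f.sum()
        if total <= 0:
            raise ValueError("PEEP shift annihilated all ventilation fractions")
        return f / total


@dataclass(frozen=True)
class VentilatorScenario:
    """One VCV measurement condition.

    Square-wave inspiratory flow delivering ``tv_per_kg`` ml/kg IBW,
    followed by an end-inspiratory pause, passive exponential expiration
    and an end-expiratory pause.  Noise amplitudes are Gaussian sd in
    cmH2O; ``cardiac_amp`` is the esophageal cardiac-artifact amplitude.
    """

    peep_set: float
    tv_per_kg: float = 6.0
    resp_rate: float = 19.0
    insp_flow: float = 600.0  # ml/s
    pause_insp_s: float = 0.5
    pause_exp_s: float = 0.5
    n_breaths: int = 15
    fs_waveform: float = 100.0
    fs_eit: float = 20.0
    noise_sd_paw: float = 0.2
    noise_sd_peso: float = 0.3
    cardiac_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tv_per_kg < 0:
            raise ValueError("tv_per_kg must be non-negative")
        if self.fs_waveform < 4 * self.fs_eit:
            raise ValueError("fs_waveform must be at least 4x fs_eit")
        if self.n_breaths < 12:
            raise ValueError("n_breaths must be >= 12 (10 usable after trimming)")


@dataclass(frozen=True)
class BreathAnnotation:
    """Index ranges (waveform rate) for one simulated breath."""

    start: int
    insp_window: tuple[int, int]  # half-open [i0, i1)
    exp_window: tuple[int, int]


@dataclass
class SignalBundle:
    """Time-aligned ventilator waveforms plus optional EIT frames.

    ``paw`` (cmH2O), ``flow`` (ml/s, positive inspiratory) and ``peso``
    (cmH2O) share the waveform clock ``t`` (s).  ``eit_frames`` is
    (n_frames, 4) pre-summed band sums or (n_frames, 1024) row-major
    32x32 images, sampled at ``fs_eit``.
    """

    t: np.ndarray
    paw: np.ndarray
    flow: np.ndarray
    peso: np.ndarray
    fs: float
    annotations: list[BreathAnnotation] = field(default_factory=list)
    eit_frames: np.ndarray | None = None
    fs_eit: float | None = None

    @property
    def volume(self) -> np.ndarray:
        """Lung volume above FRC (ml), trapezoidal integral of flow."""
        from scipy.integrate import cumulative_trapezoid

        return cumulative_trapezoid(self.flow, self.t, initial=0.0)


def make_patient(
    seed: int,
    severity: Literal["mild", "moderate", "severe"],
    patient_id: str | None = None,
) -> PatientParams:
    """Draw one virtual patient from severity-stratified mechanics ranges.

    Deterministic given ``seed``; out-of-range draws are clamped rather
    than rejected.
    """
    if severity not in SEVERITY_EL_RANGES:
        raise ValueError(f"unknown severity {severity!r}")
    rng = np.random.default_rng(seed)
    sex = "male" if rng.random() < 0.65 else "female"
    height = float(np.clip(rng.normal(170.0, 9.0), 150.0, 195.0))
    el = float(rng.uniform(*SEVERITY_EL_RANGES[severity]))
    ecw = float(rng.uniform(*ECW_RANGE))
    rrs = float(rng.uniform(*RRS_RANGE))
    base = np.clip(rng.normal(ROI_BASE_DEFAULT, 0.03), 0.01, None)
    base = base / base.sum()
    slope = rng.normal(ROI_PEEP_SLOPE_DEFAULT, 0.001)
    baseline = float(rng.uniform(*PLEURAL_BASELINE_RANGE))
    return PatientParams(
        patient_id=patient_id or f"sim{seed:05d}",
        sex=sex,
        height_cm=height,
        ibw_kg=devine_ibw(sex, height),
        el_true=el,
        ecw_true=ecw,
        rrs=rrs,
        roi_base=tuple(base),
        roi_peep_slope=tuple(slope),
        pleural_baseline=baseline,
    )


def _breath_template(
    tv_ml: float, scenario: VentilatorScenario, tau_s: float
) -> tuple[np.ndarray, int, int, int, int]:
    """One-cycle flow template (ml/s) and phase sample counts.

    The inspiratory amplitude and the expiratory decay are scaled so
    that the discrete trapezoidal integral of each zero-bounded run is
    exactly +tv_ml / -tv_ml (a zero-bounded run integrates to
    dt * sum(samples) under the trapezoid rule), making volume
    conservation exact at the waveform rate.
    """
    fs = scenario.fs_waveform
    dt = 1.0 / fs
    cycle_s = 60.0 / scenario.resp_rate
    ti = tv_ml / scenario.insp_flow if tv_ml > 0 else 0.0
    if ti + scenario.pause_insp_s + scenario.pause_exp_s >= cycle_s:
        raise ValueError(
            "infeasible timing: inspiratory time "
            f"({ti:.2f}s) + pauses ({scenario.pause_insp_s + scenario.pause_exp_s:.2f}s) "
            f"must be shorter than the cycle ({cycle_s:.2f}s)"
        )
    n_cycle = int(round(cycle_s * fs))
    ni = int(round(ti * fs))
    npi = int(round(scenario.pause_insp_s * fs))
    npe = int(round(scenario.pause_exp_s * fs))
    ne = n_cycle - ni - npi - npe
    if ne < 2 and tv_ml > 0:
        raise ValueError("infeasible timing: no room left for expiration")

    flow = np.zeros(n_cycle)
    if tv_ml > 0 and ni > 0:
        flow[:ni] = tv_ml / (ni * dt)
        shape = np.exp(-np.arange(ne) * dt / tau_s)
        flow[ni + npi : ni + npi + ne] = -shape * (tv_ml / (shape.sum() * dt))
    return flow, n_cycle, ni, npi, ne


def simulate_vcv(params: PatientParams, scenario: VentilatorScenario) -> SignalBundle:
    """Simulate airway/esophageal waveforms for one VCV measurement.

    The airway pressure follows the single-compartment equation of
    motion Paw = PEEP + Rrs.V' + Ers.V; the esophageal pressure is
    Peso = baseline + Ecw.V plus a cardiac sinusoid and Gaussian noise.
    At the occlusion pauses (flow = 0) the noiseless waveforms satisfy
    Pplat = PEEP + Ers.TV and a Peso swing of Ecw.TV exactly.
    """
    fs = scenario.fs_waveform
    tv_ml = scenario.tv_per_kg * params.ibw_kg
    tau = params.rrs / params.ers_true
    cycle_flow, n_cycle, ni, npi, ne = _breath_template(tv_ml, scenario, tau)

    # leading zero sample bounds the first inspiratory run so every
    # breath's trapezoidal integral is identical
    flow = np.concatenate([[0.0], np.tile(cycle_flow, scenario.n_breaths)])
    n = flow.size
    t = np.arange(n) / fs
    from scipy.integrate import cumulative_trapezoid

    vol_ml = cumulative_trapezoid(flow, dx=1.0 / fs, initial=0.0)
    vol_l = vol_ml / 1000.0
    flow_l = flow / 1000.0

    rng = np.random.default_rng(scenario.seed)
    paw = scenario.peep_set + params.rrs * flow_l + params.ers_true * vol_l
    peso = (
        params.pleural_baseline
        + params.ecw_true * vol_l
        + scenario.cardiac_amp * np.sin(2 * np.pi * CARDIAC_FREQ_HZ * t)
    )
    if scenario.noise_sd_paw > 0:
        paw = paw + rng.normal(0.0, scenario.noise_sd_paw, n)
    if scenario.noise_sd_peso > 0:
        peso = peso + rng.normal(0.0, scenario.noise_sd_peso, n)

    annotations = []
    for k in range(scenario.n_breaths):
        o = 1 + k * n_cycle
        annotations.append(
            BreathAnnotation(
                start=o,
                insp_window=(o + ni, o + ni + npi),
                exp_window=(o + ni + npi + ne, o + n_cycle),
            )
        )
    return SignalBundle(t=t, paw=paw, flow=flow, peso=peso, fs=fs, annotations=annotations)


def simulate_eit(
    params: PatientParams,
    volume_trace: np.ndarray,
    peep: float,
    fs_eit: float,
    seed: int,
    fs_waveform: float = 100.0,
    noise_sd: float = 0.0,
    as_image: bool = False,
) -> np.ndarray:
    """EIT frame series whose band sums track regional volume.

    Each ventral->dorsal band carries ``fraction_i(peep) * volume``
    resampled to the EIT frame rate, plus Gaussian noise; impedance is
    in arbitrary units proportional to ml.  With ``as_image`` the bands
    are spread uniformly over the four 8-row quarters of a 32x32 image
    (row-major, row 0 most ventral), shape (n_frames, 1024).
    """
    volume_trace = np.asarray(volume_trace, dtype=float)
    if np.any(volume_trace < -1e-9):
        raise ValueError("volume_trace must be non-negative")
    frac = params.roi_fractions_at(peep)
    t_w = np.arange(volume_trace.size) / fs_waveform
    t_e = np.arange(0.0, t_w[-1] + 1e-12, 1.0 / fs_eit)
    v_e = np.interp(t_e, t_w, volume_trace)
    rng = np.random.default_rng(seed)
    bands = np.outer(v_e, frac)
    if not as_image:
        if noise_sd > 0:
            bands = bands + rng.normal(0.0, noise_sd, bands.shape)
        return bands
    frames = np.zeros((v_e.size, 1024))
    for b in range(4):
        px = bands[:, b] / 256.0  # 8 rows x 32 cols per band
        block = np.repeat(px[:, None], 256, axis=1)
        frames[:, b * 256 : (b + 1) * 256] = block
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd / 256.0, frames.shape)
    return frames


def simulate_measurement(
    params: PatientParams,
    scenario: VentilatorScenario,
    eit_noise_sd: float = 0.0,
    as_image: bool = False,
) -> SignalBundle:
    """Waveforms plus matching EIT frames for one measurement."""
    bundle = simulate_vcv(params, scenario)
    bundle.eit_frames = simulate_eit(
        params,
        np.clip(bundle.volume, 0.0, None),
        peep=scenario.peep_set,
        fs_eit=scenario.fs_eit,
        seed=scenario.seed + 1,
        fs_waveform=scenario.fs_waveform,
        noise_sd=eit_noise_sd,
        as_image=as_image,
    )
    bundle.fs_eit = scenario.fs_eit
    return bundle


# --------------------------------------------------------------------------
# cohort tables


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic measurement panel (patient x condition).

    ``equation`` mode draws the five covariates around the cohort
    medians (IBW 65 kg, Ers 27 cmH2O/L, ROI% 19/37/31) and sets the
    measured DP_L to the published linear prediction equation plus
    N(0, ``dpl_noise_sd``).  ``mechanistic`` mode runs the full signal
    simulation for every measurement and leaves DP_L to the analysis
    chain.  Both record ground truth for recovery tests.
    """

    n_patients: int = 20
    conditions_per_patient: int = 3
    centers: dict = field(
        default_factory=lambda: {"ibw": 65.0, "ers": 27.0, "roi1": 19.0, "roi2": 37.0, "roi3": 31.0}
    )
    spreads: dict = field(
        default_factory=lambda: {"ibw": 8.0, "ers": 9.0, "roi1": 5.0, "roi2": 6.5, "roi3": 6.0}
    )
    dpl_noise_sd: float = 1.2
    generation_mode: Literal["equation", "mechanistic"] = "equation"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.dpl_noise_sd < 0:
            raise ValueError("dpl_noise_sd must be >= 0")


def _equation_cohort(spec: CohortSpec) -> pd.DataFrame:
    from .model import PUBLISHED_COEFFICIENTS as C

    rng = np.random.default_rng(spec.seed)
    rows = []
    for p in range(spec.n_patients):
        pid = f"P{p + 1:03d}"
        ibw = float(np.clip(rng.normal(spec.centers["ibw"], spec.spreads["ibw"]), 40.0, 100.0))
        peep_base = rng.uniform(8.0, 14.0)
        for c in range(spec.conditions_per_patient):
            ers = float(np.clip(rng.normal(spec.centers["ers"], spec.spreads["ers"]), 5.0, 80.0))
            roi = np.array(
                [
                    rng.normal(spec.centers["roi1"], spec.spreads["roi1"]),
                    rng.normal(spec.centers["roi2"], spec.spreads["roi2"]),
                    rng.normal(spec.centers["roi3"], spec.spreads["roi3"]),
                ]
            )
            roi = np.clip(roi, 0.0, 100.0)
            roi4 = 100.0 - roi.sum()
            if roi4 < 0:  # renormalize the rare overshoot
                roi *= 100.0 / roi.sum()
                roi4 = 0.0
            dpl_true = (
                C["k"]
                + C["alpha"] * ibw
                + C["beta"] * ers
                + C["gamma"] * roi[0]
                + C["delta"] * roi[1]
                + C["eps"] * roi[2]
            )
            dpl = dpl_true + (rng.normal(0.0, spec.dpl_noise_sd) if spec.dpl_noise_sd > 0 else 0.0)
            tv_ml = 6.0 * ibw
            dp = ers * tv_ml / 1000.0
            peep = peep_base + (c - 1) * 3.0
            pplat = peep + dp
            el = dpl / (tv_ml / 1000.0)
            rows.append(
                {
                    "patient_id": pid,
                    "condition": c + 1,
                    "peep": peep,
                    "ibw_kg": ibw,
                    "tv_ml": tv_ml,
                    "pplat": pplat,
                    "peep_tot": peep,
                    "dp": dp,
                    "ers": ers,
                    "roi1_pct": roi[0],
                    "roi2_pct": roi[1],
                    "roi3_pct": roi[2],
                    "roi4_pct": roi4,
                    "dpl": dpl,
                    "el": el,
                    "ecw": ers - el,
                    "pi": pplat * el / ers,
                    "dpl_true": dpl_true,
                    "quality_ok": True,
                }
            )
    return pd.DataFrame(rows)


def _mechanistic_cohort(spec: CohortSpec) -> pd.DataFrame:
    from .eit import ensemble_tidal_image, regional_compliance, roi_fractions
    from .mechanics import analyze_bundle

    rng = np.random.default_rng(spec.seed)
    severities = ["mild", "moderate", "severe"]
    rows = []
    for p in range(spec.n_patients):
        sev = severities[int(rng.integers(0, 3))]
        patient = make_patient(int(rng.integers(0, 2**31 - 1)), sev, patient_id=f"P{p + 1:03d}")
        peep_base = rng.uniform(8.0, 14.0)
        for c in range(spec.conditions_per_patient):
            peep = peep_base + (c - 1) * 3.0
            scenario = VentilatorScenario(peep_set=peep, seed=int(rng.integers(0, 2**31 - 1)))
            row = {
                "patient_id": patient.patient_id,
                "condition": c + 1,
                "peep": peep,
                "ibw_kg": patient.ibw_kg,
                "el_true": patient.el_true,
                "ecw_true": patient.ecw_true,
                "ers_true": patient.ers_true,
            }
            try:
                bundle = simulate_measurement(patient, scenario, eit_noise_sd=0.5)
                summary, breaths = analyze_bundle(bundle, with_peso=True)
                tidal, _ = ensemble_tidal_image(
                    bundle.eit_frames, breaths, fs_waveform=bundle.fs, fs_eit=bundle.fs_eit
                )
                roi = roi_fractions(tidal)
                rc = regional_compliance(summary.tv_ml, roi, summary.dp, patient.ibw_kg)
                row.update(
                    {
                        "tv_ml": summary.tv_ml,
                        "pplat": summary.pplat,
                        "peep_tot": summary.peep_tot,
                        "dp": summary.dp,
                        "ers": summary.ers,
                        "roi1_pct": roi[0],
                        "roi2_pct": roi[1],
                        "roi3_pct": roi[2],
                        "roi4_pct": roi[3],
                        "rc_roi1": rc[0],
                        "rc_roi2": rc[1],
                        "rc_roi3": rc[2],
                        "rc_roi4": rc[3],
                        "dpl": summary.dpl,
                        "el": summary.el,
                        "ecw": summary.ecw,
                        "pi": summary.pi,
                        "quality_ok": True,
                        "exclude_reason": "",
                    }
                )
            except Exception as exc:  # excluded, mirrored in manifest accounting
                row.update({"quality_ok": False, "exclude_reason": str(exc)})
            rows.append(row)
    return pd.DataFrame(rows)


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a measurement panel, one row per patient x condition."""
    if spec.generation_mode == "equation":
        return _equation_cohort(spec)
    if spec.generation_mode == "mechanistic":
        return _mechanistic_cohort(spec)
    raise ValueError(f"unknown generation_mode {spec.generation_mode!r}")


def simulate_repeated_measures(
    n_subjects: int,
    n_reps: int,
    r_within: float,
    seed: int,
    between_sd: float = 2.0,
    within_sd: float = 1.0,
    mean_x: float = 0.0,
    mean_y: float = 0.0,
) -> pd.DataFrame:
    """Paired repeated measures with a set within-subject correlation.

    Subject-specific random intercepts (sd ``between_sd``) on both
    variables plus within-subject bivariate-normal deviations with
    correlation ``r_within`` — the sampling model under which the
    repeated-measures correlation estimates ``r_within``.
    """
    if not -1.0 <= r_within <= 1.0:
        raise ValueError("r_within must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    cov = within_sd**2 * np.array([[1.0, r_within], [r_within, 1.0]])
    rows = []
    for s in range(n_subjects):
        bx, by = rng.normal(0.0, between_sd, 2)
        dev = rng.multivariate_normal([0.0, 0.0], cov, size=n_reps)
        for j in range(n_reps):
            rows.append(
                {
                    "subject": f"S{s + 1:04d}",
                    "x": mean_x + bx + dev[j, 0],
                    "y": mean_y + by + dev[j, 1],
                }
            )
    return pd.DataFrame(rows)
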