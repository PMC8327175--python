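"""EIT regional ventilation analysis.

Turns an EIT frame series into the regional quantities used by the
non-invasive mechanics chain: the ensemble tidal impedance image (mean
inspiratory-minus-expiratory frame difference over up to 10 breaths),
the percentage of tidal ventilation in four equal-height ventral->dorsal
bands (ROI1 most ventral .. ROI4 most dorsal), and the IBW-normalized
weighted regional compliance

    RC_ROI_i = TV * (ROI%_i / 100) / DP / IBW      [ml/cmH2O/kg]

Frames may be row-major 32x32 images (1024 columns) or pre-summed
4-band vectors.  Equal-height horizontal quarters stand in for the
vendor's proprietary anthropometric lung contouring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import BreathRecord

__all__ = ["RoiTidal", "ensemble_tidal_image", "roi_fractions", "regional_compliance"]


@dataclass(frozen=True)
class RoiTidal:
    """Regional tidal ventilation summary for one measurement."""

    roi_pct: np.ndarray  # ventral -> dorsal, sums to 100
    rc_roi: np.ndarray  # ml/cmH2O/kg IBW
    n_breaths_used: int


def _window_frames(window: tuple[int, int], fs_waveform: float, fs_eit: float, n_frames: int):
    a = int(np.ceil(window[0] / fs_waveform * fs_eit))
    b = int(np.floor((window[1] - 1) / fs_waveform * fs_eit)) + 1
    a, b = max(a, 0), min(b, n_frames)
    return (a, b) if b > a else None


def ensemble_tidal_image(
    frames: np.ndarray,
    breaths: list[BreathRecord],
    fs_waveform: float,
    fs_eit: float,
    n_breaths: int = 10,
) -> tuple[np.ndarray, int]:
    """Mean tidal impedance change ΔZ over the last usable breaths.

    Per breath, ΔZ = median frame over the end-inspiratory pause minus
    the median frame over the end-expiratory pause; the output is the
    mean ΔZ over the last ``min(n_breaths, available)`` breaths whose
    pause windows overlap the frame series.  Negative pixels are floored
    at 0; the flipped-pixel count is returned alongside.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    deltas = []
    for b in breaths:
        if b.insp_window is None or b.exp_window is None:
            continue
        wi = _window_frames(b.insp_window, fs_waveform, fs_eit, frames.shape[0])
        we = _window_frames(b.exp_window, fs_waveform, fs_eit, frames.shape[0])
        if wi is None or we is None:
            continue
        insp = np.median(frames[wi[0] : wi[1]], axis=0)
        exp = np.median(frames[we[0] : we[1]], axis=0)
        deltas.append(insp - exp)
    if not deltas:
        raise ValueError("no breath overlaps the EIT frame series")
    tidal = np.mean(deltas[-n_breaths:], axis=0)
    n_negative = int(np.sum(tidal < 0))
    return np.clip(tidal, 0.0, None), n_negative


def roi_fractions(tidal: np.ndarray) -> np.ndarray:
    """Percentage of tidal impedance change in four ventral->dorsal bands.

    A 1024-pixel (or 32x32) tidal image is split into its four
    equal-height horizontal quarters (rows 0-7 most ventral); a 4-vector
    input is taken as pre-summed bands and only normalized.
    """
    tidal = np.asarray(tidal, dtype=float)
    if tidal.size == 4:
        band = tidal.ravel()
    elif tidal.size == 1024:
        band = tidal.reshape(32, 32).reshape(4, 8, 32).sum(axis=(1, 2))
    else:
        raise ValueError(f"expected 4 bands or a 32x32 image, got {tidal.size} values")
    total = band.sum()
    if total <= 0:
        raise ValueError("no tidal signal (total impedance change is zero)")
    return 100.0 * band / total


def regional_compliance(
    tv_ml: float, roi_pct: np.ndarray, dp: float, ibw_kg: float
) -> np.ndarray:
    """Weighted regional compliance per ROI, ml/cmH2O/kg IBW.

    The four values sum to the IBW-specific respiratory-system
    compliance (TV/DP)/IBW.
    """
    if dp <= 0:
        raise ValueError("driving pressure must be positive")
    if ibw_kg <= 0:
        raise ValueError("ibw_kg must be positive")
    return tv_ml * (np.asarray(roi_pct, dtype=float) / 100.0) / dp / ibw_kg
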