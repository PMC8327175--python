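"""File formats and unit handling.

Canonical internal units are cmH2O, ml, ml/s and seconds; every
conversion happens at the I/O boundary.  Waveforms travel as CSV with
header ``t,paw,flow,peso``; EIT frames as CSV of shape (n_frames, 4)
band sums or (n_frames, 1024) row-major 32x32 images; cohorts as one
CSV row per measurement; metadata and models as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SignalBundle

__all__ = [
    "FLOW_UNIT_FACTORS",
    "read_waveforms",
    "write_waveforms",
    "read_eit_frames",
    "write_eit_frames",
    "read_cohort",
    "write_cohort",
    "read_metadata",
    "write_metadata",
]

WAVEFORM_COLUMNS = ["t", "paw", "flow", "peso"]

#: multiplicative factor to canonical ml/s
FLOW_UNIT_FACTORS = {"ml/s": 1.0, "l/min": 1000.0 / 60.0, "l/s": 1000.0}


def _flow_factor(units: str) -> float:
    key = units.lower().replace(" ", "")
    if key not in FLOW_UNIT_FACTORS:
        raise ValueError(
            f"unknown flow unit {units!r}; expected one of {sorted(FLOW_UNIT_FACTORS)}"
        )
    return FLOW_UNIT_FACTORS[key]


def read_waveforms(
    path, flow_units: str = "ml/s", fs: float | None = None
) -> tuple[SignalBundle, int]:
    """Load a waveform CSV into a SignalBundle (canonical units).

    Returns the bundle and the number of malformed (non-finite) rows
    dropped.  ``peso`` may be absent (all-NaN column is substituted).
    """
    factor = _flow_factor(flow_units)  # validate units before touching the file
    df = pd.read_csv(path)
    missing = [c for c in ("t", "paw", "flow") if c not in df.columns]
    if missing:
        raise ValueError(f"waveform CSV missing column(s): {', '.join(missing)}")
    if "peso" not in df.columns:
        df["peso"] = np.nan
        required = ["t", "paw", "flow"]
    else:
        required = ["t", "paw", "flow", "peso"]
    good = np.isfinite(df[required].to_numpy(dtype=float)).all(axis=1)
    n_bad = int((~good).sum())
    df = df[good].reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("waveform CSV has fewer than 2 valid rows")
    t = df["t"].to_numpy(dtype=float)
    fs = fs or 1.0 / float(np.median(np.diff(t)))
    bundle = SignalBundle(
        t=t,
        paw=df["paw"].to_numpy(dtype=float),
        flow=df["flow"].to_numpy(dtype=float) * factor,
        peso=df["peso"].to_numpy(dtype=float),
        fs=fs,
    )
    return bundle, n_bad


def write_waveforms(bundle: SignalBundle, path) -> None:
    pd.DataFrame(
        {"t": bundle.t, "paw": bundle.paw, "flow": bundle.flow, "peso": bundle.peso}
    ).to_csv(path, index=False, float_format="%.9g")


def read_eit_frames(path) -> np.ndarray:
    frames = pd.read_csv(path, header=None).to_numpy(dtype=float)
    if frames.ndim != 2 or frames.shape[1] not in (4, 1024):
        raise ValueError(
            f"EIT CSV must have 4 or 1024 columns, got shape {frames.shape}"
        )
    return frames


def write_eit_frames(frames: np.ndarray, path) -> None:
    pd.DataFrame(np.atleast_2d(frames)).to_csv(path, index=False, header=False,
                                               float_format="%.9g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("cohort CSV missing 'patient_id' column")
    return df


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_metadata(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_metadata(meta: dict, path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
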