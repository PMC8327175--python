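"""Ventilator-waveform mechanics.

Segments VCV recordings into breaths, locates the end-inspiratory and
end-expiratory occlusion pauses, and computes airway and transpulmonary
(esophageal-referenced) mechanics for one measurement:

    DP   = Pplat - PEEPtot           Ers = DP / TV
    P_L  = Pao - Peso                DP_L = P_L,insp - P_L,exp
    EL   = DP_L / TV                 Ecw = Ers - EL
    PI   = Pplat * (EL / Ers)        (elastance-derived inspiratory P_L)

Pressures are cmH2O, volumes ml, elastances cmH2O/L.  Pause pressures
are read as the median over the final half of the pause window, which
suppresses the cardiac artifact on Peso and pressure-sensor noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import SignalBundle

__all__ = [
    "BreathRecord",
    "MechanicsSummary",
    "OcclusionResult",
    "segment_breaths",
    "detect_pauses",
    "annotate_breath",
    "summarize_mechanics",
    "analyze_bundle",
    "occlusion_test",
]

FLOW_EPS_DEFAULT = 10.0  # ml/s, |flow| below this counts as occlusion
MIN_PAUSE_S_DEFAULT = 0.2
MIN_INSP_FLOW_DEFAULT = 50.0  # ml/s threshold for breath-onset detection


@dataclass
class BreathRecord:
    """One segmented breath with its pause-window landmarks."""

    start: int
    end: int
    tv_ml: float
    ppeak: float
    insp_window: tuple[int, int] | None = None
    exp_window: tuple[int, int] | None = None
    pplat: float = np.nan
    peep_tot: float = np.nan
    peso_insp: float = np.nan
    peso_exp: float = np.nan
    usable: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class MechanicsSummary:
    """Mechanics of one measurement, averaged over up to 10 breaths.

    Peso-derived fields (``pl_insp`` .. ``pi``) are None when the
    summary was computed without esophageal pressure.  All the defining
    identities (dp = pplat - peep_tot, ers = dp/TV, dpl = pl_insp -
    pl_exp, el = dpl/TV, ecw = ers - el, pi = pplat*el/ers) hold by
    construction.
    """

    tv_ml: float
    ppeak: float
    pplat: float
    peep_tot: float
    dp: float
    ers: float
    n_breaths_used: int
    pl_insp: float | None = None
    pl_exp: float | None = None
    dpl: float | None = None
    el: float | None = None
    ecw: float | None = None
    pi: float | None = None


def segment_breaths(
    bundle: SignalBundle, min_insp_flow: float = MIN_INSP_FLOW_DEFAULT
) -> list[BreathRecord]:
    """Split a recording into breaths at inspiratory flow onsets.

    A breath starts where flow crosses above ``min_insp_flow`` (walked
    back to the zero-crossing); its tidal volume is the trapezoidal
    integral of the initial positive-flow run.  Returns breaths in time
    order; an empty list (with a warning) if none is detectable.
    """
    flow = np.asarray(bundle.flow, dtype=float)
    dt = 1.0 / bundle.fs
    above = flow > min_insp_flow
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if onsets.size == 0:
        warnings.warn("no breath detected", stacklevel=2)
        return []

    starts = []
    for i in onsets:
        j = i
        while j > 0 and flow[j - 1] > 0:
            j -= 1
        starts.append(j)
    # de-duplicate onsets that walked back to the same start
    starts = sorted(set(starts))

    breaths: list[BreathRecord] = []
    for k, s in enumerate(starts):
        e = starts[k + 1] if k + 1 < len(starts) else flow.size
        # inspiratory run: contiguous positive flow from the start
        i1 = s
        while i1 < e and flow[i1] > 0:
            i1 += 1
        lo = max(s - 1, 0)
        tv = float(np.trapezoid(np.clip(flow[lo : min(i1 + 1, e)], 0.0, None), dx=dt))
        ppeak = float(np.max(bundle.paw[s:e])) if e > s else np.nan
        breaths.append(BreathRecord(start=s, end=e, tv_ml=tv, ppeak=ppeak))
    return breaths


def detect_pauses(
    breath: BreathRecord,
    bundle: SignalBundle,
    flow_eps: float = FLOW_EPS_DEFAULT,
    min_dur_s: float = MIN_PAUSE_S_DEFAULT,
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Locate the end-inspiratory and end-expiratory occlusion windows.

    Both are runs with |flow| < ``flow_eps`` lasting at least
    ``min_dur_s``: the inspiratory one is the first such run after peak
    volume, the expiratory one the last run ending at the next breath.
    Either may be None when absent.
    """
    flow = np.asarray(bundle.flow[breath.start : breath.end], dtype=float)
    n_min = max(int(round(min_dur_s * bundle.fs)), 1)
    quiet = np.abs(flow) < flow_eps

    # runs of quiet samples
    padded = np.concatenate([[False], quiet, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    runs = [(edges[i], edges[i + 1]) for i in range(0, edges.size, 2)]
    runs = [(a, b) for a, b in runs if b - a >= n_min]
    if not runs:
        return None, None

    from scipy.integrate import cumulative_trapezoid

    vol = cumulative_trapezoid(flow, dx=1.0 / bundle.fs, initial=0.0)
    i_peak = int(np.argmax(vol))

    insp = next(((a, b) for a, b in runs if a >= i_peak), None)
    exp_candidates = [(a, b) for a, b in runs if b >= flow.size - n_min and (insp is None or a > insp[0])]
    exp = exp_candidates[-1] if exp_candidates else None
    if insp is not None and exp is not None and insp == exp:
        exp = None
    off = breath.start
    return (
        (insp[0] + off, insp[1] + off) if insp else None,
        (exp[0] + off, exp[1] + off) if exp else None,
    )


def _pause_pressure(series: np.ndarray, window: tuple[int, int]) -> float:
    """Median of the final half of a pause window."""
    a, b = window
    mid = a + (b - a) // 2
    return float(np.median(series[mid:b]))


def annotate_breath(
    breath: BreathRecord,
    bundle: SignalBundle,
    flow_eps: float = FLOW_EPS_DEFAULT,
    min_dur_s: float = MIN_PAUSE_S_DEFAULT,
) -> BreathRecord:
    """Fill a breath's pause windows and landmark pressures in place."""
    insp, exp = detect_pauses(breath, bundle, flow_eps=flow_eps, min_dur_s=min_dur_s)
    breath.insp_window = insp
    breath.exp_window = exp
    if insp is None or exp is None:
        breath.usable = False
        breath.flags.append("missing inspiratory pause" if insp is None else "missing expiratory pause")
        return breath
    breath.pplat = _pause_pressure(bundle.paw, insp)
    breath.peep_tot = _pause_pressure(bundle.paw, exp)
    breath.peso_insp = _pause_pressure(bundle.peso, insp)
    breath.peso_exp = _pause_pressure(bundle.peso, exp)
    if not (breath.ppeak >= breath.pplat >= breath.peep_tot):
        breath.flags.append("pressure ordering ppeak >= pplat >= peep_tot violated")
    breath.usable = breath.tv_ml > 0
    return breath


def summarize_mechanics(
    breaths: list[BreathRecord],
    with_peso: bool = True,
    n_breaths: int = 10,
    per_breath: bool = False,
) -> MechanicsSummary:
    """Apply the mechanics formulas to the averaged breath landmarks.

    Averages the per-breath landmark pressures and volumes over the
    last ``n_breaths`` usable breaths, then applies the formulas to the
    averages (``per_breath=True`` instead computes per-breath mechanics
    and averages those — a second-order difference).
    """
    usable = [b for b in breaths if b.usable]
    if not usable:
        raise ValueError("no usable breath (all lacked pauses or tidal volume)")
    used = usable[-n_breaths:]

    def avg(attr: str) -> float:
        return float(np.mean([getattr(b, attr) for b in used]))

    if per_breath and len(used) > 1:
        parts = [summarize_mechanics([b], with_peso=with_peso, n_breaths=1) for b in used]
        mean = lambda f: float(np.mean([getattr(p, f) for p in parts]))  # noqa: E731
        peso_fields = (
            {f: mean(f) for f in ("pl_insp", "pl_exp", "dpl", "el", "ecw", "pi")}
            if with_peso
            else {}
        )
        return MechanicsSummary(
            tv_ml=mean("tv_ml"), ppeak=mean("ppeak"), pplat=mean("pplat"),
            peep_tot=mean("peep_tot"), dp=mean("dp"), ers=mean("ers"),
            n_breaths_used=len(used), **peso_fields,
        )

    tv, pplat, peep = avg("tv_ml"), avg("pplat"), avg("peep_tot")
    dp = pplat - peep
    ers = dp / (tv / 1000.0)
    if ers <= 0:
        raise ValueError(f"non-physiologic Ers = {ers:.2f} cmH2O/L (dp={dp:.2f})")
    fields = dict(
        tv_ml=tv, ppeak=avg("ppeak"), pplat=pplat, peep_tot=peep,
        dp=dp, ers=ers, n_breaths_used=len(used),
    )
    if with_peso:
        if any(np.isnan(b.peso_insp) or np.isnan(b.peso_exp) for b in used):
            raise ValueError("esophageal landmarks missing but with_peso requested")
        pl_insp = pplat - avg("peso_insp")
        pl_exp = peep - avg("peso_exp")  # may be negative; not clamped
        dpl = pl_insp - pl_exp
        el = dpl / (tv / 1000.0)
        fields.update(
            pl_insp=pl_insp, pl_exp=pl_exp, dpl=dpl, el=el,
            ecw=ers - el, pi=pplat * el / ers,
        )
    return MechanicsSummary(**fields)


def analyze_bundle(
    bundle: SignalBundle,
    with_peso: bool = True,
    min_insp_flow: float = MIN_INSP_FLOW_DEFAULT,
    flow_eps: float = FLOW_EPS_DEFAULT,
    min_dur_s: float = MIN_PAUSE_S_DEFAULT,
    n_breaths: int = 10,
) -> tuple[MechanicsSummary, list[BreathRecord]]:
    """Full chain: segment, locate pauses, summarize one measurement."""
    breaths = segment_breaths(bundle, min_insp_flow=min_insp_flow)
    for b in breaths:
        annotate_breath(b, bundle, flow_eps=flow_eps, min_dur_s=min_dur_s)
    summary = summarize_mechanics(breaths, with_peso=with_peso, n_breaths=n_breaths)
    return summary, breaths


@dataclass(frozen=True)
class OcclusionResult:
    """Baydur occlusion-test outcome: ΔPeso/ΔPaw and its validity."""

    ratio: float
    valid: bool
    dpeso: float
    dpaw: float


def occlusion_test(
    paw: np.ndarray, peso: np.ndarray, min_swing: float = 0.5
) -> OcclusionResult:
    """Esophageal-balloon position check during an airway occlusion.

    With the airway occluded, inspiratory-effort oscillations must move
    Paw and Peso equally; the peak-to-trough ratio ΔPeso/ΔPaw should
    fall in [0.8, 1.2] for a valid balloon position.
    """
    paw = np.asarray(paw, dtype=float)
    peso = np.asarray(peso, dtype=float)
    dpaw = float(np.max(paw) - np.min(paw))
    dpeso = float(np.max(peso) - np.min(peso))
    if dpaw < min_swing or dpeso < min_swing:
        raise ValueError("no oscillation detected in the occlusion segment")
    ratio = dpeso / dpaw
    return OcclusionResult(ratio=ratio, valid=0.8 <= ratio <= 1.2, dpeso=dpeso, dpaw=dpaw)
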