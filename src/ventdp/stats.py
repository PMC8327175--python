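"""Agreement statistics for repeated-measures method comparison.

Implements, from first principles, the three statistical tools used to
compare the EIT-derived and esophageal-derived quantities:

* repeated-measures correlation (rmcorr) — the common within-subject
  association, estimated by ANCOVA with subject intercepts and a shared
  slope; equivalently the Pearson correlation of the within-subject
  centered pairs, with df = n_obs - n_subjects - 1;
* Bland-Altman bias and limits of agreement, here bias ± 2 sd of the
  paired differences (the multiplier is configurable);
* simple OLS regression with R² and the slope t-test p-value.

All functions honor listwise deletion of incomplete pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RmcorrResult",
    "BlandAltman",
    "rmcorr",
    "bland_altman",
    "linreg_r2",
    "agreement_report",
    "make_agreement_plots",
]


@dataclass(frozen=True)
class RmcorrResult:
    """Repeated-measures correlation outcome."""

    r: float
    df: int
    p: float
    n_subjects: int
    n_obs: int


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement between two paired methods."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def rmcorr(subjects, x, y) -> RmcorrResult:
    """Common within-subject correlation across repeated measures.

    Centers each subject's (x, y) pairs on the subject means and
    correlates the pooled deviations; the sign follows the common
    ANCOVA slope.  Subjects with fewer than 2 complete pairs are
    excluded with a warning; the p-value is two-sided from the t
    distribution with df = n_obs - n_subjects - 1.
    """
    df_in = pd.DataFrame({"s": np.asarray(subjects), "x": np.asarray(x, dtype=float),
                          "y": np.asarray(y, dtype=float)}).dropna()
    counts = df_in.groupby("s")["x"].count()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(
            f"excluding {len(small)} subject(s) with fewer than 2 complete pairs",
            stacklevel=2,
        )
        df_in = df_in[~df_in["s"].isin(small)]
    n_subj = df_in["s"].nunique()
    if n_subj < 2:
        raise ValueError("rmcorr needs at least 2 subjects with >= 2 complete pairs")

    g = df_in.groupby("s")
    xc = df_in["x"] - g["x"].transform("mean")
    yc = df_in["y"] - g["y"].transform("mean")
    sxx = float((xc**2).sum())
    syy = float((yc**2).sum())
    if sxx == 0 or syy == 0:
        raise ValueError("no within-subject variance in x or y")
    r = float((xc * yc).sum() / np.sqrt(sxx * syy))
    r = float(np.clip(r, -1.0, 1.0))
    n_obs = len(df_in)
    dof = n_obs - n_subj - 1
    if dof < 1:
        raise ValueError("not enough observations for rmcorr degrees of freedom")
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), dof))
    return RmcorrResult(r=r, df=dof, p=p, n_subjects=int(n_subj), n_obs=int(n_obs))


def bland_altman(a, b, multiplier: float = 2.0) -> BlandAltman:
    """Bland-Altman agreement of paired measurements (d = a - b).

    Bias is mean(d); the limits of agreement are bias ± multiplier x
    sample sd (n-1 denominator), multiplier 2 by default.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    d = a[mask] - b[mask]
    if d.size < 2:
        raise ValueError("Bland-Altman needs at least 2 complete pairs")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias, sd_diff=sd,
        loa_low=bias - multiplier * sd, loa_high=bias + multiplier * sd,
        n=int(d.size),
    )


def linreg_r2(x, y) -> tuple[float, float, float, float]:
    """Simple OLS regression: (slope, intercept, R², p of the slope)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("regression needs at least 3 complete pairs")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


DEFAULT_PAIRS = {
    "dpl": ("dpl", "dpl_eit"),
    "el": ("el", "el_eit"),
    "pi": ("pi", "pi_eit"),
}


def agreement_report(
    cohort: pd.DataFrame,
    pairs: dict[str, tuple[str, str]] | None = None,
    subject_col: str = "patient_id",
    loa_multiplier: float = 2.0,
) -> dict:
    """EIT-vs-esophageal agreement for each quantity in ``pairs``.

    For every (measured, predicted) column pair: simple regression of
    predicted on measured, Bland-Altman of predicted - measured, and
    the repeated-measures correlation.  Rows with ``quality_ok`` False
    are excluded, mirroring per-measurement quality control.
    """
    pairs = pairs or DEFAULT_PAIRS
    df = cohort
    if "quality_ok" in df.columns:
        df = df[df["quality_ok"].astype(bool)]
    report: dict = {"n_rows": int(len(df)), "n_subjects": int(df[subject_col].nunique())}
    for name, (meas, pred) in pairs.items():
        slope, intercept, r2, p = linreg_r2(df[meas], df[pred])
        ba = bland_altman(df[pred], df[meas], multiplier=loa_multiplier)
        rm = rmcorr(df[subject_col], df[meas], df[pred])
        report[name] = {
            "regression": {"slope": slope, "intercept": intercept, "r2": r2, "p": p},
            "bland_altman": {
                "bias": ba.bias, "sd_diff": ba.sd_diff,
                "loa_low": ba.loa_low, "loa_high": ba.loa_high, "n": ba.n,
            },
            "rmcorr": {"r": rm.r, "df": rm.df, "p": rm.p,
                       "n_subjects": rm.n_subjects, "n_obs": rm.n_obs},
        }
    return report


def make_agreement_plots(cohort: pd.DataFrame, outdir, pairs=None) -> list:
    """Scatter + Bland-Altman plot per quantity; returns written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    pairs = pairs or DEFAULT_PAIRS
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = cohort
    if "quality_ok" in df.columns:
        df = df[df["quality_ok"].astype(bool)]
    written = []
    for name, (meas, pred) in pairs.items():
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        slope, intercept, r2, _ = linreg_r2(df[meas], df[pred])
        ax1.scatter(df[meas], df[pred], s=14, alpha=0.7)
        xs = np.linspace(df[meas].min(), df[meas].max(), 50)
        ax1.plot(xs, intercept + slope * xs, "k-", lw=1)
        ax1.set_xlabel(f"measured {name}")
        ax1.set_ylabel(f"EIT-derived {name}")
        ax1.set_title(f"R² = {r2:.2f}")
        ba = bland_altman(df[pred], df[meas])
        mean = (df[pred] + df[meas]) / 2.0
        ax2.scatter(mean, df[pred] - df[meas], s=14, alpha=0.7)
        for yv, style in ((ba.bias, "k-"), (ba.loa_low, "k--"), (ba.loa_high, "k--")):
            ax2.axhline(yv, ls=style[1:], color="k", lw=1)
        ax2.set_xlabel(f"mean {name}")
        ax2.set_ylabel("EIT - measured")
        ax2.set_title(f"bias {ba.bias:.2f}, LoA [{ba.loa_low:.2f}, {ba.loa_high:.2f}]")
        fig.tight_layout()
        path = outdir / f"agreement_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
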