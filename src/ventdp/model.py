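"""Non-invasive transpulmonary driving-pressure prediction.

The core model is a five-regressor linear equation predicting the
esophageal-referenced transpulmonary driving pressure from quantities
available without an esophageal balloon:

    DP_L,EIT = k + alpha*IBW + beta*Ers + gamma*roi1% + delta*roi2% + eps*roi3%

with IBW in kg, Ers in cmH2O/L and the regional tidal-ventilation
percentages on the 0-100 scale (ROI4 is intentionally absent: the three
ventral/central fractions plus the constraint that all four sum to 100
carry the regional information).  From the prediction, lung elastance
and the elastance-derived inspiratory transpulmonary pressure follow:

    EL_EIT = DP_L,EIT / TV            [cmH2O/L, TV in L]
    PI_EIT = Pplat * (EL_EIT / Ers)   [cmH2O]

The estimator is scikit-learn compatible (``fit``/``predict``/
``get_params``) so it composes with sklearn pipelines and model
selection; ``fit`` is pooled ordinary least squares on the stacked
patient x condition rows (panel identity kept as metadata), with a
fixed-effects within-estimator variant for sensitivity analysis.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "PUBLISHED_COEFFICIENTS",
    "FEATURES",
    "DrivingPressureRegressor",
    "predict_dpl",
    "fit_model",
    "derive_el_eit",
    "derive_pi_eit",
]

#: Reference coefficients at full printed precision (never rounded).
PUBLISHED_COEFFICIENTS = {
    "k": 16.64,
    "alpha": 0.074683,
    "beta": 0.230941,
    "gamma": -0.21449,
    "delta": -0.15974,
    "eps": -0.32996,
}

#: covariate order expected by the estimator
FEATURES = ("ibw_kg", "ers", "roi1_pct", "roi2_pct", "roi3_pct")

ERS_RANGE = (5.0, 80.0)


class DrivingPressureRegressor(RegressorMixin, BaseEstimator):
    """Linear DP_L predictor from IBW, Ers and regional ventilation.

    Parameters
    ----------
    coefficients : {"published", None}
        ``"published"`` loads the reference coefficients (no fitting
        needed); ``None`` requires :meth:`fit`.
    method : {"pooled", "within"}
        ``"pooled"`` is plain OLS with intercept on the stacked rows;
        ``"within"`` demeans by subject first (fixed-effects
        within-estimator, intercept recovered from grand means).

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (5,)
        Coefficients in :data:`FEATURES` order.
    r2_ : float
    fitted_on_ : {"published", "refit"}
    """

    def __init__(self, coefficients: str | None = None, method: str = "pooled"):
        self.coefficients = coefficients
        self.method = method

    # -- sklearn plumbing ------------------------------------------------
    def _validate_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in FEATURES if c not in X.columns]
            if missing:
                raise ValueError(f"missing covariate column(s): {', '.join(missing)}")
            X = X.loc[:, list(FEATURES)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURES):
            raise ValueError(f"X must have {len(FEATURES)} columns in order {FEATURES}")
        if np.isnan(X).any():
            bad = [FEATURES[j] for j in np.unique(np.argwhere(np.isnan(X))[:, 1])]
            raise ValueError(f"missing covariate value(s) in: {', '.join(bad)}")
        return X

    def fit(self, X, y, groups=None):
        """Fit pooled (or within) OLS of measured DP_L on the covariates.

        ``groups`` is the patient identifier per row; required for
        ``method="within"``, kept as metadata otherwise.
        """
        import statsmodels.api as sm

        if self.method not in ("pooled", "within"):
            raise ValueError(f"unknown method {self.method!r}")
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y lengths differ")

        design = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            redundant = [
                FEATURES[j]
                for j in range(len(FEATURES))
                if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
            ]
            raise ValueError(
                "rank-deficient design; collinear column(s): " + ", ".join(redundant)
            )

        if self.method == "within":
            if groups is None:
                raise ValueError('method="within" requires groups')
            g = pd.Series(np.asarray(groups))
            Xw = X - pd.DataFrame(X).groupby(g.values).transform("mean").to_numpy()
            yw = y - pd.Series(y).groupby(g.values).transform("mean").to_numpy()
            res = sm.OLS(yw, Xw).fit()
            self.coef_ = np.asarray(res.params, dtype=float)
            self.intercept_ = float(y.mean() - X.mean(axis=0) @ self.coef_)
        else:
            res = sm.OLS(y, design).fit()
            self.coef_ = np.asarray(res.params[1:], dtype=float)
            self.intercept_ = float(res.params[0])

        fitted = self.intercept_ + X @ self.coef_
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 0.0 if ss_tot == 0 else 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot
        self.results_ = res
        self.groups_ = None if groups is None else np.asarray(groups)
        self.n_obs_ = int(y.size)
        self.fitted_on_ = "refit"
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X)
        if np.any((X[:, 1] < ERS_RANGE[0]) | (X[:, 1] > ERS_RANGE[1])):
            warnings.warn("Ers outside the physiologic range [5, 80] cmH2O/L", stacklevel=2)
        roi = X[:, 2:]
        if np.any((roi < 0) | (roi > 100)):
            warnings.warn("roi% outside [0, 100]", stacklevel=2)
        out = self.intercept_ + X @ self.coef_
        if np.any(out < 0):
            warnings.warn("negative predicted DP_L (non-physiologic extrapolation)", stacklevel=2)
        return out

    def _check_fitted(self) -> None:
        if hasattr(self, "coef_"):
            return
        if self.coefficients == "published":
            c = PUBLISHED_COEFFICIENTS
            self.intercept_ = c["k"]
            self.coef_ = np.array([c["alpha"], c["beta"], c["gamma"], c["delta"], c["eps"]])
            self.fitted_on_ = "published"
            self.r2_ = np.nan
        else:
            raise ValueError("estimator is not fitted; call fit() or use coefficients='published'")

    # -- convenience -----------------------------------------------------
    @classmethod
    def published(cls) -> "DrivingPressureRegressor":
        """The reference model with the printed coefficients loaded."""
        est = cls(coefficients="published")
        est._check_fitted()
        return est

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "intercept": self.intercept_,
            "coef": dict(zip(FEATURES, (float(c) for c in self.coef_))),
            "r2": None if np.isnan(getattr(self, "r2_", np.nan)) else float(self.r2_),
            "fitted_on": self.fitted_on_,
            "n_obs": getattr(self, "n_obs_", None),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "DrivingPressureRegressor":
        with open(path) as fh:
            d = json.load(fh)
        est = cls()
        est.intercept_ = float(d["intercept"])
        est.coef_ = np.array([d["coef"][f] for f in FEATURES], dtype=float)
        est.r2_ = np.nan if d.get("r2") is None else float(d["r2"])
        est.fitted_on_ = d.get("fitted_on", "refit")
        return est


def predict_dpl(
    model: DrivingPressureRegressor | None,
    ibw_kg: float,
    ers: float,
    roi1_pct: float,
    roi2_pct: float,
    roi3_pct: float,
) -> float:
    """Evaluate the DP_L prediction for one measurement (cmH2O).

    ``model=None`` uses the published coefficients.
    """
    for name, val in (("ibw_kg", ibw_kg), ("ers", ers), ("roi1_pct", roi1_pct),
                      ("roi2_pct", roi2_pct), ("roi3_pct", roi3_pct)):
        if val is None or (np.isscalar(val) and np.isnan(val)):
            raise ValueError(f"missing covariate: {name}")
    model = model or DrivingPressureRegressor.published()
    return float(model.predict(np.array([[ibw_kg, ers, roi1_pct, roi2_pct, roi3_pct]]))[0])


def fit_model(cohort: pd.DataFrame, method: str = "pooled") -> DrivingPressureRegressor:
    """Refit the five-regressor model on a measurement panel.

    ``cohort`` needs the :data:`FEATURES` columns, a measured ``dpl``
    and a ``patient_id``; rows with ``quality_ok == False`` are dropped.
    """
    df = cohort
    if "quality_ok" in df.columns:
        df = df[df["quality_ok"].astype(bool)]
    if len(df) < 10:
        raise ValueError("cohort must contain at least 10 usable rows")
    if df["patient_id"].nunique() < 2:
        raise ValueError("cohort must contain at least 2 patients")
    est = DrivingPressureRegressor(method=method)
    return est.fit(df, df["dpl"].to_numpy(dtype=float), groups=df["patient_id"].to_numpy())


def derive_el_eit(dpl_eit: float, tv_ml: float) -> float:
    """EIT-derived lung elastance, cmH2O/L: DP_L,EIT over TV in liters."""
    if tv_ml <= 0:
        raise ValueError("tv_ml must be positive")
    return dpl_eit / (tv_ml / 1000.0)


def derive_pi_eit(pplat: float, ers: float, el_eit: float) -> float:
    """EIT-derived elastance-based inspiratory transpulmonary pressure.

    PI_EIT = Pplat - Pplat*(Ers - EL_EIT)/Ers = Pplat * EL_EIT / Ers.
    """
    if ers <= 0:
        raise ValueError("ers must be positive")
    if el_eit > ers:
        warnings.warn("EL_EIT exceeds Ers: PI_EIT exceeds Pplat", stacklevel=2)
    return pplat * el_eit / ers
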