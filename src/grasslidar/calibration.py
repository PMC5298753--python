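"""Regression calibration of lidar canopy metrics against field quadrats.

Model families follow the study design: linear, logarithmic (y = a + b ln x),
power (y = a x^b) and exponential (y = a e^{bx}) single-predictor models plus
ordinary two-predictor multiple linear regression.  R^2 is reported on the
training sample (original scale for all families); RMSE on the held-out test
sample; rRMSE as a percentage of the maximum observed response.  Nonlinear
families are fitted by Levenberg-Marquardt least squares started from their
log-linearized OLS estimates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy import stats

FAMILIES = ("linear", "logarithmic", "power", "exponential", "multiple-linear")


@dataclass
class QuadratRecord:
    """One field sample: centre, canopy heights (cm), cover (%), biomass."""

    id: int
    x: float
    y: float
    field_mean_h_cm: float
    field_max_h_cm: float
    field_min_h_cm: float
    field_cover_pct: float
    field_biomass: float

    def __post_init__(self):
        if not 0 <= self.field_cover_pct <= 100:
            raise ValueError("cover must be within [0, 100] %")
        if self.field_biomass < 0:
            raise ValueError("biomass must be non-negative")
        for h in (self.field_mean_h_cm, self.field_max_h_cm,
                  self.field_min_h_cm):
            if h < 0:
                raise ValueError("heights must be non-negative")


@dataclass
class RegressionModel:
    """A fitted model family with its training/test scores."""

    family: str
    coefficients: tuple
    r_squared: float
    rmse: float | None = None
    rrmse: float | None = None
    p_value: float | None = None
    n_train: int = 0
    n_test: int = 0
    response: str = ""
    predictors: tuple = ()

    def predict(self, x, x2=None):
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c[0] * x + c[1]
        if self.family == "logarithmic":
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(x > 0, c[0] + c[1] * np.log(
                    np.where(x > 0, x, 1.0)), np.nan)
        if self.family == "power":
            with np.errstate(invalid="ignore"):
                return np.where(x > 0, c[0] * np.where(x > 0, x, 1.0) ** c[1],
                                np.nan)
        if self.family == "exponential":
            return c[0] * np.exp(c[1] * x)
        if self.family == "multiple-linear":
            if x2 is None:
                raise ValueError("multiple-linear model needs two predictors")
            return c[0] * x + c[1] * np.asarray(x2, float) + c[2]
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coefficients"] = list(self.coefficients)
        d["predictors"] = list(self.predictors)
        return d


def train_test_split(records, n_train: int = 66, seed: int = 0):
    """Disjoint, exhaustive, seed-reproducible split (66/24 by default)."""
    if isinstance(records, pd.DataFrame):
        n = len(records)
    else:
        records = list(records)
        n = len(records)
    if n_train >= n:
        raise ValueError(f"n_train={n_train} must be < number of records {n}")
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if isinstance(records, pd.DataFrame):
        return records.iloc[tr], records.iloc[te]
    return [records[i] for i in tr], [records[i] for i in te]


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return 0.0
    return max(0.0, 1.0 - float(np.sum((y - yhat) ** 2)) / sst)


def _f_pvalue(y: np.ndarray, yhat: np.ndarray, n_params: int) -> float:
    """p-value of the regression F statistic (model vs intercept-only)."""
    n = y.size
    k = n_params - 1  # slope-like parameters
    if k < 1 or n - n_params <= 0:
        return float("nan")
    ssr = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if ssr <= 0:
        return 0.0
    f = ((sst - ssr) / k) / (ssr / (n - n_params))
    return float(stats.f.sf(f, k, n - n_params))


def fit_model(x, y, family: str) -> RegressionModel:
    """Least-squares fit of one single-predictor family.

    Power and exponential models are solved by nonlinear least squares with
    log-linearized start values; domain violations (x <= 0 for log/power,
    y <= 0 for power/exponential starts) raise naming the family.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"{family}: need at least 3 finite pairs")

    if family == "linear":
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        coef = (float(res.params[1]), float(res.params[0]))
        yhat = coef[0] * x + coef[1]
    elif family == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic: requires x > 0")
        X = sm.add_constant(np.log(x))
        res = sm.OLS(y, X).fit()
        coef = (float(res.params[0]), float(res.params[1]))
        yhat = coef[0] + coef[1] * np.log(x)
    elif family == "power":
        if np.any(x <= 0):
            raise ValueError("power: requires x > 0")
        if np.any(y <= 0):
            raise ValueError("power: requires y > 0 for fitting")
        b0, a0 = np.polyfit(np.log(x), np.log(y), 1)
        popt, _ = curve_fit(lambda t, a, b: a * t ** b, x, y,
                            p0=[np.exp(a0), b0], maxfev=10_000,
                            xtol=1e-10, ftol=1e-10)
        coef = (float(popt[0]), float(popt[1]))
        yhat = coef[0] * x ** coef[1]
    elif family == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential: requires y > 0 for fitting")
        b0, a0 = np.polyfit(x, np.log(y), 1)
        popt, _ = curve_fit(lambda t, a, b: a * np.exp(b * t), x, y,
                            p0=[np.exp(a0), b0], maxfev=10_000,
                            xtol=1e-10, ftol=1e-10)
        coef = (float(popt[0]), float(popt[1]))
        yhat = coef[0] * np.exp(coef[1] * x)
    else:
        raise ValueError(f"unknown family {family!r}")

    return RegressionModel(family=family, coefficients=coef,
                           r_squared=_r2(y, yhat),
                           p_value=_f_pvalue(y, yhat, 2), n_train=x.size)


def fit_multiple(x1, x2, y) -> RegressionModel:
    """Two-predictor ordinary least squares: y = c1 x1 + c2 x2 + c0.

    Emits a warning when the predictors are nearly collinear (|r| > 0.99).
    """
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x1) & np.isfinite(x2) & np.isfinite(y)
    x1, x2, y = x1[ok], x2[ok], y[ok]
    if x1.size < 4:
        raise ValueError("multiple-linear: need at least 4 finite triples")
    if np.std(x1) > 0 and np.std(x2) > 0:
        r = float(np.corrcoef(x1, x2)[0, 1])
        if abs(r) > 0.99:
            warnings.warn(
                f"predictors nearly collinear (r = {r:.4f}); the normal "
                f"equations are near-singular and coefficients unstable")
    X = sm.add_constant(np.column_stack([x1, x2]))
    res = sm.OLS(y, X).fit()
    coef = (float(res.params[1]), float(res.params[2]), float(res.params[0]))
    yhat = coef[0] * x1 + coef[1] * x2 + coef[2]
    return RegressionModel(family="multiple-linear", coefficients=coef,
                           r_squared=_r2(y, yhat),
                           p_value=_f_pvalue(y, yhat, 3), n_train=x1.size)


def rmse(y, yhat) -> float:
    """Root-mean-square error, same units as y."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size != yhat.size:
        raise ValueError("rmse: length mismatch")
    if y.size == 0:
        raise ValueError("rmse: empty vectors")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rrmse(rmse_value: float, y_max: float) -> float:
    """Relative RMSE: percentage of the maximum observed response."""
    if y_max <= 0:
        raise ValueError("rrmse: y_max must be positive")
    return 100.0 * rmse_value / y_max


def score_on_test(model: RegressionModel, x_test, y_test, y_max: float,
                  x2_test=None) -> RegressionModel:
    """Attach test RMSE / rRMSE (y_max is the full-sample maximum response)."""
    y_test = np.asarray(y_test, dtype=float)
    yhat = np.asarray(model.predict(x_test, x2_test), dtype=float)
    ok = np.isfinite(yhat) & np.isfinite(y_test)
    if not ok.all():
        warnings.warn(f"{model.family}: {int((~ok).sum())} test samples "
                      f"outside the model domain excluded from RMSE")
    model.rmse = rmse(y_test[ok], yhat[ok])
    model.rrmse = rrmse(model.rmse, y_max)
    model.n_test = int(ok.sum())
    return model


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r; zero-variance columns yield NaN with a warning."""
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlations")
    zero_var = [c for c in table.columns if np.nanstd(table[c].values) == 0]
    if zero_var:
        warnings.warn(f"zero-variance columns yield undefined r: {zero_var}")
    return table.corr(method="pearson")


def select_best(models: list[RegressionModel]) -> tuple[RegressionModel, pd.DataFrame]:
    """Pick the winner: lowest test RMSE, ties to higher R^2, then fewer
    parameters.  Returns (winner, leaderboard)."""
    if not models:
        raise ValueError("no candidate models")
    key = lambda m: (np.inf if m.rmse is None else m.rmse,
                     -m.r_squared, m.n_params)
    ranked = sorted(models, key=key)
    board = pd.DataFrame([{
        "rank": i + 1, "family": m.family, "response": m.response,
        "predictors": "+".join(m.predictors),
        "r_squared": m.r_squared, "rmse": m.rmse, "rrmse": m.rrmse,
        "p_value": m.p_value, "n_params": m.n_params,
    } for i, m in enumerate(ranked)])
    return ranked[0], board


def save_models(models: list[RegressionModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=1)


def load_models(path) -> list[RegressionModel]:
    with open(path) as fh:
        raw = json.load(fh)
    out = []
    for d in raw:
        d["coefficients"] = tuple(d["coefficients"])
        d["predictors"] = tuple(d["predictors"])
        out.append(RegressionModel(**d))
    return out
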