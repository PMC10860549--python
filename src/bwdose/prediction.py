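"""Model application: point predictions, prediction intervals, plan
verdicts, and accuracy metrics.

Two model flavors exist.  Published models (the shipped registry of 27
coefficient equations, nine endpoints for each of the combined, rectal and
gynecologic cohorts) carry coefficients only, so they support point
predictions but not intervals — the sufficient statistics ((X'X)^-1 and the
residual mean square) are not recoverable from coefficients, and the
package never fabricates them.  Models fitted in-package carry those
statistics and support both interval types:

    mean response:        yhat_h +- t(1-a/2, n-p) sqrt(s2 x_h'(X'X)^-1 x_h)
    individual response:  yhat_h +- t(1-a/2, n-p) sqrt(s2 + s2 x_h'(X'X)^-1 x_h)

A plan endpoint is acceptable when the actually calculated value is at or
below the upper limit of the 95% CI of the mean prediction; above it, the
plan is flagged for re-optimization.  MPE is the *signed* mean percentage
error, 100/n sum (A_i - P_i)/A_i, exactly as defined — not the mean
absolute percentage error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats

from .dosimetry import DoseEndpoints
from .geometry import SpatialFeatureVector
from .regression import FittedModel

__all__ = [
    "PublishedModel",
    "PredictionResult",
    "PlanVerdict",
    "EndpointVerdict",
    "AccuracyReport",
    "registry",
    "cohort_summaries",
    "predict_point",
    "ci_mean",
    "ci_individual",
    "evaluate_plan",
    "rmse",
    "mpe",
    "accuracy",
]

COHORTS = ("combined", "rectal", "gynecologic")


@dataclass(frozen=True)
class PublishedModel:
    """A shipped regression equation: coefficients only, no interval stats."""

    cohort: str
    endpoint: str
    terms: dict[str, float]
    intercept: float
    r2: float
    adjusted_r2: float

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "endpoint": self.endpoint,
            "terms": dict(self.terms),
            "intercept": self.intercept,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PublishedModel":
        return cls(
            cohort=d["cohort"], endpoint=d["endpoint"], terms=dict(d["terms"]),
            intercept=float(d["intercept"]), r2=float(d["r2"]),
            adjusted_r2=float(d["adjusted_r2"]),
        )


def _load_resource(name: str) -> dict:
    with resources.files("bwdose.data").joinpath(name).open() as f:
        return json.load(f)


def registry() -> list[PublishedModel]:
    """The 27 shipped models (9 endpoints x combined/rectal/gynecologic)."""
    raw = _load_resource("published_models.json")
    return [PublishedModel.from_dict(d) for d in raw["models"]]


def registry_model(cohort: str, endpoint: str) -> PublishedModel:
    for m in registry():
        if m.cohort == cohort and m.endpoint == endpoint:
            return m
    raise KeyError(f"no published model for cohort={cohort!r}, endpoint={endpoint!r}")


def cohort_summaries() -> dict:
    """Shipped cohort summary statistics (predictor and endpoint
    distributions for the combined, rectal and gynecologic cohorts)."""
    return _load_resource("cohort_summaries.json")


def _feature_dict(features) -> dict[str, float]:
    if isinstance(features, SpatialFeatureVector):
        return features.as_columns()
    return dict(features)


def predict_point(model: PublishedModel | FittedModel, features) -> float:
    """Intercept + sum(coefficient x feature); errors name any missing
    predictor."""
    feats = _feature_dict(features)
    if isinstance(model, FittedModel):
        terms, intercept = model.coefficients, model.intercept
    else:
        terms, intercept = model.terms, model.intercept
    missing = [k for k in terms if k not in feats]
    if missing:
        raise KeyError(f"features missing required predictors: {missing}")
    return float(intercept + sum(c * float(feats[k]) for k, c in terms.items()))


@dataclass
class PredictionResult:
    point: float
    ci_mean: tuple[float, float] | None
    ci_individual: tuple[float, float] | None
    alpha: float
    x_h: np.ndarray | None = None


def _interval(model: FittedModel, features, alpha: float, individual: bool):
    if not isinstance(model, FittedModel):
        raise TypeError(
            "prediction intervals require a model fitted in-package; published "
            "registry models carry coefficients only"
        )
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    x_h = model.design_row(_feature_dict(features))
    point = float(x_h @ model.beta)
    leverage = float(x_h @ model.xtx_inverse @ x_h)
    var = model.s2 * leverage + (model.s2 if individual else 0.0)
    t_crit = stats.t.ppf(1 - alpha / 2, model.n - model.p)
    half = t_crit * np.sqrt(var)
    return point, (point - half, point + half), x_h


def ci_mean(model: FittedModel, features, alpha: float = 0.05) -> PredictionResult:
    """CI of the mean predicted value at the given feature vector."""
    point, ci, x_h = _interval(model, features, alpha, individual=False)
    return PredictionResult(point=point, ci_mean=ci, ci_individual=None,
                            alpha=alpha, x_h=x_h)


def ci_individual(model: FittedModel, features, alpha: float = 0.05) -> PredictionResult:
    """CI of an individual predicted value (adds the residual variance)."""
    point, ci, x_h = _interval(model, features, alpha, individual=True)
    return PredictionResult(point=point, ci_mean=None, ci_individual=ci,
                            alpha=alpha, x_h=x_h)


def predict(model: FittedModel, features, alpha: float = 0.05) -> PredictionResult:
    """Point prediction with both interval types."""
    point, mean_ci, x_h = _interval(model, features, alpha, individual=False)
    _, ind_ci, _ = _interval(model, features, alpha, individual=True)
    return PredictionResult(point=point, ci_mean=mean_ci, ci_individual=ind_ci,
                            alpha=alpha, x_h=x_h)


@dataclass
class EndpointVerdict:
    endpoint: str
    actual: float
    predicted: float
    upper_limit: float
    acceptable: bool


@dataclass
class PlanVerdict:
    """Per-endpoint acceptability of one plan; ``needs_reoptimization`` is
    True iff any endpoint exceeds its mean-CI upper limit."""

    endpoints: list[EndpointVerdict] = field(default_factory=list)

    @property
    def needs_reoptimization(self) -> bool:
        return any(not e.acceptable for e in self.endpoints)

    @property
    def flagged(self) -> list[str]:
        return [e.endpoint for e in self.endpoints if not e.acceptable]


def evaluate_plan(
    actual: DoseEndpoints,
    models: dict[str, FittedModel],
    features,
    alpha: float = 0.05,
) -> PlanVerdict:
    """Judge a plan: each endpoint is acceptable iff the actual value is at
    or below the upper limit of the mean-prediction CI (equality passes)."""
    verdict = PlanVerdict()
    actual_cols = {f"V{int(t)}Gy": v for t, v in actual.v_gy_cc.items()}
    actual_cols["Dmean"] = actual.dmean_gy
    for name, model in models.items():
        if name not in actual_cols:
            raise KeyError(f"no actual value for endpoint {name!r}")
        res = ci_mean(model, features, alpha=alpha)
        upper = res.ci_mean[1]
        a = actual_cols[name]
        verdict.endpoints.append(EndpointVerdict(
            endpoint=name, actual=a, predicted=res.point,
            upper_limit=upper, acceptable=a <= upper,
        ))
    return verdict


def rmse(predicted, actual) -> float:
    """Root mean square error between predicted and actual values."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def mpe(predicted, actual) -> float:
    """Signed mean percentage error, 100/n sum (A_i - P_i)/A_i.

    Signed by definition: over- and under-predictions cancel.  Undefined
    when any actual value is zero.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size == 0:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    if (a == 0).any():
        raise ValueError("MPE undefined: some actual values are zero")
    return float(100.0 * np.mean((a - p) / a))


@dataclass
class AccuracyReport:
    rmse: float
    mpe_percent: float
    predicted: list[float]
    actual: list[float]


def accuracy(predicted, actual) -> AccuracyReport:
    return AccuracyReport(
        rmse=rmse(predicted, actual),
        mpe_percent=mpe(predicted, actual),
        predicted=list(map(float, predicted)),
        actual=list(map(float, actual)),
    )
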