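"""Multiple-linear-regression model construction and screening.

Prediction models for each bladder-wall endpoint are built by running three
variable-selection methods (forward, backward, stepwise) over three
candidate predictor pools (all spatial features; wall-overlap features
only; whole-bladder-overlap features only), yielding up to nine candidate
models.  Candidates are screened on the overall F-test, per-coefficient
significance, multicollinearity (VIF < 5), residual normality
(Shapiro-Wilk) and homoscedasticity (Breusch-Pagan); the best screened
model is the one with the largest adjusted R^2.

Selection uses probability-of-F-style entry/removal on coefficient
p-values with the conventional defaults alpha_enter = 0.05,
alpha_remove = 0.10.  Candidates are scanned in a fixed column order and
ties on p-value go to the earlier column, so selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

from .geometry import DEFAULT_MARGINS_CM, margin_column

__all__ = [
    "CohortTable",
    "FittedModel",
    "ScreeningReport",
    "ScreeningThresholds",
    "fit_ols",
    "r_squared",
    "adjusted_r2",
    "stepwise_select",
    "candidate_protocol",
    "screen",
    "select_best",
    "predictor_pools",
]

ALPHA_ENTER = 0.05
ALPHA_REMOVE = 0.10


@dataclass
class CohortTable:
    """One row per plan: spatial features plus dose endpoints.

    ``data`` uses the frozen column schema (Vbw_cc, Vbladder_cc, VPTV_cc,
    Pbw_0 ... Pbw_3, Pb_0 ... Pb_3, V10_cc ... V45_cc, Dmean_gy).
    """

    data: pd.DataFrame
    cohort: str = "combined"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def require_columns(self, names: list[str]) -> None:
        missing = [c for c in names if c not in self.data.columns]
        if missing:
            raise KeyError(f"cohort table is missing columns: {missing}")
        bad = [c for c in names if self.data[c].isna().any()]
        if bad:
            raise ValueError(f"cohort table has missing values in: {bad}")


@dataclass
class ScreeningReport:
    """Diagnostics for one fitted model; ``passed`` is the conjunction."""

    f_pvalue: float
    coef_pvalues: dict[str, float]
    max_vif: float
    normality_pvalue: float | None
    homoscedasticity_pvalue: float | None
    passed: bool
    degenerate: bool = False
    notes: str = ""


@dataclass(frozen=True)
class ScreeningThresholds:
    alpha_f: float = 0.05
    alpha_coef: float = 0.05
    vif_limit: float = 5.0
    alpha_normality: float = 0.05
    alpha_homoscedasticity: float = 0.05


@dataclass
class FittedModel:
    """An OLS fit with the sufficient statistics for prediction intervals.

    ``p`` counts the intercept, so the number of predictors is ``p - 1``.
    ``xtx_inverse`` is (X'X)^-1 for the intercept-augmented design and
    ``s2`` the residual mean square, the two quantities a prediction
    interval needs beyond the coefficients.
    """

    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    intercept: float
    n: int
    p: int
    residual_ss: float
    s2: float
    xtx_inverse: np.ndarray
    r2: float
    adjusted_r2: float
    vif: dict[str, float]
    column_means: dict[str, float] = field(default_factory=dict)
    screening: ScreeningReport | None = None
    provenance: dict = field(default_factory=dict)
    _sm_result: object = field(default=None, repr=False, compare=False)

    @property
    def beta(self) -> np.ndarray:
        """Coefficient vector (intercept first)."""
        return np.array([self.intercept] + [self.coefficients[c] for c in self.predictors])

    def design_row(self, features: dict[str, float]) -> np.ndarray:
        missing = [c for c in self.predictors if c not in features]
        if missing:
            raise KeyError(f"features missing required predictors: {missing}")
        return np.array([1.0] + [float(features[c]) for c in self.predictors])

    def same_equation(self, other: "FittedModel", tol: float = 1e-10) -> bool:
        return (
            self.predictors == other.predictors
            and abs(self.intercept - other.intercept) <= tol
            and all(
                abs(self.coefficients[c] - other.coefficients[c]) <= tol
                for c in self.predictors
            )
        )


def r_squared(observed, fitted) -> float:
    """R^2 = 1 - SS_res / SS_tot; defined as 0 when the response is constant."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(fitted, dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (n-1)/(n-p) (1 - R^2); p counts the intercept."""
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    return 1.0 - (n - 1) / (n - p) * (1.0 - r2)


def _vif(X: pd.DataFrame) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others."""
    if X.shape[1] < 2:
        return {c: 1.0 for c in X.columns}
    out = {}
    for j, col in enumerate(X.columns):
        others = sm.add_constant(X.drop(columns=[col]))
        r2_j = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2_j >= 1 else 1.0 / (1.0 - r2_j)
    return out


def fit_ols(
    table: CohortTable,
    response: str,
    predictors: list[str],
) -> FittedModel:
    """Least-squares fit of ``response`` on ``predictors`` with intercept.

    Raises a singularity error naming the collinear columns when the
    intercept-augmented design is rank deficient.
    """
    predictors = list(predictors)
    table.require_columns([response] + predictors)
    n = table.n
    p = len(predictors) + 1
    if n < p + 1:
        raise ValueError(f"need n >= p + 1 rows (n={n}, p={p})")

    y = table.data[response].to_numpy(dtype=float)
    Xdf = table.data[predictors].astype(float)
    X = np.column_stack([np.ones(n)] + [Xdf[c].to_numpy() for c in predictors])

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns whose removal restores full rank
        collinear = [
            c for i, c in enumerate(predictors)
            if np.linalg.matrix_rank(np.delete(X, i + 1, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {collinear or predictors}"
        )

    res = sm.OLS(y, X).fit()
    resid = y - res.fittedvalues
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    r2 = r_squared(y, res.fittedvalues)

    return FittedModel(
        response=response,
        predictors=predictors,
        coefficients={c: float(b) for c, b in zip(predictors, res.params[1:])},
        intercept=float(res.params[0]),
        n=n,
        p=p,
        residual_ss=rss,
        s2=s2,
        xtx_inverse=np.linalg.inv(X.T @ X),
        r2=r2,
        adjusted_r2=adjusted_r2(r2, n, p) if n > p else 0.0,
        vif=_vif(Xdf),
        column_means={c: float(Xdf[c].mean()) for c in predictors},
        _sm_result=res,
    )


def _coef_pvalues(table: CohortTable, response: str, predictors: list[str]) -> dict[str, float]:
    model = fit_ols(table, response, predictors)
    pv = model._sm_result.pvalues[1:]
    return dict(zip(predictors, (float(v) for v in pv)))


def stepwise_select(
    table: CohortTable,
    response: str,
    pool: list[str],
    method: str = "stepwise",
    alpha_enter: float = ALPHA_ENTER,
    alpha_remove: float = ALPHA_REMOVE,
) -> FittedModel:
    """Forward / backward / stepwise variable selection on coefficient
    p-values.

    forward: repeatedly add the candidate with the smallest p-value while
    it is <= alpha_enter.  backward: start from the full pool and drop the
    predictor with the largest p-value while it is >= alpha_remove.
    stepwise: a forward step followed by backward removal sweeps, repeated
    to a fixed point (alpha_enter < alpha_remove guarantees termination).
    An empty selection returns the intercept-only fit flagged
    ``empty_selection``.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("candidate pool is empty")
    if method not in ("stepwise", "forward", "backward"):
        raise ValueError(f"unknown selection method {method!r}")
    if not alpha_enter < alpha_remove and method == "stepwise":
        raise ValueError("stepwise requires alpha_enter < alpha_remove")
    table.require_columns([response] + pool)

    def forward_step(selected: list[str]) -> bool:
        best_c, best_p = None, None
        for c in pool:
            if c in selected:
                continue
            pv = _coef_pvalues(table, response, selected + [c])[c]
            if best_p is None or pv < best_p:
                best_c, best_p = c, pv
        if best_c is not None and best_p <= alpha_enter:
            selected.append(best_c)
            return True
        return False

    def backward_sweep(selected: list[str]) -> None:
        while selected:
            pv = _coef_pvalues(table, response, selected)
            worst = max(selected, key=lambda c: pv[c])
            if pv[worst] >= alpha_remove:
                selected.remove(worst)
            else:
                break

    if method == "backward":
        selected = list(pool)
        fit_ols(table, response, selected)  # raises on rank deficiency up front
        backward_sweep(selected)
    else:
        selected: list[str] = []
        while forward_step(selected):
            if method == "stepwise":
                backward_sweep(selected)

    if not selected:
        model = _intercept_only(table, response)
        model.provenance = {"method": method, "empty_selection": True}
        return model
    model = fit_ols(table, response, selected)
    model.provenance = {"method": method, "empty_selection": False}
    return model


def _intercept_only(table: CohortTable, response: str) -> FittedModel:
    y = table.data[response].to_numpy(dtype=float)
    n = len(y)
    resid = y - y.mean()
    rss = float(resid @ resid)
    return FittedModel(
        response=response,
        predictors=[],
        coefficients={},
        intercept=float(y.mean()),
        n=n,
        p=1,
        residual_ss=rss,
        s2=rss / (n - 1),
        xtx_inverse=np.array([[1.0 / n]]),
        r2=0.0,
        adjusted_r2=0.0,
        vif={},
    )


def predictor_pools(margins_cm=DEFAULT_MARGINS_CM) -> dict[str, list[str]]:
    """The three candidate pools: full, wall-overlap only, bladder-overlap only."""
    volumes = ["VPTV_cc", "Vbw_cc", "Vbladder_cc"]
    pbw = [margin_column("Pbw", x) for x in margins_cm]
    pb = [margin_column("Pb", x) for x in margins_cm]
    return {
        "full": volumes + pbw + pb,
        "wall-only": volumes + pbw,
        "bladder-only": volumes + pb,
    }


POOL_ORDER = ("full", "wall-only", "bladder-only")
METHOD_ORDER = ("stepwise", "backward", "forward")


def candidate_protocol(
    table: CohortTable,
    response: str,
    thresholds: ScreeningThresholds | None = None,
) -> list[FittedModel]:
    """Run the 3-methods x 3-pools protocol: nine candidate models with
    (method, pool) provenance, duplicates retained and flagged, each
    screened."""
    pools = predictor_pools()
    models: list[FittedModel] = []
    for pool_name in POOL_ORDER:
        for method in METHOD_ORDER:
            m = stepwise_select(table, response, pools[pool_name], method)
            m.provenance.update({"method": method, "pool": pool_name})
            m.screening = screen(m, thresholds=thresholds)
            models.append(m)
    for i, m in enumerate(models):
        m.provenance["duplicate_of"] = next(
            (j for j in range(i) if models[j].same_equation(m)), None
        )
    return models


def screen(
    model: FittedModel,
    residuals: np.ndarray | None = None,
    thresholds: ScreeningThresholds | None = None,
) -> ScreeningReport:
    """Screen a fitted model: F-test, coefficient t-tests, VIF, residual
    normality (Shapiro-Wilk) and homoscedasticity (Breusch-Pagan).

    Numerically zero residuals (an exact fit) make the residual tests
    meaningless; they are skipped and the report is flagged degenerate-pass.
    An empty selection always fails.
    """
    th = thresholds or ScreeningThresholds()
    if not model.predictors:
        return ScreeningReport(
            f_pvalue=1.0, coef_pvalues={}, max_vif=0.0,
            normality_pvalue=None, homoscedasticity_pvalue=None,
            passed=False, notes="empty selection",
        )
    res = model._sm_result
    if res is None:
        raise ValueError("model carries no fit result to screen")
    f_p = float(res.f_pvalue)
    coef_p = dict(zip(model.predictors, (float(v) for v in res.pvalues[1:])))
    max_vif = max(model.vif.values()) if model.vif else 0.0
    if residuals is None:
        residuals = np.asarray(res.resid, dtype=float)

    scale = max(1.0, float(np.abs(res.fittedvalues).max()))
    degenerate = bool(np.abs(residuals).max() <= 1e-10 * scale)
    if degenerate:
        norm_p = homo_p = None
        resid_ok = True
        notes = "exact fit; residual tests skipped"
    else:
        norm_p = float(stats.shapiro(residuals).pvalue)
        exog = res.model.exog
        homo_p = float(het_breuschpagan(residuals, exog)[1])
        resid_ok = norm_p >= th.alpha_normality and homo_p >= th.alpha_homoscedasticity
        notes = ""

    passed = (
        f_p < th.alpha_f
        and all(p < th.alpha_coef for p in coef_p.values())
        and max_vif < th.vif_limit
        and resid_ok
    )
    return ScreeningReport(
        f_pvalue=f_p, coef_pvalues=coef_p, max_vif=max_vif,
        normality_pvalue=norm_p, homoscedasticity_pvalue=homo_p,
        passed=passed, degenerate=degenerate, notes=notes,
    )


def select_best(models: list[FittedModel]) -> FittedModel:
    """The screened-passing model with maximal adjusted R^2.

    Ties break toward fewer predictors, then toward the earlier pool in
    (full, wall-only, bladder-only) order, then toward the earlier entry.
    """
    admissible = [
        (i, m) for i, m in enumerate(models)
        if m.screening is not None and m.screening.passed
    ]
    if not admissible:
        raise ValueError("no admissible model: every candidate failed screening")

    def key(item):
        i, m = item
        pool = m.provenance.get("pool")
        pool_rank = POOL_ORDER.index(pool) if pool in POOL_ORDER else len(POOL_ORDER)
        return (-m.adjusted_r2, len(m.predictors), pool_rank, i)

    return min(admissible, key=key)[1]
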