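"""Multivariable modelling of non-KS membership.

The pipeline: binary candidate variables (disease flags, fatal outcome,
ATC-2 use flags, selected co-reported PT flags) are screened univariately
(chi-squared / Fisher, p < 0.05), checked for collinearity (variance
inflation factor, VIF >= 5 excluded), and entered into a deterministic
bidirectional stepwise logistic regression that minimises the small-sample
Akaike criterion AICc.  The dependent variable codes the non-KS group as 1.

The maximum-likelihood fit is by iteratively reweighted least squares;
Wald chi-squared statistics are (coef/se)^2, and the primary odds-ratio
confidence intervals invert the likelihood-ratio test at 3.841459
(profile likelihood), with Wald intervals reported alongside.  Complete or
quasi-complete separation is surfaced as an explicit error naming the
offending column, never as a silently diverged estimate.

Fit metrics: McFadden pseudo R-squared, AICc and BIC with the intercept
counted in k, and the Mann–Whitney AUC (ties get half credit).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import ConvergenceError, DegenerateTableError, SeparationError
from .comparison import choose_test
from .signals import ContingencyTable

logger = logging.getLogger(__name__)

LR_CRIT_95 = 3.841459  # chi2(1) quantile inverted for profile-likelihood CIs
_COEF_DIVERGED = 15.0  # |beta| beyond this on binary data means separation


@dataclass
class FeatureMatrix:
    """Binary candidate variables plus the group label (non-KS = 1)."""

    X: pd.DataFrame
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing entries")
        if len(set(self.X.columns)) != self.X.shape[1]:
            raise ValueError("duplicate column names in feature matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class VariableFit:
    """Per-variable row of a fitted model."""

    name: str
    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    wald_ci_low: float
    wald_ci_high: float
    wald_chi2: float
    p: float
    vif: float | None = None


@dataclass
class ModelFit:
    """A fitted logistic model with its coefficient table and fit metrics."""

    variables: list[str]
    intercept: float
    table: list[VariableFit]
    loglik: float
    loglik_null: float
    n: int
    fitted: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def k(self) -> int:
        """Parameter count, intercept included."""
        return len(self.variables) + 1

    @property
    def pseudo_r2(self) -> float:
        """McFadden: 1 - l_model / l_null."""
        if self.loglik_null == 0.0:
            return 0.0
        return 1.0 - self.loglik / self.loglik_null

    @property
    def aicc(self) -> float:
        k, n = self.k, self.n
        return -2.0 * self.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.k * math.log(self.n)


# ---------------------------------------------------------------------------
# screening


def univariate_screen(
    features: FeatureMatrix, alpha: float = 0.05
) -> list[tuple[str, float]]:
    """Per-variable 2x2 test against the group label.

    Returns (variable, p) for every non-constant column; candidates for the
    multivariable model are those with p < ``alpha`` (see
    :func:`select_candidates`).  Constant columns are excluded with a
    warning — they carry no contrast.
    """
    y = features.y.astype(bool)
    out: list[tuple[str, float]] = []
    for name in features.X.columns:
        x = features.X[name].to_numpy().astype(bool)
        if x.all() or not x.any():
            logger.warning("univariate screen: column %r is constant; excluded", name)
            continue
        # orientation: rows = KS (y=0) / non-KS (y=1), columns = flag yes/no
        t = ContingencyTable(
            int((x & ~y).sum()),
            int((~x & ~y).sum()),
            int((x & y).sum()),
            int((~x & y).sum()),
        )
        try:
            out.append((name, choose_test(t, name).p))
        except DegenerateTableError:
            logger.warning("univariate screen: degenerate table for %r; excluded", name)
    return out


def select_candidates(
    screen: list[tuple[str, float]], alpha: float = 0.05
) -> list[str]:
    return [name for name, p in screen if p < alpha]


def vif_screen(
    features: FeatureMatrix, candidates: list[str], threshold: float = 5.0
) -> tuple[list[str], dict[str, float]]:
    """Iterative collinearity exclusion by variance inflation factor.

    VIF_j = 1 / (1 - R^2_j) from an intercept-included least-squares
    regression of column j on the other candidate columns.  The column
    with the highest VIF at or above the threshold is dropped and VIFs are
    recomputed, until all remaining VIFs are below the threshold.
    Perfectly collinear columns give infinite VIF and are removed first.
    Returns the retained candidates (input order) and their final VIFs.
    """
    retained = list(candidates)
    while len(retained) >= 2:
        vifs = {name: _vif_one(features.X, retained, name) for name in retained}
        worst = max(retained, key=lambda nm: vifs[nm])
        if vifs[worst] < threshold:
            return retained, vifs
        logger.info("VIF screen: dropping %r (VIF=%.3f)", worst, vifs[worst])
        retained.remove(worst)
    return retained, {name: 1.0 for name in retained}


def _vif_one(X: pd.DataFrame, columns: list[str], target: str) -> float:
    others = [c for c in columns if c != target]
    yv = X[target].to_numpy(dtype=float)
    A = np.column_stack(
        [np.ones(len(yv))] + [X[c].to_numpy(dtype=float) for c in others]
    )
    resid = yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]
    tss = float(((yv - yv.mean()) ** 2).sum())
    if tss == 0.0:
        return math.inf
    r2 = 1.0 - float((resid**2).sum()) / tss
    if r2 >= 1.0 - 1e-12:
        return math.inf
    return 1.0 / (1.0 - r2)


# ---------------------------------------------------------------------------
# logistic fit


def _check_not_constant(X: pd.DataFrame, columns: list[str]) -> None:
    for name in columns:
        col = X[name].to_numpy(dtype=float)
        if np.all(col == col[0]):
            raise SeparationError(name, f"column {name!r} is constant")


def _glm_fit(y: np.ndarray, design: np.ndarray, offset: np.ndarray | None = None):
    model = sm.GLM(y, design, family=sm.families.Binomial(), offset=offset)
    return model.fit(maxiter=200, tol=1e-12)


def _fit_core(
    features: FeatureMatrix, columns: list[str]
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, np.ndarray]:
    """IRLS fit; returns (params, bse, loglik, fitted, design)."""
    _check_not_constant(features.X, columns) if columns else None
    y = features.y
    design = np.column_stack(
        [np.ones(features.n)]
        + [features.X[c].to_numpy(dtype=float) for c in columns]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ConvergenceError(
            f"design matrix is rank-deficient on columns {columns}; "
            "remove exactly collinear predictors first"
        )
    try:
        res = _glm_fit(y, design)
    except Exception as exc:  # statsmodels raises on hard separation
        raise SeparationError(
            columns[0] if columns else "(intercept)", str(exc)
        ) from exc
    params = np.asarray(res.params, dtype=float)
    # gradient (score) check: X'(y - p) ~ 0 at the MLE
    fitted = np.asarray(res.fittedvalues, dtype=float)
    grad = design.T @ (y - fitted)
    if not np.all(np.isfinite(params)):
        raise ConvergenceError("non-finite coefficients after IRLS")
    if float(np.linalg.norm(grad)) > 1e-6:
        raise ConvergenceError(
            f"IRLS gradient norm {np.linalg.norm(grad):.3g} above tolerance"
        )
    for j, name in enumerate(columns, start=1):
        if abs(params[j]) > _COEF_DIVERGED:
            raise SeparationError(
                name, f"coefficient for {name!r} diverged ({params[j]:.2f}); "
                "complete or quasi-complete separation"
            )
    return params, np.asarray(res.bse, dtype=float), float(res.llf), fitted, design


def _profile_ci(
    features: FeatureMatrix,
    columns: list[str],
    j: int,
    params: np.ndarray,
    se: np.ndarray,
    loglik: float,
) -> tuple[float, float]:
    """Profile-likelihood CI for coefficient ``j`` (1-based; 0 = intercept).

    Inverts the likelihood-ratio test: bounds are where twice the profile
    log-likelihood drop equals 3.841459.  The nuisance parameters are
    re-maximised at each fixed value via an offset fit.
    """
    y = features.y
    xj = (
        np.ones(features.n)
        if j == 0
        else features.X[columns[j - 1]].to_numpy(dtype=float)
    )
    other_cols = [c for k, c in enumerate(columns, start=1) if k != j]
    design_rest = np.column_stack(
        ([np.ones(features.n)] if j != 0 else [])
        + [features.X[c].to_numpy(dtype=float) for c in other_cols]
    )
    if design_rest.shape[1] == 0:
        design_rest = None

    def drop(beta_j: float) -> float:
        offset = beta_j * xj
        if design_rest is None:
            mu = 1.0 / (1.0 + np.exp(-offset))
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        else:
            ll = float(_glm_fit(y, design_rest, offset=offset).llf)
        return 2.0 * (loglik - ll) - LR_CRIT_95

    mle = float(params[j])
    step = max(float(se[j]), 0.25)

    def bound(direction: int) -> float:
        width = 2.0 * step
        for _ in range(60):
            cand = mle + direction * width
            if drop(cand) > 0:
                lo, hi = sorted((mle, cand))
                return float(brentq(drop, lo, hi, xtol=1e-8))
            width *= 1.6
            if abs(cand) > 60:
                return direction * math.inf
        return direction * math.inf  # pragma: no cover

    return bound(-1), bound(+1)


def fit_logistic(
    features: FeatureMatrix,
    columns: list[str],
    *,
    ci: str = "profile",
    vifs: dict[str, float] | None = None,
) -> ModelFit:
    """Maximum-likelihood logistic regression on the named columns.

    ``ci`` selects the primary interval: ``"profile"`` (default),
    ``"wald"``, or ``"none"`` to skip intervals (used inside the stepwise
    search, where only the likelihood is needed).
    """
    params, bse, loglik, fitted, _ = _fit_core(features, columns)
    if columns:
        ll_null = _fit_core(features, [])[2]
    else:
        ll_null = loglik

    table: list[VariableFit] = []
    for j, name in enumerate(columns, start=1):
        coef, se_j = float(params[j]), float(bse[j])
        wald = (coef / se_j) ** 2 if se_j > 0 else math.inf
        p = float(chi2_dist.sf(wald, 1))
        w_lo, w_hi = coef - 1.959964 * se_j, coef + 1.959964 * se_j
        if ci == "profile":
            lo, hi = _profile_ci(features, columns, j, params, bse, loglik)
        elif ci == "wald":
            lo, hi = w_lo, w_hi
        else:
            lo, hi = math.nan, math.nan
        table.append(
            VariableFit(
                name=name,
                coef=coef,
                se=se_j,
                odds_ratio=math.exp(coef),
                ci_low=math.exp(lo) if math.isfinite(lo) else (0.0 if lo < 0 else math.inf),
                ci_high=math.exp(hi) if math.isfinite(hi) else (0.0 if hi < 0 else math.inf),
                wald_ci_low=math.exp(w_lo),
                wald_ci_high=math.exp(w_hi),
                wald_chi2=wald,
                p=p,
                vif=(vifs or {}).get(name),
            )
        )
    return ModelFit(
        variables=list(columns),
        intercept=float(params[0]),
        table=table,
        loglik=loglik,
        loglik_null=ll_null,
        n=features.n,
        fitted=fitted,
    )


# ---------------------------------------------------------------------------
# stepwise selection


def stepwise_select(
    features: FeatureMatrix,
    candidates: list[str],
    *,
    vifs: dict[str, float] | None = None,
) -> ModelFit:
    """Deterministic bidirectional stepwise search minimising AICc.

    Starts from the intercept-only model; at each step the single add or
    drop move with the largest AICc improvement is taken (ties broken by
    move type then variable name, so the result is invariant to candidate
    input order); stops when no move improves.  Moves whose fit separates
    are skipped with a warning.  The final model is refitted with profile
    intervals.
    """
    pool = sorted(set(candidates))
    current: list[str] = []
    current_fit = fit_logistic(features, current, ci="none")
    while True:
        moves: list[tuple[float, int, str, list[str]]] = []
        for name in pool:
            if name in current:
                cols = [c for c in current if c != name]
                kind = 1  # drop
            else:
                cols = sorted(current + [name])
                kind = 0  # add
            try:
                cand_fit = fit_logistic(features, cols, ci="none")
            except (SeparationError, ConvergenceError) as exc:
                logger.warning("stepwise: skipping move on %r (%s)", name, exc)
                continue
            moves.append((cand_fit.aicc, kind, name, cols))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_aicc, _, _, best_cols = moves[0]
        if best_aicc < current_fit.aicc - 1e-10:
            current = best_cols
            current_fit = fit_logistic(features, current, ci="none")
        else:
            break
    return fit_logistic(features, current, ci="profile", vifs=vifs)


# ---------------------------------------------------------------------------
# discrimination metrics


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann–Whitney statistic of scores vs labels.

    Probability a random positive outscores a random negative, counting
    ties as half a concordance.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = float(ranks[labels].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def model_metrics(fit: ModelFit, features: FeatureMatrix) -> dict[str, float]:
    """Global fit statistics of a fitted model on its data."""
    return {
        "pseudo_r2": fit.pseudo_r2,
        "aicc": fit.aicc,
        "bic": fit.bic,
        "auc": auc_mann_whitney(fit.fitted, features.y),
        "n": float(fit.n),
        "loglik": fit.loglik,
    }


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC staircase as ordered (FPR, TPR) points from (0,0) to (1,1).

    The trapezoidal area under these points equals the Mann–Whitney AUC.
    """
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float),
                                drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def roc_auc_trapezoid(points: np.ndarray) -> float:
    return float(np.trapezoid(points[:, 1], points[:, 0]))
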