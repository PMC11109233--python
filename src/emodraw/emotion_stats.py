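"""Cross-emotion statistics and the multinomial-logit emotion classifier.

The classifier is a standard softmax-link multinomial logistic
regression fitted by Newton-Raphson on the full log-likelihood with
step-halving, as SPSS-style packages do. Coefficients are log-odds of
each emotion against a reference emotion (happiness by default). Model
quality is summarised by the likelihood-ratio chi-square, Nagelkerke's
pseudo-R2 and an in-sample observed-by-predicted classification table;
percentile bootstrap intervals over case resamples quantify coefficient
stability.

Design-matrix convention: the prominent-color categorical enters as
dummy indicators with a reference level dropped. The raw color
percentages are excluded from the default design because they are
compositional (they sum to 100 across the seven colors), which makes
the percentage block exactly collinear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .palette import EXPRESSIVE_COLORS
from .style_annotations import STYLE_CATEGORIES

__all__ = [
    "EmotionModel",
    "ClassificationTable",
    "SeparationError",
    "chisq_independence",
    "oneway_anova",
    "build_design_matrix",
    "fit_multinomial_logit",
    "nagelkerke_r2",
    "bootstrap_fit",
    "classification_table",
]

EMOTIONS: tuple[str, ...] = ("anger", "happiness", "sadness", "fear")

#: Feature columns entering the default design besides the color dummies.
SCALAR_PREDICTORS: tuple[str, ...] = (
    "saturation_pct",
    "brightness_pct",
    "n_colors",
    "color_fill_pct",
    "image_coverage_pct",
)


class SeparationError(RuntimeError):
    """Raised when (quasi-)complete separation makes the MLE diverge."""


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def chisq_independence(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total: expected counts undefined")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(dof), float(p)


def oneway_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA F and upper-tail p across >= 2 groups.

    Degenerate convention: zero between- and within-group variance gives
    F = 0, p = 1; nonzero between with zero within gives F = inf, p = 0.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = sum(len(g) for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        return (0.0, 1.0) if ssb == 0.0 else (float("inf"), 0.0)
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(
    features: pd.DataFrame,
    styles: pd.DataFrame | None = None,
    *,
    color_reference: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the predictor matrix and outcome from extracted features.

    ``features`` needs an ``emotion`` column, ``prominent_color`` and
    the scalar metrics; ``styles`` (optional) is indexed like
    ``features`` with the five 0/1 style columns. The prominent-color
    reference level defaults to the first palette color present.
    Constant columns are dropped with a warning.
    """
    if "emotion" not in features.columns:
        raise ValueError("features must carry an 'emotion' column")
    y = features["emotion"].astype(str)
    bad = set(y.unique()) - set(EMOTIONS)
    if bad:
        raise ValueError(f"unknown emotion labels: {sorted(bad)}")

    present = [c for c in EXPRESSIVE_COLORS if (features["prominent_color"] == c).any()]
    if color_reference is None:
        color_reference = present[0]
    dummies = pd.get_dummies(
        pd.Categorical(features["prominent_color"], categories=list(EXPRESSIVE_COLORS)),
        prefix="color",
        dtype=float,
    )
    dummies.index = features.index
    dummies = dummies.drop(columns=f"color_{color_reference}")

    X = pd.concat([dummies, features[list(SCALAR_PREDICTORS)].astype(float)], axis=1)
    if styles is not None:
        st = styles.reindex(features.index)
        if st.isna().any().any():
            raise ValueError("styles table does not cover every drawing")
        X = pd.concat([X, st[list(STYLE_CATEGORIES)].astype(float)], axis=1)

    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant predictor columns: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    return X, y


# ---------------------------------------------------------------------------
# multinomial logit
# ---------------------------------------------------------------------------

def _softmax_ll(B: np.ndarray, X1: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-likelihood and class probabilities for coefficient block B.

    B has shape (K-1, p+1) for the non-reference classes; the reference
    class has an implicit zero row. Y is the n x K one-hot outcome.
    """
    eta = np.zeros((X1.shape[0], Y.shape[1]))
    eta[:, 1:] = X1 @ B.T
    eta -= eta.max(axis=1, keepdims=True)
    ex = np.exp(eta)
    P = ex / ex.sum(axis=1, keepdims=True)
    ll = float((Y * np.log(np.clip(P, 1e-300, None))).sum())
    return ll, P


@dataclass
class EmotionModel:
    """A fitted multinomial-logit emotion classifier."""

    coefficients: pd.DataFrame          # (K-1) x (p+1), rows = non-reference classes
    classes: tuple[str, ...]            # reference first
    reference: str
    feature_names: tuple[str, ...]
    log_likelihood: float
    null_log_likelihood: float
    lr_chi2: float
    lr_df: int
    lr_pvalue: float
    nagelkerke_r2: float
    n_obs: int
    converged: bool
    n_iter: int
    cov_params: np.ndarray | None = None

    def _design(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return np.column_stack([np.ones(len(X)), X])

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        X1 = self._design(X)
        B = self.coefficients.to_numpy()
        eta = np.zeros((X1.shape[0], len(self.classes)))
        eta[:, 1:] = X1 @ B.T
        eta -= eta.max(axis=1, keepdims=True)
        ex = np.exp(eta)
        P = ex / ex.sum(axis=1, keepdims=True)
        return pd.DataFrame(P, columns=list(self.classes))

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        P = self.predict_proba(X)
        return P.columns.to_numpy()[P.to_numpy().argmax(axis=1)]

    def coef_standard_errors(self) -> pd.DataFrame | None:
        if self.cov_params is None:
            return None
        se = np.sqrt(np.diag(self.cov_params)).reshape(self.coefficients.shape)
        return pd.DataFrame(
            se, index=self.coefficients.index, columns=self.coefficients.columns
        )


def fit_multinomial_logit(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    *,
    reference: str = "happiness",
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-10,
    coef_bound: float = 50.0,
) -> EmotionModel:
    """Fit the softmax multinomial logit by Newton-Raphson.

    Newton steps on the stacked (K-1)(p+1) coefficient vector with
    step-halving whenever a step would decrease the log-likelihood.
    Convergence: max |score| < ``grad_tol`` or relative log-likelihood
    change < ``ll_tol``. Coefficients running past ``coef_bound``
    (on standardised columns this signals separation) raise
    SeparationError rather than returning a diverged fit.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(map(str, X.columns))
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        feature_names = tuple(f"x{i}" for i in range(Xa.shape[1]))
    ya = np.asarray(y).astype(str)
    levels = [c for c in pd.unique(ya)]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from outcome")
    classes = tuple([reference] + sorted(c for c in levels if c != reference))
    K = len(classes)
    if K < 2:
        raise ValueError("outcome must have at least two levels")
    n, p = Xa.shape
    if n <= p + 1:
        raise ValueError("need more observations than parameters")

    # standardise columns for numerical stability; back-transform at the end
    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Xa - mu) / sd
    X1 = np.column_stack([np.ones(n), Z])
    Y = np.zeros((n, K))
    for j, c in enumerate(classes):
        Y[:, j] = ya == c

    d = p + 1
    B = np.zeros((K - 1, d))
    ll, P = _softmax_ll(B, X1, Y)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        R = Y[:, 1:] - P[:, 1:]                     # n x (K-1) residuals
        grad = (R.T @ X1).reshape(-1)               # stacked score
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        # observed-information Hessian, block (j,k): X' W_jk X
        H = np.empty(((K - 1) * d, (K - 1) * d))
        for j in range(1, K):
            for k in range(1, K):
                w = P[:, j] * ((j == k) - P[:, k])
                H[(j - 1) * d:j * d, (k - 1) * d:k * d] = X1.T @ (X1 * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(H.shape[0]), grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular Hessian at iteration {n_iter}") from exc
        step = step.reshape(K - 1, d)
        # step-halving: never accept a decrease in log-likelihood
        scale = 1.0
        for _ in range(30):
            ll_new, P_new = _softmax_ll(B + scale * step, X1, Y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        B = B + scale * step
        rel = abs(ll_new - ll) / (abs(ll) + 1.0)
        ll, P = ll_new, P_new
        if np.max(np.abs(B)) > coef_bound:
            raise SeparationError(
                "coefficients diverging: (quasi-)complete separation suspected"
            )
        if rel < ll_tol:
            grad_now = ((Y[:, 1:] - P[:, 1:]).T @ X1).reshape(-1)
            converged = np.max(np.abs(grad_now)) < max(grad_tol, 1e-6)
            break

    # (quasi-)complete separation: every observation fitted essentially
    # perfectly means the MLE is at infinity and the fit is meaningless
    phat = P[np.arange(n), Y.argmax(axis=1)]
    if K > 1 and p > 0 and phat.min() > 1.0 - 1e-6:
        raise SeparationError(
            "all observations fitted perfectly: (quasi-)complete separation"
        )

    # back-transform coefficients to the original predictor scale
    B_orig = np.empty_like(B)
    B_orig[:, 1:] = B[:, 1:] / sd
    B_orig[:, 0] = B[:, 0] - (B[:, 1:] * (mu / sd)).sum(axis=1)

    # null (intercept-only) log-likelihood in closed form
    counts = Y.sum(axis=0)
    pr = counts / n
    ll0 = float((counts[counts > 0] * np.log(pr[counts > 0])).sum())

    lr = max(0.0, 2.0 * (ll - ll0))
    lr_df = (K - 1) * p
    r2 = nagelkerke_r2(ll0, ll, n)

    cov = None
    try:
        H = np.empty(((K - 1) * d, (K - 1) * d))
        X1o = np.column_stack([np.ones(n), Xa])
        _, Po = _softmax_ll(B_orig, X1o, Y)
        for j in range(1, K):
            for k in range(1, K):
                w = Po[:, j] * ((j == k) - Po[:, k])
                H[(j - 1) * d:j * d, (k - 1) * d:k * d] = X1o.T @ (X1o * w[:, None])
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None

    coef = pd.DataFrame(
        B_orig,
        index=pd.Index(list(classes[1:]), name="emotion"),
        columns=["intercept", *feature_names],
    )
    return EmotionModel(
        coefficients=coef,
        classes=classes,
        reference=reference,
        feature_names=feature_names,
        log_likelihood=ll,
        null_log_likelihood=ll0,
        lr_chi2=lr,
        lr_df=lr_df,
        lr_pvalue=float(stats.chi2.sf(lr, lr_df)) if lr_df > 0 else float("nan"),
        nagelkerke_r2=r2,
        n_obs=n,
        converged=bool(converged),
        n_iter=n_iter,
        cov_params=cov,
    )


def nagelkerke_r2(ll0: float, ll1: float, n: int) -> float:
    """Nagelkerke's rescaled pseudo-R2 from null and full log-likelihoods."""
    if n <= 0:
        raise ValueError("n must be positive")
    if ll1 < ll0 - 1e-8:
        raise ValueError("full-model log-likelihood below null: invalid nesting")
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    ceiling = 1.0 - np.exp(2.0 * ll0 / n)
    if ceiling <= 0:
        return 0.0
    return float(min(1.0, max(0.0, cox_snell / ceiling)))


def bootstrap_fit(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    B: int = 5000,
    seed: int = 0,
    reference: str = "happiness",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Case-resampled percentile intervals for every coefficient.

    Returns (interval frame with columns lower/upper indexed by
    (emotion, term), number of non-convergent resamples excluded).
    ``B = 1`` with the resample forced to the original sample is the
    degenerate contract used in tests.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(X)
    draws: list[np.ndarray] = []
    failed = 0
    template = None
    for b in range(B):
        idx = rng.integers(0, n, size=n) if B > 1 else np.arange(n)
        Xb, yb = X.iloc[idx], y.iloc[idx]
        try:
            m = fit_multinomial_logit(Xb, yb, reference=reference)
            if not m.converged:
                failed += 1
                continue
        except (SeparationError, ValueError):
            failed += 1
            continue
        if template is None:
            template = m.coefficients
        draws.append(m.coefficients.to_numpy().ravel())
    if not draws:
        raise RuntimeError("no bootstrap resample converged")
    arr = np.vstack(draws)
    lo = np.percentile(arr, 100 * alpha / 2, axis=0)
    hi = np.percentile(arr, 100 * (1 - alpha / 2), axis=0)
    index = pd.MultiIndex.from_product(
        [template.index, template.columns], names=["emotion", "term"]
    )
    out = pd.DataFrame({"lower": lo, "upper": hi}, index=index)
    return out, failed


@dataclass
class ClassificationTable:
    """Observed-by-predicted counts with per-class and overall accuracy."""

    table: pd.DataFrame            # rows observed, columns predicted
    percent_correct: pd.Series     # per observed class
    overall_percent: float

    def __str__(self) -> str:
        lines = [self.table.to_string()]
        lines.append(
            "per-class % correct: "
            + ", ".join(f"{k}={v:.1f}" for k, v in self.percent_correct.items())
        )
        lines.append(f"overall % correct: {self.overall_percent:.1f}")
        return "\n".join(lines)


def classification_table(
    model: EmotionModel, X: pd.DataFrame | np.ndarray, y: pd.Series | np.ndarray
) -> ClassificationTable:
    """In-sample observed x predicted table (apparent accuracy, no holdout)."""
    pred = model.predict(X)
    ya = np.asarray(y).astype(str)
    classes = list(model.classes)
    order = [c for c in EMOTIONS if c in classes] + [
        c for c in classes if c not in EMOTIONS
    ]
    table = pd.crosstab(
        pd.Categorical(ya, categories=order),
        pd.Categorical(pred, categories=order),
        dropna=False,
    )
    table.index.name = "observed"
    table.columns.name = "predicted"
    row_tot = table.sum(axis=1)
    diag = pd.Series(np.diag(table), index=table.index)
    with np.errstate(invalid="ignore"):
        pct = 100.0 * diag / row_tot.replace(0, np.nan)
    overall = float(100.0 * np.trace(table.to_numpy()) / table.to_numpy().sum())
    return ClassificationTable(
        table=table, percent_correct=pct, overall_percent=overall
    )
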