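"""Reduced quadratic response-surface models on the coded factor basis.

A chromatographic response ``y`` (a peak-boundary time or a retention factor)
is modeled, after an optional variance-stabilizing transform, as a reduced
quadratic polynomial in the three coded factors::

    g(y) = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2

fitted by ordinary least squares.  :class:`QuadraticSurfaceRegressor` is a
scikit-learn-style estimator (``fit``/``predict``/``get_params``) whose
fitted attributes carry everything the Monte Carlo design-space engine needs:
coefficients, their standard errors and full covariance, and the standard
DoE diagnostics (R², adjusted R², PRESS-based predicted R², and the
replicate-based lack-of-fit test).

The transform is part of the model: ``fit`` transforms ``y`` before the
least-squares solve and ``predict`` back-transforms to the response scale.
Transform choice can be guided by :func:`suggest_transform`, which profiles
the Box-Cox log-likelihood of the regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .factors import DesignTable

__all__ = [
    "TERM_ORDER",
    "full_quadratic_terms",
    "term_matrix",
    "apply_transform",
    "inverse_transform",
    "Diagnostics",
    "QuadraticSurfaceRegressor",
    "RankDeficiencyError",
    "fit_rsm",
    "suggest_transform",
    "backward_eliminate",
]


class RankDeficiencyError(ValueError):
    """Raised when the model matrix is singular (collinear terms)."""


# ---------------------------------------------------------------------------
# model terms

#: canonical ordering of all quadratic-model terms in three factors
TERM_ORDER = (
    "1",
    "x1", "x2", "x3",
    "x1:x2", "x1:x3", "x2:x3",
    "x1^2", "x2^2", "x3^2",
)


def full_quadratic_terms() -> tuple[str, ...]:
    """All 10 terms of the full quadratic model in canonical order."""
    return TERM_ORDER


def canonical_terms(terms) -> tuple[str, ...]:
    """Validate a term collection and return it in canonical order with an intercept."""
    terms = set(terms) | {"1"}
    unknown = terms - set(TERM_ORDER)
    if unknown:
        raise ValueError(f"unknown model terms: {sorted(unknown)}")
    return tuple(t for t in TERM_ORDER if t in terms)


def term_matrix(X, terms) -> np.ndarray:
    """Model matrix for coded factor settings ``X`` of shape (n, 3)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"expected coded factor array of shape (n, 3), got {X.shape}")
    x1, x2, x3 = X[:, 0], X[:, 1], X[:, 2]
    columns = {
        "1": np.ones(len(X)),
        "x1": x1, "x2": x2, "x3": x3,
        "x1:x2": x1 * x2, "x1:x3": x1 * x3, "x2:x3": x2 * x3,
        "x1^2": x1 ** 2, "x2^2": x2 ** 2, "x3^2": x3 ** 2,
    }
    return np.column_stack([columns[t] for t in terms])


# ---------------------------------------------------------------------------
# transforms

_FORWARD = {
    "identity": lambda y: y,
    "reciprocal": lambda y: 1.0 / y,
    "log10": np.log10,
}
_INVERSE = {
    "identity": lambda z: z,
    "reciprocal": lambda z: 1.0 / z,
    "log10": lambda z: np.power(10.0, z),
}


def apply_transform(y, kind: str):
    """Transform a (positive) response; ``kind`` is identity, reciprocal, or log10."""
    if kind not in _FORWARD:
        raise ValueError(f"unknown transform {kind!r}; choose from {sorted(_FORWARD)}")
    y = np.asarray(y, dtype=float)
    if kind != "identity" and np.any(y <= 0):
        raise ValueError(f"{kind} transform requires strictly positive responses")
    return _FORWARD[kind](y)


def inverse_transform(z, kind: str):
    """Inverse of :func:`apply_transform`."""
    if kind not in _INVERSE:
        raise ValueError(f"unknown transform {kind!r}; choose from {sorted(_INVERSE)}")
    return _INVERSE[kind](np.asarray(z, dtype=float))


# ---------------------------------------------------------------------------
# diagnostics

@dataclass(frozen=True)
class Diagnostics:
    """Standard DoE model-quality summary.

    ``lof_pvalue`` is ``None`` when the design carries no replicated settings
    (pure error undefined), never silently 1.0.
    """

    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    lof_pvalue: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def _replicate_groups(X: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing identical coded settings (replicates)."""
    keys = {}
    for i, row in enumerate(np.round(X, 9)):
        keys.setdefault(tuple(row), []).append(i)
    return [np.array(g) for g in keys.values() if len(g) > 1]


def _lack_of_fit_pvalue(X, resid, df_resid) -> float | None:
    groups = _replicate_groups(X)
    if not groups:
        return None
    # pure error from replicate scatter; model-inadequacy from the remainder
    ss_pe = 0.0
    df_pe = 0
    for g in groups:
        # residuals within a replicate group differ from their mean only
        # through the observations, so pure error can be read off either way
        ss_pe += np.sum((resid[g] - resid[g].mean()) ** 2)
        df_pe += len(g) - 1
    df_lof = df_resid - df_pe
    ss_lof = float(resid @ resid) - ss_pe
    if df_lof <= 0 or df_pe <= 0 or ss_pe <= 0:
        return None
    F = (ss_lof / df_lof) / (ss_pe / df_pe)
    return float(stats.f.sf(F, df_lof, df_pe))


# ---------------------------------------------------------------------------
# the estimator

class QuadraticSurfaceRegressor(RegressorMixin, BaseEstimator):
    """OLS reduced quadratic surface in three coded factors.

    Parameters
    ----------
    terms : sequence of str, optional
        Model terms from :data:`TERM_ORDER`; the intercept is always included.
        ``None`` fits the full 10-term quadratic.
    transform : {"identity", "reciprocal", "log10"}
        Variance-stabilizing transform applied to ``y`` before fitting;
        ``predict`` returns values back on the response scale.

    Attributes
    ----------
    terms_ : tuple of str
        Terms actually fitted, canonical order.
    coef_ : ndarray
        Coefficients on the transformed/coded scale, aligned with ``terms_``.
    se_ : ndarray
        Coefficient standard errors.
    cov_ : ndarray
        Full coefficient covariance matrix.
    sigma2_ : float
        Residual variance on the transformed scale.
    df_resid_ : int
    diagnostics_ : :class:`Diagnostics`

    Examples
    --------
    >>> reg = QuadraticSurfaceRegressor(terms=["x1", "x2"], transform="log10")
    >>> reg.fit(X_coded, y).predict([[0, 0, 0]])  # doctest: +SKIP
    """

    def __init__(self, terms=None, transform: str = "identity"):
        self.terms = terms
        self.transform = transform

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        terms = canonical_terms(self.terms if self.terms is not None else TERM_ORDER)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        if len(y) < len(terms):
            raise ValueError(
                f"need at least {len(terms)} runs to fit {len(terms)} terms, got {len(y)}"
            )
        M = term_matrix(X, terms)
        rank = np.linalg.matrix_rank(M)
        if rank < M.shape[1]:
            raise RankDeficiencyError(
                f"model matrix is rank deficient (rank {rank} < {M.shape[1]}); "
                f"collinear terms among {terms}"
            )
        z = apply_transform(y, self.transform)
        res = sm.OLS(z, M).fit()

        self.terms_ = terms
        self.coef_ = np.asarray(res.params)
        self.df_resid_ = int(res.df_resid)
        if self.df_resid_ > 0:
            self.se_ = np.asarray(res.bse)
            self.cov_ = np.asarray(res.cov_params())
            self.sigma2_ = float(res.mse_resid)
        else:  # saturated interpolation: no residual information
            self.se_ = np.zeros_like(self.coef_)
            self.cov_ = np.zeros((len(terms), len(terms)))
            self.sigma2_ = 0.0
        self.n_features_in_ = 3

        resid = np.asarray(res.resid)
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((z - z.mean()) ** 2))
        n, p = M.shape
        leverage = np.sum(M * (M @ np.linalg.inv(M.T @ M)), axis=1)
        if np.any(leverage >= 1.0 - 1e-10):  # LOO undefined at an interpolated run
            press = float("nan")
        else:
            press_resid = resid / (1.0 - leverage)
            press = float(press_resid @ press_resid)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            adj_r2 = (
                1.0 - (ss_res / (n - p)) / (ss_tot / (n - 1))
                if ss_tot > 0 and n > p
                else r2
            )
            pred_r2 = 1.0 - press / ss_tot if ss_tot > 0 else 1.0
        self.diagnostics_ = Diagnostics(
            r2=float(r2),
            adj_r2=float(adj_r2),
            pred_r2=float(pred_r2),
            press=press,
            lof_pvalue=_lack_of_fit_pvalue(X, resid, self.df_resid_),
        )
        self._resid_ = resid
        return self

    # -- prediction ---------------------------------------------------------

    def predict_transformed(self, X) -> np.ndarray:
        """Linear predictor on the transformed scale."""
        self._check_fitted()
        return term_matrix(np.atleast_2d(np.asarray(X, dtype=float)), self.terms_) @ self.coef_

    def predict(self, X) -> np.ndarray:
        """Predicted response on the natural response scale."""
        return inverse_transform(self.predict_transformed(X), self.transform)

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise AttributeError("model is not fitted; call fit(X, y) first")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-ready representation (terms, transform, b, SE, covariance, diagnostics)."""
        self._check_fitted()
        return {
            "terms": list(self.terms_),
            "transform": self.transform,
            "coefficients": self.coef_.tolist(),
            "standard_errors": self.se_.tolist(),
            "covariance": self.cov_.tolist(),
            "sigma2": self.sigma2_,
            "df_resid": self.df_resid_,
            "diagnostics": self.diagnostics_.as_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticSurfaceRegressor":
        reg = cls(terms=list(d["terms"]), transform=d["transform"])
        reg.terms_ = tuple(d["terms"])
        reg.coef_ = np.asarray(d["coefficients"], dtype=float)
        reg.se_ = np.asarray(d["standard_errors"], dtype=float)
        reg.cov_ = np.asarray(d["covariance"], dtype=float)
        reg.sigma2_ = float(d["sigma2"])
        reg.df_resid_ = int(d["df_resid"])
        diag = d.get("diagnostics")
        if diag is not None:
            reg.diagnostics_ = Diagnostics(**diag)
        reg.n_features_in_ = 3
        return reg


def _as_coded(design) -> np.ndarray:
    return design.coded if isinstance(design, DesignTable) else np.asarray(design, dtype=float)


def fit_rsm(design, y, terms=None, transform: str = "identity") -> QuadraticSurfaceRegressor:
    """Fit a reduced quadratic surface; thin wrapper over the estimator.

    ``design`` may be a :class:`~chromodr.factors.DesignTable` or an (n, 3)
    coded array.
    """
    return QuadraticSurfaceRegressor(terms=terms, transform=transform).fit(_as_coded(design), y)


# ---------------------------------------------------------------------------
# Box-Cox transform suggestion

def suggest_transform(design, y, terms=None, lambdas=None, level: float = 0.95) -> str:
    """Choose a transform by profiling the Box-Cox log-likelihood of the fit.

    For each candidate exponent λ, ``y`` is Box-Cox transformed, the model is
    refitted, and the profile log-likelihood (with the Jacobian term) is
    recorded.  The returned transform depends on which canonical exponents the
    confidence region covers: −1 (but neither 0 nor 1) → ``"reciprocal"``;
    0 (but not 1) → ``"log10"``; otherwise ``"identity"`` (ties toward
    identity, i.e. no transform when λ = 1 is plausible).
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.any(y <= 0):
        raise ValueError("Box-Cox profiling requires strictly positive responses")
    X = _as_coded(design)
    terms = canonical_terms(terms if terms is not None else TERM_ORDER)
    M = term_matrix(X, terms)
    if lambdas is None:
        lambdas = np.linspace(-2.0, 2.0, 81)
    n = len(y)
    if np.ptp(y) == 0:  # constant response: likelihood flat, keep identity
        return "identity"
    log_y_sum = float(np.sum(np.log(y)))
    Q, _ = np.linalg.qr(M)
    llf = np.empty(len(lambdas))
    for i, lam in enumerate(lambdas):
        z = np.log(y) if abs(lam) < 1e-12 else (y ** lam - 1.0) / lam
        resid = z - Q @ (Q.T @ z)
        sse = max(float(resid @ resid), 1e-300)
        llf[i] = -0.5 * n * np.log(sse / n) + (lam - 1.0) * log_y_sum
    cutoff = llf.max() - 0.5 * stats.chi2.ppf(level, 1)
    covered = lambdas[llf >= cutoff]
    lo, hi = covered.min(), covered.max()

    def covers(lam0):
        return lo <= lam0 <= hi

    if covers(1.0):
        return "identity"
    if covers(0.0):
        return "log10"
    if covers(-1.0):
        return "reciprocal"
    return "identity"


# ---------------------------------------------------------------------------
# backward elimination

def backward_eliminate(design, y, transform: str = "identity", alpha: float = 0.05):
    """Backward term elimination from the full quadratic, respecting hierarchy.

    Repeatedly drops the non-intercept term with the largest coefficient
    p-value above ``alpha``; a linear term is protected while any surviving
    interaction or quadratic term contains its factor.  Returns the final
    term tuple (always including the intercept).
    """
    X = _as_coded(design)
    y = np.asarray(y, dtype=float).ravel()
    terms = list(full_quadratic_terms())
    z = apply_transform(y, transform)
    while True:
        M = term_matrix(X, terms)
        res = sm.OLS(z, M).fit()
        if res.df_resid <= 0:
            warnings.warn("saturated model: no residual df for p-values; stopping elimination")
            break
        protected = {"1"}
        for t in terms:
            if ":" in t:
                a, b = t.split(":")
                protected.update((a, b))
            elif t.endswith("^2"):
                protected.add(t[:-2])
        candidates = [
            (res.pvalues[i], t)
            for i, t in enumerate(terms)
            if t not in protected and t != "1"
        ]
        if not candidates:
            break
        worst_p, worst_t = max(candidates)
        if worst_p <= alpha:
            break
        terms.remove(worst_t)
    return canonical_terms(terms)
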