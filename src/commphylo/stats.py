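"""Statistical layer relating diversity outputs to the aridity gradient.

Contains Mantel tests (Spearman, label permutation), paired t tests between
seasons, quadratic log-aridity linear models with heteroscedasticity-robust
fallback, MANOVA of component scores on aridity, and independent principal
component analysis of community weighted means with its sparse variant —
the latter two exposed as sklearn-style transformers (`IPCA`, `SIPCA`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.utils.validation import check_array, check_is_fitted

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.multivariate.manova import MANOVA
from statsmodels.stats.diagnostic import het_breuschpagan

from .containers import DistanceMatrix, ValidationError

log = logging.getLogger("commphylo")


def bonferroni_threshold(alpha_family: float, n_tests: int) -> float:
    """Per-test significance threshold for a family of tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha_family / n_tests


# ---------------------------------------------------------------------------
# Mantel test (Spearman)
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    rho: float
    p_perm: float
    n_perm: int
    alternative: str


def mantel_spearman(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
                    rng=None, alternative: str = "greater") -> MantelResult:
    """Mantel test with Spearman rank correlation of the upper triangles.

    p comes from jointly permuting the row/column order of ``d2``
    (``n_perm`` draws, observed included in the reference set); one-sided
    upper by default, ``alternative="two-sided"`` available.
    """
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) != set(d2.ids):
            raise ValidationError("matrices cover different labels")
        d2 = d2.submatrix(d1.ids)
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    n = len(d1)
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    if np.std(x) == 0 or np.std(d2.values[iu]) == 0:
        raise ValidationError("zero variance in a distance triangle")
    rng = np.random.default_rng() if rng is None else rng

    def rho_of(mat):
        return sps.spearmanr(x, mat[iu]).statistic

    obs = rho_of(d2.values)
    count = 1  # observed included
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = rho_of(d2.values[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r >= obs
        elif alternative == "two-sided":
            count += abs(r) >= abs(obs)
        else:
            raise ValidationError(f"unknown alternative {alternative!r}")
    return MantelResult(rho=float(obs), p_perm=count / (n_perm + 1),
                        n_perm=n_perm, alternative=alternative)


def aridity_distance(aridity: pd.Series) -> DistanceMatrix:
    """Pairwise Euclidean (absolute) differences of site aridity."""
    a = aridity.to_numpy(dtype=float)
    return DistanceMatrix(list(aridity.index),
                          np.abs(a[:, None] - a[None, :]), check=False)


# ---------------------------------------------------------------------------
# paired t test
# ---------------------------------------------------------------------------

def paired_t(x, y):
    """Paired t test on differences x - y; returns (t, df, p two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("paired_t needs two equal-length vectors, n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            return 0.0, len(d) - 1, 1.0
        raise ValidationError("zero-variance non-zero differences")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), int(res.df), float(res.pvalue)


# ---------------------------------------------------------------------------
# quadratic aridity x season linear models
# ---------------------------------------------------------------------------

@dataclass
class LmResult:
    params: pd.DataFrame          # term, estimate, se, t, p
    robust_se_used: bool
    shapiro_p: float
    breusch_pagan_p: float
    r_squared: float
    model: object = field(repr=False, default=None)


def fit_gradient_lm(response, aridity, season, center: bool = True) -> LmResult:
    """OLS of a diversity response on log10 aridity, its square, season and
    their interactions.

    log-aridity is centred before squaring (reduces the collinearity of the
    linear and quadratic terms; ``center=False`` keeps the raw scale).
    Residual normality (Shapiro) and homoscedasticity (Breusch-Pagan) are
    checked; heteroscedastic fits report HC3 sandwich standard errors with
    the ``robust_se_used`` flag set.
    """
    response = np.asarray(response, dtype=float)
    aridity = np.asarray(aridity, dtype=float)
    season = pd.Series(season).astype(str).to_numpy()
    if np.any(aridity <= 0):
        raise ValidationError("aridity must be positive (log10 applied)")
    if len(set(season)) < 2:
        raise ValidationError("both seasons must be present")
    la = np.log10(aridity)
    if center:
        la = la - la.mean()
    df = pd.DataFrame({"y": response, "a": la, "a2": la ** 2,
                       "season": pd.Categorical(season,
                                                categories=["wet", "dry"])})
    model = smf.ols("y ~ a + a2 + season + a:season + a2:season", data=df).fit()
    if model.df_resid < 1:
        raise ValidationError("not enough residual degrees of freedom")
    resid = model.resid
    shapiro_p = float(sps.shapiro(resid).pvalue) if len(resid) >= 3 else np.nan
    bp_p = float(het_breuschpagan(resid, model.model.exog)[1])
    robust = bp_p < 0.05
    fit = model.get_robustcov_results(cov_type="HC3") if robust else model
    params = pd.DataFrame({
        "term": model.params.index,
        "estimate": np.asarray(fit.params, dtype=float),
        "se": np.asarray(fit.bse, dtype=float),
        "t": np.asarray(fit.tvalues, dtype=float),
        "p": np.asarray(fit.pvalues, dtype=float),
    })
    return LmResult(params=params, robust_se_used=robust, shapiro_p=shapiro_p,
                    breusch_pagan_p=bp_p, r_squared=float(model.rsquared),
                    model=fit)


# ---------------------------------------------------------------------------
# IPCA / SIPCA
# ---------------------------------------------------------------------------

def _soft_threshold_top(v: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so that at most ``keep`` entries stay nonzero."""
    if keep >= len(v):
        return v.copy()
    mags = np.abs(v)
    lam = np.sort(mags)[::-1][keep]
    return np.sign(v) * np.maximum(mags - lam, 0.0)


class IPCA(BaseEstimator, TransformerMixin):
    """Independent principal component analysis.

    PCA does not deliver independent components when the data depart from
    multivariate normality; IPCA scales the variables, extracts the top
    ``n_components`` PCA loading vectors, unmixes them with deflationary
    fixed-point ICA (cube nonlinearity), and projects the data onto the
    resulting independent loadings.  Components are ordered by decreasing
    absolute excess kurtosis of their scores (strongly non-Gaussian
    components first); signs are fixed by making each component's
    largest-magnitude loading positive.

    Attributes (after ``fit``)
    --------------------------
    loadings_ : (n_features, n_components) independent loading vectors
    scores_ : (n_samples, n_components) component scores of the training data
    kurtosis_ : excess kurtosis of each score column
    explained_variance_ratio_ : score variance / total variance of scaled X
    converged_ : False when FastICA hit its iteration cap
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 max_iter: int = 1000, tol: float = 1e-6, n_init: int = 5,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    def _scale(self, X):
        X = check_array(X, dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1) if self.scale else np.ones(X.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        return (X - mu) / sd, mu, sd

    def fit(self, X, y=None):
        Xs, self.mean_, self.scale_ = self._scale(X)
        n, p = Xs.shape
        m = self.n_components
        if m > min(n, p):
            raise ValidationError("n_components exceeds the rank of X")
        u, s, vt = np.linalg.svd(Xs, full_matrices=False)
        if s[m - 1] <= 1e-12 * s[0]:
            raise ValidationError("n_components exceeds the rank of X")
        V = vt[:m].T                        # p x m loading vectors
        self.converged_ = True
        if m == 1:
            L = V
        else:
            # the fixed-point iteration is sensitive to its random start;
            # restart and keep the unmixing with the most non-Gaussian scores
            base = (0 if self.random_state is None else int(self.random_state))
            best, best_score, best_ok = None, -np.inf, True
            for trial in range(max(self.n_init, 1)):
                ica = FastICA(n_components=m, algorithm="deflation",
                              fun="cube", whiten="unit-variance",
                              max_iter=self.max_iter, tol=self.tol,
                              random_state=base + trial)
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    cand = ica.fit_transform(V)    # p x m independent loadings
                ok = not any("did not converge" in str(w.message)
                             for w in caught)
                cand = cand / np.linalg.norm(cand, axis=0, keepdims=True)
                kurt = np.abs(sps.kurtosis(Xs @ cand, axis=0, fisher=True,
                                           bias=False)).sum()
                if kurt > best_score:
                    best, best_score, best_ok = cand, kurt, ok
            L = best
            if not best_ok:
                self.converged_ = False
                log.warning("FastICA did not converge; partial result kept")
        L = L / np.linalg.norm(L, axis=0, keepdims=True)
        self.loadings_ = self._finalize_loadings(Xs, L)
        self.scores_ = Xs @ self.loadings_
        self.kurtosis_ = sps.kurtosis(self.scores_, axis=0, fisher=True, bias=False)
        total_var = float(np.sum(Xs ** 2))
        self.explained_variance_ratio_ = (
            np.sum(self.scores_ ** 2, axis=0) / total_var)
        return self

    def _finalize_loadings(self, Xs, L):
        scores = Xs @ L
        kurt = np.abs(sps.kurtosis(scores, axis=0, fisher=True, bias=False))
        order = np.argsort(kurt)[::-1]
        L = L[:, order]
        for k in range(L.shape[1]):
            if L[np.argmax(np.abs(L[:, k])), k] < 0:
                L[:, k] = -L[:, k]
        return L

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        return (X - self.mean_) / self.scale_ @ self.loadings_

    def fit_transform(self, X, y=None):
        return self.fit(X, y).scores_


class SIPCA(IPCA):
    """Sparse IPCA: keep the ``keep_x`` largest-magnitude traits per
    independent loading vector (the rest soft-thresholded to exactly zero)
    and re-project the scores.  Aids interpretation of which traits drive
    each component."""

    def __init__(self, n_components: int = 2, keep_x: int = 5,
                 scale: bool = True, max_iter: int = 1000, tol: float = 1e-6,
                 random_state: int | None = 0):
        super().__init__(n_components=n_components, scale=scale,
                         max_iter=max_iter, tol=tol, random_state=random_state)
        self.keep_x = keep_x

    def fit(self, X, y=None):
        if self.keep_x < 1:
            raise ValidationError("keep_x must be >= 1")
        X_arr = check_array(X, dtype=float)
        if self.keep_x > X_arr.shape[1]:
            raise ValidationError("keep_x exceeds the number of traits")
        return super().fit(X_arr, y)

    def _finalize_loadings(self, Xs, L):
        L = super()._finalize_loadings(Xs, L)
        for k in range(L.shape[1]):
            L[:, k] = _soft_threshold_top(L[:, k], self.keep_x)
            norm = np.linalg.norm(L[:, k])
            if norm > 0:
                L[:, k] /= norm
        return L


def ipca(X, n_components: int, random_state: int | None = 0) -> IPCA:
    """Functional wrapper over :class:`IPCA`."""
    return IPCA(n_components=n_components, random_state=random_state).fit(X)


def sipca(X, n_components: int, keep_x: int = 5,
          random_state: int | None = 0) -> SIPCA:
    """Functional wrapper over :class:`SIPCA`."""
    return SIPCA(n_components=n_components, keep_x=keep_x,
                 random_state=random_state).fit(X)


def select_components_by_kurtosis(kurtosis) -> int:
    """Number of components before the largest relative drop in sorted
    absolute kurtosis (ties broken toward fewer components)."""
    k = np.sort(np.abs(np.asarray(kurtosis, dtype=float)))[::-1]
    if len(k) < 2:
        raise ValidationError("need >= 2 components")
    eps = 1e-12
    ratios = (k[:-1] + eps) / (k[1:] + eps)
    if np.allclose(ratios, ratios[0]):
        if np.allclose(k, k[0]):
            warnings.warn("all kurtosis values equal; keeping 1 component")
            return 1
    return int(np.argmax(ratios)) + 1


# ---------------------------------------------------------------------------
# MANOVA of component scores on aridity
# ---------------------------------------------------------------------------

@dataclass
class ManovaResult:
    statistic: float     # Wilks' lambda (or Pillai's trace)
    f_approx: float
    df_num: float
    df_den: float
    p: float
    stat_name: str


def manova_components(scores, aridity, stat: str = "Wilks' lambda"
                      ) -> ManovaResult:
    """Multivariate regression of component scores on aridity with Wilks'
    lambda (Rao's F approximation); Pillai's trace via ``stat``."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    n, m = scores.shape
    aridity = np.asarray(aridity, dtype=float)
    if n <= m + 1:
        raise ValidationError("need more sites than components + 1")
    data = pd.DataFrame(scores, columns=[f"c{i+1}" for i in range(m)])
    data["aridity"] = aridity
    if m == 1:
        model = smf.ols("c1 ~ aridity", data=data).fit()
        f = float(model.fvalue)
        return ManovaResult(statistic=1.0 / (1.0 + f * 1.0 / model.df_resid),
                            f_approx=f, df_num=1.0,
                            df_den=float(model.df_resid),
                            p=float(model.f_pvalue), stat_name="Wilks' lambda")
    lhs = " + ".join(data.columns[:-1])
    mv = MANOVA.from_formula(f"{lhs} ~ aridity", data=data)
    table = mv.mv_test().results["aridity"]["stat"]
    row = table.loc[stat]
    return ManovaResult(statistic=float(row["Value"]),
                        f_approx=float(row["F Value"]),
                        df_num=float(row["Num DF"]), df_den=float(row["Den DF"]),
                        p=float(row["Pr > F"]), stat_name=stat)
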