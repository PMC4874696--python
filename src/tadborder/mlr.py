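"""Multiple logistic regression over genomic features.

The central model of the package: the log-odds of a genomic bin being a
TAD border is a linear function of the feature columns,

    ln[ P(Y=1|X) / (1 - P(Y=1|X)) ] = beta_0 + beta . X

By default the likelihood is maximized by iteratively reweighted least
squares (IRLS), giving unbiased estimates with Wald standard errors from
the inverse observed information.  For large sets of correlated features
an L1-regularized fit with cross-validated penalty is available instead;
there a feature is "influential" iff its coefficient is nonzero, and no
standard errors are reported.

The module follows the statsmodels convention: :class:`BorderLogit` is
built from data and ``fit()`` returns a :class:`BorderLogitResults`
carrying estimates, uncertainties and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.special import expit
from scipy.stats import chi2, norm

from .binning import FeatureMatrix

__all__ = [
    "BorderLogit",
    "BorderLogitResults",
    "LRTResult",
    "ConvergenceError",
    "CollinearityError",
    "fit_logistic_irls",
    "fit_logistic_l1",
    "wald_inference",
    "lrt",
    "expand_interactions",
    "fit_metrics",
]

_MAX_ABS_BETA = 1e2  # coefficient magnitude beyond which separation is diagnosed


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the last iterate for diagnosis."""

    def __init__(self, message: str, last_params: np.ndarray | None = None):
        super().__init__(message)
        self.last_params = last_params


class CollinearityError(ValueError):
    """Singular design; names the linearly dependent columns."""

    def __init__(self, columns: list[str]):
        super().__init__(f"design matrix is singular; dependent columns: {columns}")
        self.columns = columns


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))


def _collapse_binary(X: np.ndarray, y: np.ndarray):
    """Collapse duplicate (pattern, y) rows of an all-binary design.

    Returns ``(Xc, yc, weights)`` or ``None`` when the design is not
    binary or too wide to pack.  The weighted Bernoulli likelihood of the
    collapsed data is identical to the row-level likelihood, so
    estimates, standard errors and log-likelihood are unchanged.
    """
    n, p = X.shape
    if p > 22:
        return None  # bincount table would dominate memory
    is_binary = ((X == 0) | (X == 1)).all()
    if not is_binary:
        return None
    code = (X.astype(np.int64) @ (1 << np.arange(p, dtype=np.int64))) * 2 + (
        y.astype(np.int64)
    )
    counts = np.bincount(code, minlength=2 ** (p + 1))
    nz = np.nonzero(counts)[0]
    if nz.size >= n // 2:
        return None  # no real compression
    yc = (nz & 1).astype(float)
    patterns = nz >> 1
    Xc = ((patterns[:, None] >> np.arange(p)) & 1).astype(float)
    return Xc, yc, counts[nz].astype(float)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        raise CollinearityError([names[i] for i in sorted(piv[rank:])])


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    tol: float,
    max_iter: int,
):
    """Weighted IRLS for the binomial-logit likelihood.

    ``X`` includes the intercept column.  Returns
    (params, cov, loglik, converged, n_iter).
    """
    n, k = X.shape
    beta = np.zeros(k)
    ybar = float(np.average(y, weights=w))
    ybar = min(max(ybar, 1e-10), 1 - 1e-10)
    beta[0] = np.log(ybar / (1 - ybar))
    ll = _bernoulli_loglik(y, expit(X @ beta), w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        var = np.clip(mu * (1 - mu), 1e-10, None)
        wvar = w * var
        z = eta + (y - mu) / var
        WX = X * wvar[:, None]
        H = X.T @ WX
        try:
            beta_new = np.linalg.solve(H, WX.T @ z)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                "information matrix is singular during IRLS (possible separation "
                "or collinearity)",
                beta,
            )
        # step-halving safeguard: never accept a likelihood decrease
        step = beta_new - beta
        ll_new = _bernoulli_loglik(y, expit(X @ beta_new), w)
        halvings = 0
        while ll_new < ll - 1e-10 and halvings < 25:
            step /= 2.0
            beta_new = beta + step
            ll_new = _bernoulli_loglik(y, expit(X @ beta_new), w)
            halvings += 1
        delta = float(np.max(np.abs(beta_new - beta)))
        beta, ll = beta_new, ll_new
        if np.max(np.abs(beta)) > _MAX_ABS_BETA:
            raise ConvergenceError(
                "coefficients diverged during IRLS (|beta| > "
                f"{_MAX_ABS_BETA:g}); data are likely separable",
                beta,
            )
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"IRLS did not converge in {max_iter} iterations "
            f"(last max coefficient change {delta:.3g})",
            beta,
        )
    mu = expit(X @ beta)
    wvar = w * np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * wvar[:, None]))
    return beta, cov, ll, converged, it


class BorderLogit:
    """Logistic regression of border labels on genomic features.

    Parameters
    ----------
    endog : array of 0/1 border labels, one per genomic bin.
    exog : n x p feature matrix (no intercept column; one is added).
    feature_names : labels for the p columns.
    freq_weights : optional per-row frequency weights (e.g., collapsed
        contingency counts).
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        feature_names: Sequence[str] | None = None,
        freq_weights: np.ndarray | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog.reshape(-1, 1)
        self.exog = exog
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog row counts differ")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j + 1}" for j in range(exog.shape[1])]
        )
        if len(self.feature_names) != exog.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.freq_weights = (
            np.asarray(freq_weights, dtype=float)
            if freq_weights is not None
            else np.ones(self.endog.shape[0])
        )
        w = self.freq_weights
        if (w <= 0).any():
            raise ValueError("freq_weights must be positive")
        pos = float(w[self.endog == 1].sum())
        if pos == 0 or pos == float(w.sum()):
            raise ValueError("endog must contain both classes")

    @classmethod
    def from_feature_matrix(cls, matrix: FeatureMatrix) -> "BorderLogit":
        return cls(matrix.Y, matrix.X, matrix.feature_names)

    @property
    def n_obs(self) -> float:
        return float(self.freq_weights.sum())

    @property
    def p(self) -> int:
        return self.exog.shape[1]

    def _null_loglik(self) -> float:
        w = self.freq_weights
        ybar = float(np.average(self.endog, weights=w))
        ybar = min(max(ybar, 1e-12), 1 - 1e-12)
        return _bernoulli_loglik(self.endog, np.full_like(self.endog, ybar), w)

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> "BorderLogitResults":
        """Maximum-likelihood fit by IRLS.

        Convergence is declared when the largest absolute coefficient
        change drops below ``tol``.  Separation or non-convergence raises
        :class:`ConvergenceError` carrying the last iterate; a singular
        design raises :class:`CollinearityError` naming the dependent
        columns.
        """
        if self.n_obs <= self.p:
            raise ValueError("need more observations than features")
        X, y, w = self.exog, self.endog, self.freq_weights
        if (w == 1).all():
            collapsed = _collapse_binary(X, y)
            if collapsed is not None:
                X, y, w = collapsed
        design = np.column_stack([np.ones(X.shape[0]), X])
        names = ["const"] + self.feature_names
        _check_rank(design * np.sqrt(w)[:, None], names)
        beta, cov, ll, converged, n_iter = _irls(design, y, w, tol, max_iter)
        return BorderLogitResults(
            model=self,
            params=beta,
            cov_params=cov,
            llf=ll,
            null_llf=self._null_loglik(),
            converged=converged,
            n_iter=n_iter,
            method="irls",
        )

    def fit_regularized(
        self,
        lambda_grid: np.ndarray | None = None,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        n_folds: int = 10,
        seed: int = 0,
        standardize: bool = False,
        tol: float = 1e-8,
        max_iter: int = 5000,
    ) -> "BorderLogitResults":
        """L1-regularized fit with cross-validated penalty.

        The coefficient path is computed over a log-spaced ``lambda`` grid
        (from the smallest penalty that zeroes every slope down by
        ``lambda_min_ratio``), the penalty minimizing the mean
        cross-validated binomial deviance is selected, and the model is
        refit on all data at that penalty.  The intercept is never
        penalized; features are not standardized by default because
        coordinate-mode values already share the [0, 1] scale.
        """
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import StratifiedKFold

        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        X, y, w = self.exog, self.endog, self.freq_weights
        if not np.any(X):
            raise ValueError("all-zero design matrix")
        scale = X.std(axis=0, ddof=0) if standardize else np.ones(self.p)
        scale[scale == 0] = 1.0
        Xs = X / scale

        n = self.n_obs
        ybar = float(np.average(y, weights=w))
        if lambda_grid is None:
            lam_max = float(np.max(np.abs((Xs * w[:, None]).T @ (y - ybar))) / n)
            lam_max = max(lam_max, 1e-12)
            lambda_grid = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
        lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

        def _sk_fit(Xt, yt, wt, lam, coef0=None):
            # lasso objective: (1/N) sum loss + lam * ||b||_1  <=>  C = 1/(N*lam)
            clf = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (lam * float(wt.sum())),
                solver="saga",
                fit_intercept=True,
                tol=tol,
                max_iter=max_iter,
            )
            clf.fit(Xt, yt, sample_weight=wt)
            b0, b = clf.intercept_[0], clf.coef_[0]
            if not b.any():
                # saga can stop prematurely under full shrinkage; the
                # unpenalized intercept then has a closed form
                m = float(np.average(yt, weights=wt))
                m = min(max(m, 1e-12), 1 - 1e-12)
                b0 = float(np.log(m / (1 - m)))
            return b0, b

        # stratified, seeded folds on the original rows
        classes, class_counts = np.unique(y, return_counts=True)
        min_class = int(class_counts.min())
        folds = min(n_folds, min_class)
        if folds < 2:
            raise ValueError(
                "cannot build cross-validation folds with both classes present"
            )
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_dev = np.zeros(len(lambda_grid))
        for train, test in skf.split(Xs, y):
            for i, lam in enumerate(lambda_grid):
                b0, b = _sk_fit(Xs[train], y[train], w[train], lam)
                mu = expit(b0 + Xs[test] @ b)
                cv_dev[i] += -2.0 * _bernoulli_loglik(y[test], mu, w[test])
        cv_dev /= float(w.sum())
        best = int(np.argmin(cv_dev))
        lam_best = float(lambda_grid[best])
        b0, b = _sk_fit(Xs, y, w, lam_best)
        params = np.concatenate([[b0], b / scale])
        mu = expit(params[0] + X @ (params[1:]))
        ll = _bernoulli_loglik(y, mu, w)
        return BorderLogitResults(
            model=self,
            params=params,
            cov_params=None,
            llf=ll,
            null_llf=self._null_loglik(),
            converged=True,
            n_iter=0,
            method="l1",
            lambda_=lam_best,
            lambda_path=lambda_grid,
            cv_deviance=cv_dev,
        )


class BorderLogitResults:
    """Fitted multiple logistic regression.

    Attributes follow statsmodels naming: ``params`` (intercept first),
    ``bse``, ``tvalues`` (the Wald statistic W = beta / se), ``pvalues``
    (two-sided normal), ``llf``, ``aic``.  L1 fits carry no standard
    errors: ``bse``/``tvalues``/``pvalues`` raise for them.
    """

    def __init__(
        self,
        model: BorderLogit,
        params: np.ndarray,
        cov_params: np.ndarray | None,
        llf: float,
        null_llf: float,
        converged: bool,
        n_iter: int,
        method: str,
        lambda_: float | None = None,
        lambda_path: np.ndarray | None = None,
        cv_deviance: np.ndarray | None = None,
    ):
        self.model = model
        self._params = np.asarray(params)
        self._cov = cov_params
        self.llf = float(llf)
        self.null_llf = float(null_llf)
        self.converged = converged
        self.n_iter = n_iter
        self.method = method
        self.lambda_ = lambda_
        self.lambda_path = lambda_path
        self.cv_deviance = cv_deviance
        self.names = ["const"] + list(model.feature_names)

    # -- estimates -------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params, index=self.names)

    @property
    def beta0(self) -> float:
        return float(self._params[0])

    @property
    def betas(self) -> pd.Series:
        return self.params.iloc[1:]

    def _require_cov(self) -> np.ndarray:
        if self._cov is None:
            raise ValueError(
                "standard errors are not available for an L1-regularized fit"
            )
        return self._cov

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self._require_cov())), index=self.names)

    @property
    def tvalues(self) -> pd.Series:
        """Wald statistics W = beta_hat / se(beta_hat)."""
        return self.params / self.bse

    wald = tvalues

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2.0 * norm.sf(np.abs(self.tvalues)), index=self.names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    # -- diagnostics -----------------------------------------------------
    @property
    def df_model(self) -> int:
        return self.model.p

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def null_deviance(self) -> float:
        return -2.0 * self.null_llf

    def deviance_ratio(self, explained: bool = False) -> float:
        """Fitted-to-null deviance ratio (lower is a better fit).

        With ``explained=True`` returns the complementary fraction of
        null deviance explained, 1 - D_fit / D_null.
        """
        ratio = self.deviance / self.null_deviance
        return 1.0 - ratio if explained else ratio

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * (self.model.p + 1)

    @property
    def support(self) -> list[str]:
        """Names of influential features (nonzero coefficient)."""
        return [n for n, b in self.betas.items() if b != 0.0]

    # -- presentation ----------------------------------------------------
    def wald_frame(
        self, alpha: float = 0.05, n_tests: int | None = None
    ) -> pd.DataFrame:
        """Per-coefficient Wald inference with Bonferroni significance.

        ``significant`` is true when the two-sided p-value falls below
        ``alpha / n_tests``; ``n_tests`` defaults to the number of slope
        coefficients in the model at hand.
        """
        self._require_cov()
        if n_tests is None:
            n_tests = max(self.model.p, 1)
        ci = self.conf_int()
        df = pd.DataFrame(
            {
                "beta": self.params,
                "se": self.bse,
                "W": self.tvalues,
                "p_value": self.pvalues,
                "ci_low": ci["ci_low"],
                "ci_high": ci["ci_high"],
            }
        )
        df["significant"] = df["p_value"] < (alpha / n_tests)
        return df

    def summary(self) -> str:
        lines = [
            "Border multiple logistic regression",
            f"  estimator: {self.method}    n_obs: {self.model.n_obs:.0f}    "
            f"features: {self.model.p}",
            f"  log-likelihood: {self.llf:.4f}    AIC: {self.aic:.4f}",
            f"  deviance ratio (fitted/null): {self.deviance_ratio():.6f}",
        ]
        if self.method == "l1":
            lines.append(f"  selected lambda: {self.lambda_:.6g}")
            lines.append(f"  influential features: {self.support}")
            body = self.params.to_frame("beta")
        else:
            lines.append(f"  converged: {self.converged} in {self.n_iter} iterations")
            body = self.wald_frame()
        return "\n".join(lines) + "\n" + body.to_string()


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of one feature against the full model."""

    feature: str
    D: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_logistic_irls(
    matrix: FeatureMatrix, tol: float = 1e-8, max_iter: int = 100
) -> BorderLogitResults:
    """Unpenalized maximum-likelihood fit of the full model."""
    return BorderLogit.from_feature_matrix(matrix).fit(tol=tol, max_iter=max_iter)


def fit_logistic_l1(
    matrix: FeatureMatrix,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    **kwargs,
) -> BorderLogitResults:
    """L1 fit with cross-validated penalty selection."""
    return BorderLogit.from_feature_matrix(matrix).fit_regularized(
        lambda_grid=lambda_grid, n_folds=n_folds, seed=seed, **kwargs
    )


def wald_inference(
    fit: BorderLogitResults, alpha: float = 0.05, n_tests: int | None = None
) -> pd.DataFrame:
    """Wald statistics, p-values, CIs and Bonferroni flags for a fit."""
    return fit.wald_frame(alpha=alpha, n_tests=n_tests)


def lrt(matrix: FeatureMatrix, feature: str) -> LRTResult:
    """Likelihood-ratio test for one feature.

    Fits the full model M1 and the reduced model M2 without the feature;
    D = 2 (lnL_M1 - lnL_M2) is referenced to chi-squared with 1 df.
    """
    if feature not in matrix.feature_names:
        raise KeyError(f"unknown feature {feature!r}")
    keep = [n for n in matrix.feature_names if n != feature]
    idx = [matrix.feature_names.index(n) for n in keep]
    reduced_matrix = FeatureMatrix(
        Y=matrix.Y,
        X=matrix.X[:, idx],
        feature_names=keep,
        mode=matrix.mode,
        bin_index=matrix.bin_index,
    )
    try:
        reduced = fit_logistic_irls(reduced_matrix)
    except (ConvergenceError, CollinearityError) as exc:
        raise RuntimeError(f"reduced model (M2) failed to fit: {exc}") from exc
    col = matrix.X[:, matrix.feature_names.index(feature)]
    if np.ptp(col) == 0:
        # a constant column adds nothing; M1 and M2 are the same model
        return LRTResult(
            feature=feature,
            D=0.0,
            df=1,
            p_value=1.0,
            loglik_full=reduced.llf,
            loglik_reduced=reduced.llf,
        )
    try:
        full = fit_logistic_irls(matrix)
    except (ConvergenceError, CollinearityError) as exc:
        raise RuntimeError(f"full model (M1) failed to fit: {exc}") from exc
    D = max(2.0 * (full.llf - reduced.llf), 0.0)
    return LRTResult(
        feature=feature,
        D=D,
        df=1,
        p_value=float(chi2.sf(D, df=1)),
        loglik_full=full.llf,
        loglik_reduced=reduced.llf,
    )


def expand_interactions(
    matrix: FeatureMatrix, pairs: Sequence[tuple[str, str]]
) -> FeatureMatrix:
    """Append one elementwise-product column per feature pair.

    The new column for (A, B) is named ``"A:B"``; marginal columns are
    retained, so the expanded model is the two-way interaction model.
    """
    seen: set[tuple[str, str]] = set()
    cols = [matrix.X]
    names = list(matrix.feature_names)
    for a, b in pairs:
        if a not in matrix.feature_names or b not in matrix.feature_names:
            missing = a if a not in matrix.feature_names else b
            raise KeyError(f"interaction names unknown feature {missing!r}")
        if (a, b) in seen:
            raise ValueError(f"duplicate interaction pair ({a}, {b})")
        seen.add((a, b))
        ia, ib = matrix.feature_names.index(a), matrix.feature_names.index(b)
        cols.append((matrix.X[:, ia] * matrix.X[:, ib]).reshape(-1, 1))
        names.append(f"{a}:{b}")
    return FeatureMatrix(
        Y=matrix.Y,
        X=np.hstack(cols),
        feature_names=names,
        mode=matrix.mode,
        bin_index=matrix.bin_index,
    )


def all_pairs(feature_names: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered feature pairs, for the full two-way interaction model."""
    return [
        (a, b)
        for i, a in enumerate(feature_names)
        for b in feature_names[i + 1 :]
    ]


def fit_metrics(fit: BorderLogitResults, matrix: FeatureMatrix | None = None):
    """(deviance ratio, AIC) of a converged fit."""
    return fit.deviance_ratio(), fit.aic
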