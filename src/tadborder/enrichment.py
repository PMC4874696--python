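"""Enrichment test of genomic features at domain borders.

The classical 2x2 contingency analysis (feature presence inside versus
outside border bins) and its reformulation as a simple logistic
regression, whose slope is exactly the natural log of the odds ratio for
a binary feature.  The test is marginal: it ignores all other features,
which is precisely the weakness the multiple regression addresses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import FeatureMatrix
from .mlr import BorderLogit, BorderLogitResults, CollinearityError, ConvergenceError

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "odds_ratio",
    "contingency_from_vectors",
    "enrichment_test",
    "enrichment_scan",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Border-by-feature counts.

    a: inside border, feature present;  b: inside border, feature absent;
    c: outside border, feature present; d: outside border, feature absent.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must contain at least one count")


@dataclass(frozen=True)
class EnrichmentResult:
    """Simple-logistic enrichment of one feature at borders."""

    feature: str
    odds_ratio: float
    beta: float
    se: float
    W: float
    p_value: float
    ci_low: float
    ci_high: float
    significant: bool | None = None
    error: str | None = None


def odds_ratio(table: ContingencyTable, haldane: bool = False) -> float:
    """Ratio of inside-border odds to outside-border odds, (a/b)/(c/d).

    OR > 1 means enrichment, OR < 1 depletion.  A zero cell makes the OR
    0 or infinite; with ``haldane=True`` the Haldane–Anscombe +0.5
    correction is applied to every cell instead (off by default).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b == 0 or c == 0:
        return float("inf")
    if a == 0 or d == 0:
        return 0.0 if a == 0 else float("inf")
    return (a / b) / (c / d)


def contingency_from_vectors(
    Y: np.ndarray, x: np.ndarray, presence_threshold: float = 0.0
) -> ContingencyTable:
    """Build the 2x2 table from the border labels and one feature column.

    For coordinate-mode fractional values, "feature present" means a
    value strictly greater than ``presence_threshold`` (default 0).
    """
    Y = np.asarray(Y).astype(bool)
    present = np.asarray(x) > presence_threshold
    return ContingencyTable(
        a=int(np.sum(Y & present)),
        b=int(np.sum(Y & ~present)),
        c=int(np.sum(~Y & present)),
        d=int(np.sum(~Y & ~present)),
    )


def enrichment_test(
    Y: np.ndarray, x: np.ndarray, feature: str = "feature", alpha: float = 0.05
) -> EnrichmentResult:
    """Simple logistic regression of the border labels on one feature.

    Fits ln(P/(1-P)) = beta0 + beta x by maximum likelihood and reports
    the slope, its standard error, the Wald statistic W = beta/se, the
    two-sided normal p-value and the 95% confidence interval.  For a
    binary feature the slope equals ln(OR) of the corresponding 2x2
    table exactly.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"feature {feature!r} is constant")
    fit = BorderLogit(Y, x.reshape(-1, 1), [feature]).fit()
    return _result_from_fit(fit, feature, alpha=alpha, n_tests=1)


def _result_from_fit(
    fit: BorderLogitResults, feature: str, alpha: float, n_tests: int
) -> EnrichmentResult:
    beta = float(fit.betas.iloc[0])
    se = float(fit.bse.iloc[1])
    W = beta / se
    p = float(fit.pvalues.iloc[1])
    ci = fit.conf_int().iloc[1]
    return EnrichmentResult(
        feature=feature,
        odds_ratio=float(np.exp(beta)),
        beta=beta,
        se=se,
        W=W,
        p_value=p,
        ci_low=float(ci["ci_low"]),
        ci_high=float(ci["ci_high"]),
        significant=p < alpha / n_tests,
    )


def enrichment_scan(
    matrix: FeatureMatrix, alpha: float = 0.05
) -> list[EnrichmentResult]:
    """One marginal enrichment test per feature with Bonferroni flags.

    Each feature is tested alone (ignoring all others); the significance
    flag uses the Bonferroni-adjusted threshold ``alpha / p``.  A feature
    whose fit fails is reported with its error rather than aborting the
    scan.
    """
    n_tests = max(matrix.p, 1)
    results: list[EnrichmentResult] = []
    for j, name in enumerate(matrix.feature_names):
        x = matrix.X[:, j]
        try:
            if np.ptp(x) == 0:
                raise ValueError(f"feature {name!r} is constant")
            fit = BorderLogit(matrix.Y, x.reshape(-1, 1), [name]).fit()
            results.append(_result_from_fit(fit, name, alpha, n_tests))
        except (ValueError, ConvergenceError, CollinearityError) as exc:
            results.append(
                EnrichmentResult(
                    feature=name,
                    odds_ratio=float("nan"),
                    beta=float("nan"),
                    se=float("nan"),
                    W=float("nan"),
                    p_value=float("nan"),
                    ci_low=float("nan"),
                    ci_high=float("nan"),
                    significant=None,
                    error=str(exc),
                )
            )
    return results
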