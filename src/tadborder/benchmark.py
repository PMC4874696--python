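"""Method-comparison harness: MLR vs enrichment test vs random forests.

Replicated threshold-model simulations are scored by how well each
method recovers the causal features: squared correlation between true
and estimated parameters, the rate at which the top-ranked feature is
causal, the family-wise empirical type-I error at a fixed significance
threshold, and ROC AUC over feature scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .binning import FeatureMatrix
from .enrichment import enrichment_test
from .mlr import CollinearityError, ConvergenceError, fit_logistic_irls
from .simulate import (
    simulate_threshold_response,
    solve_p0_p1,
    synth_feature_matrix,
)

__all__ = [
    "BenchmarkResult",
    "recovery_r2",
    "rank_first_rate",
    "type1_error_rate",
    "roc_auc",
    "rf_comparator",
    "run_comparison",
    "ARCHITECTURAL_PROTEIN_PRESET",
]

logger = logging.getLogger(__name__)

# Known or suspected human architectural proteins used as ROC positives
# when scoring real GM12878-style analyses.
ARCHITECTURAL_PROTEIN_PRESET = (
    "CTCF",
    "RAD21",
    "YY1",
    "ZBTB33",  # Kaiso
    "MAZ",
    "JUND",
    "ZNF143",
    "EZH2",
)


@dataclass
class BenchmarkResult:
    """Long-format per-(replicate, method, feature) records.

    ``records`` columns: replicate, method, feature, score, p_value,
    causal.  ``n_failed`` counts replicates excluded due to fit errors.
    """

    records: pd.DataFrame
    alpha: float = 1e-5
    n_failed: int = 0
    replicate_seeds: list[int] = field(default_factory=list)

    def for_method(self, method: str) -> pd.DataFrame:
        return self.records[self.records["method"] == method]

    def rank_first_rate(self, method: str) -> float:
        reps = [g for _, g in self.for_method(method).groupby("replicate")]
        return rank_first_rate(
            [g[["feature", "score"]] for g in reps],
            [set(g.loc[g["causal"], "feature"]) for g in reps],
        )

    def type1_error_rate(self, method: str, alpha: float | None = None) -> float:
        df = self.for_method(method)
        if df["p_value"].isna().all():
            raise ValueError(f"no p-values available for method {method!r}")
        return type1_error_rate(df, alpha=alpha if alpha is not None else self.alpha)


def recovery_r2(true_betas: np.ndarray, est_betas: np.ndarray) -> float:
    """Squared Pearson correlation between true and estimated parameter
    values, in percent (scale-free: est = 2*true + 1 scores 100%)."""
    t = np.asarray(true_betas, dtype=float)
    e = np.asarray(est_betas, dtype=float)
    if t.shape != e.shape or t.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        raise ValueError("zero variance makes R^2 undefined")
    r, _ = pearsonr(t, e)
    return float(r * r * 100.0)


def rank_first_rate(
    replicate_scores: list[pd.DataFrame], causal_sets: list[set[str]]
) -> float:
    """Percent of replicates whose top-scoring feature is causal.

    A tie at the top involving any non-causal feature counts as a
    failure: a method that cannot separate the causal feature from the
    rest gets no credit for it.
    """
    if len(replicate_scores) != len(causal_sets):
        raise ValueError("replicate count mismatch")
    if not replicate_scores:
        return float("nan")
    hits = 0
    for scores, causal in zip(replicate_scores, causal_sets):
        if scores["score"].isna().any():
            raise ValueError("missing scores in a replicate")
        top = scores["score"].max()
        top_features = set(scores.loc[scores["score"] == top, "feature"])
        if len(top_features) == 1 and top_features <= causal:
            hits += 1
    return 100.0 * hits / len(replicate_scores)


def type1_error_rate(records: pd.DataFrame, alpha: float = 1e-5) -> float:
    """Family-wise empirical type-I error, in percent.

    The fraction of replicates in which at least one non-causal feature
    reaches ``p < alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    grouped = records.groupby("replicate")
    n = grouped.ngroups
    if n == 0:
        return float("nan")
    fp = sum(
        bool((g.loc[~g["causal"], "p_value"] < alpha).any()) for _, g in grouped
    )
    return 100.0 * fp / n


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC of score-ranked features.

    Ties are handled by midrank, so the result equals the Mann-Whitney
    U statistic divided by n1 * n0.
    """
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def rf_comparator(
    matrix: FeatureMatrix,
    n_trees: int = 500,
    seed: int = 0,
    max_features: str | float = "sqrt",
) -> pd.Series:
    """Random-forest variable importances (mean impurity decrease).

    The non-parametric comparator: an ensemble classifier predicting
    border labels from the feature matrix, scoring each feature by mean
    impurity decrease.  Deterministic given the seed.
    """
    from sklearn.ensemble import RandomForestClassifier

    y = np.asarray(matrix.Y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate border labels: only one class present")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(matrix.X, y)
    return pd.Series(clf.feature_importances_, index=matrix.feature_names)


def _draw_causal_set(
    p: int, rng: np.random.Generator, sizes: tuple[int, ...]
) -> tuple[int, ...]:
    k = int(rng.choice(sizes))
    return tuple(sorted(rng.choice(p, size=k, replace=False).tolist()))


def run_comparison(
    reps: int = 100,
    n_rows: int = 1_000_000,
    p_features: int = 11,
    odds_ratio: float = 4.0,
    border_rate: float = 0.01,
    sparsity: float = 0.97,
    correlation: float = 0.25,
    causal_sizes: tuple[int, ...] = (1, 2, 3),
    methods: tuple[str, ...] = ("MLR", "ET"),
    alpha: float = 1e-5,
    seed: int = 0,
    rf_trees: int = 100,
    rf_subsample: int | None = None,
) -> BenchmarkResult:
    """Replicated threshold-model comparison of MLR, ET and RF.

    Each replicate draws a sparse correlated feature matrix, a random
    causal subset (size uniform over ``causal_sizes``), solves (p0, p1)
    for the requested odds ratio at the realized exposure rate, draws
    border labels from the threshold model, and scores every method.
    Scores are beta parameters for MLR and ET and variable importances
    for RF (which provides no p-values).  Replicates where a fit fails
    are excluded and counted.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    n_failed = 0
    rep_seeds: list[int] = []
    names = [f"X{j + 1}" for j in range(p_features)]
    for rep in range(reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        rep_seeds.append(rep_seed)
        rep_rng = np.random.default_rng(rep_seed)
        X = synth_feature_matrix(n_rows, p_features, sparsity, correlation, rep_rng)
        causal = _draw_causal_set(p_features, rep_rng, causal_sizes)
        exposure = float((X[:, list(causal)] >= 0.5).any(axis=1).mean())
        if not (0 < exposure < 1):
            n_failed += 1
            logger.warning("replicate %d: degenerate exposure, skipped", rep)
            continue
        p0, p1 = solve_p0_p1(odds_ratio, border_rate, exposure)
        ds = simulate_threshold_response(X, causal, p0, p1, rep_rng)
        if ds.Y.sum() == 0 or ds.Y.sum() == len(ds.Y):
            n_failed += 1
            continue
        matrix = FeatureMatrix(Y=ds.Y, X=X, feature_names=names)
        try:
            rep_rows: list[dict] = []
            if "MLR" in methods:
                fit = fit_logistic_irls(matrix)
                for j, name in enumerate(names):
                    rep_rows.append(
                        {
                            "replicate": rep,
                            "method": "MLR",
                            "feature": name,
                            "score": float(fit.betas.iloc[j]),
                            "p_value": float(fit.pvalues.iloc[j + 1]),
                            "causal": j in causal,
                        }
                    )
            if "ET" in methods:
                for j, name in enumerate(names):
                    res = enrichment_test(matrix.Y, X[:, j], feature=name)
                    rep_rows.append(
                        {
                            "replicate": rep,
                            "method": "ET",
                            "feature": name,
                            "score": res.beta,
                            "p_value": res.p_value,
                            "causal": j in causal,
                        }
                    )
            if "RF" in methods:
                if rf_subsample is not None and rf_subsample < n_rows:
                    idx = rep_rng.choice(n_rows, size=rf_subsample, replace=False)
                    rf_matrix = FeatureMatrix(
                        Y=ds.Y[idx], X=X[idx], feature_names=names
                    )
                else:
                    rf_matrix = matrix
                importances = rf_comparator(
                    rf_matrix, n_trees=rf_trees, seed=rep_seed
                )
                for j, name in enumerate(names):
                    rep_rows.append(
                        {
                            "replicate": rep,
                            "method": "RF",
                            "feature": name,
                            "score": float(importances.iloc[j]),
                            "p_value": float("nan"),
                            "causal": j in causal,
                        }
                    )
        except (ConvergenceError, CollinearityError, ValueError) as exc:
            n_failed += 1
            logger.warning("replicate %d failed: %s", rep, exc)
            continue
        rows.extend(rep_rows)
    records = pd.DataFrame(
        rows,
        columns=["replicate", "method", "feature", "score", "p_value", "causal"],
    )
    return BenchmarkResult(
        records=records, alpha=alpha, n_failed=n_failed, replicate_seeds=rep_seeds
    )
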