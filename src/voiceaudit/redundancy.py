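"""Feature redundancy removal via distance correlation.

Distance correlation (Szekely) detects arbitrary — including non-monotonic —
dependence between two variables and lies in [0, 1]. The *Independence
Factor* algorithm walks the features in alphabetical (i.e., arbitrary but
fixed) order and greedily removes every later feature whose distance
correlation with a retained feature exceeds a threshold, leaving a subset in
which no retained pair exceeds it. A threshold sweep over
[1.0, 0.9, ..., 0.2] produces nested-size subsets; the parsimonious subset is
the smallest whose best model stays within a tolerance of the full-feature
performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

DEFAULT_THRESHOLDS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)


def _centered_distances(x: np.ndarray) -> np.ndarray:
    """Double-centered pairwise Euclidean distance matrix of a 1-d sample."""
    x = np.asarray(x, dtype=float).reshape(-1)
    d = np.abs(x[:, None] - x[None, :])
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def distance_correlation(x, y) -> float:
    """Empirical (biased-estimator) distance correlation of two vectors.

    Zero iff the empirical distance covariance vanishes; defined as 0 when
    either vector is constant (a constant carries no dependence and should be
    removable).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError("distance correlation requires n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    a = _centered_distances(x)
    b = _centered_distances(y)
    dcov2 = float((a * b).mean())
    dvar_x = float((a * a).mean())
    dvar_y = float((b * b).mean())
    denom = np.sqrt(dvar_x * dvar_y)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def pairwise_dcor(X: pd.DataFrame) -> pd.DataFrame:
    """Symmetric matrix of pairwise distance correlations between columns.

    Vectorized: each column's double-centered distance matrix is flattened
    once, so all pairwise distance covariances come from a single Gram
    product. Memory is held at float32 for wide/long tables.
    """
    cols = list(X.columns)
    n, p = X.shape
    if n < 4:
        raise ValueError("pairwise dcor requires n >= 4 rows")
    dtype = np.float64 if n * n * p <= 2e8 else np.float32
    flat = np.empty((p, n * n), dtype=dtype)
    const = np.zeros(p, dtype=bool)
    for j, c in enumerate(cols):
        v = X[c].to_numpy(dtype=float)
        if np.nanstd(v) == 0 or not np.all(np.isfinite(v)):
            v = np.where(np.isfinite(v), v, np.nanmedian(v) if
                         np.any(np.isfinite(v)) else 0.0)
        if np.std(v) == 0:
            const[j] = True
        flat[j] = _centered_distances(v).ravel()
    gram = (flat @ flat.T).astype(np.float64) / (n * n)
    dvar = np.diag(gram).copy()
    denom = np.sqrt(np.outer(dvar, dvar))
    with np.errstate(divide="ignore", invalid="ignore"):
        dcor = np.sqrt(np.clip(gram, 0.0, None) / denom)
    dcor[~np.isfinite(dcor)] = 0.0
    dcor[const, :] = 0.0
    dcor[:, const] = 0.0
    np.fill_diagonal(dcor, 1.0)
    dcor = np.clip((dcor + dcor.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(dcor, index=cols, columns=cols)


@dataclass
class FeatureSubset:
    """Result of one Independence Factor pass."""

    threshold: float
    retained: list[str]
    removed: dict[str, tuple[str, float]] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_dict(self) -> dict:
        return {"threshold": self.threshold, "retained": self.retained,
                "removed": {k: {"keeper": v[0], "dcor": v[1]}
                            for k, v in self.removed.items()}}


def _alpha_order(names) -> list[str]:
    """Case-insensitive lexicographic order (name itself breaks case ties)."""
    return sorted(names, key=lambda s: (s.lower(), s))


def independence_factor(X: pd.DataFrame | None, threshold: float,
                        dcor_matrix: pd.DataFrame | None = None
                        ) -> FeatureSubset:
    """Greedy alphabetical deduplication at one distance-correlation threshold.

    The first not-yet-removed feature (alphabetically) is retained; every
    later surviving feature whose dcor with it exceeds ``threshold`` is
    removed and attributed to that keeper; the pass continues with the next
    survivor. Pass either the raw table or a precomputed dcor matrix.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if dcor_matrix is None:
        if X is None:
            raise ValueError("need a feature table or a dcor matrix")
        if X.shape[1] < 2:
            return FeatureSubset(threshold, list(X.columns), {})
        dcor_matrix = pairwise_dcor(X)
    names = list(dcor_matrix.columns)
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    order = _alpha_order(names)
    removed: dict[str, tuple[str, float]] = {}
    retained: list[str] = []
    for i, keeper in enumerate(order):
        if keeper in removed:
            continue
        retained.append(keeper)
        for later in order[i + 1:]:
            if later in removed:
                continue
            d = float(dcor_matrix.loc[keeper, later])
            if d > threshold:
                removed[later] = (keeper, d)
    return FeatureSubset(threshold, retained, removed)


def threshold_sweep(X: pd.DataFrame,
                    thresholds=DEFAULT_THRESHOLDS,
                    dcor_matrix: pd.DataFrame | None = None
                    ) -> dict[float, FeatureSubset]:
    """Independence Factor at every threshold (matrix computed once)."""
    if dcor_matrix is None:
        dcor_matrix = pairwise_dcor(X)
    return {float(t): independence_factor(None, float(t), dcor_matrix)
            for t in thresholds}


@dataclass
class ParsimoniousChoice:
    threshold: float
    subset: FeatureSubset
    used_full_set: bool = False


def select_parsimonious(sweep: dict[float, FeatureSubset],
                        eval_results: dict[float, dict[str, float]],
                        full_auc: dict[str, float],
                        tolerance: float = 0.03) -> ParsimoniousChoice:
    """Smallest retained set whose best model is within ``tolerance`` of the
    best full-feature model; ties broken toward the smaller threshold.

    ``eval_results`` maps threshold -> {model name: median AUC}. If no
    threshold qualifies the full set is returned with a warning flag.
    """
    target = max(full_auc.values()) - tolerance
    qualifying = [(sweep[t].n_retained, t) for t in sweep
                  if t in eval_results and max(eval_results[t].values()) >= target]
    if not qualifying:
        full_t = max(sweep)
        return ParsimoniousChoice(full_t, sweep[full_t], used_full_set=True)
    _, best_t = min(qualifying)     # smallest size, then smallest threshold
    return ParsimoniousChoice(best_t, sweep[best_t])


def cluster_features(dcor_matrix: pd.DataFrame
                     ) -> tuple[list[str], np.ndarray]:
    """Average-linkage hierarchical clustering of the dcor matrix rows using
    Euclidean row distance; returns (dendrogram leaf order, linkage tree)."""
    names = list(dcor_matrix.columns)
    if len(names) < 2:
        return names, np.empty((0, 4))
    dist = pdist(dcor_matrix.to_numpy(dtype=float), metric="euclidean")
    tree = linkage(dist, method="average")
    order = [names[i] for i in leaves_list(tree)]
    return order, tree


def dcor_to_csv(dcor_matrix: pd.DataFrame, path) -> None:
    dcor_matrix.to_csv(path)
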