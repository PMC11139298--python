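"""Model-agnostic feature importance via Kernel SHAP.

Kernel SHAP approximates Shapley values by regressing a model's output on
randomly drawn feature coalitions: features absent from a coalition are
replaced by background values, and the regression coefficients (under the
Shapley kernel weighting, with the local-accuracy constraint enforced
exactly) are the per-feature attributions for one prediction.

Importance is aggregated the way the analysis pipeline reports it: per model,
the mean of absolute SHAP values over all explained test predictions, then
the mean over bootstrap splits, weighted by the model's median ROC AUC (an
important feature in a bad model should count less); across models, features
are ranked per model and the ranks averaged with the same performance
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import Lasso

from .evaluation import (EvalResult, ScoreDistribution, SplitPlan,
                         _seed_for, _split_rows, decision_scores, evaluate_table,
                         make_model)
from .features import FeatureTable, MedianImputer

BACKGROUND_CAP = 25        # k-means summary size for the SHAP background
DEFAULT_EXPLAIN_ROWS = 8   # test rows explained per split


def _shapley_size_distribution(m: int) -> np.ndarray:
    s = np.arange(1, m)
    w = (m - 1) / (s * (m - s))
    return w / w.sum()


class KernelShapExplainer:
    """Kernel SHAP for a single fitted model and background sample.

    ``predict_fn`` maps an (n, M) array to continuous scores. The background
    is summarized to at most ``BACKGROUND_CAP`` k-means centroids. Coalitions
    are drawn from the Shapley kernel distribution (so the regression is
    solved with uniform weights), and the efficiency constraint
    sum(phi) = f(x) - E[f] is eliminated algebraically, which makes the
    additivity identity hold exactly for every explanation.
    """

    def __init__(self, predict_fn, background: np.ndarray,
                 nsamples: int | None = None, seed: int = 0):
        bg = np.asarray(background, dtype=float)
        if bg.ndim != 2 or len(bg) == 0:
            raise ValueError("background must be a non-empty 2-d array")
        if len(bg) > BACKGROUND_CAP:
            km = KMeans(n_clusters=BACKGROUND_CAP, n_init=4,
                        random_state=seed).fit(bg)
            bg = km.cluster_centers_
        self.background = bg
        self.predict_fn = predict_fn
        self.base_value = float(np.mean(predict_fn(bg)))
        m = bg.shape[1]
        self.n_features = m
        self.nsamples = nsamples or min(2 * m + 512, 2**m - 2 if m < 30 else 10**9)
        self.rng = np.random.default_rng(seed)

    def _coalitions(self) -> np.ndarray:
        m = self.n_features
        if m == 1:
            return np.ones((1, 1))
        n_all = 2**m - 2 if m < 30 else None
        if n_all is not None and n_all <= self.nsamples:
            z = ((np.arange(1, n_all + 1)[:, None]
                  >> np.arange(m)[None, :]) & 1).astype(float)
            return z
        p = _shapley_size_distribution(m)
        sizes = self.rng.choice(np.arange(1, m), size=self.nsamples, p=p)
        z = np.zeros((self.nsamples, m))
        for i, s in enumerate(sizes):
            z[i, self.rng.choice(m, size=s, replace=False)] = 1.0
        return z

    def _kernel_weights(self, z: np.ndarray) -> np.ndarray | None:
        """Exact kernel weights when coalitions are fully enumerated; None
        when they were *sampled from* the kernel (uniform weights then)."""
        m = self.n_features
        if not (m < 30 and 2**m - 2 <= self.nsamples):
            return None
        from scipy.special import comb
        s = z.sum(axis=1)
        return (m - 1) / (comb(m, s) * s * (m - s))

    def shap_values(self, x: np.ndarray) -> np.ndarray:
        """Attributions phi (length M) for one row x;
        base_value + phi.sum() equals predict_fn(x) exactly."""
        x = np.asarray(x, dtype=float).reshape(-1)
        m = self.n_features
        fx = float(self.predict_fn(x[None, :])[0])
        e = fx - self.base_value
        if m == 1:
            return np.array([e])
        z = self._coalitions()
        bg = self.background
        # hybrid inputs: coalition features from x, the rest from background
        hybrids = np.where(z[:, None, :] == 1.0, x[None, None, :],
                           bg[None, :, :])
        preds = self.predict_fn(hybrids.reshape(-1, m))
        y = preds.reshape(len(z), len(bg)).mean(axis=1) - self.base_value
        w = self._kernel_weights(z)
        # eliminate the constraint: phi_last = e - sum(others)
        a = z[:, :-1] - z[:, -1:]
        b = y - z[:, -1] * e
        if w is not None:
            sw = np.sqrt(w)
            a = a * sw[:, None]
            b = b * sw
        if len(z) < 2 * m:
            # underdetermined: L1 selection, then least squares on support
            lasso = Lasso(alpha=1e-3 * max(np.abs(b).max(), 1e-9),
                          fit_intercept=False, max_iter=5000)
            lasso.fit(a, b)
            support = np.flatnonzero(np.abs(lasso.coef_) > 1e-12)
            phi_rest = np.zeros(m - 1)
            if len(support):
                sol, *_ = np.linalg.lstsq(a[:, support], b, rcond=None)
                phi_rest[support] = sol
        else:
            phi_rest, *_ = np.linalg.lstsq(a, b, rcond=None)
        phi = np.append(phi_rest, e - phi_rest.sum())
        return phi


def shap_importance(model, background: np.ndarray, X_test: np.ndarray,
                    nsamples: int | None = None, seed: int = 0,
                    return_values: bool = False):
    """Mean absolute Kernel SHAP attribution per feature over the test rows.

    ``model`` is any fitted estimator exposing predict_proba or
    decision_function. With ``return_values`` the raw per-row attributions
    and base value come back too (used by the additivity checks).
    """
    explainer = KernelShapExplainer(
        lambda X: decision_scores(model, X), background,
        nsamples=nsamples, seed=seed)
    X_test = np.asarray(X_test, dtype=float)
    values = np.vstack([explainer.shap_values(row) for row in X_test])
    mean_abs = np.abs(values).mean(axis=0)
    if return_values:
        return mean_abs, values, explainer.base_value
    return mean_abs


# ---------------------------------------------------------------------------
# Aggregation across splits and models
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    """Performance-weighted importance per (model, feature) and the
    cross-model weighted mean rank (1 = most important)."""

    weighted_importance: pd.DataFrame   # features x models
    ranks: pd.DataFrame                 # features x models, permutation 1..n
    model_weights: pd.Series            # median AUC per model
    weighted_mean_rank: pd.Series       # features, ascending = important

    def top_features(self, k: int = 5) -> list[str]:
        return list(self.weighted_mean_rank.nsmallest(k).index)


def _rank_descending(values: pd.Series) -> pd.Series:
    """Rank 1 = largest; ties broken by feature name for determinism."""
    order = sorted(values.index, key=lambda f: (-values[f], f))
    return pd.Series({f: i + 1 for i, f in enumerate(order)},
                     index=values.index, dtype=float)


def aggregate_importance(per_split: dict[str, list[np.ndarray]],
                         model_medians: dict[str, float],
                         feature_names: list[str]) -> ImportanceTable:
    """Combine per-split mean |SHAP| vectors into the importance table.

    Per model: mean over splits, multiplied by the model's median AUC.
    Cross-model: each model's importance ranking contributes to the mean rank
    with weight equal to that same median AUC.
    """
    models = list(per_split)
    wimp = {}
    for m in models:
        stack = np.vstack(per_split[m])
        wimp[m] = stack.mean(axis=0) * model_medians[m]
    imp = pd.DataFrame(wimp, index=feature_names)
    ranks = pd.DataFrame({m: _rank_descending(imp[m]) for m in models})
    weights = pd.Series({m: model_medians[m] for m in models})
    wmr = (ranks * weights).sum(axis=1) / weights.sum()
    return ImportanceTable(imp, ranks, weights, wmr.sort_values())


def compute_importance(table: FeatureTable, plan: SplitPlan,
                       model_names=("logreg_l1", "sgd_logloss_en",
                                    "random_forest", "mlp"),
                       n_explain: int = DEFAULT_EXPLAIN_ROWS,
                       nsamples: int | None = None, seed: int = 0,
                       score_dists: dict[str, ScoreDistribution] | None = None
                       ) -> ImportanceTable:
    """Fit each model on every split, explain a sample of its test rows, and
    aggregate. ``score_dists`` supplies precomputed median AUCs (weights);
    otherwise they are computed here."""
    X_all, y_all = table.X, table.y.to_numpy()
    per_split: dict[str, list[np.ndarray]] = {m: [] for m in model_names}
    medians: dict[str, float] = {}
    for m in model_names:
        if score_dists and m in score_dists:
            medians[m] = score_dists[m].median
        else:
            from .evaluation import fit_eval
            medians[m] = fit_eval(m, table, plan, seed=seed).median
        for s, (train_ids, test_ids) in enumerate(plan.assignments):
            tr, te = _split_rows(table, train_ids, test_ids)
            imputer = MedianImputer().fit(X_all[tr])
            X_tr = imputer.transform(X_all[tr]).to_numpy(dtype=float)
            X_te = imputer.transform(X_all[te]).to_numpy(dtype=float)
            y_tr = y_all[tr]
            if len(np.unique(y_tr)) < 2:
                continue
            rs = _seed_for(seed, s, m)
            model = make_model(m, random_state=rs)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_tr, y_tr)
            rng = np.random.default_rng(rs)
            rows = (X_te if len(X_te) <= n_explain else
                    X_te[rng.choice(len(X_te), n_explain, replace=False)])
            per_split[m].append(shap_importance(
                model, X_tr, rows, nsamples=nsamples, seed=rs))
    return aggregate_importance(per_split, medians, list(X_all.columns))


def topk_experiments(table: FeatureTable, importance: ImportanceTable,
                     plan: SplitPlan, k: int = 5,
                     model_names=("logreg_l1", "sgd_logloss_en",
                                  "random_forest", "mlp"),
                     single_feature_model: str = "logreg_l1",
                     with_null: bool = False, seed: int = 0
                     ) -> dict[str, EvalResult]:
    """Evaluate top-k features alone, everything minus top-k, and each top-k
    feature individually (single-feature runs use the L1 logistic model)."""
    top = importance.top_features(k)
    rest = [f for f in table.feature_names if f not in top]
    out: dict[str, EvalResult] = {}
    out["topk"] = evaluate_table(table.subset(top), plan, model_names,
                                 with_null=with_null, seed=seed)
    if rest:
        out["minus_topk"] = evaluate_table(table.subset(rest), plan,
                                           model_names, with_null=with_null,
                                           seed=seed)
    for f in top:
        out[f"single:{f}"] = evaluate_table(
            table.subset([f]), plan, (single_feature_model,),
            with_null=with_null, seed=seed)
    return out
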