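"""Bootstrapped classifier evaluation with permutation nulls.

Four classifiers of increasing complexity are evaluated on participant-level
bootstrapped group-shuffle splits: for each of 50 iterations a group-balanced
20% of the *participants* is held out (all samples of a participant stay on
one side, so no leakage across splits), the remaining 80% train the model,
and the test ROC AUC is recorded. A matched null distribution is produced by
permuting the training labels at participant level before fitting (test
labels untouched), and each model's observed median is compared to its null
with an empirical p-value; Benjamini-Hochberg controls the FDR across models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from statsmodels.stats.multitest import multipletests

from .features import FeatureTable, MedianImputer

log = logging.getLogger(__name__)

MODEL_NAMES = ("logreg_l1", "sgd_logloss_en", "random_forest", "mlp")

N_SPLITS = 50
TEST_FRACTION = 0.20
ALPHA = 0.05


def _seed_for(seed: int, split: int, model: str) -> int:
    h = np.random.SeedSequence(
        entropy=seed, spawn_key=(split, sum(map(ord, model))))
    return int(h.generate_state(1)[0] % (2**31 - 1))


def make_model(name: str, random_state: int = 0) -> Pipeline:
    """One of the four fixed classifier configurations, behind a
    standardization step (features carry heterogeneous physical units)."""
    if name == "logreg_l1":
        clf = LogisticRegression(penalty="l1", solver="liblinear",
                                 random_state=random_state)
    elif name == "sgd_logloss_en":
        clf = SGDClassifier(loss="log_loss", penalty="elasticnet",
                            max_iter=5000, early_stopping=True,
                            random_state=random_state)
    elif name == "random_forest":
        clf = RandomForestClassifier(random_state=random_state)
    elif name == "mlp":
        clf = MLPClassifier(hidden_layer_sizes=(100,), max_iter=1000,
                            alpha=1.0, random_state=random_state)
    else:
        raise ValueError(f"unknown model name: {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Continuous scores for ROC AUC: class-1 probability when available,
    else the decision function."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


# ---------------------------------------------------------------------------
# Split plan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    n_splits: int
    test_fraction: float
    seed: int
    assignments: tuple[tuple[frozenset, frozenset], ...]  # (train, test) ids

    def __len__(self) -> int:
        return self.n_splits


def make_split_plan(participants: pd.DataFrame, n_splits: int = N_SPLITS,
                    test_fraction: float = TEST_FRACTION,
                    seed: int = 0) -> SplitPlan:
    """Participant-level bootstrap group-shuffle plan.

    Each split holds out ``test_fraction`` of the participants, balanced
    between the two groups (equal per-group counts, so within one of exact
    balance overall); the rest train. Deterministic given ``seed``.
    """
    groups = participants.groupby("group")["id"].apply(list).to_dict()
    if set(groups) != {"UVFP", "control"}:
        raise ValueError("participants must contain groups 'UVFP' and 'control'")
    for g, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 participants")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    assignments = []
    for _ in range(n_splits):
        test: set[str] = set()
        for g in ("UVFP", "control"):
            ids = sorted(groups[g])
            n_test = max(1, round(test_fraction * len(ids)))
            test.update(rng.choice(ids, size=n_test, replace=False))
        train = frozenset(i for ids in groups.values() for i in ids) - test
        assignments.append((frozenset(train), frozenset(test)))
    return SplitPlan(n_splits, test_fraction, seed, tuple(assignments))


# ---------------------------------------------------------------------------
# Fitting and scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    model: str
    aucs: np.ndarray
    null_aucs: np.ndarray | None = None
    skipped_splits: list[int] = field(default_factory=list)

    @property
    def median(self) -> float:
        return float(np.median(self.aucs))

    @property
    def ci90(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.aucs, [5, 95])
        return float(lo), float(hi)

    @property
    def null_median(self) -> float:
        if self.null_aucs is None:
            raise ValueError("no null distribution attached")
        return float(np.median(self.null_aucs))

    def summary(self) -> dict:
        out = {"model": self.model, "median_auc": self.median,
               "ci90": list(self.ci90), "n_splits": int(len(self.aucs))}
        if self.null_aucs is not None:
            out["null_median_auc"] = self.null_median
        return out


def _split_rows(table: FeatureTable, train_ids, test_ids):
    in_train = table.groups.isin(train_ids).to_numpy()
    in_test = table.groups.isin(test_ids).to_numpy()
    return in_train, in_test


def _fit_scores(model_name: str, table: FeatureTable, plan: SplitPlan,
                permute_train: bool, base_seed: int | None) -> ScoreDistribution:
    seed = plan.seed if base_seed is None else base_seed
    X_all = table.X
    y_all = table.y.to_numpy()
    aucs, skipped = [], []
    for s, (train_ids, test_ids) in enumerate(plan.assignments):
        tr, te = _split_rows(table, train_ids, test_ids)
        if tr.sum() == 0 or te.sum() == 0:
            skipped.append(s)
            continue
        imputer = MedianImputer().fit(X_all[tr])
        X_tr = imputer.transform(X_all[tr]).to_numpy(dtype=float)
        X_te = imputer.transform(X_all[te]).to_numpy(dtype=float)
        y_tr = y_all[tr].copy()
        y_te = y_all[te]
        rs = _seed_for(seed, s, model_name)
        if permute_train:
            # permute labels at participant level on the training side only
            rng = np.random.default_rng(rs)
            tr_groups = table.groups[tr].to_numpy()
            uniq = sorted(set(tr_groups))
            label_of = {g: int(y_tr[tr_groups == g][0]) for g in uniq}
            permuted = rng.permutation([label_of[g] for g in uniq])
            new_label = dict(zip(uniq, permuted))
            y_tr = np.array([new_label[g] for g in tr_groups])
        if len(np.unique(y_tr)) < 2:
            log.warning("split %d: single-class training labels; skipped", s)
            skipped.append(s)
            continue
        model = make_model(model_name, random_state=rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X_tr, y_tr)
            scores = decision_scores(model, X_te)
        if len(np.unique(y_te)) < 2:
            skipped.append(s)
            continue
        aucs.append(roc_auc_score(y_te, scores))
    if not aucs:
        raise RuntimeError("every split was skipped; cannot score model")
    return ScoreDistribution(model_name, np.asarray(aucs),
                             skipped_splits=skipped)


def fit_eval(model_name: str, table: FeatureTable, plan: SplitPlan,
             seed: int | None = None) -> ScoreDistribution:
    """Observed bootstrap score distribution for one model."""
    return _fit_scores(model_name, table, plan, permute_train=False,
                       base_seed=seed)


def fit_null(model_name: str, table: FeatureTable, plan: SplitPlan,
             seed: int | None = None) -> ScoreDistribution:
    """Null distribution: training labels permuted at participant level."""
    null = _fit_scores(model_name, table, plan, permute_train=True,
                       base_seed=None if seed is None else seed + 104729)
    return null


def empirical_p(observed: ScoreDistribution) -> float:
    """Add-one permutation p-value of the observed median against the null:
    p = (1 + #{null >= median}) / (1 + n). Never returns 0."""
    if observed.null_aucs is None:
        raise ValueError("attach a null distribution first")
    n = len(observed.null_aucs)
    k = int(np.sum(observed.null_aucs >= observed.median))
    return (1 + k) / (1 + n)


def bh_adjust(pvalues, alpha: float = ALPHA):
    """Benjamini-Hochberg step-up: (rejected flags, adjusted p-values)."""
    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return np.array([], dtype=bool), np.array([])
    if len(p) == 1:
        return np.array([p[0] <= alpha]), p.copy()
    rejected, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, adj


@dataclass
class EvalResult:
    """Per-model score distributions + significance for one feature table."""

    feature_set: str
    task: str
    scores: dict[str, ScoreDistribution]
    pvalues: dict[str, float] = field(default_factory=dict)
    bh_rejected: dict[str, bool] = field(default_factory=dict)
    bh_adjusted: dict[str, float] = field(default_factory=dict)

    @property
    def median_aucs(self) -> dict[str, float]:
        return {m: s.median for m, s in self.scores.items()}

    @property
    def best_median(self) -> float:
        return max(self.median_aucs.values())

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set, "task": self.task,
            "models": {m: {**s.summary(), "p": self.pvalues.get(m),
                           "bh_rejected": self.bh_rejected.get(m),
                           "bh_adjusted": self.bh_adjusted.get(m)}
                       for m, s in self.scores.items()},
        }


def evaluate_table(table: FeatureTable, plan: SplitPlan,
                   model_names=MODEL_NAMES, with_null: bool = True,
                   alpha: float = ALPHA, seed: int | None = None) -> EvalResult:
    """Full evaluation of one feature table: observed + null distributions,
    empirical p-values and BH correction across the models."""
    scores: dict[str, ScoreDistribution] = {}
    for m in model_names:
        dist = fit_eval(m, table, plan, seed=seed)
        if with_null:
            dist.null_aucs = fit_null(m, table, plan, seed=seed).aucs
        scores[m] = dist
    result = EvalResult(table.feature_set, table.task, scores)
    if with_null:
        ps = {m: empirical_p(s) for m, s in scores.items()}
        rej, adj = bh_adjust([ps[m] for m in model_names], alpha=alpha)
        result.pvalues = ps
        result.bh_rejected = dict(zip(model_names, map(bool, rej)))
        result.bh_adjusted = dict(zip(model_names, map(float, adj)))
    return result


def results_table(results: dict[str, EvalResult]) -> pd.DataFrame:
    """Publication-style CSV frame: rows task x feature set, cells
    'median (p5-p95; null median)'."""
    rows = {}
    for key, res in results.items():
        row = {}
        for m, s in res.scores.items():
            lo, hi = s.ci90
            null = f"; {s.null_median:.2f}" if s.null_aucs is not None else ""
            row[m] = f"{s.median:.2f} ({lo:.2f}-{hi:.2f}{null})"
        rows[key] = row
    return pd.DataFrame(rows).T
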