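"""Recording-bias audit and mitigation.

Two dataset biases are probed and then mitigated:

* **Duration bias** — recordings of one group cropped to fixed lengths while
  the other group's vary. A classifier fed *audio duration alone* quantifies
  how much of the apparent performance the bias can explain. Mitigation trims
  the longer reading recordings to the fixed control duration (sustained
  vowels cannot be matched by trimming).
* **Intensity / gain bias** — one group recorded with extra microphone gain,
  inflating loudness-family features and the noise floor. The direction
  check flags intensity features whose patient mean exceeds the control mean
  (the counterintuitive direction for a weak-voice disorder); mitigation
  drops every intensity-category feature plus any feature whose distance
  correlation with one of them reaches a cutoff (0.3 or 0.4), computed on the
  trimmed reading samples.

Clinician ratings corroborate the audit: inter-rater reliability (ICC for
numeric scales, Light's kappa for the binary call), per-rater screening
accuracy, and models fed only the ratings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .evaluation import EvalResult, SplitPlan, evaluate_table
from .features import FeatureTable, build_feature_table, extract_feature_frame
from .redundancy import pairwise_dcor
from .synth import Recording

log = logging.getLogger(__name__)

AGREEMENT_CUTOFFS = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"))


def agreement_label(value: float) -> str:
    """Qualitative agreement label: poor < .40 <= fair < .60 <= good < .75
    <= excellent."""
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ReliabilityResult:
    variable: str
    statistic: str           # "ICC" | "lights_kappa"
    value: float

    @property
    def label(self) -> str:
        return agreement_label(self.value)


# ---------------------------------------------------------------------------
# Reliability statistics
# ---------------------------------------------------------------------------

def icc(ratings: np.ndarray, model: str = "absolute") -> float:
    """Single-rater intraclass correlation from ANOVA mean squares.

    ``ratings`` is an (n targets x k raters) complete numeric matrix. The
    default is the two-way random-effects, absolute-agreement, single-rater
    coefficient ICC(2,1); ``model="consistency"`` gives ICC(3,1).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (targets x >=2 raters)")
    if x.shape[0] < 5:
        raise ValueError("need at least 5 rated targets")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings matrix must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError("model must be 'absolute' or 'consistency'")
    if denom == 0:
        return 0.0
    return float((msr - mse) / denom)


def _pairwise_kappa(a: np.ndarray, b: np.ndarray) -> float:
    # Cohen's kappa; degenerate tables (a constant rater) count as 0
    if len(set(a)) < 2 and len(set(b)) < 2:
        return 1.0 if np.all(a == b) else 0.0
    k = cohen_kappa_score(a, b)
    return 0.0 if np.isnan(k) else float(k)


def lights_kappa(ratings: np.ndarray) -> float:
    """Light's kappa: mean pairwise Cohen's kappa across >= 2 raters of a
    categorical variable (targets x raters matrix)."""
    x = np.asarray(ratings)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be (targets x >=2 raters)")
    k = x.shape[1]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    return float(np.mean([_pairwise_kappa(x[:, i], x[:, j])
                          for i, j in pairs]))


def clinician_auc(calls: pd.DataFrame, truth: pd.Series) -> dict:
    """Screening accuracy of each rater's binary call.

    A binary rating admits a single operating point, so the AUC equals
    (sensitivity + specificity) / 2. ``calls`` columns are raters (values
    'yes'/'no' or 1/0) indexed like ``truth`` (1 = patient).
    """
    y = truth.astype(int)
    per_rater = {}
    for r in calls.columns:
        c = calls[r]
        pred = (c.map({"yes": 1, "no": 0}) if c.dtype == object
                else c.astype(int))
        pos, neg = y == 1, y == 0
        sens = float((pred[pos] == 1).mean()) if pos.any() else 0.0
        spec = float((pred[neg] == 0).mean()) if neg.any() else 0.0
        per_rater[r] = (sens + spec) / 2.0
    return {"per_rater": per_rater,
            "median": float(np.median(list(per_rater.values())))}


def rater_reliability(rater_table: pd.DataFrame) -> list[ReliabilityResult]:
    """ICC for each numeric 0-100 scale, Light's kappa for the binary call
    and the two ordinal recording-condition ratings."""
    numeric = ["severity", "roughness", "breathiness", "strain", "pitch",
               "loudness"]
    out = []
    wide = {v: rater_table.pivot(index="recording_id", columns="rater_id",
                                 values=v) for v in numeric
            + ["uvfp_call", "background_noise", "recording_loudness"]}
    for v in numeric:
        out.append(ReliabilityResult(v, "ICC", icc(wide[v].to_numpy())))
    for v in ("uvfp_call", "background_noise", "recording_loudness"):
        out.append(ReliabilityResult(
            v, "lights_kappa", lights_kappa(wide[v].to_numpy())))
    return out


# ---------------------------------------------------------------------------
# Rating-based models
# ---------------------------------------------------------------------------

_ORDINAL = {"None": 0, "Some": 1, "High": 2, "low": 0, "medium": 1, "high": 2}
_CAPEV = ("severity", "roughness", "breathiness", "strain", "pitch",
          "loudness")


def ratings_feature_table(rater_table: pd.DataFrame, manifest: pd.DataFrame,
                          feature_set: str = "clinician6") -> FeatureTable:
    """Average the ratings across raters per recording and expose them as a
    feature table: ``clinician6`` = the six 0-100 perceptual scales,
    ``clinician2`` = ordinal background-noise + recording-loudness."""
    group_of = manifest.drop_duplicates("participant_id").set_index(
        "participant_id")["group"]
    if feature_set == "clinician6":
        df = rater_table.groupby("recording_id")[list(_CAPEV)].mean()
    elif feature_set == "clinician2":
        enc = rater_table.assign(
            background_noise=rater_table["background_noise"].map(_ORDINAL),
            recording_loudness=rater_table["recording_loudness"].map(_ORDINAL))
        df = enc.groupby("recording_id")[
            ["background_noise", "recording_loudness"]].mean()
    else:
        raise ValueError(f"unknown rating feature set: {feature_set!r}")
    pid = rater_table.drop_duplicates("recording_id").set_index(
        "recording_id")["participant_id"]
    pid = pid.loc[df.index]
    y = (pid.map(group_of) == "UVFP").astype(int)
    return FeatureTable(df, y.rename("label"), pid.rename("participant_id"),
                        feature_set, "reading")


def ratings_models(rater_table: pd.DataFrame, manifest: pd.DataFrame,
                   plan: SplitPlan, model_names=("logreg_l1",
                                                 "sgd_logloss_en",
                                                 "random_forest", "mlp"),
                   with_null: bool = True, seed: int = 0
                   ) -> dict[str, EvalResult]:
    """Standard evaluation on the clinician6 and clinician2 feature sets."""
    out = {}
    for fs in ("clinician6", "clinician2"):
        table = ratings_feature_table(rater_table, manifest, fs)
        out[fs] = evaluate_table(table, plan, model_names,
                                 with_null=with_null, seed=seed)
    return out


# ---------------------------------------------------------------------------
# Bias probes
# ---------------------------------------------------------------------------

def duration_probe(recordings, manifest: pd.DataFrame, plan: SplitPlan,
                   task_filter: str = "reading",
                   model_names=("logreg_l1", "sgd_logloss_en",
                                "random_forest", "mlp"),
                   with_null: bool = False, seed: int = 0) -> EvalResult:
    """Can audio duration alone classify the groups? (It should not, unless
    the dataset carries a duration bias.)"""
    table = build_feature_table(recordings, manifest, "duration1", task_filter)
    return evaluate_table(table, plan, model_names, with_null=with_null,
                          seed=seed)


def intensity_direction_check(table: FeatureTable,
                              category_map: dict[str, str]) -> pd.DataFrame:
    """Group means of every intensity-category feature and a flag where the
    patient mean exceeds the control mean — the counterintuitive direction
    for a disorder characterized by a weak voice."""
    names = [f for f in table.feature_names
             if category_map.get(f) == "intensity"]
    if not names:
        raise ValueError("no intensity-category features present")
    pat = table.X.loc[table.y == 1, names].mean()
    ctl = table.X.loc[table.y == 0, names].mean()
    diff = pat - ctl
    return pd.DataFrame({"patient_mean": pat, "control_mean": ctl,
                         "difference": diff,
                         "patient_higher": diff > 0})


# ---------------------------------------------------------------------------
# Mitigation
# ---------------------------------------------------------------------------

def trim_to_match(recordings, target_duration: float,
                  task: str = "reading") -> tuple[list, list[str]]:
    """Truncate every reading recording to the fixed control duration.

    Recordings shorter than the target are excluded (returned in the second
    element) with a warning; other tasks pass through untouched.
    """
    kept, excluded = [], []
    n_target = None
    for rec in recordings:
        if rec.task != task:
            kept.append(rec)
            continue
        n_target = int(round(target_duration * rec.sample_rate))
        if len(rec.waveform) < n_target:
            log.warning("%s shorter than %.2f s target; excluded",
                        rec.recording_id, target_duration)
            excluded.append(rec.recording_id)
            continue
        kept.append(Recording(rec.recording_id, rec.participant_id, rec.task,
                              rec.segment_index,
                              rec.waveform[:n_target].copy(),
                              rec.sample_rate, dict(rec.true_params)))
    return kept, excluded


def remove_intensity_associated(table: FeatureTable,
                                category_map: dict[str, str],
                                dcor_cutoff: float,
                                dcor_matrix: pd.DataFrame | None = None
                                ) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop all intensity-category features plus any feature whose distance
    correlation with ANY of them reaches ``dcor_cutoff``.

    Returns the reduced table and a removal manifest attributing each removal
    to the triggering intensity feature and its dcor value.
    """
    if dcor_cutoff <= 0:
        raise ValueError("dcor_cutoff must be positive")
    names = table.feature_names
    intensity = [f for f in names if category_map.get(f) == "intensity"]
    if not intensity:
        raise ValueError("no intensity-category features in table")
    if dcor_matrix is None:
        dcor_matrix = pairwise_dcor(table.X)
    rows = [{"feature": f, "reason": "intensity category",
             "trigger": f, "dcor": 1.0} for f in intensity]
    removed = set(intensity)
    for f in names:
        if f in removed:
            continue
        vals = dcor_matrix.loc[f, intensity]
        if float(vals.max()) >= dcor_cutoff:
            trig = str(vals.idxmax())
            rows.append({"feature": f, "reason": "associated",
                         "trigger": trig, "dcor": float(vals.max())})
            removed.add(f)
    survivors = [f for f in names if f not in removed]
    if not survivors:
        raise ValueError(
            "dcor cutoff removed every feature; with few samples the "
            "empirical dcor of even independent pairs is biased upward — "
            "use more samples or a higher cutoff")
    manifest = pd.DataFrame(rows)
    return table.subset(survivors), manifest


@dataclass(frozen=True)
class MitigationConfig:
    dcor_cutoff: float = 0.3
    target_duration: float = 3.5     # the fixed control reading duration

    def __post_init__(self) -> None:
        if not (0 < self.dcor_cutoff < 1):
            raise ValueError("dcor_cutoff must be in (0, 1)")
        if self.target_duration <= 0:
            raise ValueError("target_duration must be > 0")


@dataclass
class MitigationResult:
    pre: EvalResult
    post: EvalResult
    removed: pd.DataFrame
    retained_features: list[str]
    excluded_recordings: list[str]

    @property
    def delta_best_median(self) -> float:
        return self.post.best_median - self.pre.best_median


def mitigation_eval(recordings, manifest: pd.DataFrame,
                    config: MitigationConfig, plan: SplitPlan,
                    model_names=("logreg_l1", "sgd_logloss_en",
                                 "random_forest", "mlp"),
                    category_map: dict[str, str] | None = None,
                    pre_features: pd.DataFrame | None = None,
                    with_null: bool = False, seed: int = 0
                    ) -> MitigationResult:
    """Full mitigation experiment on the reading task.

    Baseline: the biased reading-task table. Mitigated: recordings trimmed to
    the control duration, features re-extracted, intensity-associated
    features removed at the configured cutoff (dcor computed on the trimmed
    reading table, groups pooled), then the same evaluation.
    """
    from .features import load_category_map

    cmap = category_map or load_category_map()
    reading = [r for r in recordings if r.task == "reading"]
    pre_table = build_feature_table(reading, manifest, "egemaps88", "reading",
                                    features=pre_features)
    pre = evaluate_table(pre_table, plan, model_names, with_null=with_null,
                         seed=seed)

    trimmed, excluded = trim_to_match(reading, config.target_duration)
    man = manifest[~manifest["recording_id"].isin(excluded)]
    post_features = extract_feature_frame(trimmed, "egemaps88")
    post_table = build_feature_table(trimmed, man, "egemaps88", "reading",
                                     features=post_features)
    reduced, removal_manifest = remove_intensity_associated(
        post_table, cmap, config.dcor_cutoff)
    post = evaluate_table(reduced, plan, model_names, with_null=with_null,
                          seed=seed)
    return MitigationResult(pre, post, removal_manifest,
                            reduced.feature_names, excluded)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class BiasReport:
    duration_probe: EvalResult | None = None
    intensity_direction: pd.DataFrame | None = None
    reliability: list[ReliabilityResult] = field(default_factory=list)
    clinician: dict | None = None
    ratings_models: dict[str, EvalResult] = field(default_factory=dict)
    mitigation: dict[float, MitigationResult] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {}
        if self.duration_probe is not None:
            out["duration_probe"] = self.duration_probe.to_dict()
        if self.intensity_direction is not None:
            out["intensity_direction"] = {
                f: {"difference": float(r["difference"]),
                    "patient_higher": bool(r["patient_higher"])}
                for f, r in self.intensity_direction.iterrows()}
        out["reliability"] = [
            {"variable": r.variable, "statistic": r.statistic,
             "value": r.value, "label": r.label} for r in self.reliability]
        if self.clinician is not None:
            out["clinician_auc"] = self.clinician
        out["ratings_models"] = {k: v.to_dict()
                                 for k, v in self.ratings_models.items()}
        out["mitigation"] = {
            str(c): {"pre_best_median": m.pre.best_median,
                     "post_best_median": m.post.best_median,
                     "delta": m.delta_best_median,
                     "n_retained": len(m.retained_features),
                     "n_excluded_recordings": len(m.excluded_recordings)}
            for c, m in self.mitigation.items()}
        return out
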