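"""End-to-end orchestration: config, stage sequencing, artifact output.

``run_all`` executes the whole audit from a single config: synthesize (or
ingest) the cohort, extract features, sweep the redundancy thresholds,
evaluate every feature set, aggregate SHAP importance, audit the recording
biases and run the mitigation experiment. Every artifact is written as
CSV/JSON under the output directory together with a checksum manifest; a
second run with the same config reproduces the numbers exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bias as bias_mod
from . import synth
from .evaluation import MODEL_NAMES, evaluate_table, make_split_plan, results_table
from .explain import compute_importance, topk_experiments
from .features import (build_feature_table, extract_feature_frame,
                       load_category_map)
from .redundancy import pairwise_dcor, select_parsimonious, threshold_sweep

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single source of truth for a pipeline run (YAML-loadable)."""

    out_dir: str = "voiceaudit_run"
    seed: int = 0
    n_per_group: int = 20
    n_splits: int = 10
    tasks: tuple[str, ...] = ("reading", "vowel")
    feature_sets: tuple[str, ...] = ("egemaps88", "cpp4", "duration1")
    thresholds: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2)
    top_k: int = 5
    mitigation_cutoffs: tuple[float, ...] = (0.3, 0.4)
    model_names: tuple[str, ...] = MODEL_NAMES
    with_null: bool = True
    with_raters: bool = True
    with_shap: bool = True
    scenario: str = "default_biased"   # or bias_only / pathology_only / null
    manifest_path: str | None = None   # ingest instead of synthesizing

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("tasks", "feature_sets", "thresholds",
                    "mitigation_cutoffs", "model_names"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if self.manifest_path and not Path(self.manifest_path).exists():
            raise ValueError(f"manifest not found: {self.manifest_path}")
        if self.scenario not in ("default_biased", "bias_only",
                                 "pathology_only", "null"):
            raise ValueError(f"unknown scenario: {self.scenario!r}")
        for m in self.model_names:
            if m not in MODEL_NAMES:
                raise ValueError(f"unknown model: {m!r}")


def make_cohort(config: RunConfig) -> synth.Cohort:
    spec_fn = getattr(synth.CohortSpec, config.scenario)
    return synth.generate_cohort(spec_fn(n_per_group=config.n_per_group,
                                         seed=config.seed))


def ingest_manifest(manifest_path) -> tuple[list, pd.DataFrame]:
    """Load an on-disk cohort (manifest.csv + WAVs) back into recordings.

    Rows with missing or unreadable files are rejected with a log entry;
    duplicate recording ids are an error.
    """
    path = Path(manifest_path)
    man = pd.read_csv(path)
    if man["recording_id"].duplicated().any():
        raise ValueError("duplicate recording_id in manifest")
    recordings, kept_rows = [], []
    for _, row in man.iterrows():
        wav = path.parent / row["path"]
        try:
            w, sr = synth.read_wav(wav)
        except (FileNotFoundError, ValueError) as exc:
            log.warning("rejected %s: %s", row["recording_id"], exc)
            continue
        if len(w) == 0:
            log.warning("rejected %s: empty audio", row["recording_id"])
            continue
        recordings.append(synth.Recording(
            row["recording_id"], row["participant_id"], row["task"],
            int(row["segment_index"]), w, sr, {}))
        kept_rows.append(row)
    return recordings, pd.DataFrame(kept_rows).reset_index(drop=True)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=str))


def _checksum_dir(out: Path) -> dict[str, str]:
    sums = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "artifacts.json":
            sums[str(p.relative_to(out))] = hashlib.sha256(
                p.read_bytes()).hexdigest()[:16]
    return sums


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    A stage failure aborts with the stage name; artifacts written so far are
    left on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        t0 = time.time()
        stage = "synth"
        if config.manifest_path:
            recordings, manifest = ingest_manifest(config.manifest_path)
            cohort = None
        else:
            cohort = make_cohort(config)
            recordings, manifest = cohort.recordings, cohort.manifest
        manifest.to_csv(out / "manifest.csv", index=False)
        participants = (synth.participants_frame(cohort) if cohort is not None
                        else manifest.drop_duplicates("participant_id")
                        .rename(columns={"participant_id": "id"})
                        [["id", "group"]])
        log.info("stage synth: %d recordings (%.1fs)",
                 len(recordings), time.time() - t0)

        stage = "features"
        t0 = time.time()
        frames = {fs: extract_feature_frame(recordings, fs)
                  for fs in config.feature_sets}
        for fs, df in frames.items():
            df.to_csv(out / f"features_{fs}.csv")
        log.info("stage features: %s (%.1fs)",
                 {k: v.shape for k, v in frames.items()}, time.time() - t0)

        stage = "split_plan"
        plan = make_split_plan(participants, config.n_splits, seed=config.seed)

        stage = "evaluate"
        t0 = time.time()
        results = {}
        for task in config.tasks:
            for fs in config.feature_sets:
                table = build_feature_table(recordings, manifest, fs, task,
                                            features=frames[fs])
                results[f"{task}_{fs}"] = evaluate_table(
                    table, plan, config.model_names,
                    with_null=config.with_null, seed=config.seed)
                _write_json(out / f"eval_{task}_{fs}.json",
                            results[f"{task}_{fs}"].to_dict())
        results_table(results).to_csv(out / "performance_table.csv")
        log.info("stage evaluate: %d tables (%.1fs)", len(results),
                 time.time() - t0)

        stage = "reduce"
        t0 = time.time()
        if "egemaps88" in config.feature_sets:
            task = config.tasks[0]
            table = build_feature_table(recordings, manifest, "egemaps88",
                                        task, features=frames["egemaps88"])
            dmat = pairwise_dcor(table.X)
            dmat.to_csv(out / f"dcor_matrix_all_{task}.csv")
            sweep = threshold_sweep(table.X, config.thresholds,
                                    dcor_matrix=dmat)
            sweep_eval = {}
            for t, subset in sweep.items():
                res = evaluate_table(table.subset(subset.retained), plan,
                                     config.model_names, with_null=False,
                                     seed=config.seed)
                sweep_eval[t] = res.median_aucs
                _write_json(out / f"subset_{t:.1f}.json", subset.to_dict())
            full = sweep_eval[max(sweep_eval)]
            choice = select_parsimonious(sweep, sweep_eval, full)
            _write_json(out / "parsimonious.json",
                        {"threshold": choice.threshold,
                         "n_retained": choice.subset.n_retained,
                         "used_full_set": choice.used_full_set})
            log.info("stage reduce: chose %.1f (%d features, %.1fs)",
                     choice.threshold, choice.subset.n_retained,
                     time.time() - t0)

        stage = "explain"
        if config.with_shap and "egemaps88" in config.feature_sets:
            t0 = time.time()
            task = config.tasks[0]
            table = build_feature_table(recordings, manifest, "egemaps88",
                                        task, features=frames["egemaps88"])
            key = f"{task}_egemaps88"
            imp = compute_importance(table, plan, config.model_names,
                                     seed=config.seed,
                                     score_dists=results[key].scores)
            imp_df = imp.weighted_importance.copy()
            imp_df["weighted_mean_rank"] = imp.weighted_mean_rank
            imp_df.to_csv(out / f"importance_{task}_egemaps88.csv")
            top = imp.top_features(config.top_k)
            _write_json(out / "top5.json", {"features": top})
            topk = topk_experiments(table, imp, plan, config.top_k,
                                    config.model_names, seed=config.seed)
            _write_json(out / "topk_eval.json",
                        {k: v.to_dict() for k, v in topk.items()})
            log.info("stage explain: top-%d %s (%.1fs)", config.top_k, top,
                     time.time() - t0)

        stage = "audit"
        t0 = time.time()
        report = bias_mod.BiasReport()
        if "reading" in config.tasks:
            report.duration_probe = bias_mod.duration_probe(
                recordings, manifest, plan, "reading", config.model_names,
                seed=config.seed)
        if "egemaps88" in config.feature_sets:
            task = config.tasks[0]
            table = build_feature_table(recordings, manifest, "egemaps88",
                                        task, features=frames["egemaps88"])
            report.intensity_direction = bias_mod.intensity_direction_check(
                table, load_category_map())
        if config.with_raters and cohort is not None:
            raters = synth.generate_rater_table(cohort)
            raters.to_csv(out / "raters.csv", index=False)
            report.reliability = bias_mod.rater_reliability(raters)
            calls = raters.pivot(index="participant_id", columns="rater_id",
                                 values="uvfp_call")
            truth = (manifest.drop_duplicates("participant_id")
                     .set_index("participant_id")["group"] == "UVFP"
                     ).astype(int).loc[calls.index]
            report.clinician = bias_mod.clinician_auc(calls, truth)
            report.ratings_models = bias_mod.ratings_models(
                raters, manifest, plan, config.model_names,
                with_null=config.with_null, seed=config.seed)
        log.info("stage audit done (%.1fs)", time.time() - t0)

        stage = "mitigate"
        t0 = time.time()
        if "reading" in config.tasks and "egemaps88" in config.feature_sets:
            reading_ids = manifest.loc[manifest["task"] == "reading",
                                       "recording_id"]
            pre_feats = frames["egemaps88"].loc[
                frames["egemaps88"].index.intersection(reading_ids)]
            target = (cohort.spec.biases.control_reading_duration
                      if cohort is not None else 3.5)
            for cutoff in config.mitigation_cutoffs:
                mit = bias_mod.mitigation_eval(
                    recordings, manifest,
                    bias_mod.MitigationConfig(cutoff, target), plan,
                    config.model_names, pre_features=pre_feats,
                    seed=config.seed)
                report.mitigation[cutoff] = mit
            rows = [{"cutoff": c, "n_features": len(m.retained_features),
                     **{f"{name}_post": s.median
                        for name, s in m.post.scores.items()}}
                    for c, m in report.mitigation.items()]
            pd.DataFrame(rows).to_csv(out / "mitigation_table.csv",
                                      index=False)
        log.info("stage mitigate done (%.1fs)", time.time() - t0)

        _write_json(out / "bias_report.json", report.to_dict())
        _write_json(out / "run_config.json", asdict(config))
        _write_json(out / "artifacts.json", _checksum_dir(out))
        return out
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
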