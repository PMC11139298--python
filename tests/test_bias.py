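"""Bias audit: reliability statistics against independent oracles, clinician
accuracy, duration/intensity probes, trimming, and intensity-associated
feature removal."""

import numpy as np
import pandas as pd
import pytest

import voiceaudit as va
from conftest import toy_participants
from voiceaudit.redundancy import pairwise_dcor


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        assert va.icc(x) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 3))
        assert abs(va.icc(x)) < 0.15

    def test_matches_mean_squares_oracle(self):
        """Hand ANOVA decomposition on a fixture with known components."""
        rng = np.random.default_rng(1)
        n, k = 40, 3
        subject = rng.normal(0, 3.0, n)[:, None]
        rater = np.array([[-1.0, 0.0, 1.0]])
        x = subject + rater + rng.normal(0, 1.0, (n, k))

        grand = x.mean()
        msr = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((x - x.mean(1, keepdims=True) - x.mean(0, keepdims=True)
                + grand) ** 2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert va.icc(x) == pytest.approx(expected, abs=1e-8)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2, (25, 1))[:, [0, 0, 0]] + rng.normal(0, 1, (25, 3))
        long = pd.DataFrame({
            "target": np.repeat(np.arange(25), 3),
            "rater": np.tile(np.arange(3), 25),
            "score": x.ravel()})
        ref = pingouin.intraclass_corr(long, targets="target", raters="rater",
                                       ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        icc3 = float(ref.loc[ref["Type"] == "ICC(C,1)", "ICC"].iloc[0])
        assert va.icc(x) == pytest.approx(icc2, abs=1e-8)
        assert va.icc(x, model="consistency") == pytest.approx(icc3, abs=1e-8)

    def test_validation(self):
        with pytest.raises(ValueError):
            va.icc(np.ones((3, 3)))          # too few targets
        with pytest.raises(ValueError):
            va.icc(np.ones((10, 1)))         # one rater
        x = np.ones((10, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            va.icc(x)


class TestLightsKappa:
    def test_identical_raters(self):
        x = np.array([["y", "y", "y"], ["n", "n", "n"], ["y", "y", "y"],
                      ["n", "n", "n"]])
        assert va.lights_kappa(x) == 1.0

    def test_two_raters_equals_cohen(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, 60)
        b = np.where(rng.uniform(size=60) < 0.8, a, 1 - a)
        x = np.column_stack([a, b])
        assert va.lights_kappa(x) == pytest.approx(cohen_kappa_score(a, b))

    def test_constant_rater_pulls_mean_down(self):
        """Three raters, one constant: its two pairwise kappas are 0, so
        Light's kappa = kappa(r1, r2) / 3."""
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(4)
        r1 = rng.integers(0, 2, 50)
        r2 = np.where(rng.uniform(size=50) < 0.9, r1, 1 - r1)
        r3 = np.zeros(50, dtype=int)
        expected = cohen_kappa_score(r1, r2) / 3.0
        assert va.lights_kappa(np.column_stack([r1, r2, r3])) == \
            pytest.approx(expected)


class TestAgreementLabels:
    @pytest.mark.parametrize("value,label", [
        (0.39, "poor"), (0.40, "fair"), (0.59, "fair"), (0.60, "good"),
        (0.74, "good"), (0.75, "excellent"), (1.0, "excellent")])
    def test_printed_cutoffs_at_boundaries(self, value, label):
        assert va.agreement_label(value) == label


class TestClinicianAUC:
    def _frame(self, preds, truth):
        idx = [f"r{i}" for i in range(len(truth))]
        return (pd.DataFrame({j: p for j, p in enumerate(preds)}, index=idx),
                pd.Series(truth, index=idx))

    def test_perfect_and_inverted(self):
        truth = [1, 1, 0, 0, 1, 0]
        calls, y = self._frame([truth, [1 - t for t in truth]], truth)
        out = va.clinician_auc(calls, y)
        assert out["per_rater"][0] == 1.0
        assert out["per_rater"][1] == 0.0
        assert out["median"] == 0.5

    def test_coin_flip_near_half(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 2, 154)
        calls, y = self._frame([rng.integers(0, 2, 154)], truth)
        assert va.clinician_auc(calls, y)["median"] == pytest.approx(0.5,
                                                                     abs=0.12)

    def test_yes_no_strings_accepted(self):
        truth = [1, 0, 1, 0]
        calls, y = self._frame([["yes", "no", "yes", "no"]], truth)
        assert va.clinician_auc(calls, y)["per_rater"][0] == 1.0


class TestTrim:
    def _recording(self, rid, task, dur):
        return va.Recording(rid, "p0", task, 1,
                            np.ones(int(dur * 16000)), 16000, {})

    def test_trims_excludes_and_passes_through(self):
        recs = [self._recording("long", "reading", 10.2),
                self._recording("exact", "reading", 3.5),
                self._recording("short", "reading", 2.0),
                self._recording("vowel", "vowel", 1.0)]
        kept, excluded = va.trim_to_match(recs, 3.5)
        assert excluded == ["short"]
        by_id = {r.recording_id: r for r in kept}
        assert by_id["long"].duration == pytest.approx(3.5)
        assert by_id["exact"].duration == pytest.approx(3.5)
        assert by_id["vowel"].duration == pytest.approx(1.0)
        durations = {r.duration for r in kept if r.task == "reading"}
        assert len(durations) == 1


class TestRemoveIntensityAssociated:
    def _table(self, cols):
        n = len(next(iter(cols.values())))
        ids = [f"r{i}" for i in range(n)]
        X = pd.DataFrame(cols, index=ids)
        y = pd.Series(np.tile([0, 1], len(X) // 2 + 1)[:len(X)], index=ids,
                      name="label")
        g = pd.Series(ids, index=ids, name="participant_id")
        return va.FeatureTable(X, y, g, "egemaps88", "reading")

    def test_cutoff_above_one_removes_only_intensity(self):
        rng = np.random.default_rng(6)
        table = self._table({"loud": rng.standard_normal(30),
                             "other": rng.standard_normal(30)})
        cmap = {"loud": "intensity", "other": "prosody"}
        reduced, manifest = va.remove_intensity_associated(table, cmap, 1.01)
        assert reduced.feature_names == ["other"]
        assert manifest["feature"].tolist() == ["loud"]

    def test_duplicate_of_intensity_removed_with_attribution(self):
        rng = np.random.default_rng(7)
        loud = rng.standard_normal(40)
        table = self._table({"loud": loud, "copy": loud.copy(),
                             "free": rng.standard_normal(40)})
        cmap = {"loud": "intensity", "copy": "prosody", "free": "prosody"}
        reduced, manifest = va.remove_intensity_associated(table, cmap, 0.3)
        assert "copy" not in reduced.feature_names
        row = manifest.set_index("feature").loc["copy"]
        assert row["trigger"] == "loud"
        assert row["dcor"] == pytest.approx(1.0)

    def test_survivors_all_below_cutoff_exhaustive(self):
        rng = np.random.default_rng(8)
        loud = rng.standard_normal(60)
        cols = {"loudA": loud, "loudB": loud + 0.2 * rng.standard_normal(60)}
        for i in range(12):
            mix = rng.uniform(0, 1)
            cols[f"f{i:02d}"] = mix * loud + (1 - mix) * \
                rng.standard_normal(60)
        table = self._table(cols)
        cmap = {c: ("intensity" if c.startswith("loud") else "prosody")
                for c in cols}
        cutoff = 0.3
        reduced, _ = va.remove_intensity_associated(table, cmap, cutoff)
        dmat = pairwise_dcor(table.X)
        for f in reduced.feature_names:
            for i in ("loudA", "loudB"):
                assert dmat.loc[f, i] < cutoff


class TestIntensityDirection:
    def test_flags_follow_construction(self, biased_cohort, biased_features,
                                       category_map):
        table = va.build_feature_table(biased_cohort.recordings,
                                       biased_cohort.manifest, "egemaps88",
                                       "reading", features=biased_features)
        flags = va.intensity_direction_check(table, category_map)
        # gain bias on: the equivalent-sound-level analogue must be flagged
        assert flags.loc["equivalentSoundLevel_dBp", "patient_higher"]

    def test_weak_voice_without_gain_not_flagged(self):
        spec = va.CohortSpec.pathology_only(n_per_group=6, seed=21)
        c = va.generate_cohort(spec)
        table = va.build_feature_table(c.recordings, c.manifest, "egemaps88",
                                       "vowel")
        flags = va.intensity_direction_check(table, va.load_category_map())
        assert not flags.loc["equivalentSoundLevel_dBp", "patient_higher"]

    def test_identical_groups_zero_difference(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal(10)
        ids = [f"r{i}" for i in range(20)]
        X = pd.DataFrame({"equivalentSoundLevel_dBp": np.tile(vals, 2)},
                         index=ids)
        y = pd.Series([1] * 10 + [0] * 10, index=ids, name="label")
        g = pd.Series(ids, index=ids, name="participant_id")
        table = va.FeatureTable(X, y, g, "egemaps88", "reading")
        flags = va.intensity_direction_check(
            table, {"equivalentSoundLevel_dBp": "intensity"})
        assert flags["difference"].abs().max() < 1e-12
        assert not flags["patient_higher"].any()


class TestRatingsModels:
    def test_truth_linked_ratings_predict(self):
        # needs enough participants for non-quantized participant-level AUC
        cohort = va.generate_cohort(va.CohortSpec.default_biased(30, seed=7))
        rt = va.generate_rater_table(cohort)
        plan = va.make_split_plan(va.participants_frame(cohort),
                                  n_splits=20, seed=1)
        out = va.ratings_models(rt, cohort.manifest, plan,
                                model_names=("logreg_l1",), with_null=False)
        assert out["clinician6"].best_median > 0.7

    def test_single_rater_average_is_identity(self, biased_cohort):
        rt = va.generate_rater_table(biased_cohort)
        one = rt[rt.rater_id == 1]
        t = va.ratings_feature_table(one, biased_cohort.manifest,
                                     "clinician6")
        merged = t.X.join(one.set_index("recording_id")["severity"],
                          rsuffix="_raw")
        assert np.allclose(merged["severity"], merged["severity_raw"])

    def test_reliability_bundle_complete(self, biased_cohort):
        rt = va.generate_rater_table(biased_cohort)
        results = va.rater_reliability(rt)
        stats = {(r.variable, r.statistic) for r in results}
        assert ("severity", "ICC") in stats
        assert ("uvfp_call", "lights_kappa") in stats
        for r in results:
            assert r.label in ("poor", "fair", "good", "excellent")
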