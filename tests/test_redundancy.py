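"""Distance correlation against a brute-force oracle, the Independence
Factor contract, threshold sweep monotonicity, parsimonious selection, and
average-linkage clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import voiceaudit as va
from voiceaudit.redundancy import FeatureSubset, pairwise_dcor


def dcor_bruteforce(x, y):
    """Independent double-centering implementation (naive loops avoided but
    written directly from the definition, separately from the library)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    a = np.abs(np.subtract.outer(x, x))
    b = np.abs(np.subtract.outer(y, y))
    A = a - a.mean(0) - a.mean(1)[:, None] + a.mean()
    B = b - b.mean(0) - b.mean(1)[:, None] + b.mean()
    dcov2 = (A * B).sum() / n**2
    dvx = (A * A).sum() / n**2
    dvy = (B * B).sum() / n**2
    if dvx * dvy == 0:
        return 0.0
    return np.sqrt(max(dcov2, 0) / np.sqrt(dvx * dvy))


class TestDistanceCorrelation:
    def test_matches_bruteforce_on_100_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50) + 0.5 * x
            assert va.distance_correlation(x, y) == pytest.approx(
                dcor_bruteforce(x, y), abs=1e-10)

    def test_self_dependence_is_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        assert va.distance_correlation(x, x) == pytest.approx(1.0)

    def test_nonmonotonic_beats_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(200)
        y = x**2
        d = va.distance_correlation(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert d > 0.4
        assert abs(r) < 0.15

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(3)
        assert va.distance_correlation(rng.standard_normal(500),
                                       rng.standard_normal(500)) < 0.15

    def test_constant_vector_defined_as_zero(self):
        x = np.ones(20)
        y = np.arange(20.0)
        assert va.distance_correlation(x, y) == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            va.distance_correlation([1, 2], [1, 2])
        with pytest.raises(ValueError):
            va.distance_correlation([1, 2, 3, 4], [1, 2, 3])

    def test_pairwise_matrix_consistent_with_scalar(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((60, 5)),
                         columns=list("abcde"))
        X["b"] = X["a"] ** 2
        m = pairwise_dcor(X)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert ((m.to_numpy() >= 0) & (m.to_numpy() <= 1)).all()
        for i, j in [("a", "b"), ("c", "d"), ("a", "e")]:
            assert m.loc[i, j] == pytest.approx(
                va.distance_correlation(X[i], X[j]), abs=1e-8)


def independence_factor_oracle(dmat: pd.DataFrame, threshold: float):
    """Step-by-step simulation of the greedy definition, written
    independently of the library implementation."""
    order = sorted(dmat.columns, key=lambda s: (s.lower(), s))
    removed, retained = {}, []
    remaining = list(order)
    while remaining:
        keeper = remaining.pop(0)
        retained.append(keeper)
        still = []
        for f in remaining:
            if dmat.loc[keeper, f] > threshold:
                removed[f] = keeper
            else:
                still.append(f)
        remaining = still
    return retained, removed


class TestIndependenceFactor:
    def test_threshold_one_keeps_all(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((30, 6)),
                         columns=[f"f{i}" for i in range(6)])
        sub = va.independence_factor(X, 1.0)
        assert sorted(sub.retained) == sorted(X.columns)
        assert not sub.removed

    def test_duplicate_removed_with_attribution(self):
        rng = np.random.default_rng(6)
        a = rng.standard_normal(50)
        X = pd.DataFrame({"A": a, "B": a, "C": rng.standard_normal(50)})
        sub = va.independence_factor(X, 0.9)
        assert sub.retained == ["A", "C"]
        keeper, d = sub.removed["B"]
        assert keeper == "A"
        assert d == pytest.approx(1.0)

    @pytest.mark.parametrize("threshold", [0.3, 0.5, 0.7])
    def test_matches_stepwise_oracle_on_random_tables(self, threshold):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((40, 8))
        cols = {}
        for i in range(20):
            j = i % 8
            noise = rng.standard_normal(40) * rng.uniform(0.1, 2.0)
            cols[f"feat{i:02d}"] = base[:, j] + noise
        X = pd.DataFrame(cols)
        dmat = pairwise_dcor(X)
        sub = va.independence_factor(None, threshold, dmat)
        retained_o, removed_o = independence_factor_oracle(dmat, threshold)
        assert sub.retained == retained_o
        assert {k: v[0] for k, v in sub.removed.items()} == removed_o

    def test_retained_pairs_below_threshold(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal((50, 4))
        X = pd.DataFrame({f"g{i}": base[:, i % 4]
                          + 0.3 * rng.standard_normal(50) for i in range(12)})
        dmat = pairwise_dcor(X)
        for t in (0.9, 0.6, 0.3):
            sub = va.independence_factor(None, t, dmat)
            kept = dmat.loc[sub.retained, sub.retained].to_numpy()
            np.fill_diagonal(kept, 0.0)
            assert kept.max() <= t
            for f, (keeper, d) in sub.removed.items():
                assert d > t
                assert keeper in sub.retained

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            va.independence_factor(pd.DataFrame({"a": [1, 2, 3, 4.0],
                                                 "b": [2, 1, 4, 3.0]}), 0.0)


class TestThresholdSweep:
    def test_sizes_nonincreasing_with_threshold(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal((60, 6))
        X = pd.DataFrame({f"h{i:02d}": base[:, i % 6]
                          + rng.uniform(0.05, 1.5) * rng.standard_normal(60)
                          for i in range(25)})
        sweep = va.threshold_sweep(X)
        ts = sorted(sweep, reverse=True)
        sizes = [sweep[t].n_retained for t in ts]
        assert sizes == sorted(sizes, reverse=True)
        assert sweep[1.0].n_retained == 25

    def test_single_feature_table(self):
        X = pd.DataFrame({"only": np.arange(10.0)})
        sweep = va.threshold_sweep(X, thresholds=(1.0, 0.5, 0.2))
        assert all(s.retained == ["only"] for s in sweep.values())


class TestParsimoniousSelection:
    @staticmethod
    def _sweep_of_sizes(sizes: dict[float, int]):
        return {t: FeatureSubset(t, [f"f{i}" for i in range(n)], {})
                for t, n in sizes.items()}

    def test_all_tie_picks_smallest(self):
        sweep = self._sweep_of_sizes({1.0: 88, 0.5: 40, 0.3: 10})
        evals = {t: {"m": 0.85} for t in sweep}
        choice = va.select_parsimonious(sweep, evals, {"m": 0.85})
        assert choice.subset.n_retained == 10

    def test_three_point_rule(self):
        """Sizes 88/39/13 scoring .87/.87/.80 with tolerance .03 -> 39."""
        sweep = self._sweep_of_sizes({1.0: 88, 0.5: 39, 0.3: 13})
        evals = {1.0: {"m": 0.87}, 0.5: {"m": 0.87}, 0.3: {"m": 0.80}}
        choice = va.select_parsimonious(sweep, evals, {"m": 0.87},
                                        tolerance=0.03)
        assert choice.subset.n_retained == 39
        assert not choice.used_full_set

    def test_nothing_qualifies_returns_full_with_warning(self):
        sweep = self._sweep_of_sizes({1.0: 10, 0.5: 5})
        evals = {1.0: {"m": 0.80}, 0.5: {"m": 0.70}}
        choice = va.select_parsimonious(sweep, evals, {"m": 0.90},
                                        tolerance=0.0)
        assert choice.used_full_set
        assert choice.subset.n_retained == 10


def average_linkage_oracle(points: np.ndarray) -> list[float]:
    """O(n^3) naive agglomeration returning sorted merge heights."""
    clusters = [[i] for i in range(len(points))]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i]
                               for b in clusters[j]])
                if avg < best[0]:
                    best = (avg, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


class TestClustering:
    def test_duplicate_blocks_contiguous(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal(50)
        b = rng.standard_normal(50)
        X = pd.DataFrame({"a1": a, "a2": a + 0.01 * rng.standard_normal(50),
                          "b1": b, "b2": b + 0.01 * rng.standard_normal(50)})
        order, _ = va.cluster_features(pairwise_dcor(X))
        pos = {f: i for i, f in enumerate(order)}
        assert abs(pos["a1"] - pos["a2"]) == 1
        assert abs(pos["b1"] - pos["b2"]) == 1

    def test_merge_heights_match_naive_oracle(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.standard_normal((30, 10)),
                         columns=[f"c{i}" for i in range(10)])
        dmat = pairwise_dcor(X)
        _, tree = va.cluster_features(dmat)
        expected = average_linkage_oracle(dmat.to_numpy())
        assert np.allclose(sorted(tree[:, 2]), sorted(expected), atol=1e-8)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
def test_dcor_affine_invariance(seed, scale):
    """dcor is invariant to shifting/scaling either argument."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(30)
    y = rng.standard_normal(30)
    d0 = va.distance_correlation(x, y)
    d1 = va.distance_correlation(scale * x + 3.0, y)
    assert d1 == pytest.approx(d0, abs=1e-8)
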