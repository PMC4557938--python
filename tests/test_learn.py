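"""Classification statistics, LOOV SVMs, and the clustering baseline."""

import io
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from nichecast import learn
from nichecast.errors import NichecastError
from nichecast.learn import (SVMConfig, cluster_profiles, confidence, f_score,
                             filter_features, high_weight_features,
                             linkage_to_newick, loov_ovr_svm, niche_overlap)

SD = np.sqrt(2.0)  # sample SD of |[1, 3]|
POS_DIST = np.array([1.0, 3.0])


class TestFScore:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (5, 0, 0, 1.0),
        (2, 1, 1, 2 / 3),
        (0, 3, 2, 0.0),
        (3, 1, 2, 2 * (3 / 4) * (3 / 5) / (3 / 4 + 3 / 5)),
    ])
    def test_values(self, tp, fp, fn, expected):
        assert f_score(tp, fp, fn) == pytest.approx(expected)

    def test_undefined_when_denominator_zero(self):
        assert np.isnan(f_score(0, 0, 2))
        assert np.isnan(f_score(0, 3, 0))

    def test_symmetric_in_fp_fn(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, fn = (int(v) for v in rng.integers(1, 20, 3))
            assert f_score(tp, fp, fn) == pytest.approx(f_score(tp, fn, fp))

    def test_negative_counts_rejected(self):
        with pytest.raises(NichecastError):
            f_score(-1, 0, 0)


class TestConfidence:
    def test_zero_decision_is_full_confidence(self):
        assert confidence(0.0, POS_DIST) == 1.0

    def test_z_of_one(self):
        assert confidence(SD, POS_DIST) == pytest.approx(1 - 0.341345, abs=1e-4)

    def test_significance_boundary(self):
        # confidence hits 0.95 exactly where Phi(z) = 0.55
        z95 = norm.ppf(0.55)
        assert z95 == pytest.approx(0.12566, abs=1e-5)
        assert confidence(z95 * SD, POS_DIST) == pytest.approx(0.95, abs=1e-9)

    def test_strictly_decreasing_in_abs_decision(self):
        vals = [confidence(x, POS_DIST) for x in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert all(0.5 < v <= 1.0 for v in vals)
        assert confidence(-1.0, POS_DIST) == confidence(1.0, POS_DIST)

    def test_matches_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            d = rng.normal(2, 1, size=rng.integers(2, 10))
            x = float(rng.normal(0, 3))
            sd = np.abs(d).std(ddof=1)
            if sd == 0:
                continue
            expected = 1 - (norm.cdf(abs(x) / sd) - 0.5)
            assert confidence(x, d) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_sd_fatal(self):
        with pytest.raises(NichecastError, match="standard deviation"):
            confidence(1.0, np.array([2.0, 2.0]))
        with pytest.raises(NichecastError):
            confidence(1.0, np.array([2.0]))

    def test_centered_mode(self):
        # z measured from the mean positive distance (2.0 here)
        assert confidence(2.0, POS_DIST, mode="centered") == 1.0
        assert confidence(2.0 + SD, POS_DIST, mode="centered") == \
            pytest.approx(1 - 0.341345, abs=1e-4)


class TestFilterFeatures:
    def test_constant_feature_removed(self):
        df = pd.DataFrame({"const": [3.0] * 4, "ok": [1.0, 5.0, 2.0, 8.0]})
        assert list(filter_features(df).columns) == ["ok"]

    def test_majority_is_strict(self):
        # non-zero in exactly half the genomes is not "more than half"
        df = pd.DataFrame({"half": [1.0, 2.0, 0.0, 0.0], "ok": [1.0, 5.0, 2.0, 8.0]})
        assert list(filter_features(df).columns) == ["ok"]

    def test_sd_threshold_is_strict(self):
        vals = [1.0, 1.2, 1.4, 1.2]  # nonzero everywhere
        df = pd.DataFrame({"low_sd": vals, "ok": [1.0, 5.0, 2.0, 8.0]})
        assert pd.Series(vals).std(ddof=1) < 0.2
        assert list(filter_features(df).columns) == ["ok"]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            df = pd.DataFrame(np.round(rng.normal(0, 1, (20, 50)) *
                                       (rng.random((20, 50)) < 0.7), 2))
            try:
                kept = set(filter_features(df).columns)
            except NichecastError:
                kept = set()
            expected = set()
            for c in df.columns:
                col = df[c].to_numpy()
                if (col != 0).sum() > 0.5 * len(col) and np.std(col, ddof=1) > 0.2:
                    expected.add(c)
            assert kept == expected or (not expected and not kept)

    def test_all_removed_fatal(self):
        with pytest.raises(NichecastError, match="filter removed all"):
            filter_features(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


class TestHighWeightFeatures:
    def test_equal_weights_flag_nothing(self, caplog):
        flags = high_weight_features(pd.Series([2.0, 2.0, 2.0]))
        assert not flags.any()
        assert any("identical" in r.message for r in caplog.records)

    def test_single_outlier(self):
        w = pd.Series([1.0] * 9 + [11.0])
        flags = high_weight_features(w)
        # mean 2, sample SD sqrt(10): only the 11 exceeds the 2-SD band
        assert flags.sum() == 1 and bool(flags.iloc[-1])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            w = pd.Series(rng.normal(0, 1, rng.integers(3, 40)))
            got = high_weight_features(w)
            mu, sd = w.mean(), w.std(ddof=1)
            expected = [abs(x - mu) > 2 * sd for x in w]
            assert list(got) == expected

    def test_too_few_features_fatal(self):
        with pytest.raises(NichecastError):
            high_weight_features(pd.Series([1.0, 2.0]))


def separable_features(n=12, seed=5):
    rng = np.random.default_rng(seed)
    y = np.array([True] * (n // 2) + [False] * (n - n // 2))
    X = pd.DataFrame(
        {"sig": y * 5.0 + rng.normal(1, 0.3, n),
         "noise1": rng.normal(2, 1, n),
         "noise2": rng.normal(2, 1, n)},
        index=[f"g{i}" for i in range(n)],
    )
    labels = pd.DataFrame({"niche": y}, index=X.index)
    return X, labels


class TestLoovOvrSvm:
    def test_one_prediction_per_genome_per_niche(self):
        X, labels = separable_features()
        report = loov_ovr_svm(X, labels, SVMConfig(seed=0))
        preds = report.per_niche["niche"].predictions
        assert len(preds) == len(X)
        assert preds.index.tolist() == X.index.tolist()
        assert report.per_niche["niche"].f_score == 1.0

    def test_niche_with_too_few_positives_skipped(self, caplog):
        X, labels = separable_features()
        labels = labels.copy()
        labels["rare"] = [True] + [False] * (len(X) - 1)
        report = loov_ovr_svm(X, labels, SVMConfig(seed=0))
        assert report.skipped == ["rare"]
        assert set(report.per_niche) == {"niche"}

    def test_duplicating_genomes_preserves_prediction_signs(self):
        X, labels = separable_features()
        base = loov_ovr_svm(X, labels, SVMConfig(seed=0)).per_niche["niche"].predictions
        X2 = pd.concat([X, X.set_index(X.index + "_dup")])
        labels2 = pd.concat([labels, labels.set_index(labels.index + "_dup")])
        dup = loov_ovr_svm(X2, labels2, SVMConfig(seed=0)).per_niche["niche"].predictions
        for g in X.index:
            assert dup.loc[g, "predicted"] == base.loc[g, "predicted"]

    def test_mismatched_genome_ids_fatal(self):
        X, labels = separable_features()
        with pytest.raises(NichecastError, match="g0"):
            loov_ovr_svm(X, labels.drop(index="g0"))

    def test_confidence_columns_well_formed(self):
        X, labels = separable_features()
        preds = loov_ovr_svm(X, labels, SVMConfig(seed=0)).per_niche["niche"].predictions
        # the statistic's range is (0.5, 1]; far from the hyperplane it
        # approaches 0.5 and rounds to it in floating point
        assert ((preds["confidence"] >= 0.5) & (preds["confidence"] <= 1.0)).all()
        assert (preds["significant"] == (preds["confidence"] >= 0.95)).all()

    def test_per_fold_filter_mode_runs(self):
        X, labels = separable_features(n=14)
        report = loov_ovr_svm(X, labels, SVMConfig(seed=0, filter_per_fold=True))
        assert report.per_niche["niche"].f_score == 1.0


class TestNicheOverlap:
    def test_disjoint_sets(self):
        out = niche_overlap({"a": {"f1"}, "b": {"f2"}})
        both = out[(out["a"]) & (out["b"])]
        only_a = out[(out["a"]) & (~out["b"])]
        assert both["count"].iloc[0] == 0
        assert only_a["percent"].iloc[0] == 50.0

    def test_identical_sets(self):
        out = niche_overlap({"a": {"f1", "f2"}, "b": {"f1", "f2"}})
        both = out[(out["a"]) & (out["b"])]
        assert both["percent"].iloc[0] == 100.0
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_matches_membership_pattern_tally(self):
        rng = np.random.default_rng(10)
        feats = [f"x{i}" for i in range(30)]
        sets = {f"n{j}": {f for f in feats if rng.random() < 0.4} for j in range(4)}
        out = niche_overlap(sets)
        union = set().union(*sets.values())
        for _, row in out.iterrows():
            members = [f for f in union
                       if all((f in sets[n]) == row[n] for n in sets)]
            assert row["count"] == len(members)
        assert out["percent"].sum() == pytest.approx(100.0)

    def test_needs_two_niches(self):
        with pytest.raises(NichecastError):
            niche_overlap({"a": {"f"}})


def naive_upgma_cophenetic(X, metric="braycurtis"):
    """Brute-force O(n^3) group-average agglomeration oracle."""
    D = squareform(pdist(X, metric=metric))
    clusters = {i: [i] for i in range(len(X))}
    coph = np.zeros_like(D)
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] += clusters.pop(b)
    return squareform(coph)


class TestClusterProfiles:
    def test_identical_rows_merge_at_zero(self):
        df = pd.DataFrame([[1, 2], [1, 2], [5, 9]], index=["a", "b", "c"])
        Z, labels = cluster_profiles(df)
        assert set(labels) == {"a", "b", "c"}
        assert Z[0, 2] == 0.0
        assert sorted(Z[0, :2]) == [0, 1]  # the coincident pair merges first

    def test_merge_structure_matches_naive_oracle(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.integers(1, 9, (6, 4)).astype(float))
        Z, _ = cluster_profiles(df)
        got = cophenet(Z)
        expected = naive_upgma_cophenetic(df.to_numpy())
        assert np.allclose(got, expected)

    def test_newick_is_parseable_and_complete(self):
        from Bio import Phylo

        rng = np.random.default_rng(14)
        df = pd.DataFrame(rng.random((5, 3)), index=[f"g{i}" for i in range(5)])
        Z, labels = cluster_profiles(df)
        tree = Phylo.read(io.StringIO(linkage_to_newick(Z, labels)), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)

    def test_single_genome_fatal(self):
        with pytest.raises(NichecastError):
            cluster_profiles(pd.DataFrame([[1.0]]))
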