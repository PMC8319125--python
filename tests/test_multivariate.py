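"""Z-scores, hierarchical clustering, UMAP, feature selection, classifiers."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster
from sklearn.metrics import silhouette_score

import omiflim as of
from omiflim.cells import OMI_VARIABLES
from omiflim.multivariate import (EfficiencyClassifier, SplitSpec,
                                  ZScoreTable, chi2_rank, chi2_scores,
                                  cluster_dendrogram, train_classifier,
                                  umap_embed, zscore_conditions)
from omiflim.simulate import generate_feature_table, make_condition_spec


def records_with_condition_means(means_by_condition, n=4):
    """Tiny table whose per-condition means are exactly as requested."""
    rows = []
    for cond, mu in means_by_condition.items():
        for i in range(n):
            delta = (i - (n - 1) / 2) * 1e-6
            rec = {v: mu + delta for v in OMI_VARIABLES}
            rec.update(condition=cond, efficiency=50.0,
                       efficiency_class="high", cell_id=len(rows),
                       dataset=1)
            rows.append(rec)
    return pd.DataFrame(rows)


class TestZScore:
    def test_three_conditions_give_minus1_0_1(self):
        rec = records_with_condition_means({"a": 1.0, "b": 2.0, "c": 3.0})
        z = zscore_conditions(rec)
        np.testing.assert_allclose(z.values.loc["nadph_tau_m"].to_numpy(),
                                   [-1.0, 0.0, 1.0], atol=1e-5)

    def test_rows_are_standardized(self):
        tab = generate_feature_table(
            50, [make_condition_spec(10.0 * k, name=f"c{k}")
                 for k in range(1, 5)], seed=2)
        z = zscore_conditions(tab)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1.0,
                                   atol=1e-9)

    def test_constant_variable_rejected_by_name(self):
        rec = records_with_condition_means({"a": 1.0, "b": 2.0}, n=1)
        rec["fad_tau1"] = 5.0  # exactly constant across conditions
        with pytest.raises(ValueError, match="fad_tau1"):
            zscore_conditions(rec)

    def test_single_condition_rejected(self):
        rec = records_with_condition_means({"a": 1.0})
        with pytest.raises(ValueError, match="2 conditions"):
            zscore_conditions(rec)


def brute_force_average_linkage(points):
    """O(n³) agglomerative average linkage on raw Euclidean distances."""
    clusters = {i: [i] for i in range(len(points))}
    heights = []
    d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                avg = np.mean([d[i, j] for i in clusters[a]
                               for j in clusters[b]])
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        avg, a, b = best
        heights.append(avg)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestDendrogram:
    def test_identical_conditions_merge_first_at_zero(self):
        rec = records_with_condition_means({"a": 1.0, "b": 1.0, "c": 9.0},
                                           n=1)
        rec2 = rec.copy()
        # exact duplicates for a and b
        for v in OMI_VARIABLES:
            rec2.loc[rec2.condition == "b", v] = \
                rec2.loc[rec2.condition == "a", v].to_numpy()
        z = zscore_conditions(rec2)
        link = cluster_dendrogram(z).condition_linkage
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(link[0, 0]), int(link[0, 1])}
        labels = cluster_dendrogram(z).condition_labels
        assert {labels[i] for i in merged} == {"a", "b"}

    def test_nearest_pair_merges_before_distant_condition(self):
        rec = records_with_condition_means({"a": 0.0, "b": 0.1, "c": 10.0},
                                           n=1)
        z = zscore_conditions(rec)
        link = cluster_dendrogram(z).condition_linkage
        labels = cluster_dendrogram(z).condition_labels
        first = {labels[int(link[0, 0])], labels[int(link[0, 1])]}
        assert first == {"a", "b"}

    def test_linkage_heights_match_bruteforce_oracle(self):
        tab = generate_feature_table(
            30, [make_condition_spec(10.0 + 15 * k, name=f"c{k}",
                                     shift={"nadph_tau_m": 0.5 * k})
                 for k in range(5)], seed=4)
        z = zscore_conditions(tab)
        link = cluster_dendrogram(z).condition_linkage
        oracle = brute_force_average_linkage(z.values.T.to_numpy())
        np.testing.assert_allclose(sorted(link[:, 2]), oracle, rtol=1e-9)


@pytest.fixture(scope="module")
def separated_table():
    # widely separated classes: shift across several variables so the
    # separation survives standardization of the 13-dimensional space
    shift = {v: 10.0 for v in ("nadph_tau_m", "nadph_tau1", "fad_tau_m",
                               "redox_ratio", "nadph_intensity",
                               "fad_intensity")}
    specs = [make_condition_spec(20.0, name="low"),
             make_condition_spec(70.0, shift=shift, name="high")]
    return generate_feature_table(60, specs, seed=5)


class TestUmap:

    def test_fixed_seed_is_deterministic(self, separated_table):
        a = umap_embed(separated_table, seed=3)
        b = umap_embed(separated_table, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_separated_classes_form_separated_clusters(self, separated_table):
        coords = umap_embed(separated_table, seed=3)
        score = silhouette_score(
            coords, separated_table["efficiency_class"])
        assert score > 0.5

    def test_single_class_smoke(self):
        tab = generate_feature_table(30, [make_condition_spec(70.0)], seed=6)
        coords = umap_embed(tab, seed=0)
        assert np.isfinite(coords).all() and coords.shape == (30, 2)

    def test_too_few_cells_rejected(self):
        tab = generate_feature_table(5, [make_condition_spec(70.0)], seed=6)
        with pytest.raises(ValueError, match="n_neighbors"):
            umap_embed(tab, seed=0)


def hand_chi2(x01, y):
    """Classic one-way chi-squared on per-class feature sums."""
    classes = np.unique(y)
    observed = np.array([x01[y == c].sum(axis=0) for c in classes])
    priors = np.array([(y == c).mean() for c in classes])
    expected = priors[:, None] * x01.sum(axis=0)[None, :]
    return ((observed - expected) ** 2 / expected).sum(axis=0)


class TestChi2Selection:
    def test_separated_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 100
        tab = pd.DataFrame(rng.normal(size=(n, 13)), columns=OMI_VARIABLES)
        y = np.repeat(["low", "high"], n // 2)
        tab["nadph_tau2"] = np.where(y == "high", 10.0, 0.0)
        tab["efficiency_class"] = y
        assert chi2_scores(tab).idxmax() == "nadph_tau2"

    def test_duplicated_feature_ties_keep_column_order(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame(rng.normal(size=(60, 13)), columns=OMI_VARIABLES)
        tab["fad_tau1"] = tab["nadph_tau1"]  # exact duplicate
        tab["efficiency_class"] = np.repeat(["low", "high"], 30)
        s = chi2_scores(tab)
        assert s["nadph_tau1"] == pytest.approx(s["fad_tau1"], rel=1e-12)
        ranked, _ = chi2_rank(tab, n_resamples=2)
        assert ranked.index("nadph_tau1") < ranked.index("fad_tau1")

    def test_scores_match_handrolled_formula(self):
        tab = generate_feature_table(
            25, [make_condition_spec(20.0, name="low"),
                 make_condition_spec(70.0, shift={"nadph_tau_m": 2.0},
                                     name="high")], seed=9)
        from sklearn.preprocessing import MinMaxScaler
        x01 = MinMaxScaler().fit_transform(
            tab[OMI_VARIABLES].to_numpy(dtype=float))
        expected = hand_chi2(x01, tab["efficiency_class"].to_numpy())
        np.testing.assert_allclose(chi2_scores(tab).to_numpy(), expected,
                                   rtol=1e-9)

    def test_pure_noise_accuracy_curve_hovers_at_chance(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(rng.normal(size=(400, 13)),
                           columns=OMI_VARIABLES)
        tab["efficiency_class"] = np.repeat(["low", "high"], 200)
        _, curve = chi2_rank(tab, n_resamples=5)
        # binomial noise on an 80-cell validation fold
        assert (np.abs(curve["accuracy_mean"] - 0.5) < 0.17).all()

    def test_single_class_rejected(self):
        tab = generate_feature_table(30, [make_condition_spec(70.0)], seed=1)
        with pytest.raises(ValueError, match="class"):
            chi2_scores(tab)


def mann_whitney_auc(scores, labels):
    pos = scores[labels == "high"]
    neg = scores[labels == "low"]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.fixture(scope="module")
def shifted_table():
    specs = [make_condition_spec(20.0, name="low"),
             make_condition_spec(70.0, shift={"nadph_tau_m": 3.0},
                                 name="high")]
    return generate_feature_table(300, specs, seed=12)


class TestTrainClassifier:

    def test_auc_equals_mann_whitney_oracle(self, shifted_table):
        rep = train_classifier(shifted_table)
        clf = EfficiencyClassifier()
        tr = shifted_table[shifted_table.dataset == 1]
        ev = shifted_table[shifted_table.dataset == 2]
        clf.fit(tr[OMI_VARIABLES], tr["efficiency_class"])
        scores = clf.decision_scores(ev[OMI_VARIABLES])
        expected = mann_whitney_auc(scores, ev["efficiency_class"].to_numpy())
        # report trained on the 80% fold, so refit AUC is a separate check
        fpr, tpr = rep.roc_fpr, rep.roc_tpr
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        from sklearn.metrics import auc as sk_auc, roc_curve
        f2, t2, _ = roc_curve(ev["efficiency_class"], scores,
                              pos_label="high")
        assert sk_auc(f2, t2) == pytest.approx(expected, abs=1e-9)

    def test_auc_invariant_under_monotone_score_transform(self,
                                                          shifted_table):
        ev = shifted_table[shifted_table.dataset == 2]
        tr = shifted_table[shifted_table.dataset == 1]
        clf = EfficiencyClassifier().fit(tr[OMI_VARIABLES],
                                         tr["efficiency_class"])
        s = clf.decision_scores(ev[OMI_VARIABLES])
        from sklearn.metrics import auc as sk_auc, roc_curve
        y = ev["efficiency_class"]
        a1 = sk_auc(*roc_curve(y, s, pos_label="high")[:2])
        a2 = sk_auc(*roc_curve(y, np.tanh(s / 3) * 7 + 2,
                               pos_label="high")[:2])
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_split_sizes_follow_80_20(self, shifted_table):
        rep = train_classifier(shifted_table)
        n = (shifted_table.dataset == 1).sum()
        assert rep.n_train == int(np.floor(0.8 * n))
        assert rep.n_validation == n - rep.n_train

    def test_leakage_guard_rejects_shared_cell_ids(self, shifted_table):
        leaky = shifted_table.copy()
        leaky["cell_id"] = leaky["cell_id"] // 2  # ids collide across sets
        with pytest.raises(ValueError, match="leakage"):
            train_classifier(leaky)

    def test_named_subsets_restrict_weights(self, shifted_table):
        rep = train_classifier(shifted_table, subset="nadph_lifetime")
        assert set(rep.weights) == {"nadph_tau_m", "nadph_tau2",
                                    "nadph_alpha2", "nadph_alpha1",
                                    "nadph_tau1"}

    @pytest.mark.parametrize("family", ["svm", "random_forest"])
    def test_alternative_families_run(self, shifted_table, family):
        rep = train_classifier(shifted_table, family=family)
        assert 0.5 < rep.auc <= 1.0
        assert rep.weights is None

    def test_same_dataset_for_train_and_eval_rejected(self):
        with pytest.raises(ValueError, match="leakage"):
            SplitSpec(train_dataset=1, eval_dataset=1)
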