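"""State–fate datasets, CV harness, SHAP summaries, differential enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from celltagmulti.clones import CloneTable
from celltagmulti.statefate import (
    assemble_dataset,
    cross_validate_fate,
    differential_enrichment,
    knn_impute,
    shap_summary,
    tf_activity_qc_filter,
)
from celltagmulti.stats import benjamini_hochberg


def labeled_clone_table(clone_cells, fates, time_point="d2.5"):
    """clone_cells: {clone_id: [(cell, modality), ...]}; fates: {clone_id: label}."""
    rows = []
    for cid, members in clone_cells.items():
        for cell, modality in members:
            rows.append(
                (cid, cell, modality, time_point, "s", fates.get(cid, pd.NA), 1.0, False)
            )
    return CloneTable(
        pd.DataFrame(
            rows,
            columns=[
                "clone_id", "cell", "modality", "time_point", "sample",
                "fate_label", "fate_bias", "tie_flag",
            ],
        )
    )


def synthetic_dataset(n_clones=20, cells_per_clone=3, n_features=5, effect=3.0, seed=0):
    """RNA-only labeled dataset with a planted fate effect on feature 0."""
    rng = np.random.default_rng(seed)
    clone_cells, fates, rows, index = {}, {}, [], []
    for cid in range(n_clones):
        fate = "A" if cid % 2 == 0 else "B"
        fates[cid] = fate
        members = []
        for j in range(cells_per_clone):
            cell = f"c{cid}_{j}"
            members.append((cell, "RNA"))
            x = rng.normal(size=n_features)
            if fate == "A":
                x[0] += effect
            rows.append(x)
            index.append(cell)
        clone_cells[cid] = members
    table = labeled_clone_table(clone_cells, fates)
    features = {"RNA": pd.DataFrame(rows, index=index)}
    return assemble_dataset(features, table, "rna_hvg_residuals")


class TestAssembleDataset:
    def features(self):
        rna = pd.DataFrame(
            np.arange(8).reshape(4, 2), index=["r1", "r2", "r3", "r4"], columns=["g1", "g2"]
        )
        atac = pd.DataFrame(
            np.arange(6).reshape(3, 2), index=["a1", "a2", "a3"], columns=["t1", "t2"]
        )
        return {"RNA": rna, "ATAC": atac}

    def test_single_modality_one_sample_per_state_cell(self):
        table = labeled_clone_table(
            {0: [("r1", "RNA"), ("r2", "RNA"), ("r3", "RNA")]}, {0: "Mono"}
        )
        ds = assemble_dataset(self.features(), table, "rna_hvg_residuals")
        assert ds.n_samples == 3
        assert set(ds.y) == {"Mono"}

    def test_combined_pairs_min_of_siblings(self):
        table = labeled_clone_table(
            {0: [("r1", "RNA"), ("r2", "RNA"), ("a1", "ATAC")]}, {0: "Mono"}
        )
        ds = assemble_dataset(self.features(), table, "combined", pairing_seed=1)
        assert ds.n_samples == 1  # min(2 RNA, 1 ATAC)
        assert ds.X.shape[1] == 4  # concatenated features
        assert ds.feature_names[:2] == ["RNA:g1", "RNA:g2"]

    def test_combined_excludes_single_modality_clones(self):
        table = labeled_clone_table(
            {0: [("r1", "RNA"), ("a1", "ATAC")], 1: [("r2", "RNA")]}, {0: "A", 1: "B"}
        )
        ds = assemble_dataset(self.features(), table, "combined")
        assert set(ds.clone_ids) == {0}

    def test_combined_without_multiomic_clones_raises(self):
        table = labeled_clone_table({0: [("r1", "RNA")]}, {0: "A"})
        with pytest.raises(ValueError):
            assemble_dataset(self.features(), table, "combined")

    def test_unlabeled_clones_excluded_with_warning(self):
        table = labeled_clone_table(
            {0: [("r1", "RNA")], 1: [("r2", "RNA")]}, {0: "A"}
        )
        with pytest.warns(UserWarning, match="without a fate label"):
            ds = assemble_dataset(self.features(), table, "rna_hvg_residuals")
        assert ds.sample_ids == ["r1"]

    def test_pairing_deterministic_given_seed(self):
        table = labeled_clone_table(
            {0: [("r1", "RNA"), ("r2", "RNA"), ("r3", "RNA"),
                 ("a1", "ATAC"), ("a2", "ATAC")]},
            {0: "A"},
        )
        ds1 = assemble_dataset(self.features(), table, "combined", pairing_seed=7)
        ds2 = assemble_dataset(self.features(), table, "combined", pairing_seed=7)
        assert ds1.sample_ids == ds2.sample_ids


class TestKnnImpute:
    def test_k1_is_identity(self):
        x = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)))
        out = knn_impute(x, k=1)
        pd.testing.assert_frame_equal(out, x)

    def test_two_cells_average(self):
        x = np.array([[0.0], [2.0]])
        np.testing.assert_allclose(knn_impute(x, k=2), [[1.0], [1.0]])

    def test_matches_bruteforce_neighbor_oracle(self):
        rng = np.random.default_rng(5)
        space = rng.normal(size=(50, 4))
        values = rng.normal(size=(50, 3))
        k = 7
        out = knn_impute(values, k=k, neighbor_space=space)
        # oracle: all-pairs distances, stable top-k
        d = np.linalg.norm(space[:, None, :] - space[None, :, :], axis=2)
        for i in range(50):
            nn = np.argsort(d[i], kind="stable")[:k]
            np.testing.assert_allclose(out[i], values[nn].mean(axis=0), atol=1e-12)

    def test_k_exceeding_cells_raises(self):
        with pytest.raises(ValueError):
            knn_impute(np.ones((3, 2)), k=4)


class TestCrossValidateFate:
    def test_returns_exactly_25_scores(self):
        ds = synthetic_dataset()
        cv = cross_validate_fate(ds, model="logistic_regression", grid={}, seed=0)
        assert len(cv.accuracies) == 25
        assert len(cv.f1_weighted) == 25

    def test_separable_signal_is_learned_perfectly(self):
        ds = synthetic_dataset(effect=8.0)
        cv = cross_validate_fate(ds, model="logistic_regression", grid={}, seed=0)
        assert cv.accuracies.mean() == pytest.approx(1.0)

    def test_shuffled_labels_fall_to_majority_baseline(self):
        ds = synthetic_dataset(effect=0.0, n_clones=30, seed=3)
        baseline = ds.majority_class_frequency()
        means = []
        for shuffle_seed in range(5):
            rng = np.random.default_rng(shuffle_seed)
            # permute fate labels across clones
            clones = np.unique(ds.clone_ids)
            fate_of = dict(zip(clones, rng.permutation(
                [ds.y[ds.clone_ids == c][0] for c in clones]
            )))
            ds_shuf = type(ds)(
                X=ds.X, y=np.array([fate_of[c] for c in ds.clone_ids]),
                clone_ids=ds.clone_ids, sample_ids=ds.sample_ids,
                feature_names=ds.feature_names, feature_space=ds.feature_space,
            )
            cv = cross_validate_fate(ds_shuf, model="logistic_regression", grid={}, seed=1)
            means.append(cv.accuracies.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - baseline) <= max(3 * se, 0.1)

    def test_group_by_clone_keeps_siblings_in_one_fold(self):
        ds = synthetic_dataset()
        cv = cross_validate_fate(ds, model="logistic_regression", grid={}, seed=0)
        for test in cv.fold_test_indices:
            test_clones = set(ds.clone_ids[test])
            train = np.setdiff1d(np.arange(ds.n_samples), test)
            assert not test_clones & set(ds.clone_ids[train])

    def test_deterministic_given_seed(self):
        ds = synthetic_dataset()
        cv1 = cross_validate_fate(ds, model="logistic_regression", grid={}, seed=5)
        cv2 = cross_validate_fate(ds, model="logistic_regression", grid={}, seed=5)
        np.testing.assert_array_equal(cv1.accuracies, cv2.accuracies)

    def test_nested_grid_search_runs(self):
        ds = synthetic_dataset(n_clones=16, cells_per_clone=2)
        cv = cross_validate_fate(
            ds, model="logistic_regression", grid={"C": [0.01, 10.0]},
            n_splits=3, n_repeats=1, seed=0,
        )
        assert len(cv.accuracies) == 3
        assert all("C" in p for p in cv.chosen_params)

    def test_small_class_rejected(self):
        ds = synthetic_dataset(n_clones=4, cells_per_clone=1)
        with pytest.raises(ValueError, match="n_splits"):
            cross_validate_fate(ds, model="logistic_regression", grid={})

    def test_lightgbm_model_runs(self):
        ds = synthetic_dataset(effect=8.0)
        cv = cross_validate_fate(
            ds, model="gradient_boosted_trees",
            grid={"n_estimators": [20], "min_child_samples": [5]},
            n_splits=3, n_repeats=1, seed=0,
        )
        assert cv.accuracies.mean() > 0.9


class TestShapSummary:
    def make_cv(self, effect=4.0, seed=0):
        ds = synthetic_dataset(
            n_clones=16, cells_per_clone=3, n_features=4, effect=effect, seed=seed
        )
        cv = cross_validate_fate(
            ds, model="random_forest", grid={"n_estimators": [25]},
            n_splits=3, n_repeats=2, seed=0,
        )
        return ds, cv

    def test_planted_feature_dominates_importance_with_positive_correlation(self):
        ds, cv = self.make_cv()
        importance, corr = shap_summary(cv, ds, background_size=15, seed=0)
        # feature 0 carries the fate-A signal
        assert importance["A"].idxmax() == ds.feature_names[0]
        assert corr.loc[ds.feature_names[0], "A"] > 0.5
        assert corr.loc[ds.feature_names[0], "B"] < -0.5

    def test_constant_feature_has_zero_importance(self):
        ds, cv = self.make_cv(seed=1)
        ds.X[:, 2] = 1.0
        cv = cross_validate_fate(
            ds, model="random_forest", grid={"n_estimators": [25]},
            n_splits=3, n_repeats=1, seed=0,
        )
        importance, corr = shap_summary(cv, ds, background_size=10, seed=0)
        assert importance.loc[ds.feature_names[2]].max() == pytest.approx(0.0, abs=1e-10)
        assert corr.loc[ds.feature_names[2]].isna().all()

    def test_importance_nonnegative_and_correlation_bounded(self):
        ds, cv = self.make_cv(seed=2)
        importance, corr = shap_summary(cv, ds, background_size=10, seed=0)
        assert (importance.to_numpy() >= 0).all()
        finite = corr.to_numpy()[np.isfinite(corr.to_numpy())]
        assert ((finite >= -1) & (finite <= 1)).all()

    def test_non_tree_model_rejected(self):
        ds = synthetic_dataset()
        cv = cross_validate_fate(ds, model="logistic_regression", grid={}, seed=0)
        with pytest.raises(ValueError, match="tree"):
            shap_summary(cv, ds)


def ranksum_enumeration_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    m = len(x)
    u_obs = mannwhitneyu(x, y).statistic
    us = []
    for idx in itertools.combinations(range(len(pooled)), m):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        us.append(mannwhitneyu(pooled[mask], pooled[~mask]).statistic)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestDifferentialEnrichment:
    def frame(self, a, b):
        values = np.concatenate([a, b])
        cells = [f"c{i}" for i in range(len(values))]
        features = pd.DataFrame({"f": values}, index=cells)
        groups = pd.Series(["g1"] * len(a) + ["g2"] * len(b), index=cells)
        return features, groups

    def test_worked_example_p_point_one(self):
        features, groups = self.frame([1, 2, 3], [4, 5, 6])
        table = differential_enrichment(
            features, groups, effect="mean_difference", effect_threshold=0.5
        )
        g2 = table[table["group"] == "g2"].iloc[0]
        assert g2["p_value"] == pytest.approx(0.1)
        assert g2["p_adj"] == pytest.approx(0.1)  # single feature: BH is identity
        assert g2["effect"] == pytest.approx(3.0)

    def test_identical_distributions_not_enriched(self):
        features, groups = self.frame([1, 2, 3], [1, 2, 3])
        table = differential_enrichment(features, groups, effect="mean_difference")
        assert (table["p_value"] == 1.0).all()
        assert not table["enriched"].any()

    def test_pvalues_match_enumeration_oracle_up_to_5_5(self):
        rng = np.random.default_rng(8)
        for m, n in [(3, 3), (4, 5), (5, 5), (2, 5)]:
            x = rng.permutation(np.arange(m + n, dtype=float))[:m]
            y = np.setdiff1d(np.arange(m + n, dtype=float), x)
            features, groups = self.frame(x, y)
            table = differential_enrichment(features, groups, effect="mean_difference")
            p = table.loc[table["group"] == "g1", "p_value"].item()
            assert p == pytest.approx(ranksum_enumeration_oracle(x, y), abs=1e-12)

    def test_shared_enrichment_is_not_unique(self):
        # one feature high in g1 and g3, low in the large background group g2
        cells = [f"c{i}" for i in range(36)]
        g1_vals = np.arange(10.0, 16.0)
        g3_vals = np.arange(10.5, 16.5)
        g2_vals = np.linspace(0.0, 5.0, 24)
        values = np.r_[g1_vals, g2_vals, g3_vals]
        features = pd.DataFrame({"f": values}, index=cells)
        groups = pd.Series(["g1"] * 6 + ["g2"] * 24 + ["g3"] * 6, index=cells)
        table = differential_enrichment(
            features, groups, effect="mean_difference", effect_threshold=0.5
        )
        enriched = table[table["enriched"]]
        assert set(enriched["group"]) == {"g1", "g3"}
        assert not enriched["uniquely_enriched"].any()

    def test_log_fold_change_uses_pseudocount(self):
        features, groups = self.frame([3.0, 3.0, 3.0], [1.0, 1.0, 1.0])
        table = differential_enrichment(features, groups, effect="log_fold_change")
        eff = table.loc[table["group"] == "g1", "effect"].item()
        assert eff == pytest.approx(np.log2(4 / 2))

    def test_small_group_rejected(self):
        features, groups = self.frame([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            differential_enrichment(features, groups)


class TestBenjaminiHochberg:
    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(benjamini_hochberg(p), ref, atol=1e-12)

    def test_adjusted_at_least_raw_and_rank_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.random(30)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestTfActivityQcFilter:
    def test_perfect_and_negated_correlation(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(100, 2))
        activity = pd.DataFrame(base, columns=["TF1", "TF2"])
        scores = pd.DataFrame(
            np.column_stack([base[:, 0], -base[:, 1]]), columns=["TF1", "TF2"]
        )
        assert tf_activity_qc_filter(activity, scores) == ["TF1"]

    def test_planted_correlation_split(self):
        rng = np.random.default_rng(1)
        n, n_tf = 2000, 100
        scores = rng.normal(size=(n, n_tf))
        activity = np.empty_like(scores)
        # first half: r ~ 0.5; second half: r ~ 0
        activity[:, :50] = scores[:, :50] + rng.normal(0, np.sqrt(3), size=(n, 50))
        activity[:, 50:] = rng.normal(size=(n, 50))
        cols = [f"TF{i}" for i in range(n_tf)]
        kept = tf_activity_qc_filter(
            pd.DataFrame(activity, columns=cols), pd.DataFrame(scores, columns=cols)
        )
        assert kept == cols[:50]

    def test_column_mismatch_raises(self):
        a = pd.DataFrame(np.ones((3, 2)), columns=["TF1", "TF2"])
        b = pd.DataFrame(np.ones((3, 2)), columns=["TF1", "TF3"])
        with pytest.raises(ValueError):
            tf_activity_qc_filter(a, b)
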