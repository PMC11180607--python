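"""State–fate analysis: can a cell's early profile predict its clone's fate?

Clonal lineage tracing links cells profiled at an early "state" time point
to the eventual fate of their clone (the modal type among later-captured
siblings). This module assembles labeled datasets from state cells and
fate-annotated clones — single-modality, or "combined" where an RNA and an
ATAC state sibling of the same clone are randomly paired and their features
concatenated — and runs a repeated stratified cross-validation harness
(n_splits=5, n_repeats=5, yielding 25 accuracy and 25 weighted-F1 values)
over a small model zoo with nested hyperparameter selection. Trained tree
models are interpreted with interventional Shapley values (mean |value| per
feature–fate importance, and the Pearson correlation between a feature and
its attributions, whose sign says whether high feature values push toward
or away from a fate).

Differential feature enrichment between fate-destined groups uses two-sided
rank-sum tests with Benjamini–Hochberg correction and an effect-size
threshold (log fold-change for count-derived features, difference of means
for z-scored activities).
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import clone as sk_clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import (
    GridSearchCV,
    ParameterGrid,
    StratifiedGroupKFold,
    StratifiedKFold,
)
from sklearn.neighbors import NearestNeighbors

from .clones import CloneTable
from .shapley import shapley_values
from .stats import benjamini_hochberg

TREE_MODELS = ("random_forest", "gradient_boosted_trees")
MODELS = TREE_MODELS + ("logistic_regression",)

#: Hyperparameter grids searched by the reference workflow.
DEFAULT_GRIDS: dict[str, dict] = {
    "random_forest": {
        "n_estimators": [100, 300, 1000],
        "max_depth": [10, 50, None],
        "min_samples_leaf": [1, 2, 4],
        "bootstrap": [True, False],
    },
    "gradient_boosted_trees": {
        "num_leaves": [7, 15, 31, 80],
        "max_depth": [5, 9, 30],
        "min_child_samples": [20, 40, 80],
        "subsample": [0.8, 1.0],
        "subsample_freq": [3],
        "colsample_bytree": [0.1, 0.9],
    },
    "logistic_regression": {
        "penalty": ["l2", None],
        "C": np.logspace(-4, 4, 20).tolist(),
        "solver": ["lbfgs", "newton-cg", "saga"],
        "max_iter": [1000],
    },
}


def make_model(name: str, params: Mapping | None = None, seed: int = 0):
    """Instantiate a classifier from the model zoo."""
    params = dict(params or {})
    if name == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if name == "gradient_boosted_trees":
        from lightgbm import LGBMClassifier

        params.setdefault("verbose", -1)
        return LGBMClassifier(random_state=seed, n_jobs=1, **params)
    if name == "logistic_regression":
        params.setdefault("max_iter", 1000)
        return LogisticRegression(random_state=seed, **params)
    raise ValueError(f"unknown model {name!r}; choose from {MODELS}")


@dataclass
class StateFateDataset:
    """Labeled feature matrix for fate prediction, with clone grouping."""

    X: np.ndarray
    y: np.ndarray
    clone_ids: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]
    feature_space: str
    pairing_seed: int | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.clone_ids = np.asarray(self.clone_ids)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.clone_ids) == len(self.sample_ids) == n):
            raise ValueError("sample axis mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> list[str]:
        return sorted(set(map(str, self.y)))

    def majority_class_frequency(self) -> float:
        _, counts = np.unique(self.y, return_counts=True)
        return float(counts.max() / counts.sum())


_SPACE_MODALITY = {
    "rna_hvg_residuals": "RNA",
    "tf_activity": "ATAC",
    "tf_expression": "RNA",
}


def assemble_dataset(
    features: Mapping[str, pd.DataFrame],
    clones: CloneTable,
    feature_space: str,
    state_timepoints: list[str] | None = None,
    pairing_seed: int = 0,
) -> StateFateDataset:
    """Build a state–fate dataset from per-modality features and labeled clones.

    Parameters
    ----------
    features
        Modality -> (cells x features) frame of state-cell features.
    clones
        Fate-annotated clone table; clones without a fate label are
        excluded with a warning.
    feature_space
        ``rna_hvg_residuals`` / ``tf_expression`` (RNA cells),
        ``tf_activity`` (ATAC cells), ``combined`` (random RNA–ATAC sibling
        pairing within each clone, features concatenated) or ``custom``
        (``features`` must hold exactly one frame).
    state_timepoints
        Restrict to cells at these time points (default: all cells present
        in the feature frames).
    pairing_seed
        Seed of the random sibling bijection in combined mode. Within each
        clone min(#RNA, #ATAC) pairs are formed; surplus siblings are
        dropped.
    """
    cells = clones.cells
    unlabeled = cells["fate_label"].isna()
    if unlabeled.any():
        n_excl = cells.loc[unlabeled, "clone_id"].nunique()
        warnings.warn(f"excluding {n_excl} clones without a fate label", stacklevel=2)
    labeled = cells[~unlabeled]
    if state_timepoints is not None:
        labeled = labeled[labeled["time_point"].isin(set(state_timepoints))]

    def modality_cells(modality: str, frame: pd.DataFrame) -> pd.DataFrame:
        sub = labeled[labeled["modality"] == modality]
        return sub[sub["cell"].isin(frame.index)]

    if feature_space == "combined":
        rna_frame, atac_frame = features["RNA"], features["ATAC"]
        rna = modality_cells("RNA", rna_frame)
        atac = modality_cells("ATAC", atac_frame)
        rng = np.random.default_rng(pairing_seed)
        rows, labels, clone_col, ids = [], [], [], []
        for cid in sorted(set(rna["clone_id"]) & set(atac["clone_id"])):
            r_cells = sorted(rna.loc[rna["clone_id"] == cid, "cell"])
            a_cells = sorted(atac.loc[atac["clone_id"] == cid, "cell"])
            n_pairs = min(len(r_cells), len(a_cells))
            r_pick = rng.permutation(r_cells)[:n_pairs]
            a_pick = rng.permutation(a_cells)[:n_pairs]
            fate = labeled.loc[labeled["clone_id"] == cid, "fate_label"].iloc[0]
            for rc, ac in zip(r_pick, a_pick):
                rows.append(
                    np.concatenate(
                        [rna_frame.loc[rc].to_numpy(), atac_frame.loc[ac].to_numpy()]
                    )
                )
                labels.append(fate)
                clone_col.append(cid)
                ids.append(f"{rc}|{ac}")
        if not rows:
            raise ValueError("combined mode: no multi-omic state–fate clones")
        names = [f"RNA:{c}" for c in rna_frame.columns] + [
            f"ATAC:{c}" for c in atac_frame.columns
        ]
        return StateFateDataset(
            X=np.vstack(rows),
            y=np.array(labels),
            clone_ids=np.array(clone_col),
            sample_ids=ids,
            feature_names=names,
            feature_space=feature_space,
            pairing_seed=pairing_seed,
        )

    if feature_space == "custom":
        if len(features) != 1:
            raise ValueError("custom mode expects exactly one feature frame")
        (modality, frame), = features.items()
    else:
        modality = _SPACE_MODALITY.get(feature_space)
        if modality is None:
            raise ValueError(f"unknown feature space {feature_space!r}")
        frame = features[modality]

    sub = modality_cells(modality, frame)
    if len(sub) == 0:
        raise ValueError(f"no labeled state cells for feature space {feature_space!r}")
    cell_list = sub["cell"].tolist()
    return StateFateDataset(
        X=frame.loc[cell_list].to_numpy(dtype=float),
        y=sub["fate_label"].to_numpy(),
        clone_ids=sub["clone_id"].to_numpy(),
        sample_ids=cell_list,
        feature_names=list(frame.columns),
        feature_space=feature_space,
    )


def knn_impute(
    features: pd.DataFrame | np.ndarray,
    k: int = 20,
    neighbor_space: np.ndarray | None = None,
) -> pd.DataFrame | np.ndarray:
    """Smooth noisy per-cell features by averaging over k nearest neighbors.

    Neighbors (self included — a cell is its own nearest neighbor at
    distance 0) are found by Euclidean distance in ``neighbor_space``
    (e.g. a reduced-dimension embedding), defaulting to the feature space
    itself.
    """
    values = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    space = values if neighbor_space is None else np.asarray(neighbor_space, dtype=float)
    n = values.shape[0]
    if space.shape[0] != n:
        raise ValueError("neighbor_space rows must align with features rows")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    nn = NearestNeighbors(n_neighbors=k).fit(space)
    _, idx = nn.kneighbors(space)
    smoothed = values[idx].mean(axis=1)
    if isinstance(features, pd.DataFrame):
        return pd.DataFrame(smoothed, index=features.index, columns=features.columns)
    return smoothed


@dataclass
class CVResult:
    """Outcome of repeated stratified k-fold cross-validation."""

    model_name: str
    accuracies: np.ndarray
    f1_weighted: np.ndarray
    fold_test_indices: list[np.ndarray] = field(repr=False)
    models: list = field(repr=False)
    chosen_params: list = field(repr=False)
    classes: list[str] = field(default_factory=list)
    n_splits: int = 5
    n_repeats: int = 5
    seed: int = 0

    def summary(self) -> dict:
        return {
            "model": self.model_name,
            "mean_accuracy": float(self.accuracies.mean()),
            "sd_accuracy": float(self.accuracies.std(ddof=1)),
            "mean_f1_weighted": float(self.f1_weighted.mean()),
            "sd_f1_weighted": float(self.f1_weighted.std(ddof=1)),
            "n_folds": len(self.accuracies),
        }


def cross_validate_fate(
    ds: StateFateDataset,
    model: str = "random_forest",
    grid: Mapping | None = None,
    n_splits: int = 5,
    n_repeats: int = 5,
    seed: int = 0,
    group_by_clone: bool = True,
    inner_splits: int = 3,
) -> CVResult:
    """Repeated stratified k-fold fate prediction.

    Produces ``n_splits * n_repeats`` accuracy and weighted-F1 values (25
    by default). Folds are stratified by fate label; with
    ``group_by_clone`` (default) all samples of one clone land in the same
    fold, so sibling correlation cannot leak between train and test. When
    ``grid`` spans more than one hyperparameter combination, selection runs
    as a nested grid search on the training folds only. ``grid=None`` uses
    the reference grids (:data:`DEFAULT_GRIDS`); pass ``{}`` for the model
    defaults.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    classes, counts = np.unique(ds.y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 fate classes")
    if counts.min() < n_splits:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} samples < n_splits={n_splits}"
        )
    grid = DEFAULT_GRIDS[model] if grid is None else dict(grid)
    combos = list(ParameterGrid(grid)) if grid else [{}]

    accs, f1s, test_sets, models, chosen = [], [], [], [], []
    for rep in range(n_repeats):
        rep_seed = seed * 1000 + rep
        if group_by_clone:
            splitter = StratifiedGroupKFold(
                n_splits=n_splits, shuffle=True, random_state=rep_seed
            )
            splits = splitter.split(ds.X, ds.y, groups=ds.clone_ids)
        else:
            splitter = StratifiedKFold(
                n_splits=n_splits, shuffle=True, random_state=rep_seed
            )
            splits = splitter.split(ds.X, ds.y)
        for train, test in splits:
            if len(combos) > 1:
                search = GridSearchCV(
                    make_model(model, seed=rep_seed),
                    grid,
                    cv=StratifiedKFold(
                        n_splits=inner_splits, shuffle=True, random_state=rep_seed
                    ),
                    scoring="accuracy",
                    n_jobs=1,
                )
                search.fit(ds.X[train], ds.y[train])
                est = sk_clone(search.best_estimator_)
                params = search.best_params_
            else:
                est = make_model(model, combos[0], seed=rep_seed)
                params = combos[0]
            est.fit(ds.X[train], ds.y[train])
            pred = est.predict(ds.X[test])
            accs.append(accuracy_score(ds.y[test], pred))
            f1s.append(f1_score(ds.y[test], pred, average="weighted"))
            test_sets.append(np.asarray(test))
            models.append(est)
            chosen.append(params)
    return CVResult(
        model_name=model,
        accuracies=np.array(accs),
        f1_weighted=np.array(f1s),
        fold_test_indices=test_sets,
        models=models,
        chosen_params=chosen,
        classes=[str(c) for c in classes],
        n_splits=n_splits,
        n_repeats=n_repeats,
        seed=seed,
    )


def shap_summary(
    cv: CVResult,
    ds: StateFateDataset,
    background_size: int = 50,
    method: str = "auto",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature importance and feature–attribution correlation from a CV run.

    For every fold's trained tree model, Shapley values of each test-set
    sample are computed per fate class against a background drawn from the
    fold's training data; each data point appears in one test set per
    repeat, so its ``n_repeats`` attribution vectors are averaged before
    summarising (smoothing out model-training artifacts). Returns

    * importance: mean |Shapley value| per (feature, fate);
    * shap_correlation: Pearson r between a feature's values and its
      attributions for a fate — positive when high feature values push the
      model toward that fate.
    """
    if cv.model_name not in TREE_MODELS:
        raise ValueError(f"shap_summary supports tree models, not {cv.model_name!r}")
    rng = np.random.default_rng(seed)
    n, p = ds.X.shape
    classes = cv.classes
    sums = np.zeros((n, p, len(classes)))
    counts = np.zeros(n)
    all_idx = np.arange(n)
    for est, test in zip(cv.models, cv.fold_test_indices):
        train = np.setdiff1d(all_idx, test)
        bg_idx = rng.choice(train, size=min(background_size, len(train)), replace=False)
        background = ds.X[bg_idx]
        model_classes = [str(c) for c in est.classes_]
        for c_i, cls in enumerate(classes):
            if cls not in model_classes:
                continue
            col = model_classes.index(cls)

            def predict(Z: np.ndarray, _est=est, _col=col) -> np.ndarray:
                return _est.predict_proba(Z)[:, _col]

            phi, _ = shapley_values(
                predict, ds.X[test], background, method=method, seed=seed
            )
            sums[test, :, c_i] += phi
        counts[test] += 1
    counts = np.maximum(counts, 1)[:, None, None]
    mean_phi = sums / counts

    importance = pd.DataFrame(
        np.abs(mean_phi).mean(axis=0), index=ds.feature_names, columns=classes
    )
    corr = pd.DataFrame(index=ds.feature_names, columns=classes, dtype=float)
    for j in range(p):
        xj = ds.X[:, j]
        for c_i in range(len(classes)):
            sj = mean_phi[:, j, c_i]
            if np.std(xj) == 0 or np.std(sj) == 0:
                corr.iloc[j, c_i] = np.nan
            else:
                corr.iloc[j, c_i] = float(np.corrcoef(xj, sj)[0, 1])
    importance.index.name = corr.index.name = "feature"
    return importance, corr


def differential_enrichment(
    features: pd.DataFrame,
    groups: pd.Series,
    effect: str = "log_fold_change",
    fdr_threshold: float = 0.05,
    effect_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest differential feature enrichment between labeled groups.

    For each group, every feature is tested with a two-sided rank-sum test
    against all remaining cells; p-values are Benjamini–Hochberg adjusted
    across features within the group. Effect sizes: ``log_fold_change`` =
    log2 of (mean + pseudocount) ratios, for count-derived features;
    ``mean_difference`` for already z-scored features. A feature is
    enriched when adjusted p < ``fdr_threshold`` and effect >
    ``effect_threshold``, and uniquely enriched when that holds in exactly
    one group.
    """
    if effect not in ("log_fold_change", "mean_difference"):
        raise ValueError(f"unknown effect {effect!r}")
    groups = groups.loc[features.index]
    labels = sorted(groups.unique())
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"groups of size < 2: {sizes[sizes < 2].index.tolist()}")
    X = features.to_numpy(dtype=float)
    frames = []
    for g in labels:
        mask = (groups == g).to_numpy()
        a, b = X[mask], X[~mask]
        pvals = np.array(
            [
                mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
                for j in range(X.shape[1])
            ]
        )
        padj = benjamini_hochberg(pvals)
        if effect == "log_fold_change":
            eff = np.log2(
                (a.mean(axis=0) + pseudocount) / (b.mean(axis=0) + pseudocount)
            )
        else:
            eff = a.mean(axis=0) - b.mean(axis=0)
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "feature": features.columns,
                    "p_value": pvals,
                    "p_adj": padj,
                    "effect": eff,
                    "enriched": (padj < fdr_threshold) & (eff > effect_threshold),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    n_enriched = table.groupby("feature")["enriched"].transform("sum")
    table["uniquely_enriched"] = table["enriched"] & (n_enriched == 1)
    return table


def tf_activity_qc_filter(
    tf_activity: pd.DataFrame,
    gene_scores: pd.DataFrame,
    min_corr: float = 0.3,
) -> list[str]:
    """Retain TFs whose motif activity tracks their gene-level accessibility.

    A TF whose chromVAR-style activity z-score is uncorrelated with its own
    gene score is likely a motif-family artefact; TFs with Pearson
    correlation >= ``min_corr`` (columns matched by name, cells by index)
    are kept.
    """
    if list(tf_activity.columns) != list(gene_scores.columns):
        raise ValueError("tf_activity and gene_scores must have matching TF columns")
    common = tf_activity.index.intersection(gene_scores.index)
    a = tf_activity.loc[common].to_numpy(dtype=float)
    g = gene_scores.loc[common].to_numpy(dtype=float)
    a_c = a - a.mean(axis=0)
    g_c = g - g.mean(axis=0)
    denom = np.sqrt((a_c**2).sum(axis=0) * (g_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (a_c * g_c).sum(axis=0) / denom, np.nan)
    return [t for t, ri in zip(tf_activity.columns, r) if np.isfinite(ri) and ri >= min_corr]
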