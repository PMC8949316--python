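"""Composition analytics for the selected (proliferative) clusters: per-sample
lipid class shares of TIC, within-class species mole percentages, two-group
fold changes with t-tests, and PCA separation of study groups.

A note on "mole %": as is conventional for MALDI imaging data, percentages are
computed from intensity shares without molar response correction, so values
are comparable only within a lipid class, never across classes.

Group statistics operate on section-level values (one row per biological
replicate); pixel-level replicates are averaged within the selected cluster
first, which avoids pseudo-replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .ims_proc import AnnotatedFeatureMatrix
from .lipid_chem import LipidClass
from .segmentation import SegmentationResult

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionTable",
    "GroupComparison",
    "composition",
    "build_composition_table",
    "compare_groups",
    "pca_separation",
]


@dataclass
class CompositionTable:
    """Per-sample composition of the selected cluster.

    ``class_shares``: samples x classes, share of TIC within the sample's
    polarity (rows sum to 1 per polarity block). ``species_molpct``: per
    class, samples x species mole-% (rows sum to 100).
    """

    class_shares: pd.DataFrame
    species_molpct: dict[str, pd.DataFrame]
    group: str = ""

    @property
    def samples(self) -> list[str]:
        return list(self.class_shares.index)


def composition(
    features: AnnotatedFeatureMatrix,
    segmentation: SegmentationResult,
    sample_id: str,
    cluster: int | None = None,
) -> CompositionTable:
    """Composition of one sample's selected cluster.

    Pixel vectors are averaged within the cluster, then class share is the
    summed species intensity of the class over the cluster TIC, and species
    mole-% is 100 x species / class total.
    """
    if cluster is None:
        cluster = segmentation.selected_cluster
    if cluster is None:
        raise ValueError("no cluster selected; run match_roi or pass cluster=")
    rows = segmentation.cluster_pixels(cluster)
    if rows.size == 0:
        raise ValueError(f"selected cluster {cluster} is empty")

    mean_vec = features.matrix[rows].mean(axis=0)
    tic = mean_vec.sum()
    if tic <= 0:
        raise ValueError("selected cluster has zero total intensity")

    classes = sorted({f.species.lipid_class for f in features.features},
                     key=lambda c: c.value)
    share_row, molpct = {}, {}
    for cls in classes:
        idx = [j for j, f in enumerate(features.features)
               if f.species.lipid_class is cls]
        class_total = mean_vec[idx].sum()
        share_row[cls.value] = class_total / tic
        if class_total <= 0:
            logger.warning("composition: class %s has zero total in %s; "
                           "species mole%% undefined", cls.value, sample_id)
            continue
        molpct[cls.value] = pd.DataFrame(
            [100.0 * mean_vec[idx] / class_total],
            index=[sample_id],
            columns=[features.features[j].species.shorthand for j in idx],
        )
    return CompositionTable(
        class_shares=pd.DataFrame([share_row], index=[sample_id]),
        species_molpct=molpct,
    )


def build_composition_table(
    tables: list[CompositionTable], group: str = ""
) -> CompositionTable:
    """Stack per-sample composition tables into one group-level table."""
    if not tables:
        raise ValueError("no samples")
    class_shares = pd.concat([t.class_shares for t in tables])
    species = {}
    for cls in {c for t in tables for c in t.species_molpct}:
        frames = [t.species_molpct[cls] for t in tables if cls in t.species_molpct]
        species[cls] = pd.concat(frames)
    return CompositionTable(class_shares=class_shares,
                            species_molpct=species, group=group)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _two_group_frame(
    a: pd.DataFrame, b: pd.DataFrame, equal_var: bool
) -> pd.DataFrame:
    """Per-column two-sample t-test and fold-change table (b relative to a)."""
    cols = [c for c in a.columns if c in b.columns]
    rows = []
    for c in cols:
        xa, xb = a[c].to_numpy(float), b[c].to_numpy(float)
        mean_a, mean_b = xa.mean(), xb.mean()
        if np.isclose(xa.var(), 0) and np.isclose(xb.var(), 0):
            # degenerate: no within-group variance
            t_stat, p = (0.0, 1.0) if np.isclose(mean_a, mean_b) else (np.inf, 0.0)
        else:
            t_stat, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
        fold = mean_b / mean_a if mean_a > 0 else np.inf
        rows.append({
            "feature": c,
            "mean_a": mean_a,
            "sem_a": stats.sem(xa) if len(xa) > 1 else np.nan,
            "mean_b": mean_b,
            "sem_b": stats.sem(xb) if len(xb) > 1 else np.nan,
            "fold_change": fold,
            "fold_display": (f"{fold:.2f}-fold increase" if fold >= 1
                             else f"{1.0 / fold:.2f}-fold decrease"),
            "t": float(t_stat),
            "p": float(p),
        })
    out = pd.DataFrame(rows).set_index("feature")
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    out["stars"] = [_stars(p) for p in out["p"]]
    return out


@dataclass
class GroupComparison:
    """Two-group comparison (B vs A) of class shares and species mole-%.

    ``classes`` has one row per lipid class; ``species[cls]`` one row per
    species with a ``display`` flag marking species reaching 5% mean
    abundance in at least one group (the plotting convention for the
    species panels).
    """

    classes: pd.DataFrame
    species: dict[str, pd.DataFrame] = field(default_factory=dict)
    group_a: str = "A"
    group_b: str = "B"

    def class_fold(self, lipid_class: str | LipidClass) -> float:
        name = (lipid_class.value if isinstance(lipid_class, LipidClass)
                else lipid_class)
        return float(self.classes.loc[name, "fold_change"])


def compare_groups(
    table_a: CompositionTable,
    table_b: CompositionTable,
    equal_var: bool = True,
    display_min_pct: float = 5.0,
) -> GroupComparison:
    """Compare two groups of sections feature-by-feature.

    Student's t (equal variance) by default, Welch via ``equal_var=False``.
    Fold changes are reported as mean_b / mean_a, with the display string
    flipping to "x-fold decrease" below 1. Species below ``display_min_pct``
    mean abundance in both groups are flagged out of the display set but kept
    in the table.
    """
    if len(table_a.samples) < 3 or len(table_b.samples) < 3:
        raise ValueError("need at least 3 samples per group")
    classes = _two_group_frame(table_a.class_shares, table_b.class_shares,
                               equal_var)
    species = {}
    for cls in sorted(set(table_a.species_molpct) & set(table_b.species_molpct)):
        frame = _two_group_frame(table_a.species_molpct[cls],
                                 table_b.species_molpct[cls], equal_var)
        frame["display"] = (frame["mean_a"] >= display_min_pct) | (
            frame["mean_b"] >= display_min_pct
        )
        species[cls] = frame
    return GroupComparison(
        classes=classes,
        species=species,
        group_a=table_a.group or "A",
        group_b=table_b.group or "B",
    )


def pca_separation(
    composition_rows: pd.DataFrame,
    group_labels: pd.Series | list[str],
    n_components: int = 2,
) -> dict:
    """Unsupervised PCA of standardised composition rows.

    Constant features are dropped (with a warning) before z-scoring; group
    labels are *not* used in the fit, only to score the PC1-2 silhouette.
    Returns scores, explained variance ratios and the group silhouette.
    """
    X = composition_rows.to_numpy(float)
    labels = np.asarray(group_labels)
    keep = X.std(axis=0) > 0
    n_const = int((~keep).sum())
    if n_const:
        logger.warning("pca_separation: dropping %d constant features", n_const)
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    n_components = min(n_components, X.shape[0], X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)

    sil = np.nan
    if len(np.unique(labels)) > 1 and scores.shape[0] > len(np.unique(labels)):
        sil = float(silhouette_score(scores[:, : min(2, scores.shape[1])], labels))
    return {
        "scores": pd.DataFrame(
            scores,
            index=composition_rows.index,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "group_silhouette": sil,
    }
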