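"""Pixel-spectrum segmentation: background filtration, k-means clustering of
lipid profiles with silhouette-based model selection over k = 2..8, and
Dice-overlap matching of clusters against the proliferative (MKI67+) ROI.

The clustering backend is pluggable (``method="kmeans"`` today) so a
hierarchical variant can be slotted in; what downstream stages rely on is only
that pixels with similar lipid composition share a label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .ims_proc import AnnotatedFeatureMatrix, tic_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationResult",
    "filter_background",
    "segment",
    "match_roi",
    "segment_section",
]

BACKGROUND_LABEL = -1


@dataclass
class SegmentationResult:
    """Per-pixel cluster labels plus the ROI-matched cluster.

    ``labels`` is full-length over the feature-matrix rows with
    ``BACKGROUND_LABEL`` (-1) marking background pixels excluded from
    clustering. ``roi_overlap``/``selected_cluster`` are filled by
    :func:`match_roi`.
    """

    labels: np.ndarray
    k: int
    coords: np.ndarray
    silhouette: float
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    roi_overlap: dict[int, float] = field(default_factory=dict)
    selected_cluster: int | None = None

    def cluster_pixels(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def filter_background(raw_tic: np.ndarray, frac: float = 0.1) -> np.ndarray:
    """Tissue mask: pixels whose raw TIC reaches ``frac`` x median TIC.

    Matrix-only pixels carry only faint chemical noise, so their total ion
    current sits orders of magnitude below tissue. ``frac = 0`` keeps all
    pixels.
    """
    if not 0 <= frac < 1:
        raise ValueError("frac must be in [0, 1)")
    raw_tic = np.asarray(raw_tic, dtype=float)
    mask = raw_tic >= frac * np.median(raw_tic)
    if not mask.any():
        raise ValueError("background filtration removed every pixel")
    return mask


def segment(
    features: AnnotatedFeatureMatrix,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
    n_init: int = 10,
    background_frac: float = 0.1,
    log1p: bool = False,
    silhouette_sample: int = 2000,
) -> SegmentationResult:
    """Cluster TIC-normalised pixel profiles into 2-8 segments.

    Background pixels (raw TIC below ``background_frac`` of the median) are
    excluded first. With ``k`` fixed a single k-means fit is used; with a
    range, k maximising the mean silhouette (on up to ``silhouette_sample``
    pixels) wins. Deterministic given ``seed``.
    """
    tissue = filter_background(features.raw_tic, frac=background_frac)
    norm = tic_normalize(
        AnnotatedFeatureMatrix(
            matrix=features.matrix[tissue],
            features=features.features,
            coords=features.coords[tissue],
            raw_tic=features.raw_tic[tissue],
            kept_pixel_index=np.flatnonzero(tissue),
            metadata=features.metadata,
        )
    )
    X = np.log1p(norm.matrix) if log1p else norm.matrix
    n_tissue = X.shape[0]

    ks = [k] if k is not None else list(range(k_range[0], min(k_range[1], n_tissue - 1) + 1))
    if min(ks) > n_tissue:
        raise ValueError(f"k={min(ks)} exceeds {n_tissue} tissue pixels")

    rng = np.random.default_rng(seed)
    sil_by_k: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for kk in ks:
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        fits[kk] = lab
        if len(np.unique(lab)) < 2:
            sil_by_k[kk] = -1.0
            continue
        sample = min(silhouette_sample, n_tissue)
        sil_by_k[kk] = float(
            silhouette_score(
                X, lab,
                sample_size=sample if sample < n_tissue else None,
                random_state=int(rng.integers(2**31 - 1)),
            )
        )
    best_k = max(sil_by_k, key=sil_by_k.get) if len(ks) > 1 else ks[0]
    if sil_by_k[best_k] < 0.25:
        logger.warning(
            "segment: weak cluster structure (silhouette %.3f at k=%d)",
            sil_by_k[best_k], best_k,
        )

    labels = np.full(features.matrix.shape[0], BACKGROUND_LABEL)
    labels[norm.kept_pixel_index] = fits[best_k]
    return SegmentationResult(
        labels=labels,
        k=best_k,
        coords=features.coords,
        silhouette=sil_by_k[best_k],
        silhouette_by_k=sil_by_k,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 0.0


def match_roi(
    result: SegmentationResult, roi_mask: np.ndarray
) -> tuple[int, pd.DataFrame]:
    """Score each cluster against the ROI mask by Dice overlap and select the
    argmax; ties break toward the larger cluster (logged)."""
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    in_roi = roi_mask[result.coords[:, 1], result.coords[:, 0]]

    rows = []
    overlap: dict[int, float] = {}
    clusters = sorted(c for c in np.unique(result.labels) if c != BACKGROUND_LABEL)
    n_roi = int(roi_mask.sum())
    for c in clusters:
        members = result.labels == c
        inter = int((members & in_roi).sum())
        d = 2.0 * inter / (members.sum() + n_roi)
        overlap[c] = d
        rows.append({"cluster": c, "size": int(members.sum()),
                     "intersection": inter, "dice": d})
    table = pd.DataFrame(rows)

    best = table["dice"].max()
    tied = table[np.isclose(table["dice"], best)]
    if len(tied) > 1:
        logger.info("match_roi: Dice tie among clusters %s; choosing largest",
                    tied["cluster"].tolist())
    selected = int(tied.sort_values(["size", "cluster"],
                                    ascending=[False, True]).iloc[0]["cluster"])
    result.roi_overlap = overlap
    result.selected_cluster = selected
    return selected, table


def segment_section(
    features: AnnotatedFeatureMatrix,
    roi_mask: np.ndarray,
    **segment_kwargs,
) -> SegmentationResult:
    """Convenience: segment then match the ROI; returns the filled result."""
    result = segment(features, **segment_kwargs)
    match_roi(result, roi_mask)
    return result
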