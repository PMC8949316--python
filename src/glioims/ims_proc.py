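"""IMS spectrum processing: peak alignment across pixels, annotation against a
lipid panel, TIC normalisation, and the cross-sample presence filter.

The input is a pixel grid of centroided spectra (one sorted m/z array plus
intensities per pixel). Alignment is a greedy one-pass centroid clustering
along the global m/z axis; a pixel contributes at most one peak per consensus
bin. Downstream statistics operate on the pixels x annotated-features matrix,
row-normalised to total ion current.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lipid_chem import Adduct, Annotation, LipidSpecies, Panel, annotate

logger = logging.getLogger(__name__)

__all__ = [
    "IMSDataset",
    "PeakMatrix",
    "AnnotatedFeatureMatrix",
    "align_peaks",
    "annotate_features",
    "tic_normalize",
    "presence_filter",
    "process_section",
    "write_imzml",
    "read_imzml",
]


@dataclass
class IMSDataset:
    """A pixel grid of centroided spectra with acquisition metadata.

    ``coords`` is (n_pixels, 2) integer (x, y); ``mzs``/``intensities`` are
    per-pixel arrays with m/z sorted ascending.
    """

    coords: np.ndarray
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if len(self.mzs) != len(self.coords) or len(self.intensities) != len(self.coords):
            raise ValueError("coords, mzs and intensities must be parallel")
        if len({tuple(c) for c in self.coords}) != len(self.coords):
            raise ValueError("pixel coordinates must be unique")
        for mz, inten in zip(self.mzs, self.intensities):
            if mz.size and np.any(np.diff(mz) < 0):
                raise ValueError("per-pixel m/z arrays must be sorted")
            if inten.size and np.any(inten < 0):
                raise ValueError("intensities must be non-negative")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    @property
    def polarity(self) -> str:
        return self.metadata.get("polarity", "negative")

    def raw_tic(self) -> np.ndarray:
        return np.array([float(v.sum()) for v in self.intensities])


@dataclass
class PeakMatrix:
    """Aligned pixels x consensus-bin intensity matrix."""

    consensus_mz: np.ndarray
    matrix: np.ndarray            # (n_pixels, n_bins)
    coords: np.ndarray
    metadata: dict = field(default_factory=dict)


@dataclass
class AnnotatedFeatureMatrix:
    """Pixels x annotated lipid features, optionally TIC-normalised.

    One column per (species, adduct); ``raw_tic`` keeps each pixel's total ion
    current over *all* aligned bins (annotated or not) for background
    filtration, and ``kept_pixel_index`` maps rows back to the source pixels.
    """

    matrix: np.ndarray
    features: list[Annotation]
    coords: np.ndarray
    raw_tic: np.ndarray
    kept_pixel_index: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def feature_keys(self) -> list[tuple[LipidSpecies, Adduct]]:
        return [f.key for f in self.features]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix,
            columns=[f.species.shorthand for f in self.features],
        )


def align_peaks(dataset: IMSDataset, tol_ppm: float = 9.0) -> PeakMatrix:
    """Greedy centroid clustering of all pixel peaks along m/z.

    The global peak list is sorted; a new consensus bin opens whenever the gap
    between a peak and the running intensity-weighted bin centroid exceeds
    ``tol_ppm``. Within a bin each pixel keeps its maximum-intensity peak.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if dataset.n_pixels == 0 or all(v.size == 0 for v in dataset.mzs):
        raise ValueError("empty dataset: no peaks to align")

    all_mz = np.concatenate(dataset.mzs)
    all_int = np.concatenate(dataset.intensities)
    all_pix = np.concatenate(
        [np.full(m.size, i) for i, m in enumerate(dataset.mzs)]
    )
    order = np.argsort(all_mz, kind="stable")
    all_mz, all_int, all_pix = all_mz[order], all_int[order], all_pix[order]

    bin_ids = np.empty(all_mz.size, dtype=int)
    centroids: list[float] = []
    centroid = all_mz[0]
    weight = max(all_int[0], 1e-30)
    current = 0
    bin_ids[0] = 0
    for i in range(1, all_mz.size):
        mz = all_mz[i]
        if (mz - centroid) / centroid * 1e6 > tol_ppm:
            centroids.append(centroid)
            current += 1
            centroid = mz
            weight = max(all_int[i], 1e-30)
        else:
            w = max(all_int[i], 1e-30)
            centroid = (centroid * weight + mz * w) / (weight + w)
            weight += w
        bin_ids[i] = current
    centroids.append(centroid)

    n_bins = len(centroids)
    matrix = np.zeros((dataset.n_pixels, n_bins))
    # per pixel per bin keep the max-intensity peak (centroided spectra carry
    # at most one true peak per species)
    np.maximum.at(matrix, (all_pix, bin_ids), all_int)
    return PeakMatrix(
        consensus_mz=np.array(centroids),
        matrix=matrix,
        coords=dataset.coords,
        metadata=dict(dataset.metadata),
    )


def annotate_features(
    peaks: PeakMatrix, panel: Panel, tol_ppm: float = 9.0
) -> AnnotatedFeatureMatrix:
    """Annotate consensus bins against the panel and keep annotated columns.

    Bins mapping to the same (species, adduct) are summed so the output has
    exactly one column per feature. Raw TIC (over all bins) is preserved.
    """
    annotations = annotate(peaks.consensus_mz, panel, tol_ppm=tol_ppm)
    raw_tic = peaks.matrix.sum(axis=1)

    by_key: dict[tuple, tuple[Annotation, list[int]]] = {}
    for j, ann in enumerate(annotations):
        if ann is None:
            continue
        if ann.key in by_key:
            by_key[ann.key][1].append(j)
        else:
            by_key[ann.key] = (ann, [j])

    keys = sorted(by_key, key=lambda k: by_key[k][0].theoretical_mz)
    features, cols = [], []
    for k in keys:
        ann, idx = by_key[k]
        features.append(ann)
        cols.append(peaks.matrix[:, idx].sum(axis=1))
    matrix = np.column_stack(cols) if cols else np.zeros((peaks.matrix.shape[0], 0))
    return AnnotatedFeatureMatrix(
        matrix=matrix,
        features=features,
        coords=peaks.coords,
        raw_tic=raw_tic,
        kept_pixel_index=np.arange(peaks.matrix.shape[0]),
        metadata=dict(peaks.metadata),
    )


def tic_normalize(features: AnnotatedFeatureMatrix) -> AnnotatedFeatureMatrix:
    """Divide each pixel row by its sum over kept features; drop zero-TIC rows.

    Idempotent: normalising an already-normalised matrix is a no-op.
    """
    sums = features.matrix.sum(axis=1)
    keep = sums > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("tic_normalize: dropped %d zero-TIC pixels", n_dropped)
    return AnnotatedFeatureMatrix(
        matrix=features.matrix[keep] / sums[keep, None],
        features=features.features,
        coords=features.coords[keep],
        raw_tic=features.raw_tic[keep],
        kept_pixel_index=features.kept_pixel_index[keep],
        metadata=features.metadata,
    )


def presence_filter(
    sample_tables: Sequence[AnnotatedFeatureMatrix],
    threshold: float = 0.8,
    p_min: float = 0.01,
) -> tuple[list[tuple[LipidSpecies, Adduct]], pd.DataFrame]:
    """Keep features present in at least ``ceil(threshold * n_samples)`` samples.

    A feature is *present* in a sample when it is detected (nonzero) in at
    least ``p_min`` of that sample's pixels. Returns the kept feature keys and
    a per-feature log table (sample counts, kept flag).
    """
    if len(sample_tables) < 2:
        raise ValueError("presence filter needs at least 2 samples")
    n_samples = len(sample_tables)
    n_required = int(np.ceil(threshold * n_samples))

    counts: dict[tuple, int] = {}
    labels: dict[tuple, str] = {}
    for table in sample_tables:
        if table.matrix.shape[0] == 0:
            continue
        detected_frac = (table.matrix > 0).mean(axis=0)
        for f, frac in zip(table.features, detected_frac):
            if frac >= p_min:
                counts[f.key] = counts.get(f.key, 0) + 1
            else:
                counts.setdefault(f.key, 0)
            labels[f.key] = f.species.shorthand

    kept = [k for k, c in counts.items() if c >= n_required]
    log = pd.DataFrame(
        {
            "species": [labels[k] for k in counts],
            "adduct": [k[1].label for k in counts],
            "n_present": list(counts.values()),
            "n_samples": n_samples,
            "kept": [c >= n_required for c in counts.values()],
        }
    ).sort_values(["kept", "species"], ascending=[False, True], ignore_index=True)
    for _, row in log[~log["kept"]].iterrows():
        logger.info(
            "presence_filter: dropped %s (%d/%d samples)",
            row["species"], row["n_present"], n_samples,
        )
    return kept, log


def restrict_features(
    table: AnnotatedFeatureMatrix,
    kept_keys: Iterable[tuple[LipidSpecies, Adduct]],
) -> AnnotatedFeatureMatrix:
    """Subset columns to the kept (species, adduct) keys."""
    kept = set(kept_keys)
    idx = [j for j, f in enumerate(table.features) if f.key in kept]
    return AnnotatedFeatureMatrix(
        matrix=table.matrix[:, idx],
        features=[table.features[j] for j in idx],
        coords=table.coords,
        raw_tic=table.raw_tic,
        kept_pixel_index=table.kept_pixel_index,
        metadata=table.metadata,
    )


def process_section(
    dataset: IMSDataset, panel: Panel, tol_ppm: float = 9.0
) -> AnnotatedFeatureMatrix:
    """align -> annotate for one section; normalisation is applied downstream
    (after background filtration) so raw TIC stays available."""
    peaks = align_peaks(dataset, tol_ppm=tol_ppm)
    pol = dataset.metadata.get("polarity")
    sub = panel.subset(pol) if pol else panel
    return annotate_features(peaks, sub, tol_ppm=tol_ppm)


# --- imzML-style container I/O -------------------------------------------------

def write_imzml(dataset: IMSDataset, path: str | Path) -> Path:
    """Write a dataset as continuous-accession imzML (.imzML + .ibd pair)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    polarity = dataset.metadata.get("polarity", "negative")
    with ImzMLWriter(str(path), polarity=polarity, mode="processed") as writer:
        for (x, y), mz, inten in zip(dataset.coords, dataset.mzs, dataset.intensities):
            writer.addSpectrum(mz, inten, (int(x) + 1, int(y) + 1))
    return path if path.suffix == ".imzML" else path.with_suffix(".imzML")


def read_imzml(path: str | Path, metadata: Mapping | None = None) -> IMSDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    parser = ImzMLParser(str(path))
    coords, mzs, intensities = [], [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        coords.append((int(x) - 1, int(y) - 1))
        mzs.append(np.asarray(mz, dtype=float))
        intensities.append(np.asarray(inten, dtype=float))
    meta = dict(metadata or {})
    meta.setdefault("polarity", parser.polarity or "negative")
    return IMSDataset(
        coords=np.array(coords), mzs=mzs, intensities=intensities, metadata=meta
    )
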