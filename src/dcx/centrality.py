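"""Thresholded-correlation degree centrality (DC).

DC of a voxel (or ROI) is the sum, over all other in-mask voxels, of the
edge weight of its suprathreshold positive Pearson correlations:

    DC(i) = sum_{j != i} w(r_ij) * [r_ij > r_threshold]

with the default edge weight ``w = atanh`` (Fisher r-to-z of the retained
correlations), or the raw correlation (``weighted_r``) or a unit count
(``binary``). Only positive correlations above the threshold (default
r > 0.2, strict) contribute, which suppresses weak noise-driven edges.
Each subject's map is then divided by its whole-brain (in-mask) mean so
maps are comparable across subjects, and finally averaged within the
parcels of an atlas to give the region-wise feature vector used for
classification.

The voxel-wise computation is blockwise: rows of the voxel-by-voxel
correlation matrix are produced in strips and reduced immediately, so the
full matrix is never materialized; the result is exactly independent of
the strip size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import BoldImage

__all__ = [
    "fisher_z",
    "voxelwise_dc",
    "normalize_dc",
    "parcel_average",
    "roi_dc",
    "DCMap",
    "Parcellation",
    "FeatureMatrix",
    "RoiDegreeCentrality",
    "EDGE_KINDS",
    "R_CLIP",
]

EDGE_KINDS = ("weighted_z", "weighted_r", "binary")

#: correlations are clipped to +/-(1 - R_CLIP_EPS) before atanh so that
#: degenerate duplicated series yield a large but finite edge weight
R_CLIP_EPS = 1e-6
R_CLIP = 1.0 - R_CLIP_EPS


def fisher_z(r):
    """Fisher r-to-z transform, ``z = atanh(r)``, with |r| clipped to
    ``1 - 1e-6`` so boundary values stay finite."""
    r = np.clip(np.asarray(r, dtype=float), -R_CLIP, R_CLIP)
    return np.arctanh(r)


@dataclass
class Parcellation:
    """Integer label volume (0 = background) plus label names."""

    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if (self.labels < 0).any():
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = set(self.names) - present
        if missing:
            raise ValueError(f"named labels absent from volume: {sorted(missing)}")

    @property
    def n_rois(self) -> int:
        return len(self.names)

    @property
    def roi_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]


@dataclass
class DCMap:
    """Per-subject degree-centrality map with its provenance."""

    values: np.ndarray  # 3D volume (voxel mode) or 1D ROI vector
    threshold_r: float = 0.2
    edge_kind: str = "weighted_z"
    normalized: bool = False
    mask: np.ndarray = None  # 3D boolean; None in ROI mode


@dataclass
class FeatureMatrix:
    """Subjects x ROIs degree-centrality table with group labels."""

    values: pd.DataFrame  # index: subject ids, columns: ROI names
    groups: pd.Series  # subject id -> group label

    def __post_init__(self):
        self.groups = self.groups.loc[self.values.index]
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def roi_names(self) -> list[str]:
        return list(self.values.columns)

    def binary_labels(self, positive: str) -> np.ndarray:
        """0/1 labels with `positive` coded 1."""
        return (self.groups == positive).to_numpy().astype(int)


def _edge_weights(r_block: np.ndarray, threshold_r: float, edge_kind: str) -> np.ndarray:
    """Apply the threshold + weight rule to a strip of correlations."""
    above = r_block > threshold_r
    if edge_kind == "weighted_z":
        w = fisher_z(r_block)
    elif edge_kind == "weighted_r":
        w = r_block
    elif edge_kind == "binary":
        w = np.ones_like(r_block)
    else:
        raise ValueError(f"edge_kind must be one of {EDGE_KINDS}, got {edge_kind!r}")
    return np.where(above, w, 0.0)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit norm, so x @ x.T is the correlation."""
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    return x / norms


def voxelwise_dc(
    bold: BoldImage,
    mask: np.ndarray = None,
    threshold_r: float = 0.2,
    edge_kind: str = "weighted_z",
    block_size: int = 512,
) -> DCMap:
    """Voxel-wise degree centrality over all in-mask voxel pairs.

    Zero-variance voxels are removed from the mask with a warning (they
    have no defined correlation). Self-edges are excluded. The voxel-pair
    correlation matrix is processed in row strips of `block_size`; the
    result does not depend on the strip size.

    Returns an unnormalized :class:`DCMap`; apply :func:`normalize_dc`
    for the whole-brain-mean standardization.
    """
    mask = np.asarray(bold.mask if mask is None else mask, dtype=bool)
    if mask.shape != bold.spatial_shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    series = bold.data[mask]  # (n_voxels, T)
    if series.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    variances = series.var(axis=1)
    if (variances == 0).any():
        n_bad = int((variances == 0).sum())
        warnings.warn(f"removing {n_bad} zero-variance voxels from mask", stacklevel=2)
        keep = variances > 0
        idx = np.argwhere(mask)
        bad = idx[~keep]
        mask = mask.copy()
        mask[tuple(bad.T)] = False
        series = series[keep]
    if series.shape[0] < 2:
        raise ValueError("need at least 2 in-mask voxels with nonzero variance")

    z = _standardize_rows(series)
    n = z.shape[0]
    dc = np.empty(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        r_block = z[start:stop] @ z.T  # (strip, n)
        w = _edge_weights(r_block, threshold_r, edge_kind)
        # zero the self-edge of each row in the strip
        w[np.arange(stop - start), np.arange(start, stop)] = 0.0
        dc[start:stop] = w.sum(axis=1)

    vol = np.zeros(bold.spatial_shape)
    vol[mask] = dc
    return DCMap(values=vol, threshold_r=threshold_r, edge_kind=edge_kind, normalized=False, mask=mask)


def normalize_dc(dc: DCMap, mask: np.ndarray = None) -> DCMap:
    """Divide by the whole-brain (in-mask) mean DC, so the in-mask mean is 1."""
    if dc.values.ndim == 1:
        vals = dc.values
        mean = vals.mean()
        if mean <= 0:
            raise ValueError(
                "mean DC is not positive (graph fully disconnected); consider a lower threshold"
            )
        return DCMap(values=vals / mean, threshold_r=dc.threshold_r, edge_kind=dc.edge_kind, normalized=True)
    m = dc.mask if mask is None else np.asarray(mask, dtype=bool)
    mean = dc.values[m].mean()
    if mean <= 0:
        raise ValueError(
            "mean DC is not positive (graph fully disconnected); consider a lower threshold"
        )
    out = np.zeros_like(dc.values)
    out[m] = dc.values[m] / mean
    return DCMap(values=out, threshold_r=dc.threshold_r, edge_kind=dc.edge_kind, normalized=True, mask=m)


def parcel_average(dc: DCMap, parcellation: Parcellation, mask: np.ndarray = None) -> pd.Series:
    """Average the DC map within each atlas label.

    Labels with no in-mask voxels are dropped (callers must harmonize the
    dropped set across subjects — :class:`RoiDegreeCentrality` does).
    """
    labels = parcellation.labels
    if labels.shape != dc.values.shape:
        raise ValueError("label volume shape must match DC map")
    m = dc.mask if mask is None else np.asarray(mask, dtype=bool)
    lab = labels[m]
    vals = dc.values[m]
    inside = lab > 0
    if not inside.any():
        raise ValueError("no atlas labels overlap the mask")
    sums = np.bincount(lab[inside], weights=vals[inside])
    counts = np.bincount(lab[inside])
    out = {}
    for k in sorted(parcellation.names):
        if k < len(counts) and counts[k] > 0:
            out[parcellation.names[k]] = sums[k] / counts[k]
    return pd.Series(out)


def roi_dc(roi_series, threshold_r: float = 0.2, edge_kind: str = "weighted_z") -> np.ndarray:
    """Region-level degree centrality from a ``(T, n_rois)`` series table.

    Applies the same edge rule as :func:`voxelwise_dc` to the ROI-by-ROI
    correlation matrix, then normalizes by the mean over ROIs. This is the
    fast path for cohorts simulated directly at the region level.
    """
    x = np.asarray(roi_series, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a (T, n_rois) table with at least 2 ROIs")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    variances = x.var(axis=0)
    if (variances == 0).any():
        offenders = np.nonzero(variances == 0)[0].tolist()
        raise ValueError(f"zero-variance ROI series at columns {offenders}")
    z = _standardize_rows(x.T)
    r = z @ z.T
    w = _edge_weights(r, threshold_r, edge_kind)
    np.fill_diagonal(w, 0.0)
    dc = w.sum(axis=1)
    mean = dc.mean()
    if mean <= 0:
        raise ValueError("mean DC is not positive (all correlations below threshold)")
    return dc / mean


class RoiDegreeCentrality(TransformerMixin, BaseEstimator):
    """Transformer mapping per-subject ROI time series to normalized DC features.

    `transform` accepts a sequence of ``(T, n_rois)`` arrays (one per
    subject) and returns an ``(n_subjects, n_rois)`` feature array of
    whole-set-mean-normalized degree centrality. Stateless; `fit` only
    validates parameters.

    Parameters
    ----------
    threshold_r : float, default 0.2
        Strict lower bound on positive correlations that count as edges.
    edge_kind : {"weighted_z", "weighted_r", "binary"}
        Edge weight: Fisher z of r, raw r, or a unit count.
    """

    def __init__(self, threshold_r: float = 0.2, edge_kind: str = "weighted_z"):
        self.threshold_r = threshold_r
        self.edge_kind = edge_kind

    def fit(self, X, y=None):
        if self.edge_kind not in EDGE_KINDS:
            raise ValueError(f"edge_kind must be one of {EDGE_KINDS}")
        if not -1.0 <= self.threshold_r < 1.0:
            raise ValueError("threshold_r must lie in [-1, 1)")
        self.n_features_in_ = None
        return self

    def transform(self, X):
        self.fit(X)
        rows = [roi_dc(x, self.threshold_r, self.edge_kind) for x in X]
        return np.vstack(rows)
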