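"""Temporal preprocessing of BOLD series.

Covers the denoising stages that operate on the time axis of a resting-state
acquisition: dropping initial volumes (field-stabilization dummies), the
Friston 24-parameter head-motion expansion, nuisance-signal extraction
(global / white-matter / CSF means), ordinary-least-squares confound
regression, linear detrending, ideal (DFT-mask) bandpass filtering in the
canonical 0.01-0.08 Hz resting-state band, and optional isotropic Gaussian
smoothing. Spatial registration stages (realignment, normalization) are out
of scope: inputs are assumed already in a common voxel grid.

All series-level routines take and return ``(T, channels)`` arrays and are
stateless, so they compose in any order; :class:`TemporalPipeline` records
the order actually applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "BoldImage",
    "drop_initial_volumes",
    "friston24_expand",
    "extract_nuisance_signals",
    "regress_confounds",
    "detrend_linear",
    "bandpass",
    "smooth_gaussian",
    "TemporalPipeline",
]

FRISTON24_BLOCKS = ("motion", "motion_lag", "motion_sq", "motion_lag_sq")


@dataclass
class BoldImage:
    """A 4D BOLD acquisition: ``data[x, y, z, t]`` plus geometry and TR.

    `mask` marks in-brain voxels; `meta` accumulates a record of the
    processing stages applied.
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = None
    mask: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_series(self) -> np.ndarray:
        """In-mask voxel time series as a ``(T, n_voxels)`` array."""
        return self.data[self.mask].T

    def with_voxel_series(self, series: np.ndarray) -> "BoldImage":
        """Return a copy with in-mask series replaced by ``(T, n_voxels)``."""
        series = np.asarray(series, dtype=float)
        out = np.zeros(self.spatial_shape + (series.shape[0],))
        out[self.mask] = series.T
        return replace(self, data=out, meta=dict(self.meta))


def drop_initial_volumes(bold: BoldImage, k: int) -> BoldImage:
    """Remove the first `k` volumes (magnetic-field stabilization period)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= bold.n_volumes:
        raise ValueError(f"cannot drop {k} of {bold.n_volumes} volumes")
    meta = dict(bold.meta)
    meta.setdefault("stages", []).append(f"drop:{k}")
    return replace(bold, data=bold.data[..., k:], meta=meta)


def friston24_expand(motion6) -> pd.DataFrame:
    """Expand 6 rigid-body motion parameters to the Friston-24 model.

    Output column blocks, in order: the 6 parameters ``R_t``, their
    one-volume lags ``R_{t-1}`` (first row set to 0), the squares
    ``R_t^2``, and the squared lags ``R_{t-1}^2``.
    """
    m = pd.DataFrame(motion6)
    if m.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {m.shape[1]}")
    vals = m.to_numpy(dtype=float)
    lag = np.vstack([np.zeros((1, 6)), vals[:-1]])
    names = [str(c) for c in m.columns] if not isinstance(m.columns, pd.RangeIndex) else [
        f"mot{i+1}" for i in range(6)
    ]
    blocks = [vals, lag, vals**2, lag**2]
    suffix = ["", "_lag", "_sq", "_lag_sq"]
    cols = [f"{n}{s}" for s, _ in zip(suffix, blocks) for n in names]
    return pd.DataFrame(np.hstack(blocks), columns=cols, index=m.index)


def extract_nuisance_signals(bold: BoldImage, masks: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean in-mask signal per volume for each named nuisance mask.

    Typical masks are ``global`` (whole brain), ``wm`` and ``csf``. Each
    mask is intersected with the image's brain mask.
    """
    cols = {}
    for name, m in masks.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != bold.spatial_shape:
            raise ValueError(f"mask {name!r} shape mismatch")
        m = m & bold.mask
        if not m.any():
            raise ValueError(f"mask {name!r} selects no in-brain voxels")
        cols[name] = bold.data[m].mean(axis=0)
    return pd.DataFrame(cols)


def regress_confounds(series, confounds) -> np.ndarray:
    """OLS residuals of each channel on the confound columns plus intercept.

    Rank-deficient designs are handled by dropping collinear columns (with a
    warning) via a pivoted QR; residuals are orthogonal to every retained
    confound column.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    c = pd.DataFrame(confounds).to_numpy(dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != y.shape[0]:
        raise ValueError("series and confounds must have equal row counts")
    if np.isnan(c).any():
        raise ValueError("confounds contain missing values")
    design = np.column_stack([np.ones(y.shape[0]), c])
    # detect collinearity via rank
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            f"confound design is rank-deficient ({rank}/{design.shape[1]}); "
            "dropping collinear columns",
            stacklevel=2,
        )
        # greedy keep of columns that increase rank
        keep = [0]
        for j in range(1, design.shape[1]):
            cand = design[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > len(keep):
                keep.append(j)
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid.ravel() if squeeze else resid


def detrend_linear(series) -> np.ndarray:
    """Remove the per-channel best-fit straight line (intercept + slope)."""
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    t = y.shape[0]
    if t < 3:
        raise ValueError("need at least 3 time points")
    x = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return resid.ravel() if squeeze else resid


def bandpass(series, tr_seconds: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Ideal DFT-mask bandpass filter.

    Frequency bins ``f`` with ``low_hz <= f <= high_hz`` (inclusive at both
    edges) are retained, all others zeroed; the 0 Hz bin is removed whenever
    ``low_hz > 0``. Being a projection onto a set of Fourier bins, the
    filter is idempotent. Output is real-valued.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    if tr_seconds <= 0:
        raise ValueError("TR must be positive")
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low < high")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high cutoff {high_hz} Hz exceeds Nyquist {nyquist} Hz")
    t = y.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    keep = (freqs >= low_hz - 1e-12) & (freqs <= high_hz + 1e-12)
    spec = np.fft.rfft(y, axis=0)
    spec[~keep] = 0.0
    out = np.fft.irfft(spec, n=t, axis=0)
    return out.ravel() if squeeze else out


def _isotropic_voxel_size(affine: np.ndarray) -> float:
    sizes = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if not np.allclose(sizes, sizes[0], rtol=1e-4):
        raise ValueError(f"anisotropic voxels {sizes}; resampling is out of scope")
    return float(sizes[0])


def smooth_gaussian(bold: BoldImage, fwhm_mm: float) -> BoldImage:
    """Per-volume 3D Gaussian smoothing with the given FWHM (mm).

    ``fwhm = 0`` is the identity. Requires isotropic voxels (the voxel size
    is read off the affine).
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return replace(bold, data=bold.data.copy(), meta=dict(bold.meta))
    vox = _isotropic_voxel_size(bold.affine)
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vox
    out = np.empty_like(bold.data)
    for t in range(bold.n_volumes):
        out[..., t] = ndimage.gaussian_filter(bold.data[..., t], sigma=sigma_vox)
    meta = dict(bold.meta)
    meta.setdefault("stages", []).append(f"smooth:{fwhm_mm}mm")
    return replace(bold, data=out, meta=meta)


@dataclass
class TemporalPipeline:
    """Default temporal pipeline: drop -> (smooth) -> confound regression ->
    detrend -> bandpass.

    Nuisance regression precedes filtering, mirroring the usual processing
    order for resting-state denoising; smoothing, when enabled, is applied
    before confound regression. The applied order is recorded in the output
    metadata.

    Parameters
    ----------
    n_drop : int
        Initial volumes to discard.
    low_hz, high_hz : float
        Bandpass edges.
    fwhm_mm : float
        Gaussian smoothing FWHM; 0 disables (default — synthetic cohorts
        carry no spatial autocorrelation worth smoothing).
    """

    n_drop: int = 10
    low_hz: float = 0.01
    high_hz: float = 0.08
    fwhm_mm: float = 0.0

    def run_image(self, bold: BoldImage, confounds=None) -> BoldImage:
        """Apply the pipeline to a 4D image; confounds rows must match the
        post-drop length."""
        img = drop_initial_volumes(bold, self.n_drop)
        if self.fwhm_mm > 0:
            img = smooth_gaussian(img, self.fwhm_mm)
        series = img.voxel_series()
        series = self.run_series(series, confounds, tr_seconds=img.tr_seconds, drop=False)
        out = img.with_voxel_series(series)
        out.meta.setdefault("stages", []).extend(
            (["confound_regression"] if confounds is not None else [])
            + ["detrend", f"bandpass:{self.low_hz}-{self.high_hz}Hz"]
        )
        return out

    def run_series(self, series, confounds=None, *, tr_seconds: float, drop: bool = True) -> np.ndarray:
        """Apply the temporal stages to a ``(T, channels)`` array."""
        y = np.asarray(series, dtype=float)
        if drop:
            if self.n_drop >= y.shape[0]:
                raise ValueError("cannot drop all volumes")
            y = y[self.n_drop :]
        if confounds is not None:
            y = regress_confounds(y, confounds)
        y = detrend_linear(y)
        return bandpass(y, tr_seconds, self.low_hz, self.high_hz)
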