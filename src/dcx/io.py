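"""NIfTI and TSV input/output.

BOLD images and label volumes go through nibabel (NIfTI-1, ``.nii`` or
``.nii.gz``); all tables are TSV with a header row. Round-trips are
lossless for data, affine and TR (the TR is taken from the header's
time-axis spacing; an explicit override wins with a logged warning).
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .centrality import Parcellation
from .preprocess import BoldImage

__all__ = [
    "read_bold",
    "write_bold",
    "read_labels",
    "write_labels",
    "read_table",
    "write_table",
]

log = logging.getLogger("dcx")


def read_bold(path, tr_seconds: float = None, mask: np.ndarray = None) -> BoldImage:
    """Load a 4D NIfTI BOLD image.

    Parameters
    ----------
    path : str or Path
    tr_seconds : float, optional
        Overrides the header TR (warns when both disagree or the header
        TR is unusable).
    mask : 3D boolean array, optional
        Brain mask; defaults to all voxels.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got {data.ndim}D")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_seconds is not None:
        if header_tr > 0 and not np.isclose(header_tr, tr_seconds):
            log.warning("%s: header TR %.3fs overridden by %.3fs", path, header_tr, tr_seconds)
        elif header_tr <= 0:
            log.warning("%s: unusable header TR; using override %.3fs", path, tr_seconds)
        tr = tr_seconds
    else:
        if header_tr <= 0:
            raise ValueError(f"{path}: header has no usable TR and no override was given")
        tr = header_tr
    return BoldImage(data=data, tr_seconds=tr, affine=img.affine, mask=mask)


def write_bold(bold: BoldImage, path) -> None:
    """Write a :class:`BoldImage` as NIfTI-1, storing the TR in the header."""
    img = nib.Nifti1Image(bold.data, bold.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = bold.tr_seconds
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_labels(path, names: dict[int, str] = None) -> Parcellation:
    """Load a 3D integer label volume; `names` default to ``ROI_<label>``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label volume, got {data.ndim}D")
    labels = np.rint(data).astype(np.int32)
    if names is None:
        names = {int(k): f"ROI_{int(k):03d}" for k in np.unique(labels) if k != 0}
    return Parcellation(labels=labels, names=names)


def write_labels(parcellation: Parcellation, path, affine: np.ndarray = None) -> None:
    img = nib.Nifti1Image(parcellation.labels.astype(np.int32), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
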