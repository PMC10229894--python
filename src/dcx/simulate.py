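"""Synthetic two-group resting-state cohorts with planted degree effects.

The generator is the test bed for the whole pipeline: it emulates a study
design of 22 expertise subjects (radiology interns) and 22 controls, each
with 190 volumes at TR = 2 s, a parcellation of ~246 regions, signed
group differences in degree centrality at designated ROIs, and behavioral
scores (expertise task accuracy and response time, plus a face-memory
control measure) whose expertise-group accuracy is coupled to one
designated "fusiform-analog" ROI's degree centrality.

Model: each group has a modular target correlation matrix (``rho_within``
inside modules, ``rho_between`` across). A planted effect at ROI ``k``
shifts that ROI's off-diagonal row/column by a signed delta — a node-level
("degree") perturbation, matching degree centrality being a node
statistic — then the matrix is repaired to positive definite by eigenvalue
flooring. Subject time series follow a vector AR(1),
``x_t = phi * x_{t-1} + eps_t`` with innovation covariance equal to the
group matrix; the common AR coloring leaves the lag-0 correlation equal to
the innovation correlation. In voxel mode, ROI series are copied to the
voxels of a contiguous-block parcellation with independent additive noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .centrality import Parcellation, roi_dc
from .preprocess import BoldImage

__all__ = [
    "SimConfig",
    "BehaviorTargets",
    "CorrelationStructure",
    "GroundTruth",
    "Cohort",
    "default_planted_effects",
    "build_group_covariance",
    "simulate_cohort",
    "generate_behavior",
    "PLANTED_ROI_SIGNS",
]

#: default planted-effect signs, keyed by the Brainnetome-style analog
#: names of the seven discriminative subregions (sign = direction of the
#: expertise-group DC change; FuG_L and SFG_L increase, the rest decrease)
PLANTED_ROI_SIGNS = {
    "MFG_L_7_7": -1,
    "OrG_R_6_4": -1,
    "FuG_L_3_3": +1,
    "PhG_L_6_1": -1,
    "PhG_R_6_4": -1,
    "SFG_R_7_6": -1,
    "SFG_L_7_7": +1,
}

#: the ROI whose degree centrality drives the expertise score
BEHAVIOR_COUPLED_ROI = "FuG_L_3_3"

EIG_FLOOR = 1e-6
CLIP_R = 0.95


@dataclass
class BehaviorTargets:
    """Per-group behavioral generative targets (mean, SD) and the
    brain-behavior coupling.

    Defaults: expertise-task score (RET) 0.80 +/- 0.04 vs 0.53 +/- 0.04,
    its response time 2.6 +/- 0.4 s vs 3.7 +/- 0.7 s, face-memory control
    score (CFMT) 56.95 +/- 5.23 vs 58.68 +/- 5.31, and a within-expertise
    correlation of 0.5 between RET and the coupled ROI's DC. RT and CFMT
    are generated group-wise without brain coupling.
    """

    ret_mean: tuple[float, float] = (0.80, 0.53)  # (expertise, control)
    ret_sd: tuple[float, float] = (0.04, 0.04)
    rt_mean: tuple[float, float] = (2.6, 3.7)
    rt_sd: tuple[float, float] = (0.4, 0.7)
    cfmt_mean: tuple[float, float] = (56.95, 58.68)
    cfmt_sd: tuple[float, float] = (5.23, 5.31)
    brain_behavior_r: float = 0.5
    coupled_roi: str = BEHAVIOR_COUPLED_ROI


def default_planted_effects(n_rois: int, magnitude: float = 0.3) -> dict[int, tuple[str, float]]:
    """Seven signed planted deltas at deterministic, spread-out ROI indices.

    Returns a mapping ROI index -> (analog name, signed delta). Only the
    signs are anchored to the reported discriminative regions; the
    magnitude is a free simulation parameter.
    """
    names = list(PLANTED_ROI_SIGNS)
    k = len(names)
    if n_rois < k:
        raise ValueError(f"need at least {k} ROIs for the default planted set")
    idx = [int(round(n_rois * (j + 0.5) / k)) for j in range(k)]
    idx = sorted(set(min(i, n_rois - 1) for i in idx))
    while len(idx) < k:  # tiny atlases: fill gaps deterministically
        for cand in range(n_rois):
            if cand not in idx:
                idx.append(cand)
                break
        idx = sorted(idx)
    return {
        i: (name, PLANTED_ROI_SIGNS[name] * magnitude)
        for i, name in zip(idx, names)
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the emulated study design: 22 subjects per group,
    190 volumes at TR = 2 s, 246 ROIs, seven planted signed degree
    effects of magnitude 0.3, AR(1) coefficient 0.4.
    """

    n_per_group: int = 22
    n_rois: int = 246
    n_modules: int = 6
    rho_within: float = 0.3
    rho_between: float = 0.1
    planted_effects: dict = None  # ROI index -> signed delta (or (name, delta))
    ar_phi: float = 0.4
    n_volumes: int = 190
    tr_seconds: float = 2.0
    n_drop: int = 10
    voxel_grid: tuple[int, int, int] = (12, 12, 12)
    voxels_per_roi: int = 7
    voxel_noise_sd: float = 0.5
    behavior_targets: BehaviorTargets = field(default_factory=BehaviorTargets)
    seed: int = 0

    def __post_init__(self):
        if self.planted_effects is None:
            self.planted_effects = default_planted_effects(self.n_rois)
        # normalize to index -> (name, delta)
        norm = {}
        for k, v in self.planted_effects.items():
            if isinstance(v, (tuple, list)):
                norm[int(k)] = (str(v[0]), float(v[1]))
            else:
                norm[int(k)] = (f"ROI_{int(k)+1:03d}", float(v))
        self.planted_effects = norm
        self.validate()

    def validate(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0 <= self.rho_between <= self.rho_within < 1):
            raise ValueError("need 0 <= rho_between <= rho_within < 1")
        if not -1 < self.ar_phi < 1:
            raise ValueError("ar_phi must lie in (-1, 1)")
        if self.n_volumes <= self.n_drop + 2:
            raise ValueError("n_volumes must exceed n_drop + 2")
        if self.n_modules < 1 or self.n_modules > self.n_rois:
            raise ValueError("n_modules must lie in [1, n_rois]")
        for k, (_, d) in self.planted_effects.items():
            if not 0 <= k < self.n_rois:
                raise ValueError(f"planted ROI index {k} outside [0, {self.n_rois})")
            if abs(d) >= 1:
                raise ValueError(f"planted delta {d} must have |delta| < 1")

    def roi_names(self) -> list[str]:
        names = [f"ROI_{i+1:03d}" for i in range(self.n_rois)]
        for k, (name, _) in self.planted_effects.items():
            names[k] = name
        return names

    def module_of(self) -> np.ndarray:
        """Module assignment per ROI (contiguous, near-equal blocks)."""
        return (np.arange(self.n_rois) * self.n_modules // self.n_rois).astype(int)


@dataclass
class CorrelationStructure:
    """Target per-group innovation correlation matrices."""

    expertise: np.ndarray
    control: np.ndarray
    modules: np.ndarray
    applied_deltas: dict[int, float]
    min_eigenvalue: float


@dataclass
class GroundTruth:
    """What was planted: effect indices/deltas, group labels, behavior
    generative parameters. Stored alongside every simulated cohort."""

    planted: dict[int, tuple[str, float]]
    groups: list[str]
    behavior: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": {str(k): {"name": n, "delta": d} for k, (n, d) in self.planted.items()},
                "groups": self.groups,
                "behavior": self.behavior,
            },
            indent=2,
        )


@dataclass
class Cohort:
    """A simulated two-group cohort.

    `series` holds one ``(n_rois, T)`` array per subject; in voxel mode
    `images` additionally holds one 4D :class:`BoldImage` per subject.
    """

    config: SimConfig
    series: list[np.ndarray]
    subject_ids: list[str]
    groups: pd.Series
    parcellation: Parcellation
    behavior: pd.DataFrame
    ground_truth: GroundTruth
    images: list[BoldImage] = None

    def roi_series_frames(self) -> dict[str, pd.DataFrame]:
        names = self.config.roi_names()
        return {
            sid: pd.DataFrame(s.T, columns=names) for sid, s in zip(self.subject_ids, self.series)
        }


def _floor_to_pd(mat: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalue flooring at EIG_FLOOR with unit-diagonal restoration,
    iterated until the floor holds after renormalization."""
    a = (mat + mat.T) / 2.0
    for _ in range(50):
        vals, vecs = np.linalg.eigh(a)
        if vals.min() >= EIG_FLOOR:
            return a, float(vals.min())
        vals = np.maximum(vals, EIG_FLOOR)
        a = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        np.fill_diagonal(a, 1.0)
    vals = np.linalg.eigvalsh(a)
    if vals.min() < EIG_FLOOR / 10:
        raise np.linalg.LinAlgError(
            f"correlation matrix not positive definite after projection (min eig {vals.min():.2e})"
        )
    return a, float(vals.min())


def build_group_covariance(config: SimConfig) -> CorrelationStructure:
    """Target innovation correlation matrices for both groups.

    The base matrix is modular (``rho_within`` inside modules,
    ``rho_between`` across, unit diagonal). For the expertise group, each
    planted ROI's off-diagonal row and column are shifted by its signed
    delta and clipped to [-0.95, 0.95] (a warning is raised if any entry
    would leave (-1, 1) before clipping); both matrices are then projected
    to the nearest positive-definite matrix by eigenvalue flooring with
    diagonal renormalization.
    """
    config.validate()
    mods = config.module_of()
    same = mods[:, None] == mods[None, :]
    base = np.where(same, config.rho_within, config.rho_between).astype(float)
    np.fill_diagonal(base, 1.0)

    expert = base.copy()
    for k, (_, delta) in config.planted_effects.items():
        row = expert[k].copy()
        row[np.arange(config.n_rois) != k] += delta
        if np.any(np.abs(row[np.arange(config.n_rois) != k]) >= 1.0):
            warnings.warn(
                f"planted delta at ROI {k} pushes |r| >= 1 before clipping", stacklevel=2
            )
        row = np.clip(row, -CLIP_R, CLIP_R)
        row[k] = 1.0
        expert[k] = row
        expert[:, k] = row

    control_pd, min_c = _floor_to_pd(base)
    expert_pd, min_e = _floor_to_pd(expert)
    return CorrelationStructure(
        expertise=expert_pd,
        control=control_pd,
        modules=mods,
        applied_deltas={k: d for k, (_, d) in config.planted_effects.items()},
        min_eigenvalue=min(min_c, min_e),
    )


def _simulate_var1(corr: np.ndarray, phi: float, T: int, rng: np.random.Generator) -> np.ndarray:
    """One ``(n_rois, T)`` draw of x_t = phi x_{t-1} + eps_t, eps ~ N(0, corr),
    initialized from the stationary distribution."""
    n = corr.shape[0]
    chol = np.linalg.cholesky(corr)
    eps = rng.standard_normal((T, n)) @ chol.T
    x = np.empty((T, n))
    x[0] = eps[0] / np.sqrt(1.0 - phi**2)
    for t in range(1, T):
        x[t] = phi * x[t - 1] + eps[t]
    return x.T


def _block_parcellation(config: SimConfig) -> Parcellation:
    """Contiguous equal blocks of `voxels_per_roi` voxels in flat order on
    `voxel_grid`; remaining voxels are background."""
    grid = tuple(config.voxel_grid)
    n_vox = int(np.prod(grid))
    need = config.n_rois * config.voxels_per_roi
    if need > n_vox:
        raise ValueError(
            f"voxel grid {grid} ({n_vox} voxels) too small for "
            f"{config.n_rois} x {config.voxels_per_roi} voxels"
        )
    flat = np.zeros(n_vox, dtype=np.int32)
    for r in range(config.n_rois):
        flat[r * config.voxels_per_roi : (r + 1) * config.voxels_per_roi] = r + 1
    names = {i + 1: n for i, n in enumerate(config.roi_names())}
    return Parcellation(labels=flat.reshape(grid), names=names)


def simulate_cohort(config: SimConfig, mode: str = "roi") -> Cohort:
    """Simulate a two-group cohort. Deterministic given ``config.seed``.

    Subjects ``sub-001 .. sub-0NN`` — the first half expertise, the second
    half control. In ``voxel`` mode each ROI series is copied to its
    parcel's voxels with independent Gaussian noise of SD
    ``voxel_noise_sd``, inside a contiguous-block parcellation with an
    identity affine.
    """
    if mode not in ("roi", "voxel"):
        raise ValueError("mode must be 'roi' or 'voxel'")
    config.validate()
    structure = build_group_covariance(config)
    parcellation = _block_parcellation(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    n = config.n_per_group
    groups = ["expertise"] * n + ["control"] * n
    ids = [f"sub-{i+1:03d}" for i in range(2 * n)]
    series = []
    images = [] if mode == "voxel" else None
    for g in groups:
        corr = structure.expertise if g == "expertise" else structure.control
        s = _simulate_var1(corr, config.ar_phi, config.n_volumes, rng)
        series.append(s)
    if mode == "voxel":
        grid = tuple(config.voxel_grid)
        labels = parcellation.labels
        mask = labels > 0
        for s in series:
            data = np.zeros(grid + (config.n_volumes,))
            for r in range(config.n_rois):
                vox = labels == (r + 1)
                nv = int(vox.sum())
                noise = rng.standard_normal((nv, config.n_volumes)) * config.voxel_noise_sd
                data[vox] = s[r][None, :] + noise
            images.append(
                BoldImage(data=data, tr_seconds=config.tr_seconds, affine=np.eye(4), mask=mask.copy())
            )

    groups_s = pd.Series(groups, index=ids, name="group")
    # region-level DC features of the raw series drive the behavioral coupling
    feats = pd.DataFrame(
        np.vstack([roi_dc(s.T) for s in series]), index=ids, columns=config.roi_names()
    )
    behavior = generate_behavior(feats, groups_s, config, rng=rng)
    gt = GroundTruth(
        planted=dict(config.planted_effects),
        groups=groups,
        behavior={
            "targets": asdict(config.behavior_targets),
            "coupled_roi": config.behavior_targets.coupled_roi,
        },
    )
    return Cohort(
        config=config,
        series=series,
        subject_ids=ids,
        groups=groups_s,
        parcellation=parcellation,
        behavior=behavior,
        ground_truth=gt,
        images=images,
    )


def generate_behavior(
    dc_features: pd.DataFrame,
    groups: pd.Series,
    config: SimConfig,
    rng: np.random.Generator = None,
) -> pd.DataFrame:
    """Behavioral table with group-wise targets and brain-behavior coupling.

    Expertise-group RET scores are a linear function of the coupled ROI's
    DC plus Gaussian noise, calibrated so the population correlation
    equals ``behavior_targets.brain_behavior_r``; response time and the
    face-memory score are drawn group-wise without brain coupling. When
    the coupled ROI is absent from the features (e.g. a null cohort with
    no planted effects), RET is generated group-wise without coupling.
    """
    t = config.behavior_targets
    if not -1 < t.brain_behavior_r < 1:
        raise ValueError("target brain-behavior correlation must lie in (-1, 1)")
    coupled = t.coupled_roi if t.coupled_roi in dc_features.columns else None
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    rows = {}
    for gi, gname in enumerate(("expertise", "control")):
        idx = groups.index[groups == gname]
        m = len(idx)
        if gname == "expertise" and coupled is not None:
            dc = dc_features.loc[idx, coupled].to_numpy(dtype=float)
            zd = dc - dc.mean()
            sd = zd.std()
            zd = zd / sd if sd > 0 else np.zeros_like(zd)
            rho = t.brain_behavior_r
            noise = rng.standard_normal(m)
            ret = t.ret_mean[gi] + t.ret_sd[gi] * (rho * zd + np.sqrt(1 - rho**2) * noise)
        else:
            ret = t.ret_mean[gi] + t.ret_sd[gi] * rng.standard_normal(m)
        rt = t.rt_mean[gi] + t.rt_sd[gi] * rng.standard_normal(m)
        cfmt = t.cfmt_mean[gi] + t.cfmt_sd[gi] * rng.standard_normal(m)
        for j, sid in enumerate(idx):
            rows[sid] = {
                "group": gname,
                "ret": float(np.clip(ret[j], 0.0, 1.0)),
                "ret_rt": float(np.maximum(rt[j], 1e-3)),
                "cfmt": float(cfmt[j]),
            }
    out = pd.DataFrame.from_dict(rows, orient="index").loc[groups.index]
    out.index.name = "subject_id"
    return out
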