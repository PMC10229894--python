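"""Group-level statistics: rank tests, t-tests, correlations, and FDR.

These are the behavioral-comparison and brain-behavior routines used after
classification: Mann-Whitney U for non-normal behavioral scores, Student's
two-sample t, Pearson correlation of per-ROI degree centrality against
behavioral measures, and Benjamini-Hochberg false-discovery-rate control
across ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "mann_whitney_u",
    "students_t_two_sample",
    "pearson_corr",
    "bh_fdr",
    "dc_behavior_correlation",
    "CorrelationResult",
    "EXACT_MW_MAX_N",
]

#: combined-sample-size cutoff below which the Mann-Whitney p-value is
#: computed by exhaustive enumeration rather than normal approximation
EXACT_MW_MAX_N = 12


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: number of (x_i, y_j) pairs with x_i > y_j, ties 0.5."""
    diff = x[:, None] - y[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The p-value is exact (enumeration over all ``C(n_x+n_y, n_x)`` group
    assignments of the pooled values, valid under ties) when the combined
    sample size is at most ``EXACT_MW_MAX_N``; otherwise a tie-corrected
    normal approximation with continuity correction is used.

    Parameters
    ----------
    x, y : array-like
        The two samples.

    Returns
    -------
    U : float
        The U statistic for `x` (ties counted 0.5).
    p : float
        Two-sided p-value. If every value in both samples is identical,
        ``p = 1.0``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    u = _u_statistic(x, y)

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u, 1.0

    if nx + ny <= EXACT_MW_MAX_N:
        # enumerate every way of assigning nx of the pooled values to "x";
        # two-sided p = P(|U - mu| >= |u - mu|) under the permutation null
        mu = nx * ny / 2.0
        obs = abs(u - mu)
        total = comb(nx + ny, nx)
        extreme = 0
        idx = np.arange(nx + ny)
        for subset in combinations(idx, nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(subset)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mu) >= obs - 1e-12:
                extreme += 1
        return u, extreme / total

    # normal approximation with tie correction and continuity correction
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    mu = nx * ny / 2.0
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(max(z, 0.0))
    return u, float(min(p, 1.0))


def students_t_two_sample(x, y, *, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test (pooled-variance Student's t by default).

    Set ``equal_var=False`` for the Welch variant. With zero pooled
    variance: equal means give ``(0.0, 1.0)``; unequal means give a
    infinite-magnitude t with ``p = 0.0``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-based p-value.

    Raises
    ------
    ValueError
        If ``n < 3`` or either input has zero variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotonicity is enforced and the adjusted values are returned in the
    input order. Values never exceed 1 and never fall below the raw p.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationResult:
    """Per-ROI brain-behavior correlation table for one behavioral measure."""

    measure: str
    group: str
    table: pd.DataFrame  # index=ROI, columns r, p, p_fdr, significant
    alpha: float = 0.05

    @property
    def significant_rois(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def dc_behavior_correlation(
    features,
    groups,
    behavior: pd.DataFrame,
    group: str,
    measures=None,
    alpha: float = 0.05,
) -> dict[str, CorrelationResult]:
    """Correlate each ROI's degree centrality with behavioral scores.

    Within the named group, computes a Pearson correlation of every ROI's
    DC against every behavioral measure, then applies Benjamini-Hochberg
    FDR across ROIs separately for each measure.

    Parameters
    ----------
    features : DataFrame
        subjects x ROIs DC table, indexed by subject id.
    groups : Series
        group label per subject (same index as `features`).
    behavior : DataFrame
        behavioral measures per subject (same index).
    group : str
        which group to analyse (e.g. ``"expertise"``).
    measures : sequence of str, optional
        behavioral columns to use; default all numeric columns.
    alpha : float
        FDR significance level.

    Returns
    -------
    dict mapping measure name to :class:`CorrelationResult`.
    """
    groups = pd.Series(groups, index=features.index) if not isinstance(groups, pd.Series) else groups
    in_group = groups == group
    if int(in_group.sum()) < 3:
        raise ValueError(f"need at least 3 subjects in group {group!r}")
    feats = features.loc[in_group]
    beh = behavior.loc[feats.index]
    if measures is None:
        measures = [c for c in beh.columns if pd.api.types.is_numeric_dtype(beh[c])]

    out: dict[str, CorrelationResult] = {}
    for m in measures:
        col = beh[m].to_numpy(dtype=float)
        if np.std(col) == 0:
            raise ValueError(f"behavioral column {m!r} has zero variance")
        rows = []
        for roi in feats.columns:
            r, p = pearson_corr(feats[roi].to_numpy(), col)
            rows.append((roi, r, p))
        tab = pd.DataFrame(rows, columns=["roi", "r", "p"]).set_index("roi")
        tab["p_fdr"] = bh_fdr(tab["p"].to_numpy())
        tab["significant"] = tab["p_fdr"] < alpha
        out[m] = CorrelationResult(measure=m, group=group, table=tab, alpha=alpha)
    return out
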