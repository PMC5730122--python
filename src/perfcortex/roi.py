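"""ROI-level GM CBF extraction and paired hemispheric comparisons.

GM CBF is averaged, unweighted, over the ROI voxels that survived
partial-volume correction (``valid = 1``) and have GM probability at or
above a floor (default 0.30, mirroring the brain-mask threshold).  Paired
t-tests compare occluded vs unoccluded sides with Bonferroni control over
the two regions (two-sided significance threshold 0.05 / 2 = 0.025).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateInputError, DomainError
from .grids import TissueProbMaps, VolumeGrid, check_same_grid
from .quantify import CBFMap

__all__ = ["RoiSummary", "PairedTestResult", "roi_mean_cbf", "paired_t", "asymmetry_count"]

DEFAULT_GM_FLOOR = 0.30


@dataclass
class RoiSummary:
    """Mean GM CBF of one region on one side."""

    region: str
    side: str
    mean_cbf: float
    n_voxels_used: int
    defined: bool
    thickness: float | None = None  # mm, carried through from tabular input


@dataclass
class PairedTestResult:
    """Classical paired t-test with a Bonferroni significance flag."""

    mean_a: float
    mean_b: float
    t_statistic: float
    df: int
    p_two_sided: float
    significant_after_bonferroni: bool
    alpha_adjusted: float


def roi_mean_cbf(
    cbf_map: CBFMap,
    roi: VolumeGrid,
    probmaps: TissueProbMaps,
    gm_floor: float = DEFAULT_GM_FLOOR,
    region: str = "",
    side: str = "",
) -> RoiSummary:
    """Unweighted mean GM CBF over usable ROI voxels.

    Usable voxels have ``roi = 1``, a defined CBF value, and GM probability
    >= ``gm_floor``.  With zero usable voxels the summary is returned
    undefined (NaN mean, ``defined=False``) rather than raising.
    """
    check_same_grid(cbf_map.cbf_gm, roi, probmaps.grid)
    if roi.data.sum() == 0:
        raise DomainError("ROI mask is empty")
    sel = (
        roi.data.astype(bool)
        & cbf_map.defined.data.astype(bool)
        & (probmaps.p_gm.data >= gm_floor)
    )
    n = int(sel.sum())
    if n == 0:
        return RoiSummary(region, side, float("nan"), 0, False)
    return RoiSummary(region, side, float(cbf_map.cbf_gm.data[sel].mean()), n, True)


def paired_t(occluded, unoccluded, bonferroni_m: int = 2) -> PairedTestResult:
    """Paired t-test on per-subject (occluded, unoccluded) values.

    Two-sided p from Student t with n-1 degrees of freedom on the
    differences; the Bonferroni flag requires p < 0.05 / ``bonferroni_m``
    (0.025 for the two-region family).  Identical inputs give t = 0, p = 1.
    """
    x = np.asarray(occluded, dtype=np.float64)
    y = np.asarray(unoccluded, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("paired_t requires two equal-length 1-D arrays")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise DegenerateInputError(f"paired_t requires >= 2 complete pairs, got {n}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else float(np.sign(d.mean()) * np.inf)
        p = 1.0 if d.mean() == 0 else 0.0
    else:
        t = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2 * sps.t.sf(abs(t), n - 1))
    alpha = 0.05 / bonferroni_m
    return PairedTestResult(
        mean_a=float(x.mean()),
        mean_b=float(y.mean()),
        t_statistic=t,
        df=n - 1,
        p_two_sided=p,
        significant_after_bonferroni=bool(p < alpha),
        alpha_adjusted=alpha,
    )


def asymmetry_count(table: pd.DataFrame, region: str = "M1") -> tuple[int, int]:
    """Count subjects whose CBF is lower on the occluded side.

    Uses complete cases of the region's two CBF columns; ties (equal
    values) count against the expected direction.  Returns
    ``(n_expected_direction, percent)`` with percent rounded to an int.
    """
    occ_col = f"{region.lower()}_cbf_occ"
    unocc_col = f"{region.lower()}_cbf_unocc"
    sub = table[[occ_col, unocc_col]].dropna()
    n = len(sub)
    if n == 0:
        raise DegenerateInputError("no complete cases for asymmetry count")
    count = int((sub[occ_col] < sub[unocc_col]).sum())
    return count, int(round(100.0 * count / n))
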