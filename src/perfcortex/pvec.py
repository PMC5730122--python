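"""Partial-volume-effect correction by local linear regression.

Each brain voxel's signal is modeled as a mixture of tissue-specific
components weighted by the tissue posterior probabilities,
``y(v) = sum_t p_t(v) * m_t``.  Within a small in-plane window centered on
the voxel (default 7x7x1), the tissue components are estimated by ordinary
least squares of the image values on the probability columns, with no
intercept (an intercept would absorb tissue signal).  The mean control
image is regressed on GM/WM/CSF; the mean control-label difference image is
regressed on GM/WM only, since CSF carries no perfusion signal.

Windows are truncated at the volume boundary and restricted to voxels
inside the brain mask (total tissue probability >= 30% by default).  Where
the local design matrix is rank deficient — e.g. a window of pure tissue —
the minimum-norm least-squares solution is returned and the voxel is
flagged invalid so downstream ROI averaging can exclude it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, DomainError, ShapeError
from .grids import TissueProbMaps, VolumeGrid, check_same_grid

__all__ = ["PVEcResult", "brain_mask", "local_regression", "pvec_correct"]

#: Condition-number limit above which a local Gram matrix is treated as
#: rank deficient.
COND_LIMIT = 1e6

DEFAULT_KERNEL = (7, 7, 1)
DEFAULT_MASK_THRESHOLD = 0.30


@dataclass
class PVEcResult:
    """Tissue-specific magnetization and difference maps.

    ``valid`` is 1 where both local regressions (control: GM/WM/CSF;
    difference: GM/WM) are well posed; ``n_neighbors`` counts the masked
    voxels in each regression window.
    """

    m_gm: VolumeGrid
    m_wm: VolumeGrid
    m_csf: VolumeGrid
    dm_gm: VolumeGrid
    dm_wm: VolumeGrid
    valid: VolumeGrid
    n_neighbors: VolumeGrid
    mask: VolumeGrid
    kernel: tuple[int, int, int] = DEFAULT_KERNEL


def brain_mask(probmaps: TissueProbMaps, threshold: float = DEFAULT_MASK_THRESHOLD) -> VolumeGrid:
    """Binary brain-tissue mask: total tissue probability >= threshold.

    The default 30% total-tissue threshold excludes non-brain voxels while
    keeping partial-volume boundary voxels in the regression.
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError(f"mask threshold must be in (0, 1], got {threshold}")
    total = probmaps.total()
    return total.like((total.data >= threshold).astype(np.uint8))


def _check_kernel(kernel) -> tuple[int, int, int]:
    kernel = tuple(int(k) for k in kernel)
    if len(kernel) != 3:
        raise ConfigurationError(f"kernel must have 3 dimensions, got {kernel}")
    if any(k < 1 or k % 2 == 0 for k in kernel):
        raise ConfigurationError(f"kernel dimensions must be odd and >= 1, got {kernel}")
    return kernel


def _boxsum(arr: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    """Sum of `arr` over the kernel window centered at each voxel (edges truncated)."""
    out = arr
    for axis, k in enumerate(kernel):
        if k > 1:
            out = ndimage.correlate1d(out, np.ones(k), axis=axis, mode="constant", cval=0.0)
    return out


def local_regression(
    image: VolumeGrid,
    regressors: list[VolumeGrid],
    mask: VolumeGrid,
    kernel: tuple[int, int, int] = DEFAULT_KERNEL,
) -> tuple[list[VolumeGrid], VolumeGrid, VolumeGrid]:
    """Voxelwise windowed OLS of `image` on probability `regressors`.

    At each masked voxel, the masked voxels of the kernel window centered
    there form the regression sample; coefficients solve the no-intercept
    normal equations.  Returns ``(coefficient maps, valid, n_neighbors)``.
    A voxel is invalid when its window holds fewer than ``p + 1`` masked
    voxels or the Gram matrix condition number exceeds ``COND_LIMIT``; its
    coefficients are then the minimum-norm least-squares solution.
    """
    kernel = _check_kernel(kernel)
    check_same_grid(image, mask, *regressors)
    m = mask.data.astype(bool)
    if not m.any():
        raise DomainError("empty brain mask: no voxels to regress")
    p = len(regressors)
    X = [r.data.astype(np.float64) * m for r in regressors]
    y = image.data.astype(np.float64) * m

    nvox = int(np.prod(image.shape))
    gram = np.empty((nvox, p, p))
    rhs = np.empty((nvox, p))
    for i in range(p):
        rhs[:, i] = _boxsum(X[i] * y, kernel).ravel()
        for j in range(i, p):
            s = _boxsum(X[i] * X[j], kernel).ravel()
            gram[:, i, j] = s
            gram[:, j, i] = s
    n_neighbors = np.rint(_boxsum(m.astype(np.float64), kernel)).astype(np.int32)

    # minimum-norm LS solution via pseudo-inverse of the Gram matrix
    coef = np.einsum("vij,vj->vi", np.linalg.pinv(gram, rcond=1e-12, hermitian=True), rhs)

    eig = np.linalg.eigvalsh(gram)
    lam_min, lam_max = eig[:, 0], eig[:, -1]
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(lam_min > 0, lam_max / np.where(lam_min > 0, lam_min, 1.0), np.inf)
    valid = (cond <= COND_LIMIT) & (n_neighbors.ravel() >= p + 1) & m.ravel()

    shape = image.shape
    coef_maps = [image.like((coef[:, i].reshape(shape)) * m) for i in range(p)]
    valid_map = image.like(valid.reshape(shape).astype(np.uint8))
    nn_map = image.like(n_neighbors.reshape(shape) * m)
    return coef_maps, valid_map, nn_map


def pvec_correct(
    control4d: np.ndarray,
    label4d: np.ndarray,
    probmaps: TissueProbMaps,
    kernel: tuple[int, int, int] = DEFAULT_KERNEL,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    clip_negative: bool = False,
) -> PVEcResult:
    """Full partial-volume correction of a control/label series.

    Averages the control frames and the control-label differences over
    pairs, then runs the local regression of the mean control image on
    GM/WM/CSF probabilities and of the mean difference image on GM/WM.

    Negative coefficients are retained by default (preserving unbiasedness
    of downstream ROI means); ``clip_negative=True`` clips them to zero.
    """
    control4d = np.asarray(control4d, dtype=np.float64)
    label4d = np.asarray(label4d, dtype=np.float64)
    if control4d.ndim != 4 or label4d.ndim != 4:
        raise ShapeError("control and label series must be 4-D")
    if control4d.shape != label4d.shape:
        raise ShapeError(
            f"control/label frame mismatch: {control4d.shape} vs {label4d.shape}"
        )
    if control4d.shape[:3] != probmaps.grid.shape:
        raise ShapeError(
            f"series grid {control4d.shape[:3]} does not match probability maps "
            f"{probmaps.grid.shape}"
        )
    mean_control = probmaps.grid.like(control4d.mean(axis=3))
    mean_diff = probmaps.grid.like((control4d - label4d).mean(axis=3))
    mask = brain_mask(probmaps, mask_threshold)

    m_maps, valid_m, nn = local_regression(
        mean_control, [probmaps.p_gm, probmaps.p_wm, probmaps.p_csf], mask, kernel
    )
    dm_maps, valid_dm, _ = local_regression(
        mean_diff, [probmaps.p_gm, probmaps.p_wm], mask, kernel
    )
    valid = mask.like((valid_m.data.astype(bool) & valid_dm.data.astype(bool)).astype(np.uint8))
    maps = list(m_maps) + list(dm_maps)
    if clip_negative:
        maps = [g.like(np.maximum(g.data, 0.0)) for g in maps]
    return PVEcResult(
        m_gm=maps[0], m_wm=maps[1], m_csf=maps[2],
        dm_gm=maps[3], dm_wm=maps[4],
        valid=valid, n_neighbors=nn, mask=mask, kernel=tuple(kernel),
    )
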