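"""Single-compartment CBF quantification with per-slice PLD adjustment.

The tissue-specific ratios ``dm_t / m_t`` from partial-volume correction
are converted to cerebral blood flow with the standard single-compartment
pCASL model,

    CBF = 6000 * lambda * (dM/M0) * exp(PLD/T1b)
          / (2 * alpha * T1b * (1 - exp(-LD/T1b)))    [ml*100g^-1*min^-1],

all times in seconds.  For the 2-D readout the post-labeling delay grows
with slice position: PLD(slice) = (slice - 1) * slice_dt + PLD0 with
1-based slice numbering along the third axis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .grids import VolumeGrid
from .params import AcqParams, delta_m_scale

__all__ = ["CBFMap", "adjusted_pld", "cbf_from_ratio", "quantify_volume"]

#: Default |m_t| floor, as a fraction of the median |m_t| inside the mask.
DEFAULT_M_FLOOR_FRAC = 1e-6


@dataclass
class CBFMap:
    """Tissue-specific CBF maps in ml*100g^-1*min^-1.

    ``defined`` marks voxels where both tissue ratios are quantifiable
    (valid partial-volume regression and magnetization above the floor);
    elsewhere the maps hold NaN.
    """

    cbf_gm: VolumeGrid
    cbf_wm: VolumeGrid
    defined: VolumeGrid
    params_used: AcqParams


def adjusted_pld(slice_number: int, acq: AcqParams = AcqParams()) -> float:
    """Slice-adjusted post-labeling delay in ms, 1-based slice numbering.

    PLD(slice) = (slice_number - 1) * slice_dt + pld0; with the default
    70 ms increment and 1200 ms initial delay, slice 10 has PLD 1830 ms.
    """
    if slice_number < 1:
        raise DomainError(f"slice_number is 1-based, got {slice_number}")
    return (slice_number - 1) * acq.slice_dt + acq.pld0


def cbf_from_ratio(ratio, pld: float, acq: AcqParams = AcqParams()):
    """CBF (ml*100g^-1*min^-1) from a dM/M0 ratio at the given PLD (ms).

    Exact inverse of the phantom's forward difference-signal model;
    strictly increasing in both ``ratio`` and ``pld``.
    """
    scale = delta_m_scale(pld, acq)  # validates pld >= 0; acq validates itself
    return np.asarray(ratio, dtype=np.float64) / scale if np.ndim(ratio) else float(ratio) / scale


def quantify_volume(pvec, acq: AcqParams = AcqParams(),
                    m_floor_frac: float = DEFAULT_M_FLOOR_FRAC) -> CBFMap:
    """Convert a PVEc result into GM and WM CBF maps.

    Per voxel, ``ratio_t = dm_t / m_t`` is quantified at the voxel's
    slice-adjusted PLD.  Voxels with invalid regression or with ``|m_t|``
    below ``m_floor_frac`` times the masked median ``|m_t|`` are undefined
    (NaN), never infinite.  An all-undefined output triggers a warning,
    not an error.
    """
    shape = pvec.m_gm.shape
    valid = pvec.valid.data.astype(bool)
    out = {}
    defined = valid.copy()
    for tissue, m_map, dm_map in (("gm", pvec.m_gm, pvec.dm_gm), ("wm", pvec.m_wm, pvec.dm_wm)):
        m = m_map.data
        dm = dm_map.data
        inside = pvec.mask.data.astype(bool)
        med = np.median(np.abs(m[inside])) if inside.any() else 0.0
        floor = m_floor_frac * med
        ok = valid & (np.abs(m) > floor) & (floor > 0)
        cbf = np.full(shape, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ok, dm / np.where(ok, m, 1.0), np.nan)
        for z in range(shape[2]):
            scale = delta_m_scale(adjusted_pld(z + 1, acq), acq)
            cbf[:, :, z] = ratio[:, :, z] / scale
        out[tissue] = pvec.m_gm.like(cbf)
        defined &= ok
    if not defined.any():
        import warnings

        warnings.warn("CBF map is undefined at every voxel", RuntimeWarning, stacklevel=2)
    return CBFMap(
        cbf_gm=out["gm"],
        cbf_wm=out["wm"],
        defined=pvec.m_gm.like(defined.astype(np.uint8)),
        params_used=acq,
    )
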