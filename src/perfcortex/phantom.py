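"""Digital ASL phantom and synthetic cohort generator.

The phantom emulates the inputs of the perfusion pipeline on a small voxel
grid: spatially smooth GM/WM/CSF posterior-probability maps for two
hemispheres separated by an interhemispheric fissure, tissue-specific
ground-truth perfusion with a multiplicative GM-flow deficit on the
"occluded" side, mirrored M1/V1 region masks, and noisy control/label EPI
pairs generated under the single-compartment kinetic model with per-slice
post-labeling delays.

The cohort generator emulates the tabular study data: n subjects whose M1
cortical thickness depends linearly on M1 gray-matter CBF and age while V1
thickness depends on neither, with an occluded-side CBF deficit and
covariate prevalences matching the study cohort.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, DomainError, ShapeError
from .grids import TissueProbMaps, VolumeGrid, check_same_grid
from .params import AcqParams, delta_m_scale
from .quantify import adjusted_pld

__all__ = [
    "PerfusionTruth",
    "RoiAtlas",
    "CohortSimConfig",
    "build_probmaps",
    "build_roi_atlas",
    "build_truth",
    "forward_delta_m",
    "simulate_series",
    "simulate_cohort",
    "PhantomData",
    "simulate_phantom",
]

# Tissue labels of the deterministic geometry
_BG, _GM, _WM, _CSF = 0, 1, 2, 3

#: Default magnetization of GM : WM : CSF in arbitrary control-image units
#: (plausible proton-density ordering; configurable everywhere it is used).
DEFAULT_MAGNETIZATIONS = {"m_gm": 100.0, "m_wm": 70.0, "m_csf": 120.0}

#: Default ground-truth perfusion, ml*100g^-1*min^-1 (textbook GM/WM values).
DEFAULT_FLOWS = {"f_gm": 60.0, "f_wm": 20.0}

#: Default multiplicative GM-flow deficit on the occluded side.
DEFAULT_ASYMMETRY = 0.9


@dataclass
class PerfusionTruth:
    """Ground-truth perfusion maps (CSF is not perfused: f_csf == 0)."""

    f_gm: VolumeGrid
    f_wm: VolumeGrid
    asymmetry_factor: float = DEFAULT_ASYMMETRY

    def __post_init__(self) -> None:
        check_same_grid(self.f_gm, self.f_wm)
        if np.nanmin(self.f_gm.data) < 0 or np.nanmin(self.f_wm.data) < 0:
            raise DomainError("perfusion values must be non-negative")


@dataclass
class RoiAtlas:
    """Mirrored binary region masks for primary motor and visual cortex."""

    m1_left: VolumeGrid
    m1_right: VolumeGrid
    v1_left: VolumeGrid
    v1_right: VolumeGrid

    def __post_init__(self) -> None:
        masks = [self.m1_left, self.m1_right, self.v1_left, self.v1_right]
        check_same_grid(*masks)
        total = np.zeros(masks[0].shape, dtype=int)
        for m in masks:
            if m.data.sum() == 0:
                raise ConfigurationError("ROI masks must be non-empty")
            total += m.data.astype(bool).astype(int)
        if total.max() > 1:
            raise ConfigurationError("ROI masks must be disjoint")

    def by_side(self, region: str, side_occluded: str) -> tuple[VolumeGrid, VolumeGrid]:
        """(occluded, unoccluded) masks for region 'M1' or 'V1'."""
        left = getattr(self, f"{region.lower()}_left")
        right = getattr(self, f"{region.lower()}_right")
        if side_occluded.upper() == "L":
            return left, right
        return right, left


def _geometry(shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic tissue-label volume: two mirrored hemisphere blocks.

    Each hemisphere block has a one-voxel CSF rim (sulcal CSF), a
    two-voxel GM ribbon, a WM core and a small central CSF ventricle; the
    blocks are separated by a background interhemispheric fissure wide
    enough that, after the 30% total-tissue brain mask, no in-plane 7x7
    regression window bridges the hemispheres.
    """
    nx, ny, nz = shape
    labels = np.full(shape, _BG, dtype=np.int8)
    gap = 6                       # fissure width, voxels
    margin = 3                    # background shell
    x0l, x1l = margin, nx // 2 - gap // 2 - 1          # left block, inclusive
    x0r, x1r = nx - 1 - x1l, nx - 1 - x0l              # mirrored right block
    y0, y1 = margin, ny - 1 - margin
    if x1l - x0l < 6 or y1 - y0 < 6:
        raise ConfigurationError(
            f"shape {shape} too small: each hemisphere must cover at least the "
            "7x7 in-plane regression kernel"
        )
    xs = np.arange(nx)[:, None]
    ys = np.arange(ny)[None, :]
    for (x0, x1) in ((x0l, x1l), (x0r, x1r)):
        inside = (xs >= x0) & (xs <= x1) & (ys >= y0) & (ys <= y1)
        # ring distance from the block boundary
        d = np.minimum(np.minimum(xs - x0, x1 - xs), np.minimum(ys - y0, y1 - ys))
        plane = np.where(~inside, _BG, np.where(d == 0, _CSF, np.where(d <= 2, _GM, _WM)))
        # central ventricle (CSF) inside the WM core
        cx0, cx1 = x0 + 3, x1 - 3
        cy0, cy1 = ny // 2 - 3, ny // 2 + 2
        vent = (xs >= cx0) & (xs <= cx1) & (ys >= cy0) & (ys <= cy1) & (plane == _WM)
        plane = np.where(vent, _CSF, plane).astype(np.int8)
        labels[:, :, :] = np.where(plane[:, :, None] != _BG, plane[:, :, None], labels)
    return labels


def build_probmaps(
    shape: tuple[int, int, int] = (32, 32, 12),
    voxel_size: tuple[float, float, float] = (3.5, 3.5, 8.0),
    smoothness: float = 0.8,
    seed: int = 0,
) -> TissueProbMaps:
    """Spatially smooth GM/WM/CSF posterior-probability maps.

    The maps are built by in-plane Gaussian smoothing (SD ``smoothness``
    voxels) of a deterministic tissue-label geometry, plus a small seeded
    smooth perturbation, and are normalized so the per-voxel tissue sum
    never exceeds 1 (the remainder being non-brain background).  The
    geometry contains pure-GM/WM regions (locally rank-deficient for the
    partial-volume regression) as well as mixed boundary regions where the
    regression is well conditioned.
    """
    if len(shape) != 3:
        raise ConfigurationError(f"shape must be 3-D, got {shape}")
    if shape[0] < 7 or shape[1] < 7:
        raise ConfigurationError(
            f"in-plane shape {shape[:2]} smaller than the 7x7 regression kernel"
        )
    if smoothness < 0:
        raise ConfigurationError("smoothness must be >= 0")
    labels = _geometry(tuple(int(s) for s in shape))
    rng = np.random.default_rng(seed)
    fields = []
    for lab in (_BG, _GM, _WM, _CSF):
        f = (labels == lab).astype(np.float64)
        if smoothness > 0:
            f = gaussian_filter(f, sigma=(smoothness, smoothness, 0.0))
        if lab != _BG:
            # seeded smooth multiplicative perturbation, +-~5%
            pert = gaussian_filter(rng.standard_normal(shape), sigma=(2.0, 2.0, 0.0))
            f = f * np.clip(1.0 + 0.15 * pert, 0.5, 1.5)
        fields.append(f)
    total = np.sum(fields, axis=0)
    p_gm, p_wm, p_csf = (f / total for f in fields[1:])
    return TissueProbMaps(
        VolumeGrid(p_gm, voxel_size),
        VolumeGrid(p_wm, voxel_size),
        VolumeGrid(p_csf, voxel_size),
    )


def build_roi_atlas(shape: tuple[int, int, int] = (32, 32, 12),
                    voxel_size: tuple[float, float, float] = (3.5, 3.5, 8.0),
                    m1_slice: int = 10, v1_slice: int = 10) -> RoiAtlas:
    """Mirrored M1 (anterior GM ribbon) and V1 (posterior GM ribbon) masks.

    Masks live on the GM ribbon of the label geometry, on 1-based
    acquisition slice ``m1_slice`` / ``v1_slice`` (default slice 10, where
    the slice-adjusted PLD is 1830 ms).  Left/right members are mirror
    images, so their voxel counts are equal by construction.
    """
    nx, ny, nz = shape
    for s in (m1_slice, v1_slice):
        if not 1 <= s <= nz:
            raise ConfigurationError(f"ROI slice {s} outside 1..{nz}")
    labels = _geometry(tuple(int(s) for s in shape))
    gm = labels == _GM
    left2d = np.broadcast_to(np.arange(nx)[:, None] < nx // 2, (nx, ny))
    ys2d = np.broadcast_to(np.arange(ny)[None, :], (nx, ny))

    def mask(rows2d: np.ndarray, z: int, hemi_left: bool) -> VolumeGrid:
        m = np.zeros(shape, dtype=np.uint8)
        zi = z - 1
        hemi = left2d if hemi_left else ~left2d
        m[:, :, zi] = gm[:, :, zi] & hemi & rows2d
        return VolumeGrid(m, voxel_size)

    anterior = ys2d >= ny - 10
    posterior = ys2d <= 9
    return RoiAtlas(
        m1_left=mask(anterior, m1_slice, True),
        m1_right=mask(anterior, m1_slice, False),
        v1_left=mask(posterior, v1_slice, True),
        v1_right=mask(posterior, v1_slice, False),
    )


def build_truth(
    probmaps: TissueProbMaps,
    f_gm: float = DEFAULT_FLOWS["f_gm"],
    f_wm: float = DEFAULT_FLOWS["f_wm"],
    asymmetry_factor: float = DEFAULT_ASYMMETRY,
    side_occluded: str = "L",
) -> PerfusionTruth:
    """Constant-per-hemisphere truth flows with a GM deficit on one side."""
    if f_gm < 0 or f_wm < 0:
        raise DomainError("flows must be non-negative")
    shape = probmaps.grid.shape
    nx = shape[0]
    occ_left = side_occluded.upper() == "L"
    half = np.arange(nx)[:, None, None] < nx // 2
    occ = np.broadcast_to(half if occ_left else ~half, shape)
    fg = np.where(occ, f_gm * asymmetry_factor, f_gm).astype(np.float64)
    fw = np.full(shape, f_wm, dtype=np.float64)
    return PerfusionTruth(
        probmaps.grid.like(fg), probmaps.grid.like(fw), asymmetry_factor
    )


def forward_delta_m(f, m0_tissue, pld: float, acq: AcqParams):
    """Perfusion-weighted difference signal dM of the one-compartment model.

    dM = f * m0_tissue * 2*alpha*T1b*(1 - exp(-LD/T1b))*exp(-PLD/T1b)
         / (6000*lambda), times in seconds.  Exact inverse of
    :func:`perfcortex.quantify.cbf_from_ratio`: quantifying
    ``dM/m0_tissue`` at the same PLD returns ``f``.
    """
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise DomainError("perfusion f must be non-negative")
    return f * np.asarray(m0_tissue, dtype=np.float64) * delta_m_scale(pld, acq)


def simulate_series(
    probmaps: TissueProbMaps,
    truth: PerfusionTruth,
    magnetizations: dict | None = None,
    acq: AcqParams = AcqParams(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy 4-D control and label series under the kinetic model.

    control = sum_t p_t * m_t + eps;
    label   = noiseless control - sum_{t in GM,WM} p_t * dM_t + eps,
    with eps ~ N(0, acq.noise_sd) i.i.d. per voxel per frame and the PLD of
    each voxel being the slice-adjusted PLD of its (1-based) slice.
    """
    check_same_grid(probmaps.grid, truth.f_gm)
    mags = dict(DEFAULT_MAGNETIZATIONS)
    if magnetizations:
        mags.update(magnetizations)
    shape = probmaps.grid.shape
    control0 = (
        probmaps.p_gm.data * mags["m_gm"]
        + probmaps.p_wm.data * mags["m_wm"]
        + probmaps.p_csf.data * mags["m_csf"]
    )
    dm = np.zeros(shape, dtype=np.float64)
    for z in range(shape[2]):
        pld = adjusted_pld(z + 1, acq)
        dm[:, :, z] = probmaps.p_gm.data[:, :, z] * forward_delta_m(
            truth.f_gm.data[:, :, z], mags["m_gm"], pld, acq
        ) + probmaps.p_wm.data[:, :, z] * forward_delta_m(
            truth.f_wm.data[:, :, z], mags["m_wm"], pld, acq
        )
    label0 = control0 - dm
    rng = np.random.default_rng(seed)
    n = acq.n_pairs
    control = control0[..., None] + rng.normal(0.0, acq.noise_sd, shape + (n,)) if acq.noise_sd > 0 else np.repeat(control0[..., None], n, axis=3)
    label = label0[..., None] + rng.normal(0.0, acq.noise_sd, shape + (n,)) if acq.noise_sd > 0 else np.repeat(label0[..., None], n, axis=3)
    return np.ascontiguousarray(control), np.ascontiguousarray(label)


@dataclass
class PhantomData:
    """Everything one simulated subject produces."""

    probmaps: TissueProbMaps
    truth: PerfusionTruth
    atlas: RoiAtlas
    control4d: np.ndarray
    label4d: np.ndarray
    acq: AcqParams
    magnetizations: dict
    side_occluded: str


def simulate_phantom(
    shape: tuple[int, int, int] = (32, 32, 12),
    voxel_size: tuple[float, float, float] = (3.5, 3.5, 8.0),
    smoothness: float = 0.8,
    acq: AcqParams = AcqParams(),
    magnetizations: dict | None = None,
    f_gm: float = DEFAULT_FLOWS["f_gm"],
    f_wm: float = DEFAULT_FLOWS["f_wm"],
    asymmetry_factor: float = DEFAULT_ASYMMETRY,
    side_occluded: str = "L",
    seed: int = 0,
) -> PhantomData:
    """One-call phantom: probability maps, truth, ROI atlas, noisy series."""
    probmaps = build_probmaps(shape, voxel_size, smoothness, seed)
    truth = build_truth(probmaps, f_gm, f_wm, asymmetry_factor, side_occluded)
    atlas = build_roi_atlas(shape, voxel_size)
    mags = dict(DEFAULT_MAGNETIZATIONS)
    if magnetizations:
        mags.update(magnetizations)
    control, label = simulate_series(probmaps, truth, mags, acq, seed=seed + 1)
    return PhantomData(probmaps, truth, atlas, control, label, acq, mags, side_occluded)


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Generative model of the synthetic study cohort.

    M1 cortical thickness depends linearly on same-side M1 GM CBF and on
    age; V1 thickness depends on neither (``beta_cbf_v1 = beta_age_v1 = 0``).
    CBF on the occluded side equals the subject's unoccluded-side CBF minus
    a hemispheric offset plus within-subject noise.  Covariate prevalences
    default to the study cohort (21/28 hypertension, 6/28 diabetes, 14/28
    complete occlusion, 15/6/7 cross-filling/none/unknown collateral).

    Effect sizes default to a population CBF-thickness correlation of 0.50
    and an age-thickness correlation of -0.35 in M1.
    """

    n_subjects: int = 28
    seed: int = 0
    # thickness model (mm)
    beta_cbf_m1: float = 0.003       # mm per ml*100g^-1*min^-1
    beta_age_m1: float = -0.0042     # mm per year
    beta_cbf_v1: float = 0.0
    beta_age_v1: float = 0.0
    thickness_noise_sd: float = 0.095
    m1_thick_mean_occ: float = 2.07
    m1_thick_mean_unocc: float = 2.15
    v1_thick_mean_occ: float = 1.78
    v1_thick_mean_unocc: float = 1.80
    # CBF model (ml*100g^-1*min^-1)
    m1_cbf_mean_unocc: float = 115.2
    v1_cbf_mean_unocc: float = 112.8
    m1_cbf_offset: float = 9.7       # hemispheric deficit, unocc - occ
    v1_cbf_offset: float = 6.4
    cbf_shared_sd: float = 15.0      # subject-level global flow component
    cbf_region_sd: float = 13.0      # subject-level region-specific component
    m1_cbf_diff_sd: float = 6.0      # within-subject side noise
    v1_cbf_diff_sd: float = 13.0
    hcbf_noise_sd: float = 12.0
    # demographics / covariates
    age_mean: float = 72.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (50.0, 93.0)
    p_htn: float = 21 / 28
    p_dm: float = 6 / 28
    p_occlusion_complete: float = 14 / 28
    p_collateral: tuple[float, float, float] = (15 / 28, 6 / 28, 7 / 28)
    wmh_log_mean: float = 7.5        # log volume units
    wmh_log_sd: float = 1.0
    n_missing_asl: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ConfigurationError("n_subjects must be >= 3")
        if self.thickness_noise_sd < 0:
            raise ConfigurationError("thickness_noise_sd must be >= 0")
        if not 0 <= self.n_missing_asl <= self.n_subjects:
            raise ConfigurationError("n_missing_asl outside 0..n_subjects")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["p_collateral"] = list(self.p_collateral)
        return d


def _exact_counts(n: int, probs, rng) -> np.ndarray:
    """Category assignment with deterministic margins round(p*n), shuffled."""
    probs = np.asarray(probs, dtype=float)
    counts = np.floor(probs * n).astype(int)
    # distribute the remainder to the largest fractional parts
    rem = n - counts.sum()
    order = np.argsort(-(probs * n - counts))
    counts[order[:rem]] += 1
    out = np.repeat(np.arange(len(probs)), counts)
    rng.shuffle(out)
    return out


def simulate_cohort(config: CohortSimConfig) -> pd.DataFrame:
    """Synthetic cohort table with known effect structure.

    Returns the canonical cohort schema (see ``perfcortex.io.COHORT_COLUMNS``)
    plus the ``asl_missing`` flag column.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    n = c.n_subjects
    age = np.clip(rng.normal(c.age_mean, c.age_sd, n), *c.age_range)
    htn = _exact_counts(n, [1 - c.p_htn, c.p_htn], rng)
    dm = _exact_counts(n, [1 - c.p_dm, c.p_dm], rng)
    occl = _exact_counts(n, [1 - c.p_occlusion_complete, c.p_occlusion_complete], rng)
    side = np.where(_exact_counts(n, [0.5, 0.5], rng) == 0, "L", "R")
    coll = np.array(["cross-filling", "none", "unknown"])[_exact_counts(n, c.p_collateral, rng)]

    g = rng.normal(0.0, c.cbf_shared_sd, n)  # shared hemodynamic level
    m1_unocc = c.m1_cbf_mean_unocc + g + rng.normal(0.0, c.cbf_region_sd, n)
    v1_unocc = c.v1_cbf_mean_unocc + g + rng.normal(0.0, c.cbf_region_sd, n)
    m1_occ = m1_unocc - c.m1_cbf_offset + rng.normal(0.0, c.m1_cbf_diff_sd, n)
    v1_occ = v1_unocc - c.v1_cbf_offset + rng.normal(0.0, c.v1_cbf_diff_sd, n)
    m1_unocc, v1_unocc = np.maximum(m1_unocc, 0), np.maximum(v1_unocc, 0)
    m1_occ, v1_occ = np.maximum(m1_occ, 0), np.maximum(v1_occ, 0)
    h_occ = 0.5 * (m1_occ + v1_occ) + rng.normal(0.0, c.hcbf_noise_sd, n)
    h_unocc = 0.5 * (m1_unocc + v1_unocc) + rng.normal(0.0, c.hcbf_noise_sd, n)

    def thick(mean, beta_cbf, beta_age, cbf, cbf_mean):
        noise = rng.normal(0.0, c.thickness_noise_sd, n) if c.thickness_noise_sd > 0 else 0.0
        return (
            mean
            + beta_cbf * (cbf - cbf_mean)
            + beta_age * (age - c.age_mean)
            + noise
        )

    m1_thick_occ = thick(c.m1_thick_mean_occ, c.beta_cbf_m1, c.beta_age_m1,
                         m1_occ, c.m1_cbf_mean_unocc - c.m1_cbf_offset)
    m1_thick_unocc = thick(c.m1_thick_mean_unocc, c.beta_cbf_m1, c.beta_age_m1,
                           m1_unocc, c.m1_cbf_mean_unocc)
    v1_thick_occ = thick(c.v1_thick_mean_occ, c.beta_cbf_v1, c.beta_age_v1,
                         v1_occ, c.v1_cbf_mean_unocc - c.v1_cbf_offset)
    v1_thick_unocc = thick(c.v1_thick_mean_unocc, c.beta_cbf_v1, c.beta_age_v1,
                           v1_unocc, c.v1_cbf_mean_unocc)

    wmh_occ = np.exp(rng.normal(c.wmh_log_mean, c.wmh_log_sd, n))
    wmh_unocc = np.exp(rng.normal(c.wmh_log_mean, c.wmh_log_sd, n))

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "age": age,
            "htn": htn,
            "dm": dm,
            "side_occluded": side,
            "occlusion_complete": occl,
            "collateral": coll,
            "m1_cbf_occ": m1_occ,
            "m1_cbf_unocc": m1_unocc,
            "v1_cbf_occ": v1_occ,
            "v1_cbf_unocc": v1_unocc,
            "h_cbf_occ": h_occ,
            "h_cbf_unocc": h_unocc,
            "m1_thick_occ": m1_thick_occ,
            "m1_thick_unocc": m1_thick_unocc,
            "v1_thick_occ": v1_thick_occ,
            "v1_thick_unocc": v1_thick_unocc,
            "wmh_occ": wmh_occ,
            "wmh_unocc": wmh_unocc,
        }
    )
    if c.n_missing_asl:
        # emulate subjects whose ASL series were uninterpretable
        idx = rng.choice(n, size=c.n_missing_asl, replace=False)
        cbf_cols = [col for col in df.columns if "cbf" in col]
        df.loc[idx, cbf_cols] = np.nan
    df["asl_missing"] = df[[col for col in df.columns if "cbf" in col]].isna().any(axis=1)
    return df
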