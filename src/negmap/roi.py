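"""ROI-level fMRI statistics and functional-anatomical integration.

Volumes live on 3-D grids with a voxel-index -> mm affine (MNI-style, voxel
centers).  The module covers: the 2 x 2 interaction test on percent signal
change (PSC), brain-behavior correlation of per-subject NetNegInt effects,
voxelwise conjunction, overlap fractions between a functional cluster and a
cytoarchitectonic area after nearest-neighbour resampling to a common 1 mm
grid, probability lookup at a peak coordinate, centers of mass, and
probability-map thresholding.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd
from nilearn import image as nlimage
from scipy import stats

from .behavior import AnovaResult, rm_anova_2x2

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """3-D scalar grid with an invertible voxel-index -> mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, float)
        if self.data.ndim != 3:
            raise ValueError("VolumeGrid data must be 3-D")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def count_nonzero(self) -> int:
        return int(np.count_nonzero(self.data))

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path) -> "VolumeGrid":
        img = img_or_path if isinstance(img_or_path, nib.spatialimages.SpatialImage) \
            else nib.load(str(img_or_path))
        return cls(np.asanyarray(img.dataobj), img.affine)


class ProbabilityMap(VolumeGrid):
    """VolumeGrid whose values are fractions of brains in [0, 1]."""

    def __post_init__(self):
        super().__post_init__()
        if np.nanmin(self.data) < -1e-9 or np.nanmax(self.data) > 1 + 1e-9:
            raise ValueError("probability map values must lie in [0, 1]")


def _same_grid(a: VolumeGrid, b: VolumeGrid) -> bool:
    return a.data.shape == b.data.shape and np.allclose(a.affine, b.affine)


def _check_binary(g: VolumeGrid, name: str) -> np.ndarray:
    arr = np.asarray(g.data)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} mask must be binary (0/1)")
    return arr.astype(bool)


# ---------------------------------------------------------------------------
# PSC statistics
# ---------------------------------------------------------------------------

def psc_wide(psc: pd.DataFrame, phase: str | None = None) -> pd.DataFrame:
    """Subjects x 4-cells wide table of PSC values for one phase."""
    df = psc if phase is None else psc[psc["phase"] == phase]
    if df.empty:
        raise ValueError(f"no PSC rows for phase {phase!r}")
    wide = df.pivot_table(index="subject", columns=["polarity", "probe_type"],
                          values="psc", aggfunc="mean")
    if wide.isna().any().any() or wide.columns.size < 4:
        raise ValueError("PSC table missing condition cells for some subjects")
    from .behavior import CELLS
    return wide[list(CELLS)]


def psc_interaction_test(psc: pd.DataFrame, phase: str | None = None) -> AnovaResult:
    """2 x 2 repeated-measures ANOVA on raw PSC (same engine as the log-RT
    ANOVA; PSC is already on an interval scale, so no transform)."""
    return rm_anova_2x2(psc_wide(psc, phase))


def net_neg_int_psc(psc: pd.DataFrame, phase: str | None = None) -> np.ndarray:
    """Per-subject BOLD NetNegInt: (neg-ling - pos-ling) - (neg-symb - pos-symb)."""
    wide = psc_wide(psc, phase)
    d_ling = wide[("negative", "linguistic")] - wide[("positive", "linguistic")]
    d_symb = wide[("negative", "symbolic")] - wide[("positive", "symbolic")]
    return (d_ling - d_symb).to_numpy()


def behavior_bold_correlation(behavioral_net: np.ndarray, bold_net: np.ndarray,
                              tail: str = "greater") -> tuple[float, float]:
    """Pearson correlation of per-subject behavioral (ms) and BOLD (PSC)
    NetNegInt effects; one-tailed ('greater') by default."""
    a = np.asarray(behavioral_net, float)
    b = np.asarray(bold_net, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 subjects")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance: correlation undefined", RuntimeWarning)
        return float("nan"), float("nan")
    res = stats.pearsonr(a, b, alternative=tail)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# mask algebra
# ---------------------------------------------------------------------------

def conjunction(a: VolumeGrid, b: VolumeGrid, resample: bool = False) -> VolumeGrid:
    """Voxelwise AND of two binary masks on the same grid.

    With ``resample=True``, ``b`` is first brought onto ``a``'s grid by
    nearest-neighbour interpolation.
    """
    if not _same_grid(a, b):
        if not resample:
            raise ValueError("grids differ; pass resample=True to allow "
                             "nearest-neighbour resampling")
        b = VolumeGrid.from_nifti(nlimage.resample_to_img(
            b.to_nifti(), a.to_nifti(), interpolation="nearest",
            force_resample=True, copy_header=True))
    out = (_check_binary(a, "a") & _check_binary(b, "b")).astype(np.uint8)
    logger.info("conjunction: %d shared voxels", int(out.sum()))
    return VolumeGrid(out, a.affine.copy())


@dataclass(frozen=True)
class OverlapReport:
    """Shared-voxel overlap between a functional cluster and an anatomical
    area, as percent of each, at the stated isotropic resolution."""

    shared_voxels: int
    pct_anatomical: float
    pct_functional: float
    resolution_mm: float


def _resample_mask(mask: VolumeGrid, target_affine: np.ndarray,
                   target_shape: tuple) -> np.ndarray:
    img = nlimage.resample_img(mask.to_nifti(), target_affine=target_affine,
                               target_shape=target_shape,
                               interpolation="nearest", force_resample=True,
                               copy_header=True)
    return np.asanyarray(img.dataobj) > 0.5


def overlap_fractions(functional: VolumeGrid, anatomical: VolumeGrid,
                      target_res: float = 1.0) -> OverlapReport:
    """Overlap of two binary masks after nearest-neighbour resampling onto a
    common isotropic grid (default 1 mm, the resolution of the anatomical
    probability maps)."""
    f = _check_binary(functional, "functional")
    a = _check_binary(anatomical, "anatomical")
    if not f.any() or not a.any():
        raise ValueError("both masks must be nonempty")
    iso = np.all(np.isclose(np.abs(functional.affine[:3, :3]),
                            np.diag([target_res] * 3))) and _same_grid(functional, anatomical)
    if iso:
        fr, ar = f, a
    else:
        # common bounding grid covering both masks in world space
        corners = []
        for g in (functional, anatomical):
            idx = np.array(np.meshgrid([0, g.data.shape[0] - 1],
                                       [0, g.data.shape[1] - 1],
                                       [0, g.data.shape[2] - 1])).reshape(3, -1).T
            corners.append(nib.affines.apply_affine(g.affine, idx))
        world = np.vstack(corners)
        lo = world.min(0) - target_res
        hi = world.max(0) + target_res
        target_affine = np.diag([target_res] * 3 + [1.0])
        target_affine[:3, 3] = lo
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / target_res)) + 1
                      for i in range(3))
        fr = _resample_mask(functional, target_affine, shape)
        ar = _resample_mask(anatomical, target_affine, shape)
    shared = int(np.count_nonzero(fr & ar))
    return OverlapReport(
        shared_voxels=shared,
        pct_anatomical=100.0 * shared / int(ar.sum()),
        pct_functional=100.0 * shared / int(fr.sum()),
        resolution_mm=float(target_res))


def peak_probability(coord_mm, pmap: ProbabilityMap) -> float:
    """Probability-map value at the voxel containing a mm coordinate.

    The coordinate is mapped through the inverse affine and rounded per axis
    with round-half-away-from-zero (documented tie-break for voxel-boundary
    coordinates).
    """
    coord = np.asarray(coord_mm, float)
    ijk_f = nib.affines.apply_affine(np.linalg.inv(pmap.affine), coord)
    ijk = np.sign(ijk_f) * np.floor(np.abs(ijk_f) + 0.5)
    ijk = ijk.astype(int)
    if np.any(ijk < 0) or np.any(ijk >= np.array(pmap.data.shape)):
        raise ValueError(f"coordinate {tuple(coord)} mm maps to voxel "
                         f"{tuple(ijk)} outside grid {pmap.data.shape}")
    return float(pmap.data[tuple(ijk)])


def center_of_mass(grid: VolumeGrid) -> np.ndarray:
    """Intensity-weighted mean of voxel-center mm coordinates."""
    w = np.asarray(grid.data, float)
    if np.any(w < 0):
        raise ValueError("center_of_mass requires nonnegative intensities")
    tot = w.sum()
    if tot == 0:
        raise ValueError("all-zero map has no center of mass")
    idx = np.argwhere(w > 0)
    weights = w[tuple(idx.T)]
    mm = nib.affines.apply_affine(grid.affine, idx)
    return (weights[:, None] * mm).sum(0) / tot


def threshold_roi(pmap: ProbabilityMap, thr: float) -> VolumeGrid:
    """Binary mask of voxels with probability >= thr (support of the map for
    thr = 0).  An empty result is returned with a warning."""
    if not 0.0 <= thr <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    data = np.asarray(pmap.data, float)
    mask = (data > 0) if thr == 0 else (data >= thr)
    if not mask.any():
        warnings.warn(f"threshold {thr} exceeds map maximum "
                      f"{data.max():.3f}; empty ROI", RuntimeWarning)
    return VolumeGrid(mask.astype(np.uint8), pmap.affine.copy())
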