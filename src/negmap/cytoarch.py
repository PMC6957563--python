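"""Observer-independent cytoarchitectonic border detection.

The procedure delineates cortical areas from cell-body-stained sections
without manual judgment.  A grey-level-index (GLI) image — the local volume
fraction of cell bodies, in [0, 1] — is traversed from the layer I/II
boundary to the layer VI/white-matter boundary along equidistant profiles.
Each depth-normalized profile is summarized by ten moment features (mean
amplitude, centroid depth, SD, skewness, kurtosis of the profile and of its
absolute first derivative).  A sliding window then compares the mean feature
vectors of two adjacent blocks of ``b`` profiles with the Mahalanobis
distance D^2; significance comes from the Hotelling T^2 -> F transform.
Positions where a significant D^2 maximum recurs across many blocksizes are
accepted as areal borders: genuine laminar changes are scale-stable, noise
maxima are not.

Supporting operations: Cavalieri volume estimation from per-section areas
(with shrinkage correction), voxelwise probability maps across brains, and a
paired left/right volume asymmetry test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .behavior import TTestResult, paired_t
from .roi import ProbabilityMap, VolumeGrid

logger = logging.getLogger(__name__)

FEATURE_NAMES = tuple(f"{base}_{src}" for src in ("gli", "absdiff")
                      for base in ("meanamp", "centroid", "sd", "skew", "kurt"))


# ---------------------------------------------------------------------------
# images, contours, profiles
# ---------------------------------------------------------------------------

@dataclass
class GLIImage:
    """2-D grey-level-index field (fraction of cell bodies, clipped to [0,1])."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        self.values = np.clip(np.asarray(self.values, float), 0.0, 1.0)
        if self.values.ndim != 2:
            raise ValueError("GLIImage must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class ContourPair:
    """Outer (layer I/II) and inner (layer VI/white matter) polylines.

    Polylines are (n, 2) arrays of (x, y) pixel coordinates, ordered in the
    same direction along the cortical ribbon.
    """

    outer: np.ndarray
    inner: np.ndarray

    def __post_init__(self):
        self.outer = np.asarray(self.outer, float)
        self.inner = np.asarray(self.inner, float)
        for name, poly in (("outer", self.outer), ("inner", self.inner)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
                raise ValueError(f"{name} contour must be an (n>=2, 2) array")


def _arc_positions(poly: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Points at given arc-length fractions along a polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        raise ValueError("degenerate contour of zero length")
    s = fractions * total
    x = np.interp(s, cum, poly[:, 0])
    y = np.interp(s, cum, poly[:, 1])
    return np.column_stack([x, y])


def extract_profiles(image: GLIImage, contours: ContourPair,
                     spacing_um: float, n_samples: int = 100) -> np.ndarray:
    """Depth-normalized GLI profiles along equidistant traverses.

    Traverses are straight segments joining corresponding arc-length
    fractions of the outer and inner contour, spaced ``spacing_um`` apart
    along the outer contour; each is resampled to ``n_samples`` points by
    bilinear interpolation.  Returns an (n_profiles, n_samples) array ordered
    along the ribbon.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    seg = np.linalg.norm(np.diff(contours.outer, axis=0), axis=1)
    length_um = float(seg.sum()) * image.pixel_size_um
    n_prof = int(np.floor(length_um / spacing_um)) + 1
    fractions = np.minimum(np.arange(n_prof) * spacing_um / length_um, 1.0)
    starts = _arc_positions(contours.outer, fractions)
    ends = _arc_positions(contours.inner, fractions)
    t = np.linspace(0.0, 1.0, n_samples)
    profiles = np.empty((n_prof, n_samples))
    h, w = image.values.shape
    for i in range(n_prof):
        pts = starts[i][None, :] * (1 - t)[:, None] + ends[i][None, :] * t[:, None]
        xs, ys = pts[:, 0], pts[:, 1]
        if (xs.min() < -0.5 or xs.max() > w - 0.5
                or ys.min() < -0.5 or ys.max() > h - 0.5):
            raise ValueError(f"traverse {i} leaves the image")
        profiles[i] = ndimage.map_coordinates(image.values, [ys, xs], order=1,
                                              mode="nearest")
    return profiles


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _moments(weights: np.ndarray, depth: np.ndarray) -> np.ndarray:
    """(mean weight, centroid, SD, skewness, kurtosis) treating ``weights``
    as a density over cortical depth; SD-dependent moments are 0 when the
    distribution is degenerate."""
    w = np.clip(weights, 0.0, None)
    tot = w.sum()
    meanamp = float(weights.mean())
    if tot <= 0:
        return np.array([meanamp, 0.0, 0.0, 0.0, 0.0])
    c = float((w @ depth) / tot)
    var = float((w @ (depth - c) ** 2) / tot)
    sd = np.sqrt(var)
    if sd == 0:
        return np.array([meanamp, c, 0.0, 0.0, 0.0])
    skew = float((w @ (depth - c) ** 3) / (tot * sd ** 3))
    kurt = float((w @ (depth - c) ** 4) / (tot * sd ** 4))
    return np.array([meanamp, c, sd, skew, kurt])


def profile_features(profile: np.ndarray) -> np.ndarray:
    """Ten moment features of a GLI profile.

    Five moments of the profile itself plus the same five of its absolute
    first derivative (central differences); depth is expressed as percent
    cortical depth 0-100.  Degenerate (constant) profiles get their
    SD-dependent features set to 0 with a warning.
    """
    y = np.asarray(profile, float)
    if y.ndim != 1 or y.size < 5:
        raise ValueError("profile must be 1-D with length >= 5")
    depth = np.linspace(0.0, 100.0, y.size)
    deriv = np.abs(np.gradient(y, depth))
    if np.ptp(y) == 0:
        warnings.warn("constant profile: derivative features degenerate",
                      RuntimeWarning)
    return np.concatenate([_moments(y, depth), _moments(deriv, depth)])


def features_matrix(profiles: np.ndarray) -> np.ndarray:
    """(n_profiles, 10) feature matrix."""
    return np.vstack([profile_features(p) for p in np.asarray(profiles, float)])


def standardize_features(features: np.ndarray) -> np.ndarray:
    """Column z-scores across the ROI (sample SD); zero-variance columns are
    left at 0.  Idempotent on already-standardized input."""
    X = np.asarray(features, float)
    mu = X.mean(0)
    sd = X.std(0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


# ---------------------------------------------------------------------------
# sliding Mahalanobis distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceProfile:
    """Mahalanobis D^2 between adjacent blocks of ``blocksize`` profiles.

    Position x compares blocks [x-b, x) and [x, x+b); admissible positions
    are b <= x <= N-b.  ``p`` is the Hotelling T^2 -> F significance.
    """

    blocksize: int
    positions: np.ndarray
    d2: np.ndarray
    p: np.ndarray
    regularized: bool = False


def _pooled_inv(X1: np.ndarray, X2: np.ndarray, ridge: float):
    """Pooled within-block covariance and its (possibly ridge-regularized)
    solve applied to the mean difference."""
    m1, m2 = X1.mean(0), X2.mean(0)
    d = m1 - m2
    A1 = X1 - m1
    A2 = X2 - m2
    S = (A1.T @ A1 + A2.T @ A2) / (X1.shape[0] + X2.shape[0] - 2)
    reg = False
    try:
        sol = np.linalg.solve(S, d)
        if not np.all(np.isfinite(sol)) or np.linalg.cond(S) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        eps = ridge * max(np.trace(S) / S.shape[0], 1e-12)
        sol = np.linalg.solve(S + eps * np.eye(S.shape[0]), d)
        reg = True
    return float(max(d @ sol, 0.0)), reg


def sliding_mahalanobis(features: np.ndarray, blocksize: int,
                        ridge: float = 1e-6) -> DistanceProfile:
    """Sliding-window Mahalanobis distance along the profile sequence.

    At each position the mean feature vectors of the two flanking blocks of
    ``blocksize`` profiles are compared using the pooled within-block
    covariance; significance uses Hotelling's T^2 with
    F = (n - p - 1) / (p (n - 2)) * T^2, df = (p, n - p - 1), n = 2b.
    Singular covariances fall back to a ridge-regularized solve (flagged).
    """
    X = np.asarray(features, float)
    n, p = X.shape
    b = int(blocksize)
    if b < 2:
        raise ValueError("blocksize must be >= 2")
    if n < 2 * b:
        raise ValueError("need at least 2*blocksize feature vectors")
    if b < p / 2:
        warnings.warn(f"blocksize {b} < feature dim/2; covariance estimate "
                      "will be singular and ridge-regularized", RuntimeWarning)
    positions = np.arange(b, n - b + 1)
    d2 = np.empty(positions.size)
    any_reg = False
    for j, x in enumerate(positions):
        val, reg = _pooled_inv(X[x - b:x], X[x:x + b], ridge)
        d2[j] = val
        any_reg |= reg
    ntot = 2 * b
    df2 = ntot - p - 1
    if df2 >= 1:
        t2 = (b * b / ntot) * d2
        f = (df2 / (p * (ntot - 2))) * t2
        pvals = stats.f.sf(f, p, df2)
    else:
        warnings.warn(f"blocksize {b} too small for {p} features; "
                      "significance undefined", RuntimeWarning)
        pvals = np.full(d2.shape, np.nan)
    if any_reg:
        logger.info("sliding_mahalanobis b=%d used ridge regularization", b)
    return DistanceProfile(b, positions, d2, pvals, regularized=any_reg)


# ---------------------------------------------------------------------------
# border acceptance across blocksizes
# ---------------------------------------------------------------------------

DEFAULT_BLOCKSIZES = tuple(range(8, 25, 2))


@dataclass(frozen=True)
class BorderCallSet:
    """Accepted border positions with their supporting blocksizes.

    ``stability`` is the fraction of examined blocksizes supporting each
    border; ``candidates`` maps blocksize -> significant-maximum positions.
    """

    borders: tuple
    support: dict
    stability: dict
    candidates: dict = field(default_factory=dict)


def _significant_maxima(dp: DistanceProfile, alpha: float,
                        correction: str) -> list[int]:
    p = dp.p
    if correction == "bonferroni":
        thr = alpha / p.size
    elif correction == "none":
        thr = alpha
    else:
        raise ValueError("correction must be 'bonferroni' or 'none'")
    cand = []
    d2 = dp.d2
    for j in range(d2.size):
        left = d2[j - 1] if j > 0 else -np.inf
        right = d2[j + 1] if j + 1 < d2.size else -np.inf
        if d2[j] > left and d2[j] >= right and np.isfinite(p[j]) and p[j] < thr:
            cand.append(j)
    # a transition elevates D^2 over a plateau ~one blocksize wide, so
    # significant maxima closer than the blocksize are shoulders of the same
    # border: keep only the strongest within that resolution limit
    cand.sort(key=lambda j: -d2[j])
    kept: list[int] = []
    for j in cand:
        pos = int(dp.positions[j])
        if all(abs(pos - q) >= dp.blocksize for q in kept):
            kept.append(pos)
    return sorted(kept)


def detect_borders(distance_profiles: list[DistanceProfile],
                   alpha: float = 0.05, k_stability: int | None = None,
                   tol: int = 2,
                   correction: str = "bonferroni") -> BorderCallSet:
    """Accept borders that recur as significant D^2 maxima across blocksizes.

    Per blocksize, local maxima of D^2 with (Bonferroni-corrected) p < alpha
    are candidates; a position recurring (within +/- ``tol``) in at least
    ``k_stability`` blocksizes (default: a majority) is accepted.  An empty
    call set is a valid result.
    """
    if len(distance_profiles) < 3:
        raise ValueError("need distance profiles for at least 3 blocksizes")
    nb = len(distance_profiles)
    k = k_stability if k_stability is not None else nb // 2 + 1
    candidates = {dp.blocksize: _significant_maxima(dp, alpha, correction)
                  for dp in distance_profiles}
    # flat list of (position, blocksize)
    flat = [(pos, b) for b, poss in candidates.items() for pos in poss]
    borders, support, stability = [], {}, {}
    while flat:
        # best-supported position first
        best_pos, best_set = None, []
        for pos, _ in flat:
            sup = {b for q, b in flat if abs(q - pos) <= tol}
            if len(sup) > len(best_set) or (len(sup) == len(best_set)
                                            and (best_pos is None or pos < best_pos)):
                best_pos, best_set = pos, sorted(sup)
        if len(best_set) < k:
            break
        members = [(q, b) for q, b in flat if abs(q - best_pos) <= tol]
        center = int(round(float(np.median([q for q, _ in members]))))
        borders.append(center)
        support[center] = sorted({b for _, b in members})
        stability[center] = len(support[center]) / nb
        flat = [(q, b) for q, b in flat if abs(q - best_pos) > tol]
    order = np.argsort(borders)
    borders = tuple(int(borders[i]) for i in order)
    return BorderCallSet(borders=borders, support=support, stability=stability,
                         candidates=candidates)


def border_detection_pipeline(profiles: np.ndarray,
                              blocksizes=DEFAULT_BLOCKSIZES,
                              alpha: float = 0.05,
                              k_stability: int | None = None, tol: int = 2,
                              correction: str = "bonferroni") -> BorderCallSet:
    """Convenience wrapper: features -> standardization -> sliding D^2 over a
    blocksize range -> stability-based acceptance."""
    feats = standardize_features(features_matrix(profiles))
    usable = [b for b in blocksizes if 2 * b <= feats.shape[0]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dps = [sliding_mahalanobis(feats, b) for b in usable]
    return detect_borders(dps, alpha=alpha, k_stability=k_stability, tol=tol,
                          correction=correction)


# ---------------------------------------------------------------------------
# volumes, probability maps, asymmetry
# ---------------------------------------------------------------------------

def area_volume(areas_mm2, thickness_um: float, interval: int,
                shrinkage_factor: float = 1.0) -> float:
    """Cavalieri volume estimate from per-section areas.

    volume = sum(areas) * thickness * interval * shrinkage_factor, with
    ``thickness_um`` the physical section thickness and ``interval`` the
    sampling interval (every n-th section measured).  The shrinkage factor
    corrects histological tissue shrinkage back to fresh volume.
    """
    areas = np.asarray(areas_mm2, float)
    if areas.size == 0:
        raise ValueError("empty section list")
    if thickness_um <= 0 or interval <= 0 or shrinkage_factor <= 0:
        raise ValueError("thickness, interval and shrinkage must be positive")
    return float(areas.sum() * (thickness_um / 1000.0) * interval
                 * shrinkage_factor)


def build_prob_map(grids: list[VolumeGrid],
                   n_brains: int | None = None) -> ProbabilityMap:
    """Voxelwise fraction of brains containing the area.

    All grids must already be aligned (same shape and affine); values are
    binarized before counting.
    """
    if not grids:
        raise ValueError("need at least one grid")
    first = grids[0]
    for g in grids[1:]:
        if g.data.shape != first.data.shape or not np.allclose(g.affine,
                                                               first.affine):
            raise ValueError("misaligned grids: probability map requires a "
                             "common space")
    n = n_brains if n_brains is not None else len(grids)
    counts = np.zeros(first.data.shape, float)
    for g in grids:
        counts += (np.asarray(g.data) > 0)
    return ProbabilityMap(counts / n, first.affine.copy())


def asymmetry_test(left_volumes, right_volumes,
                   tail: str = "two-sided") -> TTestResult:
    """Paired t test of left vs right per-brain area volumes."""
    return paired_t(left_volumes, right_volumes, tail=tail)
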