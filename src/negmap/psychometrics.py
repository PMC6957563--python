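"""Weber's-law Gaussian fits and the Gaussian decomposition of the negation cost.

Numerical-comparison difficulty follows Weber's law: RT as a function of the
blue/yellow numerosity proportion is bell-shaped, and the bell becomes
(closer to) a symmetric Gaussian once the proportion axis is log-compressed.
Two fits implement this:

``fit_weber``
    Fits ``baseline + amplitude * exp(-(u - center)^2 / (2 width^2))`` to the
    five per-proportion mean RTs, on a linear or log-compressed axis, and
    reports R^2.  Comparing R^2 across the two compressions is the Weber test.

``fit_gaussian_3param``
    The same three-parameter model (center fixed) fitted to the RTs of one
    condition, by default collapsed to across-participant means per
    proportion (each subject weighted equally; trial-pooled weighting via
    ``collapse='trials'``).  The fitted *baseline* absorbs
    proportion-independent costs — for the ``less`` vs ``more`` contrast it
    isolates the negation cost from the numerosity tuning, so a permutation
    test on the baseline difference (``permutation_baseline_test``) tests
    negation while leaving amplitude/width free to soak up Weber structure.

The fit is solved by variable projection: for any fixed width the
baseline/amplitude solve is linear, leaving a 1-D width search.  A
deterministic coarse log-grid over width followed by bounded Brent
refinement makes the fit fast (sub-millisecond) and reproducible, which the
permutation test exploits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

PARAM_NAMES = ("baseline", "amplitude", "width")


class FitError(RuntimeError):
    """Raised when the Gaussian fit cannot converge; carries diagnostics."""


@dataclass(frozen=True)
class GaussianFit:
    """Fixed-center Gaussian ``b + A * exp(-(u - c)^2 / (2 w^2))``.

    ``width`` is in the (possibly log-compressed) axis units; ``r2`` is
    1 - SSres/SStot on the fitted observations (NaN for degenerate input).
    """

    baseline: float
    amplitude: float
    width: float
    center: float
    r2: float
    sse: float
    compress: str
    x: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    y: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    weights: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    degenerate: bool = False

    def predict(self, u: np.ndarray) -> np.ndarray:
        g = np.exp(-((np.asarray(u, float) - self.center) ** 2)
                   / (2.0 * self.width ** 2))
        return self.baseline + self.amplitude * g

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.predict(self.x)

    def params(self) -> dict:
        return {"baseline": self.baseline, "amplitude": self.amplitude,
                "width": self.width}


def _compress_axis(x: np.ndarray, compress: str) -> np.ndarray:
    if compress == "log":
        if np.any(x <= 0):
            raise ValueError("log compression requires positive proportions")
        return np.log(x)
    if compress == "linear":
        return np.asarray(x, float)
    raise ValueError(f"unknown compression {compress!r}")


def default_center(x: np.ndarray, compress: str) -> float:
    """Compressed coordinate of the hardest proportion (ratio closest to 1).

    RT peaks at maximal comparison difficulty, i.e. where the two numerosities
    are most similar, so the Gaussian center is pinned there by default.
    """
    x = np.asarray(x, float)
    hardest = x[np.argmin(np.abs(np.log(x)))]
    return float(_compress_axis(np.array([hardest]), compress)[0])


def _linear_solve(g: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted LS solve of y ~ b + A*g; returns (b, A, sse)."""
    sw = w.sum()
    swg = w @ g
    swgg = w @ (g * g)
    swy = w @ y
    swgy = w @ (g * y)
    det = sw * swgg - swg * swg
    if det <= 1e-14 * sw * swgg + 1e-300:
        # g numerically constant: amplitude unidentifiable, fall back to mean
        b = swy / sw
        return b, 0.0, float(w @ (y - b) ** 2)
    A = (sw * swgy - swg * swy) / det
    b = (swy - A * swg) / sw
    r = y - b - A * g
    return b, A, float(w @ (r * r))


#: admissible width range as fractions of the compressed-axis span.  Beyond
#: half the span the Gaussian no longer decays to its floor inside the
#: sampled proportion range, so baseline and amplitude become collinear and
#: the baseline degenerates into an extrapolation; the bound is part of the
#: estimator definition.
WIDTH_BOUNDS = (0.02, 0.5)


def _fit_fixed_center(u: np.ndarray, y: np.ndarray, w: np.ndarray,
                      center: float) -> tuple[float, float, float, float]:
    """Variable-projection fit; returns (baseline, amplitude, width, sse)."""
    span = float(u.max() - u.min())
    if span <= 0:
        raise ValueError("need at least two distinct x positions")
    d2 = (u - center) ** 2

    def sse_of(width: float) -> float:
        g = np.exp(-d2 / (2.0 * width * width))
        return _linear_solve(g, y, w)[2]

    # deterministic coarse grid then local Brent refinement
    grid = np.geomspace(WIDTH_BOUNDS[0] * span, WIDTH_BOUNDS[1] * span, 40)
    sses = np.array([sse_of(wd) for wd in grid])
    i = int(np.argmin(sses))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(sse_of, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:  # pragma: no cover - bounded Brent always terminates
        raise FitError(f"width optimization failed: {res.message}")
    width = float(res.x)
    g = np.exp(-d2 / (2.0 * width * width))
    b, A, sse = _linear_solve(g, y, w)
    return float(b), float(A), width, sse


def _finish(u, ybar, w, center, compress, sse, b, A, width,
            sstot=None) -> GaussianFit:
    if sstot is None:
        ybar_w = (w @ ybar) / w.sum()
        sstot = float(w @ (ybar - ybar_w) ** 2)
    r2 = 1.0 - sse / sstot if sstot > 0 else math.nan
    return GaussianFit(b, A, width, center, r2, sse, compress,
                       x=u, y=ybar, weights=w)


def fit_weber(means: np.ndarray, x: np.ndarray, compress: str = "log",
              center: float | None = None) -> GaussianFit:
    """Fit the fixed-center Gaussian to per-proportion mean RTs.

    means, x : the (usually five) condition means and proportion values.
    compress : 'log' (Weber-compliant) or 'linear' axis.
    """
    means = np.asarray(means, float)
    x = np.asarray(x, float)
    if means.shape != x.shape or means.ndim != 1:
        raise ValueError("means and x must be equal-length 1-D arrays")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct proportions")
    if not np.all(np.isfinite(means)):
        raise ValueError("non-finite means")
    if center is None:
        center = default_center(x, compress)
    u = _compress_axis(x, compress)
    w = np.ones_like(means)
    if np.ptp(means) == 0.0:
        logger.warning("fit_weber: constant means; degenerate fit")
        return GaussianFit(float(means[0]), 0.0, math.nan, center, math.nan,
                           0.0, compress, x=u, y=means, weights=w,
                           degenerate=True)
    b, A, width, sse = _fit_fixed_center(u, means, w, center)
    return _finish(u, means, w, center, compress, sse, b, A, width)


def _ratio_column(trials: pd.DataFrame, ratios: dict | None) -> np.ndarray:
    if "ratio" in trials.columns:
        return trials["ratio"].to_numpy(float)
    if ratios is not None:
        return trials["proportion"].map(ratios).to_numpy(float)
    raise ValueError("trials need a 'ratio' column or a ratios mapping")


def _collapse(trials: pd.DataFrame, ratios: dict | None, collapse: str):
    """Per-proportion mean RTs and fit weights.

    collapse='subjects' (default): mean RT across participants — each
    subject's per-proportion mean enters with equal weight, so between-
    subject offsets cannot leak into the curve shape through unequal
    per-cell trial counts.  collapse='trials': count-weighted pooled trial
    means (equivalent when the design is balanced).
    """
    xcol = _ratio_column(trials, ratios)
    rt = trials["rt_ms"].to_numpy(float)
    xs, inv = np.unique(xcol, return_inverse=True)
    if collapse == "subjects" and "subject" in trials.columns:
        sub = trials["subject"].to_numpy()
        subs, si = np.unique(sub, return_inverse=True)
        S, K = subs.size, xs.size
        flat = si * K + inv
        cnt = np.bincount(flat, minlength=S * K).reshape(S, K)
        tot = np.bincount(flat, weights=rt, minlength=S * K).reshape(S, K)
        if np.any(cnt == 0):
            raise ValueError("every subject needs trials at every proportion")
        ybar = (tot / cnt).mean(axis=0)
        w = np.full(xs.size, float(S))
    elif collapse in ("subjects", "trials"):
        n = np.bincount(inv).astype(float)
        ybar = np.bincount(inv, weights=rt) / n
        w = n
    else:
        raise ValueError("collapse must be 'subjects' or 'trials'")
    return xs, ybar, w


def fit_gaussian_3param(trials: pd.DataFrame, ratios: dict | None = None,
                        compress: str = "log", center: float | None = None,
                        collapse: str = "subjects") -> GaussianFit:
    """Three-parameter Gaussian (baseline, amplitude, width; center fixed)
    fitted to the RTs of one condition.

    By default the RTs are collapsed to the across-participant mean per
    proportion (each subject weighted equally); ``collapse='trials'``
    instead pools trials with count weights, which minimizes the trial-level
    SSE and coincides with the default when cell counts are balanced.
    ``sse``/``r2`` refer to the collapsed per-proportion means.
    """
    xs, ybar, w = _collapse(trials, ratios, collapse)
    if xs.size < 3:
        raise ValueError("need at least 3 proportions represented")
    if center is None:
        center = default_center(xs, compress)
    u = _compress_axis(xs, compress)
    if np.ptp(ybar) == 0.0:
        logger.warning("fit_gaussian_3param: constant means; degenerate fit")
        return GaussianFit(float(ybar[0]), 0.0, math.nan, center, math.nan,
                           0.0, compress, x=u, y=ybar, weights=w,
                           degenerate=True)
    b, A, width, sse = _fit_fixed_center(u, ybar, w, center)
    return _finish(u, ybar, w, center, compress, sse, b, A, width)


# ---------------------------------------------------------------------------
# permutation test on the decomposition parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermTestResult:
    """Observed (less - more) parameter differences with permutation p-values.

    p uses the add-one rule (1 + #{|null| >= |observed|}) / (1 + n_perm) for
    Monte-Carlo sampling, or the exact proportion over all 2^S within-subject
    flips when exhaustive enumeration was used.
    """

    observed: dict
    p: dict
    n_perm: int
    exhaustive: bool
    seed: int | None


def _cell_stats(trials: pd.DataFrame, subjects: np.ndarray,
                xs: np.ndarray, ratios: dict | None):
    """Per subject x proportion RT sums and counts (S x K arrays)."""
    if "ratio" in trials.columns:
        xcol = trials["ratio"].to_numpy(float)
    else:
        xcol = trials["proportion"].map(ratios).to_numpy(float)
    si = np.searchsorted(subjects, trials["subject"].to_numpy())
    xi = np.searchsorted(xs, xcol)
    S, K = subjects.size, xs.size
    flat = si * K + xi
    cnt = np.bincount(flat, minlength=S * K).reshape(S, K).astype(float)
    tot = np.bincount(flat, weights=trials["rt_ms"].to_numpy(float),
                      minlength=S * K).reshape(S, K)
    return tot, cnt


def _fit_params(u, ybar, w, center):
    b, A, width, _ = _fit_fixed_center(u, ybar, w, center)
    return np.array([b, A, abs(width)])


def permutation_baseline_test(trials_more: pd.DataFrame,
                              trials_less: pd.DataFrame,
                              n_perm: int = 1999, seed: int | None = 0,
                              ratios: dict | None = None,
                              compress: str = "log",
                              center: float | None = None,
                              unit: str = "subject") -> PermTestResult:
    """Permutation test of the Gaussian-parameter differences between the
    negative and positive condition of the same subjects.

    The null is built by flipping the more/less labels of whole subjects
    (``unit='subject'``, respecting the paired design; 2^S distinct states)
    or by reshuffling labels across trials within each subject
    (``unit='trial'``).  If ``n_perm`` meets or exceeds the number of
    distinct subject flips, the test switches to exhaustive enumeration.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    subs_m = np.unique(trials_more["subject"])
    subs_l = np.unique(trials_less["subject"])
    if not np.array_equal(subs_m, subs_l):
        raise ValueError("conditions must come from the same subjects")
    subjects = subs_m
    both = pd.concat([trials_more, trials_less])
    if "ratio" in both.columns:
        xs = np.unique(both["ratio"].to_numpy(float))
    else:
        xs = np.unique(both["proportion"].map(ratios).to_numpy(float))
    if center is None:
        center = default_center(xs, compress)
    u = _compress_axis(xs, compress)

    SumM, CntM = _cell_stats(trials_more, subjects, xs, ratios)
    SumL, CntL = _cell_stats(trials_less, subjects, xs, ratios)
    if np.any(CntM == 0) or np.any(CntL == 0):
        raise ValueError("every subject needs trials at every proportion "
                         "in both conditions")
    # per-subject per-proportion means: the fit statistic weights subjects
    # equally, so unequal surviving trial counts cannot couple between-
    # subject offsets into the curve shape
    MeanM = SumM / CntM
    MeanL = SumL / CntL

    S = subjects.size
    wfit = np.full(xs.size, float(S))
    obs_m = _fit_params(u, MeanM.mean(0), wfit, center)
    obs_l = _fit_params(u, MeanL.mean(0), wfit, center)
    observed = obs_l - obs_m

    if unit == "subject":
        exhaustive = S <= 62 and n_perm >= 2 ** S - 1
        if exhaustive:
            logger.info("permutation_baseline_test: exhaustive enumeration of "
                        "%d flip patterns", 2 ** S)
            flips = np.array([[(m >> s) & 1 for s in range(S)]
                              for m in range(2 ** S)], dtype=float)
        else:
            rng = np.random.default_rng(seed)
            flips = rng.integers(0, 2, size=(n_perm, S)).astype(float)
        # per-proportion across-subject means for condition "A" (plays 'more')
        MeanA = (flips @ MeanL + (1.0 - flips) @ MeanM) / S
        MeanB = (MeanM + MeanL).mean(0)[None, :] - MeanA
        null = np.empty((flips.shape[0], 3))
        for i in range(flips.shape[0]):
            pa = _fit_params(u, MeanA[i], wfit, center)
            pb = _fit_params(u, MeanB[i], wfit, center)
            null[i] = pb - pa
    elif unit == "trial":
        exhaustive = False
        rng = np.random.default_rng(seed)
        pooled = both.reset_index(drop=True)
        null = np.empty((n_perm, 3))
        codes = pooled.groupby("subject", observed=True).indices
        for i in range(n_perm):
            lab = np.zeros(len(pooled), dtype=bool)
            for _, idx in codes.items():
                take = rng.permutation(idx)
                lab[take[: idx.size // 2]] = True
            pa = fit_gaussian_3param(pooled[~lab], ratios, compress, center,
                                     collapse="trials")
            pb = fit_gaussian_3param(pooled[lab], ratios, compress, center,
                                     collapse="trials")
            null[i] = [pb.baseline - pa.baseline, pb.amplitude - pa.amplitude,
                       abs(pb.width) - abs(pa.width)]
    else:
        raise ValueError("unit must be 'subject' or 'trial'")

    with np.errstate(invalid="ignore"):
        ge = np.abs(null) >= np.abs(observed)[None, :]
    ge = np.where(np.isnan(null), False, ge)
    counts = ge.sum(0)
    if exhaustive:
        pvals = counts / null.shape[0]  # identity flip included: p >= 2^-S
    else:
        pvals = (1.0 + counts) / (1.0 + null.shape[0])
    return PermTestResult(
        observed=dict(zip(PARAM_NAMES, observed.tolist())),
        p=dict(zip(PARAM_NAMES, pvals.tolist())),
        n_perm=int(null.shape[0] - (1 if exhaustive else 0)),
        exhaustive=bool(exhaustive), seed=seed)
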