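"""Synthetic-data generators with known ground truth.

The generators emulate the statistical structure the analysis stages assume:

* ``gen_trials`` — trial-level RT/accuracy tables from the 2 (Polarity) x
  2 (Probe type) x 5 (Proportion) within-subject verification design.  The
  mean structure is additive — grand baseline, a negation cost on negative
  linguistic trials, a symbol-reversal cost on negative symbolic trials, and
  a Gaussian Weber bump over log proportion — with a Gaussian between-subject
  offset and mean-one lognormal trial noise (RTs are positive and
  right-skewed; downstream inference works on log RT).
* ``gen_psc`` — per-subject per-condition per-phase percent-signal-change
  values for one ROI, constructed so that the subject-level BOLD NetNegInt
  correlates with a supplied behavioral NetNegInt vector at exactly the
  requested population level ``rho`` (the coupling mixes the standardized
  behavioral effect with independent noise; non-interaction cell noise is
  projected off the interaction contrast so the construction is exact).
* ``gen_histology_phantom`` — 2-D GLI images of a straight cortical ribbon
  whose columns follow per-area laminar templates, switching template at
  known traverse indices; pixelwise Gaussian noise, clipped to [0, 1].
* ``gen_volume`` — 3-D masks / scalar maps built from blob specifications
  (later blobs win on overlap).

All generators are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytoarch import ContourPair, GLIImage
from .roi import VolumeGrid

logger = logging.getLogger(__name__)

#: default blue/yellow numerosity proportions: five log-spaced ratios
#: straddling equality symmetrically (the printed stimulus ratios are not
#: public; these are configuration placeholders, not reconstructions)
DEFAULT_PROPORTIONS = tuple(np.geomspace(0.5, 2.0, 5).round(4))

POLARITIES = ("positive", "negative")
PROBE_TYPES = ("linguistic", "symbolic")


@dataclass(frozen=True)
class DesignSpec:
    """The 2 x 2 x 5 within-subject design (6 tokens per cell by default)."""

    proportions: tuple = DEFAULT_PROPORTIONS
    tokens_per_cell: int = 6
    n_subjects: int = 21
    polarities: tuple = POLARITIES
    probe_types: tuple = PROBE_TYPES

    def __post_init__(self):
        if len(self.polarities) != 2 or len(self.probe_types) != 2:
            raise ValueError("design requires exactly 2x2 condition cells")
        if len(self.proportions) != 5:
            raise ValueError("design requires exactly 5 proportions")
        if min(self.proportions) <= 0:
            raise ValueError("proportions must be positive ratios")
        if self.tokens_per_cell < 1 or self.n_subjects < 1:
            raise ValueError("counts must be positive")

    @property
    def ratios(self) -> dict:
        """proportion index (1-5) -> blue/yellow ratio"""
        return {i + 1: r for i, r in enumerate(self.proportions)}


@dataclass(frozen=True)
class RTModelParams:
    """Generative RT model (ms).

    RT = [mu0 + delta_ling*(neg & linguistic) + delta_symb*(neg & symbolic)
          + amp * exp(-(log p - center)^2 / (2 width^2)) + subject offset]
         * mean-one lognormal(sigma_e) noise.

    Defaults reproduce the published condition structure: a 152.5 ms negation
    cost and an 83.4 ms symbol-reversal cost on a ~850 ms baseline, a 100 ms
    Weber bump, 300 ms between-subject SD (truncated at +/-2.5 SD so that
    structural RTs stay positive; effective SD ~288 ms, matching the reported
    between-subject spread), 10% multiplicative trial noise and a 16% error
    rate (84% correct).
    """

    mu0: float = 850.0
    delta_ling: float = 152.5
    delta_symb: float = 83.4
    amp: float = 100.0
    width: float = 0.25
    center: float = 0.0
    tau_subj: float = 300.0
    sigma_e: float = 0.10
    err_rate: float = 0.16

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be nonnegative")
        if not 0.0 <= self.err_rate < 1.0:
            raise ValueError("err_rate must lie in [0, 1)")
        if self.tau_subj < 0:
            raise ValueError("tau_subj must be nonnegative")


def expected_cell_mean(design: DesignSpec, params: RTModelParams,
                       polarity: str, probe_type: str,
                       ratio: float) -> float:
    """Noise-free structural mean for one design cell."""
    m = params.mu0
    if polarity == "negative":
        m += params.delta_ling if probe_type == "linguistic" else params.delta_symb
    m += params.amp * np.exp(-(np.log(ratio) - params.center) ** 2
                             / (2.0 * params.width ** 2))
    return float(m)


def gen_trials(design: DesignSpec, params: RTModelParams,
               seed: int) -> pd.DataFrame:
    """Simulate the full trial table.

    Rows: n_subjects x 2 x 2 x 5 x tokens_per_cell; columns subject,
    polarity, probe_type, proportion (index 1-5), ratio, token, rt_ms,
    correct.  The lognormal noise is normalized to mean one, so the expected
    cell mean equals the structural formula.  Accuracy is Bernoulli(1 -
    err_rate), independent of RT.
    """
    rng = np.random.default_rng(seed)
    subs = np.arange(1, design.n_subjects + 1)
    # truncated Gaussian subject offsets (+/- 2.5 SD) keep structural RTs > 0
    u = rng.normal(0.0, params.tau_subj, size=design.n_subjects)
    if params.tau_subj > 0:
        out = np.abs(u) > 2.5 * params.tau_subj
        while np.any(out):
            u[out] = rng.normal(0.0, params.tau_subj, size=int(out.sum()))
            out = np.abs(u) > 2.5 * params.tau_subj
    idx = pd.MultiIndex.from_product(
        [subs, design.polarities, design.probe_types,
         range(1, 6), range(1, design.tokens_per_cell + 1)],
        names=["subject", "polarity", "probe_type", "proportion", "token"])
    df = idx.to_frame(index=False)
    ratio = df["proportion"].map(design.ratios).to_numpy(float)
    df["ratio"] = ratio
    neg = (df["polarity"] == "negative").to_numpy()
    ling = (df["probe_type"] == "linguistic").to_numpy()
    struct = (params.mu0
              + params.delta_ling * (neg & ling)
              + params.delta_symb * (neg & ~ling)
              + params.amp * np.exp(-(np.log(ratio) - params.center) ** 2
                                    / (2.0 * params.width ** 2))
              + u[df["subject"].to_numpy() - 1])
    if np.any(struct <= 0):
        raise ValueError("model parameters produce nonpositive structural "
                         "RTs; reduce tau_subj or raise mu0")
    noise = np.exp(params.sigma_e * rng.standard_normal(len(df))
                   - 0.5 * params.sigma_e ** 2)
    df["rt_ms"] = struct * noise
    df["correct"] = rng.random(len(df)) >= params.err_rate
    return df


# ---------------------------------------------------------------------------
# percent signal change
# ---------------------------------------------------------------------------

def _default_cell_means() -> dict:
    cond = {("negative", "linguistic"): 0.25, ("positive", "linguistic"): 0.20,
            ("negative", "symbolic"): 0.21, ("positive", "symbolic"): 0.21}
    return {"I": dict(cond), "II": dict(cond)}


@dataclass(frozen=True)
class PSCModelParams:
    """Generative percent-signal-change model for one ROI.

    cell_means : phase -> (polarity, probe_type) -> PSC %.  Defaults follow
        the published insular Phase I pattern (0.25 vs 0.20 for the
        linguistic pair; no symbolic difference).
    sigma_psc : SD of per-cell noise orthogonal to the interaction contrast.
    sigma_net : between-subject SD of the BOLD NetNegInt effect.
    sigma_subj : SD of the additive per-subject offset.
    rho : target population correlation between behavioral and BOLD
        NetNegInt across subjects.
    """

    cell_means: dict = field(default_factory=_default_cell_means)
    sigma_psc: float = 0.05
    sigma_net: float = 0.10
    sigma_subj: float = 0.10
    rho: float = 0.4

    def __post_init__(self):
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if min(self.sigma_psc, self.sigma_net, self.sigma_subj) < 0:
            raise ValueError("noise SDs must be nonnegative")


#: interaction contrast over cells, order (neg,ling), (pos,ling), (neg,symb), (pos,symb)
_PSC_CELLS = (("negative", "linguistic"), ("positive", "linguistic"),
              ("negative", "symbolic"), ("positive", "symbolic"))
_Q = np.array([1.0, -1.0, -1.0, 1.0])


def gen_psc(design: DesignSpec, params: PSCModelParams,
            behavioral_effects: np.ndarray, seed: int) -> pd.DataFrame:
    """Simulate the PSC table (subject, polarity, probe_type, phase, psc).

    The per-subject BOLD NetNegInt g_i is the cell-mean interaction plus
    sigma_net * (rho * z_i + sqrt(1-rho^2) * eps_i), where z_i is the
    standardized behavioral effect; cell noise is projected orthogonal to the
    interaction contrast, so the sample correlation between behavioral and
    BOLD NetNegInt converges to rho exactly.
    """
    beh = np.asarray(behavioral_effects, float)
    n = design.n_subjects
    if beh.size != n:
        raise ValueError("behavioral_effects length must equal n_subjects")
    rng = np.random.default_rng(seed)
    if beh.std() > 0:
        z = (beh - beh.mean()) / beh.std()
    else:
        if params.rho != 0:
            logger.warning("constant behavioral effects: coupling undefined")
        z = np.zeros(n)
    rows = []
    u = rng.normal(0.0, params.sigma_subj, size=n)
    for phase, means in params.cell_means.items():
        m = np.array([means[c] for c in _PSC_CELLS])
        net_mean = float(_Q @ m)
        eps = rng.standard_normal(n)
        g = net_mean + params.sigma_net * (params.rho * z
                                           + np.sqrt(1.0 - params.rho ** 2) * eps)
        e = rng.normal(0.0, params.sigma_psc, size=(n, 4))
        e -= np.outer(e @ _Q / 4.0, _Q)  # remove interaction component
        psc = m[None, :] + u[:, None] + np.outer(g - net_mean, _Q / 4.0) + e
        for si in range(n):
            for ci, (pol, pt) in enumerate(_PSC_CELLS):
                rows.append((si + 1, pol, pt, phase, psc[si, ci]))
    return pd.DataFrame(rows, columns=["subject", "polarity", "probe_type",
                                       "phase", "psc"])


# ---------------------------------------------------------------------------
# histology phantoms
# ---------------------------------------------------------------------------

def laminar_template(n: int = 128, layer4_amp: float = 0.28,
                     deep_amp: float = 0.10, base: float = 0.32) -> np.ndarray:
    """Smooth laminar GLI template over relative depth 0-1.

    A cell-sparse molecular layer, a layer-IV granularity peak near 55%
    depth, and a deep layer-V/VI density band near 85% depth.  Lowering
    ``layer4_amp`` produces the dysgranular pattern (inconspicuous,
    interrupted layer IV); raising ``deep_amp`` mimics denser multiform
    packing.
    """
    d = np.linspace(0.0, 1.0, n)
    t = (base
         - 0.20 * np.exp(-((d - 0.03) ** 2) / (2 * 0.05 ** 2))
         + layer4_amp * np.exp(-((d - 0.55) ** 2) / (2 * 0.06 ** 2))
         + deep_amp * np.exp(-((d - 0.85) ** 2) / (2 * 0.07 ** 2)))
    return np.clip(t, 0.0, 1.0)


def default_templates(separation: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Granular-ish vs dysgranular template pair.

    ``separation`` scales the laminar contrast between the two areas
    (1 = default contrast, 0 = identical templates).
    """
    t1 = laminar_template(layer4_amp=0.28, deep_amp=0.08)
    t2 = laminar_template(layer4_amp=0.06, deep_amp=0.22)
    return t1, t1 + separation * (t2 - t1)


@dataclass(frozen=True)
class HistologyPhantomSpec:
    """Straight-ribbon GLI phantom with known areal borders.

    The ribbon spans all ``n_traverses`` image columns between two horizontal
    contours; column j follows the laminar template of its area, areas
    switching at the listed border traverse indices.
    """

    n_traverses: int = 80
    ribbon_depth_px: int = 120
    margin_px: int = 8
    pixel_size_um: float = 20.0
    templates: tuple = field(default_factory=default_templates)
    borders: tuple = (40,)
    noise_sd: float = 0.05

    def __post_init__(self):
        if len(self.templates) != len(self.borders) + 1:
            raise ValueError("need exactly len(borders)+1 templates")
        for t in self.templates:
            t = np.asarray(t)
            if t.min() < 0 or t.max() > 1:
                raise ValueError("templates must be bounded in [0, 1]")
        if list(self.borders) != sorted(set(self.borders)):
            raise ValueError("borders must be strictly increasing")
        for b in self.borders:
            if not 0 < b < self.n_traverses:
                raise ValueError(f"border index {b} outside traverse range "
                                 f"(0, {self.n_traverses})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def contours(self) -> ContourPair:
        xs = np.arange(self.n_traverses, dtype=float)
        top = self.margin_px
        bot = self.margin_px + self.ribbon_depth_px - 1
        outer = np.column_stack([xs, np.full_like(xs, float(top))])
        inner = np.column_stack([xs, np.full_like(xs, float(bot))])
        return ContourPair(outer, inner)


def gen_histology_phantom(spec: HistologyPhantomSpec,
                          seed: int) -> tuple[GLIImage, tuple]:
    """Render the phantom; returns (GLIImage, true border traverse indices)."""
    rng = np.random.default_rng(seed)
    h = spec.ribbon_depth_px + 2 * spec.margin_px
    img = np.zeros((h, spec.n_traverses))
    depth_frac = np.arange(spec.ribbon_depth_px) / (spec.ribbon_depth_px - 1)
    cols = []
    for t in spec.templates:
        t = np.asarray(t, float)
        src = np.linspace(0.0, 1.0, t.size)
        cols.append(np.interp(depth_frac, src, t))
    area = np.searchsorted(np.asarray(spec.borders), np.arange(spec.n_traverses),
                           side="right")
    top = spec.margin_px
    for j in range(spec.n_traverses):
        img[top:top + spec.ribbon_depth_px, j] = cols[area[j]]
    if spec.noise_sd > 0:
        img[top:top + spec.ribbon_depth_px, :] += rng.normal(
            0.0, spec.noise_sd, size=(spec.ribbon_depth_px, spec.n_traverses))
    return GLIImage(img, spec.pixel_size_um), tuple(spec.borders)


# ---------------------------------------------------------------------------
# synthetic volumes
# ---------------------------------------------------------------------------

def gen_volume(shape: tuple, affine: np.ndarray | None = None,
               blobs: list[dict] | None = None) -> VolumeGrid:
    """Build a labelled 3-D grid from blob specifications.

    Each blob is a dict with ``value`` (default 1) and either ``voxels`` (a
    list of ijk indices) or ``center`` + ``radius`` (a voxel-space sphere:
    all voxels whose centers lie within ``radius``).  Blobs are applied in
    order; later blobs overwrite earlier ones on overlap (logged).
    """
    affine = np.eye(4) if affine is None else np.asarray(affine, float)
    data = np.zeros(shape, float)
    for k, blob in enumerate(blobs or []):
        value = blob.get("value", 1.0)
        mask = np.zeros(shape, bool)
        if "voxels" in blob:
            for ijk in blob["voxels"]:
                mask[tuple(ijk)] = True
        elif "center" in blob:
            grids = np.indices(shape).astype(float)
            c = np.asarray(blob["center"], float)
            r2 = sum((grids[i] - c[i]) ** 2 for i in range(3))
            mask = r2 <= float(blob["radius"]) ** 2
        else:
            raise ValueError(f"blob {k} needs 'voxels' or 'center'+'radius'")
        clobbered = int(np.count_nonzero(data[mask]))
        if clobbered:
            logger.info("gen_volume: blob %d overwrites %d voxels", k, clobbered)
        data[mask] = value
    return VolumeGrid(data, affine)
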