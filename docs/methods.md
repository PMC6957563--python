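# Methods

This note documents the statistical models, the synthetic-data generators,
and the numerical choices behind `negmap`.  Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The experimental design being modelled

The behavioral substrate is a 2 x 2 x 5 within-subject speeded verification
task.  A probe (Phase I) states a proportion between two colored-circle
numerosities either linguistically (*more/less than half*) or with
inequality symbols (>, <); an image (Phase II) then shows the two
numerosities and the participant verifies the probe.  The factors are:

* **Polarity** — positive (*more*, >) vs negative (*less*, <).  The negative
  linguistic quantifier carries an implicit logical negation; the negative
  symbol does not.
* **Probe type** — linguistic vs symbolic.
* **Proportion** — five blue/yellow numerosity ratios controlling
  comparison difficulty via Weber's law.

The quantity of interest is the **net negation interaction (NetNegInt)**:

    NetNegInt = (RT_less - RT_more) - (RT_< - RT_>)

i.e. the polarity cost of the linguistic pair minus the polarity cost of the
symbolic pair.  A positive NetNegInt isolates the cost of processing
implicit negation from lexical/symbol-reversal costs.  The same contrast is
applied to ROI percent signal change (PSC), and the two per-subject effect
vectors are correlated (one-tailed Pearson) to test brain-behavior coupling.

## Trial generator (`synthdata.gen_trials`)

Structural mean per trial:

    m = mu0 + delta_ling * [negative & linguistic]
            + delta_symb * [negative & symbolic]
            + amp * exp(-(log p - center)^2 / (2 width^2))
            + u_subject

with `RT = m * exp(sigma_e * z - sigma_e^2 / 2)`, `z ~ N(0,1)`.  The
lognormal factor has mean one, so the expected cell mean equals the
structural formula exactly; RTs are positive and right-skewed, which is why
downstream inference uses log RT.  Accuracy is Bernoulli(1 - err_rate),
independent of RT — a documented simplification (no speed-accuracy
trade-off).

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `mu0` | 850 ms | baseline verification RT of the easy positive conditions |
| `delta_ling` | 152.5 ms | the published less-more condition gap |
| `delta_symb` | 83.4 ms | the published < - > condition gap |
| `amp` | 100 ms | difficulty cost at the hardest proportion |
| `width` | 0.25 log-units | numerosity-comparison tuning: difficulty is mostly gone by ratio ~1.6, consistent with Weber fractions for dot comparison |
| `center` | 0 (log ratio) | difficulty peaks at equal numerosities |
| `tau_subj` | 300 ms | reproduces the published between-subject condition SDs (~287-313 ms); truncated at +/-2.5 SD so structural RTs stay positive (effective SD ~288 ms) |
| `sigma_e` | 0.10 | 10% multiplicative trial-to-trial noise; in this regime the three-parameter decomposition below recovers a baseline shift to ~10 ms, i.e. the negation cost is identifiable from a single session |
| `err_rate` | 0.16 | the published 84% +/- 4% accuracy |
| proportions | geomspace(0.5, 2, 5) | five log-spaced ratios straddling equality symmetrically; the study's printed ratios are not public, so these are config placeholders |

What the generator does **not** emulate: sequential/practice effects,
speed-accuracy coupling, RT distributions of error trials differing from
correct ones, per-proportion accuracy differences.  Tests passing on this
generator therefore certify the *analysis machinery* (calibration,
recovery, invariances), not robustness to those real-data features.

## PSC generator (`synthdata.gen_psc`)

Per subject and phase, the four condition cells get
`psc = cell_mean + u_subj + (q/4) * (g - q'm) + e_perp`, where
`q = (+1,-1,-1,+1)` is the interaction contrast over cells
(neg-ling, pos-ling, neg-symb, pos-symb), and

    g = q'm + sigma_net * (rho * z_beh + sqrt(1-rho^2) * eps)

is the subject's BOLD NetNegInt: `z_beh` is the standardized behavioral
NetNegInt supplied by the caller, `eps ~ N(0,1)`.  Cell noise `e` (SD
`sigma_psc`) is projected orthogonal to `q`, so the measured BOLD NetNegInt
equals `g` exactly and the population correlation with behavior is `rho` by
construction (sample r converges to rho; r = 1 exactly when rho = 1).
Default cell means follow the published insular Phase I pattern (0.25 vs
0.20% for the linguistic pair, no symbolic difference).

## Behavioral inference (`behavior`)

* Default trial filter: correct responses only, no RT trimming (none is
  reported for the source study; per-subject mean + k SD trimming is
  available but off).  Whether published RT means included error trials is
  unknowable from the text; correct-only is a package decision.
* `rm_anova_2x2_log`: two-way repeated-measures ANOVA on per-subject cell
  means of natural-log RT (`pingouin.rm_anova` engine).  F and p are
  invariant to the log base.  For a 2 x 2 within design the interaction F
  equals the squared paired t on the per-subject difference of differences;
  the acceptance suite verifies this identity to 1e-10 relative on random
  data.  A contrast that is identically zero across subjects yields a 0/0 F
  ratio, reported as F = 0, p = 1.
* The per-subject NetNegInt vector is computed on raw milliseconds (the
  scale of the brain-behavior correlation axis), while the ANOVA uses log
  RT; both conventions are deliberate and coexist.
* `paired_t` handles the zero-variance case explicitly: identical vectors
  give t = 0, p = 1; constant nonzero differences give infinite t, p = 0,
  flagged degenerate.

## Weber fits and the negation decomposition (`psychometrics`)

Both fits use the fixed-center Gaussian
`b + A exp(-(u - c)^2 / (2 w^2))` with exactly three free parameters
(baseline, amplitude, width); the center is pinned to the compressed
coordinate of the hardest (closest-to-equal) proportion, configurable.

* **Weber comparison** (`fit_weber`): the five per-proportion mean RTs are
  fitted on a linear and on a log-compressed proportion axis; Weber's law
  predicts the log axis fits better (higher R^2).
* **Decomposition** (`fit_gaussian_3param`): the same model fitted to the
  RTs of one condition, collapsed by default to the across-participant mean
  per proportion (each subject's per-proportion mean enters with equal
  weight).  Equal subject weighting matters once error trials are excluded:
  with unequal surviving cell counts, trial-pooled means let between-subject
  offsets (hundreds of ms) leak into the five-point curve shape and
  destabilize the width estimate; participant means remove that channel.
  `collapse='trials'` restores count-weighted trial pooling, which minimizes
  the trial-level SSE and coincides with the default for balanced data.  The
  baseline absorbs proportion-independent costs; for the less vs more
  contrast, the baseline difference is the negation cost stripped of
  numerosity tuning.

Numerics: the fit is solved by variable projection — for fixed width, the
baseline/amplitude subproblem is linear (closed form); the width is found by
a deterministic 40-point log-spaced grid over `[0.02, 0.5] * span` of the
compressed axis followed by bounded Brent refinement (xatol 1e-10).  The
upper width bound is part of the estimator definition: beyond roughly half
the sampled span the Gaussian no longer decays to its floor inside the
design, baseline and amplitude become collinear, and the "baseline"
degenerates into an unbounded extrapolation.  Degenerate inputs (constant
means) return amplitude 0 and NaN R^2, flagged.  Noise-free generator data
are recovered to ~1e-9 relative.

* **Permutation test** (`permutation_baseline_test`): the null flips the
  more/less labels of whole subjects (2^S states), respecting the paired
  design; p = (1 + #{|null| >= |obs|}) / (1 + n_perm), two-sided with
  add-one correction, so p is valid and never zero.  When `n_perm` reaches
  the number of distinct flips the test switches to exhaustive enumeration
  (exact p, identity included).  Whether the original analysis permuted
  subjects or trials is not stated in the available text; subject-level
  flips are the default and trial-level shuffling is available via
  `unit="trial"`.

## ROI statistics (`roi`)

* Coordinates: 0-based voxel indices; the affine maps indices to mm at
  voxel centers (MNI-style); all reported coordinates are mm.
* `overlap_fractions` resamples both binary masks to a common isotropic
  grid (default 1 mm) with nearest-neighbour interpolation
  (`nilearn.image.resample_img`) — label-preserving, no blurring of mask
  boundaries — then reports shared voxels as percent of the anatomical and
  of the functional volume.
* `peak_probability` rounds the inverse-affine voxel coordinate per axis
  with round-half-away-from-zero; the tie-break matters only for
  coordinates exactly on voxel boundaries and is documented here.
* The brain-behavior correlation is one-tailed by default (the directional
  hypothesis is higher BOLD NetNegInt with higher behavioral NetNegInt);
  every other test in the package is two-sided.
* White-matter exclusion of residual functional voxels is representable by
  passing an explicit exclusion mask; no tissue classifier is included.

## Observer-independent border detection (`cytoarch`)

* **Profiles**: equidistant straight traverses join corresponding
  arc-length fractions of the outer (layer I/II) and inner (layer
  VI/white-matter) contour; each is resampled to 100 points (relative
  cortical depth 0-100%), removing cortical-thickness confounds.  Curved
  field-line tracing is a possible extension; straight traverses are exact
  and testable on phantoms.
* **Features**: 10 values per profile — mean amplitude, centroid depth, SD,
  skewness, kurtosis of the GLI profile and of its absolute first
  derivative (central differences).  Features are z-scored across the ROI
  (idempotent; zero-variance columns left at 0).  The exact feature set of
  the original methodology is not published in the available text; this
  canonical moment set is a declared, configurable decision.
* **Distance**: at position x, Mahalanobis D^2 between the mean feature
  vectors of blocks [x-b, x) and [x, x+b) under the pooled within-block
  covariance; significance by Hotelling's T^2 = (b/2) D^2 with
  F = (n-p-1)/(p(n-2)) T^2, df (p, n-p-1), n = 2b.  Near-singular
  covariances (small blocks, 10 features) fall back to a ridge-regularized
  solve (eps = 1e-6 * mean diagonal), flagged in the output.
* **Acceptance rule**: blocksizes 8-24 in steps of 2.  Per blocksize,
  candidate borders are local D^2 maxima significant at alpha = 0.05 with
  Bonferroni correction across positions; maxima closer than one blocksize
  are merged into the strongest, since a single laminar transition elevates
  D^2 over a plateau about one blocksize wide (this also sets the method's
  resolution: two true borders closer than the blocksize merge).  A
  position recurring within +/-2 traverses in a majority of blocksizes is
  accepted; the reported position is the median of its supporters.
  Per-position (uncorrected) significance is available via
  `correction="none"`, but on homogeneous noise ribbons it accepts spurious
  borders far above the nominal rate because a noise outlier in the feature
  sequence persists across blocksizes (the blocksizes share data) — the
  Bonferroni default keeps the false-call rate at the few-percent level,
  which the acceptance suite measures.  Whether acceptance should require
  *consecutive* blocksizes is left open in the source methodology; the rule
  here counts distinct blocksizes regardless of adjacency.
* **Volumes**: Cavalieri estimate — sum(section areas) x section thickness
  x sampling interval x shrinkage factor.  Probability maps are voxelwise
  overlap fractions over aligned per-brain masks and satisfy the
  conservation identity sum(map) * voxel volume = mean individual volume
  exactly.

## Histology phantoms (`synthdata.gen_histology_phantom`)

A straight cortical ribbon (default 80 traverses x 120 depth pixels at
20 um) whose columns follow smooth laminar GLI templates; areas switch
template at known traverse indices.  The default template pair contrasts a
conspicuous layer-IV band with a dysgranular pattern (attenuated layer IV,
denser deep layers), mimicking the kind of laminar change that separates a
dysgranular insular area from its neighbours; `default_templates(sep)`
scales the contrast for monotonicity studies.  Pixel noise is Gaussian
(SD 0.05, a few percent of the GLI dynamic range), clipped to [0, 1].
The phantom has no curvature, no blood vessels, no section artifacts, and
its noise is white — border-recovery results on it certify the algorithm,
not performance on real sections.

## Problem sizes

Simulation-based checks use 100-500 replicates (500 x 199 permutations for
test calibration, 100 phantom realizations per border-rate estimate, 200
datasets for fit comparisons); these sizes put Monte-Carlo error comfortably
inside the asserted margins while keeping the default suite fast.

## Known limitations

* The permutation test's trial-level variant is O(n_perm x n_trials) and
  far slower than the vectorized subject-level variant.
* `extract_profiles` assumes both contours are ordered in the same
  direction; reversed contours produce crossing traverses and are not
  auto-detected.
* The 2 x 2 ANOVA engine is specialized to the balanced within-subject
  design; unbalanced cell counts are averaged within subject first.
* Real GLI computation from stained micrographs (cell segmentation), 3-D
  reconstruction and spatial normalization of histology are out of scope.
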