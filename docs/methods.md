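# Methods

## Problem setting

`ihcflow` implements the computational side of quantitative, multiplexed
immunohistochemistry (IHC): given micrographs of DAB-stained,
hematoxylin-counterstained tissue or cell-block fields, it quantifies
per-biomarker expression; given paired ordinal clinical scores from two
scoring routes over the same cases, it measures their agreement; and it
models why flowing antibody through a microchannel over the tissue
outperforms static incubation. Because no public image or score data
accompany this setting, a synthetic-data module generates both inputs
with exact ground truth, and every claim the test suite makes is a claim
about recovery of that truth.

## Color segmentation

A pixel belongs to one of three classes: SP (staining part — brown DAB
product), NSP (non-staining cell part — blue counterstain) or BG
(background). Each class's RGB distribution is a Gaussian mixture

    f(x; λ) = Σ_j p_j N(x; μ_j, Σ_j),  Σ_j p_j = 1,

with component counts 5 (SP), 10 (NSP), 2 (BG): stained tissue and
counterstained cells are strongly multi-modal in color, background is
not. Parameters are estimated by expectation-maximization:

* initialization by k-means on the training pixels with the caller's
  seed (reproducible, standard);
* every M-step adds εI to each covariance with ε = 1e-3 on the 0–255
  scale, preventing singular fits on quantized colors;
* convergence when the relative log-likelihood improvement falls below
  1e-6 (default), capped at 500 iterations; the trace is recorded and is
  non-decreasing, which the tests assert on random fixtures.

Classification is Bayes' rule over the three class mixtures. Class
priors default to uniform and are configurable; they are stored in the
persisted model JSON so a report always records what was used. All
densities are computed in log space — with 3×3 covariances on byte data,
linear-space likelihoods underflow. Ties in the posterior break by the
fixed order SP > NSP > BG, a deterministic choice that biases toward
detecting staining.

## Expression level

For a segmented field,

    staining ratio   = |SP| / (|SP| + |NSP|)          (BG excluded)
    staining intensity = mean over SP of a signal in [0, 1]
    expression level = ratio × intensity.

"Intensity" of a brown precipitate has no canonical pixel definition, so
the signal is selectable and recorded in output metadata:

* `darkness` (default): 1 − luminance/255, luminance = mean(R, G, B).
  Parameter-free and monotone in stain darkness.
* `dab_od`: the DAB channel of standard color-deconvolution
  (optical-density projection on the DAB stain vector, via
  `skimage.color.rgb2hed`), clipped to [0, 1].

Fields with no cell pixels are rejected rather than zero-scored, so
empty fields cannot dilute a channel mean. A channel is summarized as
the unweighted mean over ≥ 5 fields (configurable); per-field values are
retained. Cross-method comparisons first divide each biomarker column by
its mean (column means become exactly 1), removing per-biomarker scale
before variance comparisons.

## Clinical score translation

All biomarkers are mapped onto NEG(−) < WEAK(+) < INTERMEDIATE(++) <
STRONG(+++), codes 0–3: Allred 0 → NEG, 2–3 → WEAK, 4–6 → INTERMEDIATE,
7–8 → STRONG (a composite of 1 cannot occur and is rejected rather than
guessed); HER2 0/1+/2+/3+ maps one-to-one; Ki-67 percent-positive uses
right-closed bins at 5, 20 and 40%. Positive-cell percentages can be
derived from a mask by 8-connected component counting with a 30 px
minimum size (both configurable); border-touching components count.

## Agreement statistics

Two scoring methods are treated as m = 2 raters of the same n cases.

* Kendall's W on mid-ranked ordinal codes with the standard tie
  correction, W = 12S / (m²(n³−n) − mΣT). This reproduces the
  attribute-agreement identity χ² = m(n−1)W on n−1 degrees of freedom:
  for n = 105 and W ∈ {0.96, 0.90, 0.95, 0.98} the statistic is
  {199.68, 187.2, 197.6, 203.84}, rounding to {200, 187, 198, 204}.
* Cohen's κ unweighted (no linear/quadratic weights) with the
  large-sample normal p-value, and Fleiss' κ for m ≥ 2; both via
  `statsmodels`, cross-checked in tests against the defining formulas.
* Percent concordance with an exact binomial (Clopper–Pearson) 95% CI.
  The exact method is a deliberate choice where the CI convention is
  ambiguous; for 103/105 it gives 93.3–99.8, whose upper bound can
  differ from other conventions' by ~0.4 points.
* Pearson r, the classic Levene test (absolute deviations from group
  *means*, not medians) and the pooled two-sample t test (Welch
  optional) for quantitative expression comparisons.
* p-values print to 4 decimals, below 1e-4 as "<0.0001".

Reproducibility over repeated slides of one tumor uses the same W with
slides as raters. The slide-to-channel assignment comes from a Latin
square of order 4 so each biomarker visits each channel position once;
two constructions are provided — strict cyclic rotation, and the
pairwise-swap square (ER,HER2,PR,Ki-67 / HER2,ER,Ki-67,PR /
PR,Ki-67,ER,HER2 / Ki-67,PR,HER2,ER) used in practice for 4-biomarker
slides. They are different valid Latin squares; both are validated
definitionally.

## Synthetic data: what it emulates and what it does not

Images: cells are possibly-overlapping disks with uniform radii in
[5, 9] px on a 96×96 field of 40 cells (defaults); a rounded
`fraction_stained` share is stained. SP disks are drawn last so overlaps
resolve deterministically and the stored label mask is exact. Each
region's colors are sampled from its mixture — defaults centered on DAB
brown (means ≈ (140,90,60)/(110,70,45)), hematoxylin blue
(≈ (120,120,180)/(90,95,150)) and near-white background — then
perturbed by i.i.d. Gaussian noise (σ = 4) and clipped to [0, 255].
Recorded truth: the staining ratio computed from the label mask, and the
mean darkness over true-SP pixels of the rendered image.

These fields have well-separated class colors, no shading or glare, no
out-of-focus blur, no touching-but-distinct nuclei, and no
intermediate-hue pixels at stain boundaries. Passing recovery tests
therefore demonstrates correctness of the estimator chain, not
performance on real histology, where class overlap in color space is the
dominant error source.

Ratings: method A draws from configurable category marginals (default
(0.4, 0.3, 0.2, 0.1) over 105 cases); method B copies A with probability
`agreement` (default 0.9) and otherwise redraws from a row-stochastic
confusion kernel (default: independent redraw from the marginals, which
drives κ toward 0 as agreement → 0).

## Binding kinetics in the microchannel

Model: 2-D longitudinal channel section (length 5 mm × height 50 µm),
advection–diffusion of antibody concentration C(x, y, t) with a
parabolic (or plug) velocity profile, and reversible Langmuir binding on
the tissue wall (y = 0):

    dB/dt = k_on C_wall (R_T − B) − k_off B,

the wall flux of C balancing dB/dt. The 2-D section captures the
depletion-layer mechanism — static incubation exhausts the solution near
the tissue; flow replenishes it — without 3-D cost. Defaults are
IgG-scale: D = 4e-11 m²/s, k_on = 1e3 m³ mol⁻¹ s⁻¹ (1e6 M⁻¹s⁻¹),
k_off = 1e-4 s⁻¹, R_T = 1e-8 mol/m², C₀ = 1e-5 mol/m³ (≈1.5 µg/ml).
With these, binding is strongly transport-limited (k_on R_T / (D/H) ≈
12), the regime where flow enhancement appears; and a sealed channel
holds only C₀H ≈ 0.05 R_T of antibody per unit area, so static
incubation is additionally supply-limited.

Discretization: conservative finite volumes, first-order upwind
advection, explicit Euler in time. The step obeys the combined
advection–diffusion bound 1/Δt ≥ u_max/Δx + 2D(1/Δx² + 1/Δy²) plus two
reaction bounds (a wall cell cannot be over-drained in one step; the
Langmuir update stays in [0, R_T] without clipping); a user-supplied
unstable Δt is rejected with the largest admissible value. Because
every update is a face flux that is added to one cell and subtracted
from its neighbor, global mass (dissolved + bound + accumulated outflux
− influx) closes to machine precision, and the tests assert < 0.5%.
Open inlet/outlet are purely advective (Dirichlet C₀ at the inlet,
upwind outflow); a zero mean velocity seals both ends, modeling a
static incubation chamber. Default grid 48 × 16; with default physics
this gives Δt ≈ 0.05–0.1 s, so an 80 s transient costs ~1500 steps.

Two time horizons are used deliberately. The transient comparisons
(mass balance, bound density non-decreasing in velocity) are evaluated
at t = 80 s, where the depletion layer is developed but far from
equilibrium. The dilution-equivalence question — can a 10× diluted
antibody under flow match the undiluted static control? — is evaluated
at t = 1800 s, a full 30-minute primary-antibody incubation: at 80 s the
diluted flowing case is still reaction-limited (bound ≈ 0.47× static)
and no velocity can close the gap, whereas over a full incubation the
sealed control saturates its limited supply and a slow flow of
v = 3e-5 m/s yields a flow/static ratio of ≈ 1.15. The Reynolds number
helper uses the rectangular-duct hydraulic diameter D_h = 2wh/(w+h)
with the channel width (800 µm default) as the third dimension.

## Problem sizes and numerical choices

Test and acceptance runs use 96×96 or 80×80 px fields, 2 500 training
pixels per class, EM capped at 150 iterations for the 5/10/2 model, a
5-fraction × 20-seed recovery grid, 100 random EM fixtures, and the
48 × 16 transport grid — sizes at which the full suite runs in well
under a minute while every statistic is computed, not stored. All
randomness flows through `numpy.random.default_rng` seeded per call; no
global RNG state is touched, and identical seeds give bit-identical
images, samples and model files.

## Known limitations

* The segmentation carries no spatial prior: labels are per-pixel, so
  real images with color overlap would produce salt-and-pepper masks
  (morphological cleanup is out of scope here).
* Component counts are fixed at 5/10/2; there is no model selection
  over C.
* The generator's truth intensity is defined on the rendered image's
  true-SP pixels, so intensity recovery measures segmentation fidelity,
  not illumination correction.
* The transport model is 2-D and rigid-walled; channel deformation,
  3-D corner effects and the spatial heterogeneity of real tissue
  receptors are not modeled, and rate constants are literature-scale
  defaults, not fitted values — conclusions drawn from it are
  qualitative (orderings, ratios), not calibrated curves.
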