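# Methods

## Scientific background

A bronchial epithelium transports its protective mucus layer by the
coordinated beating of cilia.  Three measurable quantities summarise this
machinery on a cultured epithelium imaged by high-speed video microscopy:

* the **active ciliated cell density** ν — the fraction of the surface
  covered by beating cilia;
* the **ciliary beat frequency** (CBF) — the dominant temporal frequency
  of each beating pixel;
* the **beat direction** of each ciliary tuft.

On epithelial domains where the beat directions show circular
orientational order ("swirls"), the surface fluid rotates like a rigid
body: tracer beads move on concentric circles with a common angular
velocity ω, so the curvilinear speed grows linearly with radius.
Decomposing a swirl into concentric annuli gives the radial profiles
ν_r and ⟨sin α⟩_r, where α is the angle between a tuft's beat direction
and the outward radius; their product is the dimensionless **force
proxy**, proportional to the propulsive force per unit area.

## Force-balance model

The package implements the phenomenological balance between ciliary
propulsion and the viscous friction of the sheared periciliary layer
(PCL).  The propulsive stress on an annulus is

    sigma_p = (phi * n_c * f_c / A_cc) * nu_r * <sin alpha>_r,

and the resistive stress is

    tau = (1 - phi * nu_r) * eta_pc * (V_SF + V_R) / e
        ~ eta_pc * (V_SF + V_R) / e          (phi * nu_r << 1),

so the steady surface-fluid velocity is affine in the force proxy:

    V_SF = (e / eta_pc) * (phi * n_c * f_c / A_cc) * proxy - V_R.

Parameters (SI units), with the defaults shipped in `ModelParams`:

| symbol  | meaning                                | default   |
|---------|----------------------------------------|-----------|
| phi     | time fraction of the propulsive stroke | 0.1       |
| n_c     | cilia per ciliated cell                | 160       |
| f_c     | force of one cilium on the mucus       | 1 pN      |
| A_cc    | ciliated-cell area                     | 8e-11 m^2 |
| eta_pc  | PCL viscosity                          | 5e-3 Pa s |
| e       | sheared-layer thickness                | 1e-6 m    |
| V_R     | recovery-stroke tip speed              | required  |

These defaults give a velocity/force slope of 4e-5 m/s (40 um/s).  V_R
has no canonical literature value; it must be supplied (it is the
negative intercept of the velocity–force relation, and the origin of the
minimal force needed to start a flow, proxy > V_R * eta_pc / e / sigma_p(1)).

## Estimators

**Activity density.**  Pixels are classified active when the temporal
standard deviation of their mean-removed intensity exceeds `k` (default
3) times a robust noise scale.  The noise scale is the median across
pixels of the RMS spectral amplitude above 0.7× Nyquist — a band that
contains no ciliary power, so the estimate is unbiased by the active
fraction itself and remains correct on a fully active field (a
projection-percentile estimate would fail beyond ~50% coverage).  ν is
therefore invariant under affine intensity rescaling.  Otsu thresholding
of the projection is available as an alternative.

**CBF.**  Per-pixel periodogram of the mean-removed series (population
convention for all standard deviations, ddof = 0); the CBF is the
frequency of the maximal power inside the analysis band (default
3–30 Hz).  A peak is valid only if it exceeds 5× the median in-band
power.  No window and no sub-bin interpolation by default — a 3 s record
at 250 fps has 1/3 Hz bins, sufficient at the precision of interest; a
Hann window and parabolic peak interpolation are optional flags.

**Orientation.**  Structure tensor with Gaussian-derivative gradients
(`sigma_grad` = 1 px) and Gaussian window (`sigma_window` = 4 px, tufts
span ~5–20 px at the targeted magnification).  The reported angle is the
*texture axis* (eigenvector of the smaller eigenvalue, the perpendicular
of the dominant gradient axis): elongated trails in a std-projection run
along the beat axis.  Angles are radians from +x, counterclockwise
positive, in image coordinates (y down); an axis lives in [0, π).
Per-tuft axes are coherency-weighted circular means on the doubled
angle over each connected mask region (pixels with coherency < 0.2
excluded), followed by one 20%-trimming pass that discards the pixels
deviating most from the preliminary axis — this suppresses window
leakage from neighbouring tufts.  The ±π direction sign is taken from
phase correlation between first and last frames along the axis; when the
displacement is below 0.2 px the record is flagged ambiguous and the bare
axis is reported (sin α needs only the axis).

**Transport.**  Nearest-neighbour frame-to-frame linking with a
displacement gate (deliberately minimal — externally tracked CSVs are a
first-class input).  Circle fits are algebraic (Kåsa) least squares;
the angular velocity is the OLS slope of the unwrapped polar angle
versus time, a direct test of constancy.  The rigid-body test demands
≥ 3 circular fits with a common centre and reports the coefficient of
variation of ω across radii (pass below 0.1).  Trajectory classes:
immobile below 2 μm net displacement, circular when rms residual/radius
< 0.15 and swept angle > π/2, else linear.

**Swirl profiles.**  Annuli of width `dr` (default 20 μm) about a given
centre (from bead fits; `estimate_swirl_center` offers an automated
fallback maximising mean sin α).  ν_r is summed tuft area over annulus
area — the outermost annulus is truncated at `r_max` so its area matches
the sampled region; ⟨sin α⟩_r is the tuft-wise mean (sign-blind, so
ambiguous axes contribute).  Annuli with fewer than 5 tufts are treated
as missing.  All fits are unweighted OLS, matching the affine/linear
relations under study.  The swirl-size scaling R ∝ ν^m is fitted by OLS
in log10–log10 space; when several swirls share a chamber only the
largest enters, since the quantity of interest is the maximal transport
distance a given density sustains.

## Synthetic data

The generators reproduce the statistical structure the analysis assumes,
not cilium mechanics:

* **Videos** — hard-edged elliptical tufts (elongation 3 along the local
  beat axis, whole tufts kept inside the field) whose intensity
  oscillates sinusoidally at a per-tuft frequency, with a low-contrast
  (0.15) stripe texture across the axis so the structure tensor has
  interior signal, over a static background with i.i.d. Gaussian noise.
  Hard edges make the ground-truth mask identical to the rendered
  support, so density recovery is well-posed; intensity modulation
  (rather than subpixel motion) is the default because it is exactly
  what the spectral CBF estimator measures (a displacement mode exists).
  An `avoid_overlap` option enforces clearance between tufts for
  orientation benchmarks, where a partially overwritten tuft would have
  no well-defined axis.
* **Swirl tufts** — radii drawn from an affine areal-density profile
  a + b·r; beat directions scatter around the local tangent with a
  wrapped-normal dispersion of concentration κ(r) (σ = 1/√κ; κ = 0 is
  uniform, giving ⟨sin α⟩ = 2/π).  The wrapped normal was chosen for its
  single concentration parameter and easy brute-force moments.
* **Beads** — rigid or differential rotation (ω constant or ω(r)),
  translation, or immobile, plus isotropic Gaussian positional noise.
  `generate_model_consistent_swirl` couples the two: beads are advected
  with V(r) = slope·proxy(r) − V_R so the full pipeline can be tested
  for parameter recovery.
* **Scaling pairs** — log-uniform ν with R = C·ν^m·10^ε,
  ε ~ N(0, σ_log).

What the generators do *not* emulate: metachronal phase gradients,
mucus rheology, uneven illumination, photobleaching, or detection/
tracking failures of real bead movies.  Passing tests therefore
demonstrate the correctness of the estimators under their stated
assumptions, not robustness to every artefact of real recordings.

## Study sizes and numerical choices

Validation scenarios (tests and `scripts/acceptance.py`) use 128×128
videos at 250 fps for 3 s (750 frames); swirls of radius 300 μm with
10⁴ tufts for profile recovery; and 10⁵ tufts with 300 beads for the
force–velocity regression, where the recovery-stroke speed is an
extrapolated intercept and needs roughly an order of magnitude more
data than the slope.  The end-to-end construction keeps the force proxy
above the flow onset V_R/slope everywhere, because annuli below onset
carry no flow and contribute no information about the affine relation.

Degenerate inputs raise explicit errors: collinear points in circle
fits, dispersed centres in the rigid-body test, empty masks in CBF
summaries, single-frame stacks, out-of-band analysis ranges.  Ties and
floors: coherency is defined as 0 where the tensor trace vanishes;
activity thresholds are strict (a noiseless static video yields ν = 0);
steady velocities are floored at 0 with a below-onset flag.

## Known limitations

* The ±π beat-direction disambiguation relies on net image motion; for
  purely oscillatory synthetic tufts it (correctly) reports ambiguity,
  so signed-direction analyses are untested against ground truth.
* Nearest-neighbour linking has no gap closing and will fragment tracks
  at high bead density or with missed detections.
* ν_r is unbiased only if the annulus is fully inside the imaged region;
  no partial-field correction is applied beyond the r_max truncation.
* The noise-referenced activity threshold assumes temporally white
  sensor noise; strongly correlated noise would inflate ν.
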