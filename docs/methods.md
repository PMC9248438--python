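# Methods

`hypoximap` implements a quantitative-MRI-to-histology analysis for
tumor hypoxia: voxelwise IVIM and R2* parameter estimation, grid-wise
HIF-1α immunohistochemistry scoring, co-registered 1 mm² ROI analysis,
and rank-based group statistics — exercised end to end on a digital
rat-glioma phantom so that every stage is testable without animal data.

## Signal models

**IVIM.** Diffusion-weighted magnitude signal follows the two-
compartment pseudo-diffusion model

    S(b)/S(0) = (1 − f)·exp(−b·D) + f·exp(−b·D*),  D* ≥ D, f ∈ [0, 1],

with b in s/mm², the tissue diffusion coefficient D and the pseudo-
diffusion coefficient D* in mm²/s, and the perfusion fraction f.
Perfusion is the product f·D*.  The acquisition uses the 11-point
b-value schedule (0–2000 s/mm²) of the emulated protocol.

**R2\*.** Multi-echo gradient-echo magnitude decays mono-exponentially,
S(TE) = S0·exp(−TE·R2*), with R2* = 1/T2* in Hz and 16 echoes between
3.4 and 92.1 ms.

## Estimators

### Segmented IVIM fit (default)

Step 1 regresses ln S on b over the high-b subset (b > 200 s/mm²,
exclusive) for D and an intercept; step 2 sets f = 1 − intercept
(signals are normalized by the measured b = 0 image, not a fitted S0);
step 3 solves a bounded 1-D least-squares problem for D* on the full
curve (coarse-to-fine log-grid with parabolic polish, relative
resolution ≈ 3×10⁻⁴).  Because a pseudo-diffusion coefficient of
~2.9×10⁻³ mm²/s still contributes ~40% of its amplitude at
b = 300 s/mm², the plain segmented estimate is structurally biased;
the three steps are therefore iterated with the current perfusion
component subtracted from the high-b signals before the log-linear
step.  The generating parameters are a fixed point of this iteration
and on noiseless curves it converges to them (lin­ear rate ≈ 0.88 per
sweep; the default cap of 80 sweeps reaches ≈ 10⁻⁵ relative error).
The iteration is deterministic, fully vectorized over voxels, and
voxels whose corrected high-b signals become non-positive are flagged
and excluded, never imputed.

### Full IVIM fit

Per-voxel bounded nonlinear least squares over (S0, D, D* − D, f),
initialized from the segmented result, with bounds D ∈ [10⁻⁶,
4×10⁻³] mm²/s, D* ≤ 0.1 mm²/s, f ∈ [0, 1]; the D* − D
parameterization keeps the D* ≥ D constraint exact.  If the solver
does not reach the segmented residual the voxel falls back to the
segmented parameters and is flagged.  On noiseless curves the full
fit recovers the generating parameters to machine precision.

**Identifiability.** At the study's parameter scale (D* only ~7× D,
f ≈ 0.5) the two exponentials are weakly separable: the Cramér–Rao
floor at SNR 50 over the 11-b schedule is ≈ 31% median relative error
for D, ≈ 21% for f and ≈ 20% for D* — the estimators sit at that
floor.  This mirrors the instability of D and f reported for this
type of acquisition; R2* and the rank structure of D* remain the
informative quantities.

### R2* fit

Weighted log-linear regression of ln S on TE with weights ∝ S² (the
first-order variance weighting, equivalent to the linearization of
unweighted signal-domain least squares), refined by a bounded 1-D
nonlinear solve in which S0 is profiled out in closed form; the
refinement is kept only where it lowers the residual, so noiseless
data reproduce the (exact) log-linear estimate bit for bit.  Echoes
below twice the background noise sigma — estimated from the Rayleigh
mean of the four air corners — are dropped per voxel as a Rician-bias
guard; voxels with fewer than three usable echoes, or pinned at the
0.1 Hz lower bound, are flagged.  Under noise the log-linear and
nonlinear estimates differ at the few-percent level near the noise
floor (they are linearizations of each other, not the same
estimator); the refined estimate is the headline value.

## Digital phantom

The phantom emulates a rat head on the protocol grid (96×96 in-plane,
0.267 mm pixels, 1 mm slices; 12 slices so that a ~458 mm³ tumor fits
with margin).  The brain is an ellipsoid (9.5×7.4×6.0 mm semi-axes);
the tumor is a sphere offset into the basal ganglia whose surface is
modulated by a seeded smooth field (±4%, clipped at 2 SD) and whose
voxel count is chosen to match the requested volume exactly.  A
necrotic core (6% of tumor voxels, innermost), scattered vessels (4%)
and calcifications (1%) provide the composition structure the ROI
filters act on.

Per-voxel parameters are tissue-wise Gaussian fields with the study's
group means and SDs.  The HIF-1α density (0–300) is a gamma-quantile
transform of a latent Gaussian that shares the R2* latent with weight
+0.43 and the D* latent with weight −0.30: the transform is monotone,
so the latent correlations become population rank correlations of the
configured sign; the gamma marginal keeps the strongly skewed,
non-negative HIF distribution and reproduces the group means without
the truncation bias a clipped Gaussian would introduce.  Within the
tumor, HIF rises and D* and f fall linearly toward the core (relative
slopes +1.05, −0.21 and −0.13 in normalized radius, each volume-mean
one); the D*/f slopes are calibrated so the central-vs-peripheral
contrast matches the reported spatial distribution, and the HIF slope
so that the ROI-level core-rim contrast does.  Latent fields are
smoothed with a 0.6 mm Gaussian kernel (normalized by the interior
kernel norm so tissue variances stay calibrated), which reproduces
the mm-scale spatial coherence of real parameter maps; this is what
lets ROI-mean correlations survive averaging, and it also makes
per-animal regional means wobble by a few percent — realistic
inter-animal variability that pooling over the cohort averages out.

MR series are synthesized noiselessly from the closed-form models and
degraded with Rician noise, sqrt((S+g₁)² + g₂²), at sigma = 1% of the
normal-brain S0 by default (a NEX-2 7 T protocol scale).  The IHC
cell table is a Poisson point process (1000 cells/mm²) over the
tissue of the analysis slice; each cell's intensity category 0–3 is
drawn so that the expected ROI score (percent positive × mean
positive intensity) equals the local HIF density: with s = h/300,
cells are positive with probability min(3s, 1) and positive cells mix
adjacent grades to mean max(3s, 1).

All randomness derives from one master seed through named
per-stage substreams, so every artefact is a pure function of
(config, seed).

## ROI analysis

The slice with the largest tumor cross-section is tessellated into
half-open 1 mm² squares anchored at the image origin; cells crossing
the field-of-view edge are dropped and voxels belong to the square
containing their center.  A ROI is included when it contains no
background (air), its tissue is exclusively tumor (intratumoral
vessel/necrosis/calcification count as tumor tissue) or exclusively
normal, and the vessel + necrosis + calcification fraction is below
25%; exclusion reasons are assigned in the fixed order air → mixed →
composition, and ROIs left with no converged voxels or no cells are
re-excluded as empty.  Included tumor ROIs are peripheral when their
center lies strictly within 1 mm of the nearest tumor-boundary pixel
center (4-connectivity boundary), else central; a score of exactly
150 on the 0–300 HIF scale is classed low so the >150/<150 rule
partitions.  Histology shares the MR frame by default; an optional
rigid transform (rotation + translation) maps cell coordinates before
binning.  Normal-tissue ROIs enter the statistics only if they mirror
an included tumor ROI across the mid-sagittal plane (matched
contralateral design, the comparison tissue of the emulated study);
`normal_roi_policy="all"` disables this.

## Statistics

Group comparisons use the Mann–Whitney U test (U = #{x>y} + ½ ties,
mid-ranks).  The two-sided p-value is computed by exhaustive
enumeration of all C(n₁+n₂, n₁) group assignments when that count is
≤ 2×10⁵, else by the tie-corrected normal approximation with
continuity correction.  Correlations report Spearman (headline) and
Pearson side by side, with p from the t approximation, plus an
ordinary least-squares line (slope, intercept, R²).  No multiple-
testing correction drives the significance flags (α = 0.05,
uncorrected, as in the emulated design); a Holm-adjusted column is
emitted for information.  Tables report mean ± SD in display units
(D, D*, perfusion ×10⁻⁶ mm²/s; f in %; R2* in Hz; HIF score raw).

## Default study and problem sizes

The default synthetic study pools 6 phantom animals (tumor volumes
drawn N(458, 46.5²) mm³, clipped at ±2 SD), which yields ≈ 250 tumor
and ≈ 160 matched-normal ROIs — the ~480-ROI pooled scale of the
emulated design; the pipeline fits only the analysis slice of each
animal, so a full study runs in well under a minute on one CPU.  The
null-calibration battery (type-I sanity) uses a reduced 48×48×8
phantom with a ~57 mm³ tumor, two animals per replicate, identical
tissue marginals, zero couplings and gradients, and spatially
independent latent fields, so ROI values are exchangeable and the
nominal test level is well defined.

## What the phantom does and does not show

Passing tests demonstrate that the estimators recover generating
parameters at their information limits, that the grid rules implement
the stated inclusion/region logic exactly, and that the statistical
layer is calibrated and reproduces the directional structure
(tumor > normal HIF, core > rim, Spearman(R2*, HIF) > 0,
Spearman(D*, HIF) < 0) when those structures are generated.  The
phantom does not model partial-volume point spread, susceptibility
geometry, histology sectioning distortion, temporal hypoxia dynamics,
or animal-level random effects (ROIs are pooled across animals, as in
the emulated analysis); conclusions about real tissue require real
data through the same interfaces.

## Numerical choices

Grid searches operate in log-parameter space with parabolic
refinement; bounds are generous physiological envelopes (D* ≤ 0.1
mm²/s, R2* ∈ [0.1, 2000] Hz); degenerate inputs (constant series,
empty ROIs, all-tied samples) are flagged or rejected rather than
silently filled; CSV artefacts are written at 17 significant digits
and read back with round-trip float parsing so that resumed and fresh
runs are bit-identical.
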