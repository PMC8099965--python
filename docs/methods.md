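# Methods

`hybridose` implements three image-based absorbed-dose estimation chains for
[¹⁷⁷Lu]Lu-PSMA radioligand therapy and the statistics to compare them, and it
ships a digital-phantom simulator that generates the serial planar and
SPECT/CT acquisitions the chains consume. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
can and cannot show.

## Source model and ground truth

A digital patient is a voxelised body slab (water-equivalent, uniform
thickness `D`, default 20 cm abdomen / 15 cm head-and-neck, voxel 4.66 mm
isotropic) containing source organs with uniform uptake and mono-exponential
effective kinetics,

    A_j(t) = A0_j · exp(−λ_eff,j · t),     λ_eff ≥ λ_phys,

on top of a diffuse background (non-specific tissue activity) present in
*every* body voxel, organ interiors included. λ_phys = ln 2 / 159.53 h for
¹⁷⁷Lu. Ground truth for recovery tests is analytic: TIA_j = A0_j/λ_eff,j and
dose through the same dose-factor table as the analysis chain, so the imaging
and integration chains are tested against a closed form, not against a second
simulation.

Organ uptake is distributed per voxel (A0 exact by construction); organ
*volumes* carry the surface-quantisation error of voxelising spheres/boxes at
4.66 mm (up to ~10% for 6–20 ml objects). Default uptake concentrations are
set to the signal-to-background regime of post-therapy PSMA imaging
(liver SBR ≈ 13, all other regions > 100); absolute uptake fractions are
package choices, not measured patient values.

## Planar acquisition and the 2D chain

Projection is parallel-beam: anterior/posterior line integrals with a single
attenuation coefficient μ = 0.11 cm⁻¹ at 208 keV. Collimator resolution is an
isotropic Gaussian (default σ = 4 mm). The scatter-window image is a fixed
fraction (0.3) of the primary broadened by a wide kernel (σ = 18 mm), and the
photopeak contains that scatter scaled by the window-width ratio
W_pk/W_sc = 41.6/28.05, so the dual-energy-window subtraction

    C_primary = C_pk − C_sc · (W_pk / W_sc)

is exact in expectation — only the correction arithmetic is exercised, not
scatter physics. Per-pixel exposure of a whole-body sweep is
(detector axial FOV)/(table speed): ≈160 s at 15 cm/min (days 1–2) and 200 s
at 12 cm/min (day 4); the per-scan vial calibration (counts/MBq, vial decay-
corrected to scan start with λ_phys) absorbs the speed difference, so no
separate dwell normalisation is applied. Poisson noise is applied to all
count grids (photopeak, scatter, vial, blank, transmission) behind one seed;
a noiseless mode exists for oracle tests.

The 2D quantification follows the conjugate-view method: translation-only
co-registration of the serial frames (count cross-correlation), DEW scatter
correction, threshold segmentation of the geometric-mean image inside a
boundary ROI (default threshold 0.40 × in-boundary maximum, configurable —
sensitivity to it is a reported diagnostic), background subtraction scaled
from a nearby background ROI, then

    A = sqrt(C_A · C_P / T̄) · f / cf,   f = (μ t_o/2) / sinh(μ t_o/2),

with T̄ the ROI-mean transmission factor from the blank/transmission pair
(per-pixel transmission available behind a flag) and t_o the organ thickness.
Organs partially hidden by overlapping high-uptake tissue are quantified on
their visible footprint and extrapolated by the visible-area fraction
(assuming homogeneous uptake); a kidney with visible fraction below 0.55
is treated as obscured and replaced by twice the contralateral kidney.
Lesions overlapping high-uptake tissue are excluded from the 2D (and hence
hybrid) analysis altogether.

On box organs in a noiseless, overlap-free phantom this chain recovers the
true activity to within 2% (slab fixtures: within 1%, limited only by depth
quantisation). On *spherical* organs the chain carries honest negative
biases of roughly 7–15%: the threshold cuts the thin-chord rim of the
projected sphere, and the slab self-attenuation factor f(t_o) undercorrects
a source whose thickness varies across its footprint. These biases are
constant over the three time points (the geometry does not change), which is
exactly the error structure hybrid rescaling removes.

## SPECT acquisition and the 3D chain

SPECT volumes are generated post-reconstruction: the true activity grid
scaled to cps, blurred with an isotropic Gaussian PSF, Poisson-resampled at
the acquisition time (1500 s). Reconstruction itself, attenuation and scatter
corrections are assumed already applied. The calibration factor (Bq/cps)
comes from a simulated 6595 ml uniform cylinder of known activity.

Partial-volume correction uses volume-dependent recovery coefficients. The
package ships the reference table (0.85 for ≥ 20 ml; 0.79, 0.67, 0.59 at
13, 10, 6 ml) with log-linear interpolation in volume, plateau above 20 ml,
and clamping with a warning below the smallest entry (extrapolating an RC
downward would overcorrect). A single Gaussian blur cannot reproduce that
table: the printed curve falls more steeply below 20 ml and stays flat up to
170 ml, whereas Gaussian sphere recovery keeps rising with volume. The
package therefore treats RC calibration the way a physics service does:
`measure_system_rc_table` derives the recovery curve *of the configured
blur* from sphere fixtures, using the same adaptive segmentation and VOI
counting as the patient pipeline, recording recovery against the *estimated*
volume (so pipeline lookups interpolate in the same volume scale), averaging
sub-voxel placements, and enforcing monotonicity by isotonic regression.
Pipelines default to this measured table (`rc_mode="measured"`); the printed
table remains the default for plain lookups and for systems whose RC curve
is known. The default PSF σ = 5.0 mm is the least-squares fit of the
measured sphere recovery to the four reference RC values (residuals up to
~0.12 remain, for the reason above).

Segmentation inside a boundary VOI is deterministic iterative adaptive
thresholding: threshold = α × mean(current foreground), iterated to a fixed
point (α = 0.5 default; the fixed point is independent of starting from the
boundary maximum or mean). It replaces the fuzzy locally adaptive Bayesian
segmentation used clinically, with the same contract (automatic delineation
within a manually drawn boundary); segmentation is pluggable. Boundary VOIs
are propagated from the first scan by translation registration, with a
manual-offset hook instead of interactive editing. Estimated volumes
overestimate small objects under blur (+27% for 20 ml at σ = 5 mm); this is
harmless to activity because the measured RC table is indexed by estimated
volume. The end-to-end 3D chain recovers analytic organ activity to within
~3% (5% asserted) across 6–1500 ml on noiseless fixtures — the property that
makes 3D the reference method in the comparison.

## Kinetics and time integration

Each region's TAC is fitted by weighted least squares to a mono-exponential
(default Poisson-like weights 1/max(A_i, ε); exact with two points; a fitted
decay slower than physical is flagged, not rejected). The TIA uses the
piecewise scheme of post-therapy protocols:

    TIA = A(t1)·t1 + Σ trapezoids over [t1, tn] + A(tn)/λ_phys.

The first interval assumes constant activity A(t1) (equivalently a trapezoid
with A(0) := A(t1)); a flag switches to a trapezoid from the fitted A0. The
tail deliberately considers only physical decay — a conservative convention
that assumes no biological clearance after the last scan. Its consequences
are quantified by the test suite: at λ_eff = λ_phys the scheme is −0.44%
versus the analytic A0/λ_eff (the constant-A(t1) start slightly
*under*estimates a decaying curve); for faster clearance the physical-decay
tail dominates and the scheme overestimates strongly (+42% at
λ_eff = 2·λ_phys). All three methods share the integrator, so this bias
cancels in method comparisons but matters for absolute doses in
fast-clearing regions. The hybrid method multiplies the planar TAC by
s = A_SPECT/A_planar(t_anchor) at the day-1 (default) or day-2 SPECT; curve
shape, and hence the fitted decay constant, is preserved exactly.
TIAC = TIA / administered activity, reported in hours.

## Dose model

Absorbed dose is D = TIA × S(m) with a pluggable dose-factor table. The
shipped default is electron local deposition: ¹⁷⁷Lu dose is β-dominated, so
S = Δ_e · 1.602·10⁻¹³ J/MeV · 3.6·10⁹ decays/(MBq·h) / m[kg] with
Δ_e = 0.1479 MeV and photon self-dose fraction 0. Reference-organ entries
(kidneys 310 g, liver 1800 g) rescale as S_ref·m_ref/m to the CT-derived
patient mass (volume × tissue density); sphere-model entries (salivary
glands, lesions) use the measured mass directly — under local deposition the
two coincide numerically, differing only in provenance. Cross-organ photon
dose is omitted (hook available). Absolute S-value fidelity to phantom
Monte-Carlo codes is *not* claimed; internal consistency is what the
recovery tests exercise, and ground truth uses the same table.

## Agreement statistics

Relative differences are 100·(x − y)/((x+y)/2) with 3D as reference y
(negative = underestimation versus 3D). Systematic differences: median
difference with a paired signed-rank test — exact null by enumeration of all
2ⁿ sign assignments (on a half-rank grid, so midranks from ties stay exact)
for n ≤ 12, normal approximation with tie and continuity correction above;
the unpaired rank-sum variant is available and the output records which test
ran. Random differences: Bland-Altman limits of agreement, mean ± 1.96·SD of
the relative differences. Pairs are pooled over cycles and patients as
independent observations, with n logged.

## The fixture cohort and what it shows

`generate_fixture_cohort` emulates the study scale: 24 patients (13
abdominal — kidneys, liver, bone lesions in the SPECT field of view; 11
head-and-neck — parotid and submandibular glands, cervical lesions), 65
cycles (1–6 per patient), administered activity N(6.4, 1.5) GBq clipped to
3–10.9. Organ volumes, uptakes and effective half-lives (kidneys 30–60 h,
liver 30–70 h, glands 18–40 h, lesions 40–120 h) vary per patient and cycle.
Planar-specific error sources, all constant within a cycle: blur spill
through the threshold mask, per-cycle segmentation threshold U(0.30, 0.50)
(manual-delineation variability), visible-fraction estimation error
N(0, 0.06) for overlapped organs, a ±15% smooth background heterogeneity
field, a gastrointestinal structure overlapping one kidney in about half of
the abdominal patients, and Poisson noise. Because these are
time-independent scale errors, hybrid rescaling removes them by
construction, and the cohort reproduces the qualitative clinical finding:
2D underestimates versus 3D (medians ≈ −10 to −35% per region class) while
hybrid stays within a few percent with systematically narrower limits of
agreement, in every region class, for every seed tested.

What the cohort does **not** emulate: real anatomy (organs are spheres and
boxes in a slab body), vendor reconstruction physics, septal penetration,
patient motion, intra-organ uptake heterogeneity, bi-exponential kinetics,
early (<24 h) time points, manual ROI drawing, and the absolute bias
magnitudes of clinical 2D dosimetry — the generator's bias amplitudes are
documented package choices. Passing cohort tests therefore demonstrates the
*mechanism* (hybrid removes time-constant planar scale errors) and the
correctness of every correction's arithmetic, not clinical effect sizes.

## Numerical choices and degenerate inputs

- RC interpolation is log-linear in volume; below-table volumes clamp with a
  warning; plateau at/above the plateau volume.
- Registration is integer-pixel translation by cross-correlation (periodic
  shift; simulated frames have empty margins); a peak at the search-window
  edge warns.
- Adaptive segmentation declares non-convergence after 100 iterations; an
  empty foreground falls back to the boundary maximum voxel.
- Zero-activity TACs integrate to TIA 0; all-zero difference sets give
  p = 1 with a warning; pairs with zero mean are excluded from relative
  differences with a warning.
- Problem sizes: phantom grids (48, 80, 64) / (40, 60, 56) voxels at 4.66 mm,
  RC fixtures 2–2400 ml, cohort 24 patients / 65 cycles; a full cohort run
  takes ~20 s on one CPU.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seeds give byte-identical studies.
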