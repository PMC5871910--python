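# Methods

## The measurement being modeled

A single-cell western blot lane is a 1-mm electrophoretic separation
axis. After lysis, each protein species electromigrates a distance set
by its molecular mass; at fixed gel density the relation is log-linear,

    x = a − b·log10(M),      b > 0,

with x in µm from the microwell edge and M in kDa. Immunoprobing and
fluorescence scanning reduce each lane × channel × probing round to a
1-D intensity profile (arbitrary fluorescence units vs position). A
protein band is modeled as a Gaussian; the per-cell abundance readout is
the band's area (AUC, AFU·µm).

The package treats the HER2 channel as carrying two bands in one trace:
full-length p185HER2 fitted in the 40–150 µm window and the truncated
t-erbB2 forms fitted in the 150–300 µm window. The windows abut, and at
the observed band widths (FWHM ≈ 94 µm centered at ≈ 99 µm) the
full-length band's tail at 150 µm is roughly 0.44 of its peak amplitude
— far above any truncated band of realistic abundance (the
truncated/full-length AUC ratio is of order 0.02–0.5). Window fits
therefore cannot be independent; how this is handled is described below.

## Synthetic cohorts

The generator emits profiles plus a truth table (per-lane loads,
centers, widths, subpopulation and cluster labels), so recovery can be
scored exactly.

- **Migration model.** The default "BT474-like" model is solved exactly
  from the two measured band centers (185 kDa → 99.3 µm,
  128.7 kDa → 188.2 µm), giving a = 1378.24 µm, b = 564.11 µm/decade on
  a 1000 µm axis.
- **Per-cell loads** are lognormal with species-specific mean and CV
  (truncated HER2: CV = 77%, matching the measured cell-to-cell
  variation; controls 40%, full-length 50%). The distribution family is
  a modeling choice (positive support, heavy right tail); it is exposed
  in the config. Planted "detectable" bands floor the drawn load so the
  band amplitude is ≥ 15 noise SDs.
- **Band centers.** Migration variation is dominantly lane-wide (the
  whole lysate rides the same local field and gel), so a per-lane common
  offset (SD 15.7 µm, clipped at ±2 SD) shifts every band together, and
  the truncated band adds √(18.1² − 15.7²) ≈ 9 µm of band-specific
  jitter so its marginal SD matches the measured 18.1 µm. Planted
  truncated centers are additionally clipped to (165, 285) µm so that
  every planted band is interior to its fit window — the presets define
  cohorts of *detectable* planted bands.
- **Intensity model.** intensity(x) = Σ bands + baseline level +
  linear drift + N(0, noise_sd) on a 1 µm grid; band amplitude is
  load/(σ√2π) so the analytic band area equals the drawn load. Preset
  noise: baseline 50 AFU, drift 0.02 AFU/µm, noise SD 30 AFU.
- **Allocation** of lanes to subpopulations/clusters is deterministic
  largest-remainder rounding (ties to lower index), then seed-shuffled,
  so planted counts are exact (29/391, 19/127, 36/90, …), not binomial.
- **Cluster structure** for marker matrices is drawn either from
  per-component log10-load Gaussians (cohort generator) or from the
  spherical Gaussian mixture helper (`simulate_marker_mixture`), whose
  component means are placed ≥ `separation` within-component SDs apart
  (default 6).
- **Determinism:** one `numpy` Generator seeded from the config; equal
  configs give byte-identical tables.

What the generator does *not* emulate: field/heating physics,
photobleaching, antibody binding kinetics, non-Gaussian band skew,
cross-channel bleed-through, or probing-round misalignment. Passing
recovery tests therefore demonstrates correctness of the analysis chain
under the stated statistical model, not robustness to every artifact of
real scans.

## Background subtraction and noise

A first line is fitted through the lowest-intensity 20% of samples
(bands occupy a minority of the lane, so the lowest quintile is
background); because fitting only low order statistics biases the line
down, the line is refitted by OLS on all samples within 3 robust SDs of
the provisional baseline. The reported noise SD is the MAD-based scale
(1.4826·MAD) of the final residuals, which is unbiased on pure-noise
lanes and insensitive to the band samples. All-flat profiles return
zeros with noise SD 0, and SNR is reported as +inf when the noise SD
is 0.

## Band fitting and quality control

Single bands are fitted by bounded nonlinear least squares (amplitude
≥ 0, center in window, σ between the grid step and the window width;
initialization: window maximum, its position, width/8).

For the HER2 trace the two bands are estimated jointly: sequential
fit-and-subtract provides the initialization, then a six-parameter
two-Gaussian refine over 40–300 µm (each center bounded to its own
window, analytic Jacobian). An extra-sum-of-squares F test against the
best single-band model decides whether the second component is
supported at all; without it, an unconstrained second Gaussian splits a
lone full-length band or chases noise. The acceptance threshold is
deliberately stringent (p < 10⁻⁶) because background subtraction leaves
weakly correlated residuals that inflate the nominal F statistic; on
the presets, genuine planted bands show F ≥ ~500 while spurious
components stay below ~10, so the threshold sits in a ~50× gap.

Metrics: AUC = A·σ·√(2π)·erf(4/√2) (area within µ ± 4σ) for general
targets; for the truncated band the fitted Gaussian is integrated over
its set window (150–300 µm) instead. R² is the coefficient of
determination of the component against the trace (with the other
component removed) inside the window; SNR = fitted amplitude / noise
SD; FWHM = 2√(2 ln 2)·σ.

Gates: general targets pass at SNR > 3 ∧ R² > 0.7 ∧ converged;
truncated-HER2 requires SNR > 10 (the guard against residual
full-length tail signal) and a center strictly interior to its window
by one grid step — a fit pinned at the 150 µm edge is a monotone tail,
not a resolved band.

**Accuracy regimes.** For resolved bands (e.g. σ ≈ 15–20 µm) centers
are recovered within ±2 µm at SNR ≥ 10. At the measured BT474 widths
the two bands overlap strongly and the truncated center becomes
overlap-limited: even a fit started at the true parameters scatters by
several µm (the Fisher information bound, not an optimizer defect).
Tests assert ±2 µm in the resolved regime and median error < 5 µm in
the overlapping cohort regime.

## Separation resolution and mass calibration

Rs = |µ₂ − µ₁| / mean(width), with width = 4σ by default (FWHM
available as a convention switch). On the measured BT474 means the
formula gives 0.488; averaging per-cell Rs over populations drawn
independently from the printed band statistics gives ≈ 0.50, slightly
above the analytic value because width enters the denominator (Jensen
effect under independent draws — per-cell center/width correlations,
which the drawn statistics do not encode, would lower it toward the
measured 0.46).

The standard curve is OLS of log10(mass) on migration distance
(implemented via statsmodels). Mass estimates exponentiate the
prediction; the 90% interval is a *new-observation* prediction interval
on the log scale (t quantile on n − 2 df), matching the wide printed
intervals rather than a mean-confidence band. With only two ladder
points the CI is reported unavailable. Estimates more than 20% of the
ladder span outside the ladder are flagged extrapolated but returned.
Isoform classification thresholds the point estimate at 100 kDa
(boundary → p110-like). A true multi-gel-density Ferguson regression is
out of scope; the curve is a fixed-density standard curve.

## Gating and population statistics

Gating is hierarchical and monotone: cell (actinin ∧ GAPDH pass) ⊇
epithelial (∧ panCK) ⊇ HER2⁺ (∧ p185 window) ⊇ t-erbB2⁺ (∧ isoform
call). Lanes missing a control trace are excluded rather than guessed.
Truncated calls without a full-length band raise a consistency flag
(truncated forms are expected to co-occur with full-length HER2).

Summaries: %Pos; AVG = mean AUC among positives; staining = AVG × %Pos;
CV = 100·SD/AVG; fold change = max/min among QC-passing positives. The
outlier rule is a single pass discarding values beyond 4 SD of the full
sample mean (applied to electromigration distances before center
comparisons, not to AUCs). The empirical p-value convention is
max(1, #{ref ≥ obs})/n (never 0; (k+1)/(n+1) available). Copy numbers
scale the truncated/full-length ratio by an assumed receptors-per-cell
(default 5×10⁵). Capture probability is the exact Binomial(n, f) upper
tail — note Binomial(1000, 0.01, ≥5) = 0.97131, whereas the Poisson(10)
approximation gives 0.9707. Group comparisons delegate to scipy
(Mann-Whitney: exact for small tie-free samples, tie-corrected normal
approximation otherwise; Spearman; variance-ratio F with the larger
variance in the numerator and two-sided p on (n₁−1, n₂−1) df; paired t).

## Clustering

Markers are z-scored per protein (sample SD, n − 1). Hierarchical
clustering uses scipy's Ward method on raw observations, which is the
Ward-D2 criterion on Euclidean distances. The spectral spectrum builds
an unweighted ε-neighborhood graph (default ε = 0.3 × median pairwise
distance), forms the symmetric normalized Laplacian
L = I − D^(−1/2) W D^(−1/2) (isolated cells keep unit degree, with a
warning, so every cell stays in the spectrum), and suggests k as the
largest successive gap among the first min(10, n) ascending
eigenvalues; the multiplicity of near-zero eigenvalues counts graph
components. Both the automated suggestion and the visual artifacts
(dendrogram, eigenvalue scatter) are available; the pipeline defaults
to the automated k. Within-cluster statistics (Spearman of truncated
load vs p-rs6 among positives; Mann-Whitney of p-rs6 between
truncated-positive/negative cells) are reported with
Benjamini–Hochberg-adjusted p alongside raw p; groups under 3 cells are
marked not computable.

## Problem sizes and numerical choices

The preset cohorts are simulated at the study's printed sizes (391, 127
and 90 occupied lanes) and the clustering benchmark at 217 cells ×
4 markers × 5 components; Monte-Carlo checks use 20–500 replicates
depending on the statistic's variance. Near-zero eigenvalue threshold
10⁻⁸; curve-fit iteration caps 2000 (single) / 4000 (joint);
convergence failures are reported as non-converged fits that fail QC
rather than raised. Ties in deterministic allocation break to the lower
index; the dendrogram cut uses scipy's maxclust criterion.

## Known limitations

Quantification accuracy in the truncated window is bounded by band
overlap, not by the fitter (see accuracy regimes above). The F-test
threshold is calibrated for the preset noise model; strongly
non-Gaussian band shapes would require revisiting it. No cross-round
drift correction is attempted — lanes are matched by lane id only. The
printed critical values of the variance-ratio test in the source data
tables do not match standard F quantiles at those degrees of freedom;
the package reports standard quantiles.
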