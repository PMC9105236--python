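# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, the numerical conventions, and what the synthetic validation
does and does not establish about real data.

## Synthetic image volumes

**Model.** A two-channel, two-modality ROI is simulated as a homogeneous
spatial Poisson process: paired synapse loci at rate `synapse_density`
(per µm³) uniform in the box; each pair is split into a presynaptic and a
postsynaptic punctum separated by a random offset whose length is
Normal(`pair_sep_mean_nm` = 150, `pair_sep_sd_nm` = 50), truncated at zero,
along a uniformly random 3D direction.  Unpaired distractor punctae are drawn
independently per channel (default 0.3/µm³), and STED-only artifacts —
spurious maxima with no confocal counterpart — at 0.1/µm³ per channel.

**Rendering.** Each punctum is an isotropic 3D Gaussian integrated exactly
over every voxel (product of per-axis erf differences, truncated at 4σ).
Integration rather than sampling guarantees that the deposited energy of a
punctum is independent of PSF width to well under 1% — blur redistributes
signal, it never creates it — and keeps sub-voxel positions meaningful even
when σ_z is smaller than the z-step.  True punctae appear in both modalities
(STED FWHM 60 nm, confocal 250 nm); artifacts only in STED.

**Noise.** Additive Gaussian with SD 1, peak (spot-centred) signal =
`snr` × SD, clipped at zero to keep intensities non-negative.  The default
STED SNR of 15 reflects averaged/denoised super-resolution acquisitions; the
confocal channel is rendered noiseless by default because its contract is
the *deconvolved* image (deconvolution output is heavily denoised), and this
is what makes a percentile-of-nonzero confocal threshold meaningful.  Set
`conf_snr` to add confocal noise.  Poisson shot noise is deliberately
omitted so that closed-form checks (energy, peaks) stay exact.

**Geometry defaults.** 10 × 10 × 5 µm (500 µm³, the scale of the imaging
convention of ~400–700 µm³ ROIs), voxels 20 nm laterally and 100 nm axially.
Neither the lateral pixel size nor the z-step of the original acquisitions
is documented; these are conventional STED sampling choices, and both are
spec fields.  An anisotropic axial PSF is deliberately omitted (thin ROIs,
isotropic rendering keeps the oracle maths simple); consequences: none for
pairing (distances are physical), slight peak attenuation for z-straddling
spots, which the default SNR comfortably absorbs.

A resource guard rejects specs implying more than 10⁷ punctae.

## Puncta detection

A voxel is a raw punctum iff no 26-neighbour is brighter, every
equal-intensity neighbour is lexicographically larger in (z, y, x) (plateau
tie-break — the original plugin's rule is unspecified, so the rule here is
explicit and oracle-testable), and its intensity reaches the threshold.  The
default threshold is the 90th percentile of nonzero voxels — appropriate for
sparse, low-noise data; for volumes with dense Gaussian noise an absolute
threshold in noise-SD units (the pipeline uses 5.0) is the right choice and
is what the demo config resolves to.  Maxima within `min_separation_nm`
(default 100) of a brighter maximum are suppressed greedily in descending
intensity order, with 3D physical distances.  Sub-voxel refinement
(centre of mass over the 3³ neighbourhood) is on by default and can be
disabled for exact voxel-level oracle comparisons.

**Confocal cross-check.** A punctum is kept iff the maximum confocal
intensity within `validation_radius_nm` (default 250, the confocal PSF
scale) reaches a threshold — by default the 50th percentile of nonzero
confocal intensities.  Whether the original analysis used an intensity ratio
or presence-above-threshold is not documented; presence-above-threshold is
the documented choice here.  Known limitation: an artifact that happens to
fall inside the confocal skirt of a *true* punctum of the same channel
survives the check; at the default artifact and synapse densities this
contributes ≲2% extra punctae per channel.

## Synapse pairing and density

Mutual nearest neighbours within θ = 300 nm, one call per punctum, locus at
the coordinate midpoint.  The printed pairing threshold in the source
protocol ("300 µm") is treated as a units misprint for 300 nm — 300 µm would
exceed the imaged field; the threshold is configurable.  Whether the original
plugin enforced one-to-one matching is unstated: mutual-NN (one-to-one by
construction) is the default, and a greedy distance-sorted mode ships for
sensitivity analysis.  Density is the exact quotient calls/volume; multi-ROI
inputs report per-ROI densities, their mean, and the pooled quotient.

Validation: with default separations the full chain on 500 µm³ volumes
recovers generator densities to within ~2–4% (mean over 20 seeds) at both
0.85 and 1.66 synapses/µm³.  Residual bias is dominated by pairs whose
partner falls outside the volume (≈1.5%), mutual-NN interference at high
density, and chance distractor pairings (+1–2%).

## Field-potential metrics

The synthetic evoked response is: a 0.4 ms biphasic stimulus artifact; a
narrow negative Gaussian fiber volley (centre 1.2 ms, σ 0.2 ms); an fEPSP
with a *linear* falling phase of slope `fepsp_slope_mv_per_ms` down to
`fepsp_amp_mv`, then exponential recovery (τ = 4 ms).  The linear fall makes
the 20–80% fitting convention exactly recoverable, which is the point of the
generator: parameter recovery isolates measurement error from model error.

Measurement conventions (the source protocol states the quantities but not
the fitting rules, so these are documented choices): slope = least-squares
fit over samples between 20% and 80% of the falling-phase amplitude (falling
back to the interpolated 20/80 chord when fewer than three samples lie in
the band); volley = peak-to-baseline magnitude gated to 0.5–2.1 ms
post-stimulus; fEPSP gate 2.2–25 ms; all deflections smaller than
max(4 × local noise SD, 1 µV) are flagged unmeasurable (NaN) rather than
zero, and ratio operations reject NaN inputs.  fEPSPs are negative-going;
magnitudes are reported unsigned.  PPF uses the amplitude ratio (the stated
convention); a slope-ratio mode exists but is non-default.

Plasticity time courses are normalized per minute to the pre-induction
baseline mean (exactly 100% by construction) with quantification windows
LTP 50–60 min, LTD 30–40 min, PTP 0–5 min post-induction; the adult-LTP
convention ("at 35 min") is exposed as a 30–40 min window.  Baseline
stability is a linear regression of slope against time over the first
10 min, passing when the fitted total drift is ≤10% of the mean — the
original inclusion rule says only "stable", so 10% is a documented choice.

## Statistics

Shapiro–Wilk on each group at α = 0.05 gates between the equal-variance
unpaired t-test (DF = n₁ + n₂ − 2, matching the reported legends) and the
exact two-sided Mann–Whitney U.  Calibration: simulated type-I error is
≤0.06 at α = 0.05 under both branches (2,000 replicates each).  The factorial
analysis is a two-factor fixed-effect OLS ANOVA (genotype × level) with
Type III sums of squares and sum-to-zero contrasts — the GraphPad-style
convention; the repeated factor (time or stimulus intensity) is treated as
fixed on cell means, an approximation documented here rather than a
mixed-effects model.  Bonferroni post hoc: per-level t-tests with adjusted
p = min(1, raw p × number of levels).  The PCA outlier screen flags samples
whose robust z-score (1.4826 × MAD) exceeds 3 on any of the first two PC
scores within their own group; flagging only — exclusion is the caller's
decision.  The 3-SD default is a convention; the original screen reports no
rule.

## Gene-set enrichment

Ranking metric: signal-to-noise (μ₁ − μ₂)/(σ₁ + σ₂), descending, ties broken
by gene name.  ES: weighted KS running sum with weight p = 1 (p = 0 recovers
the classic unweighted statistic; both are oracle-tested).  Null: phenotype
label permutation (default 1,000), falling back to gene-set permutation when
either group has fewer than 7 samples, where label permutations are too
coarse.  NES normalizes by the mean magnitude of same-sign null scores; the
FDR q compares the observed NES against the pooled same-sign null NES
distribution, clipped to [0, 1].  Leading edge: members at or before the
running-sum extremum on the enriched side.  Sets smaller than 5 members
after intersection with the expression universe (or as large as the
universe) are skipped with a warning.  The procedure's upstream parameters
are not documented in the source protocol; metric, weight, permutation type
and count are all exposed in the API.

The expression generator plants a shifted gene set (N(0,1) background,
+`effect_sd_units` in the first group), so detection power and null
calibration are both measurable: at effect 1.0, 50 planted genes in a
10,000-gene universe with 12 vs 10 samples, the planted set is detected at
q < 0.25; under label-permuted nulls, p-values are uniform (KS test over
200 runs) and ≤10% of sets reach q < 0.1.

## Problem sizes in the validation suite

Chosen so the full suite runs comfortably on a single CPU: density recovery
uses 20 seeds per density on full 500 µm³ volumes; pairing-specificity uses
4 ROIs per genotype; GSEA null calibration uses 100–200 permutations on
reduced universes (120–2,000 genes); the type-I calibration uses 2,000
replicates.  Oracle-equivalence checks run on small volumes (≤64³ voxels)
and point sets (≤50 per channel), where exhaustive enumeration is feasible.

## What the synthetic validation does not show

The generators emulate the *geometry and signal structure* of the real
assays, not their biology or their full noise physics: no Poisson shot
noise, no anisotropic PSF, no deconvolution artifacts, no dendritic
morphology or clustered (non-Poisson) synapse placement, no amplifier drift
or stimulus-artifact variability, no microarray normalization chemistry.
Passing recovery tests therefore establishes that the *measurement chain* is
unbiased and correctly implemented under the stated models — not that it is
robust to every failure mode of real acquisitions.  Parameters most worth
re-examining on real data: the detection threshold (percentile vs absolute),
the confocal validation threshold, and the pairing threshold.
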