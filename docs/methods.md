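# Methods

This note documents the models, conventions and parameter choices behind
`restconn`, in the order the pipeline runs. Defaults live in
`restconn/config.py`; each is logged when used.

## Preprocessing

Recordings (channels x samples, microvolts, 10-20/10-10 labels) are
bandpass-filtered 0.5–70 Hz with a 4th-order Butterworth (24 dB/oct)
applied forward-backward, notch-filtered at 50 Hz (zero-phase IIR, Q = 35),
and polyphase-resampled to 256 Hz (output length `floor(n·fs_out/fs)`).
Zero-phase filtering matters here: any phase distortion would contaminate
every connectivity estimate downstream. Re-referencing subtracts the
per-sample channel mean (idempotent; removes any channel-common offset
exactly). Epochs are consecutive non-overlapping 2 s windows; the trailing
remainder is dropped. Artifact handling is a pass-through hook taking a
boolean keep-mask per window — the synthetic data is clean, and
manual/ICA cleaning belongs to an acquisition pipeline, not this one.

## Spectra and frequency bands

Per window, a 10% cosine-tapered (Tukey) window is applied and the FFT is
zero-padded from the native 2 s (0.5 Hz resolution) to 4 s, giving the
0.25 Hz grid; per-channel periodograms are averaged across windows with
taper-power normalization (Parseval holds within sampling error). Band
power is the mean PSD over bins whose centers fall in [lo, hi], both ends
closed; when bands share an edge the bin goes to the lower band
(deterministic assignment). Canonical bands: delta 1–3, theta 4–7, alpha
8–13, beta 14–30, gamma 30–49 Hz.

The individual alpha frequency (IAF) is the argmax of the channel-mean PSD
in 7–13 Hz; a monotone (peak-free) spectrum triggers a warning and a
fallback of 10.0 Hz. IAF-anchored bands rescale every canonical edge e to
(e/10)·IAF, so IAF = 10 reproduces the canonical bands and IAF = 10.1 puts
delta at 1.01–3.03 Hz. Delta, theta and beta are always rescaled; whether
alpha itself is anchored is a config switch (default: anchored). Gamma is
left canonical — the rule is an alpha-neighborhood construction and has no
sensible extension two octaves up.

## Forward model

The volume conductor is five concentric spheres — white matter, gray
matter, CSF, skull, skin — with default radii (67, 71, 74, 81, 88) mm and
conductivities (0.14, 0.33, 1.79, 0.01, 0.43) S/m, standard multishell
values on an 88 mm scalp sphere. These are conventions, not fitted
quantities, and are config-replaceable.

For a dipole at radius b inside the innermost shell, the scalp potential is
the classical Legendre series: the infinite-medium dipole expansion
supplies per-degree source coefficients, and for each degree n a small
linear system (potential and radial-current continuity at the four
interfaces, zero current through the scalp) gives the multishell gain. The
series is truncated at degree 80 or when (b/R)^n < 1e-10. The homogeneous
single sphere has a closed form via generating-function identities; the
test suite uses it as an independent oracle, together with linearity,
rotational-symmetry and radial-dipole checks.

Electrode positions come from the installed standard 10-05 template,
re-centered and radially projected onto the scalp sphere (positions more
than 5 mm off are rejected as montage/model mismatch). The source grid is
cubic (5 mm spacing in production; tests use 15 mm), restricted to one
voxel inside the gray-matter shell because beamformer weights diverge at
conductivity boundaries; the exact center is excluded (orientation
degenerate). Gain matrices (channels x 3) are average-referenced to match
the data.

## DICS beamforming

The band-limited cross-spectral density (CSD) matrix is the window- and
bin-averaged outer product of the tapered window FFTs (Hermitian by
construction). Fewer windows than channels triggers a rank-deficiency
warning; the spatial filter always regularizes the real CSD by 5% of its
mean diagonal (config `DICS_REG_FRAC`).

Per voxel, the linearly constrained minimum-variance filter is computed on
the real CSD; the dipole orientation is fixed to the minimal eigenvector of
L'C⁻¹L (the dominant direction of the voxel output-power matrix), and the
weights w = C⁻¹l/(l'C⁻¹l) have unit gain at the voxel. Power maps default
to plain unit-gain output power; a noise-normalized variant (power divided
by the noise gain w'w, the neural-activity-index convention) is available
because the unit-gain map inflates deep voxels on noisy data. Coherence
maps are magnitude-squared coherence between beamformed voxel signals and a
reference voxel; self-coherence is exactly 1 by the normalization — an
identity the acceptance script recomputes through the full chain.

**Surrogate significance.** The null hypothesis is "no temporal coupling
between the reference time course and a voxel time course beyond estimator
bias". The surrogate destroys the temporal pairing while preserving both
spectra: the reference course is circularly shifted by at least one second
(a restricted shuffle of its one-second segments — contiguous everywhere
but the seam), and the full coherence estimator is recomputed; the
per-voxel threshold is the conservative upper order statistic at the 99th
percentile of 100 shifts. Two design points matter for calibration: a
literal random re-ordering of one-second blocks whitens the stitched
windows and is anticonservative (measured 4–5% exceedance at 1% nominal),
and the interpolated 99th percentile of 100 draws is itself exceeded ~2% of
the time, hence the upper order statistic. Measured exceedance at the
study's 4-minute recording length is 1.5% (2x-nominal limit 2%); below
~2 minutes the conditional null has too few distinct shifts and the
threshold is less reliable.

**Iterative network identification.** The seed is the maximum of the
noise-normalized power map (with several sources sharing the SNR, the
unit-gain maximum drifts to deep noise-inflated voxels). Each pass computes
the coherence map of the current reference, thresholds it against the
surrogate level, and accepts the strongest unclaimed suprathreshold voxel
that is a *local maximum* of the map — beamformer leakage forms ridges
around found sources, and ridges have no peaks. Claimed neighborhoods
(radius max(10 mm, two grid steps)) are suppressed; the reference moves to
the newest source, falling back to earlier ones before stopping; at most 5
sources per band. A seed without coherent partners is returned alone and
flagged.

Correlated-source suppression is a real limit: the beamformer assumes
sources are not strongly linearly correlated at zero lag, and strongly
instantaneously-coupled simulations (coupling weight ≳ 0.8 at lag 1)
mislocalize. The synthetic default therefore couples a narrowband alpha
oscillator chain at a quarter-period lag: high within-band coherence, low
zero-lag correlation — the regime the method is built for.

## MVAR and renormalized partial directed coherence

Source time courses (beamformer weights applied to the concatenated
windows) are modeled jointly as a vector autoregression; the order is
chosen by minimizing AIC(p) = ln det Σ_p + 2pm²/n over 1..20 (ties to the
smaller order), by least squares. The fit retains the inverse regressor
Gram matrix, which carries the coefficient covariance.

For each pair j→i and frequency, RPDC forms X = (Re Ā_ij(f), Im Ā_ij(f))
with Ā(f) = I − Σ_k A_k e^(−2πifk/fs) and weights it by the inverse of its
estimator covariance V_ij(f) (from the Gram inverse and Σ_ii):
λ = X'V⁻¹X. The statistic is nonnegative, χ²(2) under the null, and
invariant under rescaling of any source. At order p = 1 the two components
are collinear and V is rank one; the quadratic form uses an
eigendecomposition pseudo-inverse (the statistic is then χ²(1)). Because λ
is unbounded, results carry both the raw statistic (inference) and the
monotone display map λ/(1+λ) in [0, 1] (presentation); the display scale
saturates for strong couplings at large n, which is why group summaries are
reported alongside the significance decisions rather than replacing them.

**Bootstrap significance.** For each directed pair, the null model is the
fitted VAR with that pair's coefficients (only) zeroed — indirect paths
stay in place, which matters: zeroing all couplings makes the null
anticonservative for indirect pairs in a chain. One hundred replicates are
driven by jointly resampled fit residuals (preserving the innovation
covariance, including instantaneous correlations), refitted at the selected
order, and summarized exactly like the observed statistic (band-mean raw
λ); the threshold is the 95th percentile. The same null also yields the
5th/95th percentiles of the null *net asymmetry* λ(j→i) − λ(i→j), used by
the time-reversal screen. Measured false-positive rate on white-noise
nulls: 7% at 5% nominal (limit 10%).

**Time-reversal testing.** The VAR is refitted on time-reversed signals at
the same order and the band-mean RPDC recomputed. An edge passes only if
its net asymmetry is *significantly* positive on the original signals and
*significantly* negative after reversal, judged against the bootstrap's
null-asymmetry percentiles. Sign conditions alone are not enough:
estimation noise in lag coefficients also reverts under time reversal, so
roughly half of bootstrap false alarms would survive a sign-only rule,
while instantaneous-mixing artifacts (volume conduction) fail both
magnitude conditions. Measured on 3-node chains (weights 0.5, n = 5000):
97/100 exact edge-set recoveries, no reverse edges; instantaneous mixtures
of a common alpha source are rejected in 50/50 runs.

Flow summaries are display-scale band means averaged over targets
(outflow), over sources (inflow), and over all directed pairs (global
mean).

## Synthetic cohorts

The generator defines the study conditions. Two groups of 17; SUVR normal
per group (HC 1.24 ± 0.2, MCI 1.45 ± 0.2; amyloid-positive at ≥ 1.265);
ApoE genotypes drawn from per-group frequency tables (MCI: 1/17 E2/E3,
11/17 E3/E3, 4/17 E3/E4, 1/17 E4/E4; HC dichotomous 13/17 E3/E3, 4/17
E3/E4) with ordinal risk coding E2/E3 < E3/E3 < E3/E4 < E4/E4 and an
ε4-carrier flag; MMSE 29.65 ± 0.6 vs 28.41 ± 1.4, CERAD z 0.75 ± 1.2 vs
−0.95 ± 1.1, education and age matched.

Per-band EEG summaries (power, coherence, RPDC) are drawn from per-group
normals; the alpha and beta cells carry the group effects and the remaining
bands are matched across groups. Each subject has a latent connectivity
factor carrying half of every summary's variance; in the MCI group this
factor is Gaussian-copula-coupled to SUVR so that the realized Spearman
correlation between SUVR and mean connectivity hits the target (default
−0.8; the latent correlation is pre-compensated analytically for the
dilution from band-specific noise). The same factor scales the MVAR
coupling weights of the subject's simulated recording (multiplier
exp(0.2·z)), so recordings and summaries tell one story. Because the
latent factor is shared within a subject, a cohort can draw incidental
group differences in matched bands — visible occasionally as extra
battery flags, as in real data with correlated measures.

Recordings project the source chain through the lead field from three
dipole positions and add white sensor noise at a stated SNR (default
10 dB against mean projected channel power; channel-correlated noise is
out of scope). Sensor noise white and uncorrelated matches the
beamformer's assumptions; real EEG violates this with spatially correlated
background activity, so passing tests here bound estimator correctness,
not real-data robustness. Clean data also means the artifact hook goes
unexercised beyond its contract.

## Statistics, classification, Bayesian estimation

Group tests are pooled-variance unpaired t (accepting summary triples, so
printed summary statistics are directly checkable), Pearson χ² without
continuity correction, and the Friedman rank test. Correlation families
use tie-corrected Spearman; partial correlations rank-transform all three
variables before residualizing on the covariate, keeping the partial and
unconditional analyses on the same scale. A variable fully explained by
the covariate returns partial r = 0 rather than an error. Multiplicity:
Bonferroni m = 15 for the band-by-measure battery; the correlation families
use percentile-bootstrap CIs (1000 simple case resamples; significance =
CI excludes 0; degenerate resamples redrawn and logged), with family sizes
30 (clinical) and 36 (cognition) exposed in config. Normality screening is
Lilliefors-corrected KS (naive KS with estimated moments is
anticonservative).

SVM classification standardizes features, drops constants with a warning,
and uses a linear kernel for clinical scalars and a degree-3 polynomial
kernel (γ = 0.25) for EEG features. Validation is 10 repeated stratified
75/25 splits; C is selected from a logarithmic 1–1000 grid by mean test
accuracy and logged. Three accuracies are reported: training, testing, and
*overall* — the split-trained model scored on the pooled data, which by
construction lies between the other two and reproduces the conventional
train > overall > test ordering.

The Bayesian two-group model treats each group as Student-t with its own
location and scale and a shared normality parameter ν: μ_k ~ Normal(pooled
mean, 1000 × pooled SD), σ_k ~ Uniform(pooled SD/1000, pooled SD × 1000),
ν − 1 ~ Exponential(mean 29). The posterior is sampled with an
affine-invariant ensemble (40 walkers; `n_steps` counts total draws after a
one-third burn-in; production default 100,000, analysis drivers use 20,000
— posterior summaries at this chain length are stable to well under the
reporting precision). Convergence is screened by split-Rhat over four
walker groups (flagged above 1.1). Reported: posterior means/SDs/95% HDIs
of the five parameters, the standardized effect size
(μ₁−μ₂)/√((σ₁²+σ₂²)/2), and the *credible separation* — the percentage of
posterior effect-size mass on its dominant side of zero (50 = none, 100 =
full).

## Problem sizes used by tests and drivers

Tests run on a 15 mm source grid (217 voxels, 60 channels), 30–240 s
recordings, n = 1000–10,000 MVAR samples, 100 bootstrap/surrogate
resamples, and 20,000 MCMC draws; Monte-Carlo claims use 50–200
repetitions. These sizes keep every statistical check at its planned power;
production settings (5 mm grid, full-length recordings, 1000 bootstrap
iterations, 100,000 draws) are config values.

## Known limitations

- The spherical conductor and template montage ignore individual anatomy;
  localization claims are grid-relative, not anatomical.
- The unit-gain beamformer's depth bias is only handled at the seeding
  step; raw power maps remain biased by design.
- Strongly zero-lag-correlated sources violate the beamformer model and
  will be suppressed or mislocalized.
- The surrogate threshold needs ≥ ~2 minutes of data to be well
  calibrated.
- RPDC display values saturate near 1 for strong couplings at large n;
  cross-study comparison should use the significance decisions and the
  display band means jointly.
- The volume-conduction rejection of TRT is demonstrated for
  instantaneous mixing; mixtures with both instantaneous and lagged
  components are only partially separable in principle.
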