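# Methods

This note documents the models, estimators, and design choices behind
`aperiodic_net`, and what the synthetic-data experiments do and do not
establish about real EEG.

## Synthetic recordings

A recording is synthesised entirely in the frequency domain and inverse
FFT'd once per channel.

**Aperiodic background.**  Channel c's spectrum gets amplitude
`A(f) = sqrt(P0 · fs · N / 2) · f^(−β_c/2)` with i.i.d. uniform random
phases, so the one-sided PSD equals `P0 · f^(−β_c)` exactly in
expectation (`P0` = 20 µV²/Hz at 1 Hz, a realistic resting-EEG scale;
`β` the aperiodic exponent, ≥ 0).  Deterministic amplitudes with random
phases were chosen over Gaussian spectral coefficients because they make
the exponent exactly controllable, which turns slope recovery into an
unambiguous accuracy test.  DC is zeroed.

**Oscillations.**  A bump is Gaussian-profile narrowband noise: peak PSD
= `amplitude ×` the background PSD at the centre frequency, Gaussian
standard deviation `bandwidth` Hz on the PSD profile, independent random
phases.  Bumps rather than sinusoids are used so the MAD peak-exclusion
step of the slope fit is exercised on realistic spectral shapes.
Defaults place an alpha bump (10 Hz, σ 1.5 Hz, ×4) over parieto-occipital
channels and a beta bump (20 Hz, σ 2 Hz, ×2) over central channels.

**Coupling.**  A coupling of strength κ ∈ [0, 1] on a channel pair and
band replaces, within the band, `sqrt(1−κ)` of each channel's own
spectral content with `sqrt(κ)` of a shared narrowband source, the second
channel's copy phase-rotated by the stated lag.  κ is therefore the
shared fraction of in-band power: κ = 0 leaves the channels independent,
κ = 1 with a quarter-cycle lag drives band lagged coherence toward 1
(the measured value, ≈ 0.91 at 180 s, is limited only by spectral
leakage of the Welch windows).  Band lagged coherence grows
monotonically with κ (≈ (κ sin φ)² / (1 − (κ cos φ)²) at lag φ when the
source and background levels match).

**Volume conduction.**  Leakage is a symmetric instantaneous mixing
matrix `M = I + s · exp(−d_ij / λ)` built from montage distances
(default s = 0.2, λ = 0.05 m), applied after coupling injection.
Because it is real and zero-lag it must not create lagged coherence;
the calibration suite verifies median beta-band LC stays below 0.005
even at s = 0.5.

**Cohorts.**  Per-subject exponents are drawn once,
`β_sc ~ N(1.5, 0.2)` per channel, coupling strengths `~ N(0.3, 0.1)`
clipped to [0, 1]; condition effects are additive on top of the same
subject draw (paired design).  Defaults mirror a 15-subject, 32-channel
(BioSemi 10-20 montage), 512 Hz, 180 s ON/OFF study, with the ON
condition's exponent raised by Δβ = 0.5 on five left-central channels
(C3, CP1, CP5, FC1, FC5).  No published effect sizes exist for these
quantities in physical units, so the planted magnitudes are free
simulation parameters chosen to sit clearly above between-subject
variability; they were fixed once and are recorded in every cohort's
truth table.  Recordings are generated lazily from stored per-recording
seeds, so identical (subject, condition) cells are bit-identical across
runs and platforms.

What the simulator does **not** emulate: artifacts (EMG/EOG), drifts and
line noise, nonstationarity, bad channels, knee-shaped aperiodic spectra,
or biophysically realistic source-to-sensor projection.  Passing tests
show the estimators are correct and calibrated under the stated
generative model, not that real recordings satisfy that model.

## Preprocessing

High-pass: linear-phase windowed-sinc (Hamming) FIR of order 1536
(1537 taps), applied forward-backward (zero phase).  The taps are built
by spectral inversion of a unity-DC lowpass so DC is nulled exactly; at
512 Hz the two-pass transition spans roughly 0.45–1.5 Hz and a 0.1 Hz
drift is attenuated by far more than 20 dB while 10 Hz passes within 1 %.
Only the filter order and two-pass application were prescribed; the
window and design method are this package's documented choice.
Re-referencing subtracts the instantaneous channel mean (idempotent;
channel means are zero to machine precision afterwards).

The pipeline applies the common average reference by default but leaves
the high-pass off (`AnalysisConfig.highpass = None`): synthetic
backgrounds are drift-free by construction and the time-domain
forward-backward filter is by far the most expensive stage.  Set
`highpass = 1.0` for data with real drifts.  ICA, bad-channel
interpolation, and artifact marking are out of scope; recordings carry
clean-segment boundaries `[start, end)` that the spectral estimators
honour instead.

## Spectra and the slope estimator

Welch PSD: Hamming window of one second (512 samples at 512 Hz → 1 Hz
bins), 50 % overlap, density scaling `2 / (fs · Σw²)` with DC/Nyquist
undoubled.  Windows are laid out within each clean segment independently
(never across a cut), and pooling all windows weights segments by window
count.  Splitting a continuous record into three segments moves slope
estimates by < 0.02, so segmented estimation is safe.

Slope fitting on `[2, 45]` Hz:

1. the spectrum is resampled onto 256 log10-equally spaced frequencies
   (linear interpolation in log-log space, exact for power laws) so the
   regression is not dominated by the dense high-frequency bins;
2. a bisquare IRLS line fit (tuning constant 4.685, scale = MAD/0.6745,
   MATLAB-robustfit style) gives provisional residuals; points with
   residual `> 1 × MAD` (unscaled MAD, median-centred; switchable to
   uncentred via `mad_centered=False`) are flagged as oscillatory peaks,
   and each flagged run is extended over the contiguous surrounding
   points with positive residuals — the base of the bump.  Only positive
   residuals are flagged, since oscillations add power;
3. an ordinary least-squares refit on the unflagged points yields the
   reported slope (signed) and intercept.

A floor of at least 10 surviving grid points is enforced (error
otherwise).  An absolute tolerance of `1e-9 · max(1, |log10 P|)` on the
flagging rule prevents floating-point noise from being flagged on exact
power laws.  Accuracy under the default cohort conditions (180 s, alpha
and beta bumps present): mean |error| < 0.05 for β ∈ {0.5 … 2.5}, and an
alpha bump of ×10 moves the fit by < 0.1.

Band power over 13–30 Hz (edges inclusive on the 1 Hz grid, 18 bins):
`raw` is the arithmetic mean PSD; `residual` is the mean log10 deviation
from the fitted aperiodic line evaluated on the original bins, i.e.
slope-corrected oscillatory power (0 for a pure power law).

Note an interaction that matters when interpreting contrasts: because a
steeper slope lowers broadband power, a planted slope effect moves *raw*
band power too (and the common average reference plus leakage spread the
difference across the montage).  Raw-power contrasts on this simulator
therefore co-vary with slope effects by construction; the residual
measure is the slope-invariant one.

## Connectivity

Cross-spectra use the same Welch segmentation as the PSD (the
window/overlap for connectivity estimation is this package's choice,
made so one spectral backend serves both), restricted to 1–35 Hz, with
the scipy convention `S_ij = E[conj(X_i) X_j]`; the diagonal equals the
Welch PSD exactly.  Lagged coherence
`Im(S_ij)² / (S_ii S_jj − Re(S_ij)²)` is computed per 1 Hz bin and
averaged entrywise over band bins (13–30 beta, 8–12 alpha) — averaging
the per-frequency values, not the cross-spectra.  Values are clipped to
[0, 1] against floating-point excursions; a degenerate denominator
(perfectly real coherency, e.g. `y = 2x`) returns 0 with a warning since
no lagged coupling is identifiable.  The measure is invariant to
rescaling any channel and, by construction, to any fixed real mixing of
independent sources.

## Networks

Proportional thresholding keeps the `K = round(pt/100 · n(n−1)/2)`
strongest upper-triangle weights (round half away from zero: 4 % of 496
pairs → 19.84 → 20 links, 36 % → 179) and binarises.  Exact ties at the
cutoff — measure-zero for real coherence values but possible in
constructed inputs — are broken deterministically by (row, column)
lexicographic order.  Metrics are computed on the binary graph:
clustering coefficient `mean_i 2 t_i / (k_i (k_i − 1))` with degree-< 2
nodes contributing 0, and global efficiency as the mean inverse
unweighted shortest-path length over ordered pairs with unreachable
pairs contributing 0.  Both match independent reference implementations
(networkx) to 1e-12 on random graphs; weighted-graph variants and
small-world indices are out of scope.

## Statistics

**Cluster-based permutation test** (paired, two conditions): per-channel
paired t statistics; channels with `t` beyond the per-tail t-distribution
quantile at `cluster_alpha = 0.05` (the "95th quantile" threshold read as
one threshold per sign, FieldTrip-style) are clustered by connectedness
under the montage adjacency (neighbours = pairs within the 0.15 quantile
of all pairwise electrode distances; ~4.8 neighbours per channel on the
32-channel cap); cluster mass is the sum of member t values; the null is
built from `n_permutations` independent within-subject sign flips of the
differences, recording each permutation's maximum |mass|; each observed
cluster's p is `(1 + #{null ≥ |mass|}) / (1 + n_permutations)` (the +1
smoothing keeps p > 0), significant at p < 0.05 two-tailed.  Minimum
cluster size is one channel.  Zero-variance channels get t = 0 with a
warning.  Calibration on i.i.d. null data (15 × 32, 500 permutations,
200 replicates): family-wise positive rate ≈ 0.03–0.06; power for a
1.5-SD shift on a 5-channel connected set: ≥ 0.98 with ≥ 3-channel
localisation.

**Wilcoxon signed rank**: zeros dropped, ties mid-ranked; for n ≤ 25 the
p-value is exact, from the full sign-flip distribution of the rank sum
computed by convolution over doubled mid-ranks (equivalent to enumerating
all 2ⁿ sign patterns, verified against brute-force enumeration); above
that, a normal approximation with tie correction and continuity
correction.  Two-tailed p = 2 × the smaller tail, capped at 1.

**Spearman + FDR**: average-rank Spearman rho with two-sided p per
channel (scipy), Benjamini–Hochberg step-up across channels at q = 0.05
(statsmodels); constant channels are excluded from the family with a
warning.  The channel-wise slope-vs-GE analysis uses GE at the 20 %
reference threshold, with the full threshold grid repeated for the
global-slope correlation.

**Seeding.**  Every permutation seed derives from the analysis base seed
XOR a CRC-32 hash of the contrast name, so results are reproducible and
adding a contrast never perturbs existing ones.  Pipeline runs on a fixed
cohort and seed produce byte-identical tables.

## Problem sizes

Simulation-based checks use the study-scale conditions throughout:
180 s recordings at 512 Hz; 50 seeds per exponent for slope recovery;
20 seeds for leakage immunity; 200 null and 50 planted replicates (500
permutations each) for test calibration; 50 full 15-subject cohorts
(1000 permutations) for end-to-end effect recovery.

## Known limitations

Sensor-space networks on 32 channels say nothing about source-space
topology; lagged coherence discards genuinely instantaneous neural
coupling along with volume conduction; the exact Wilcoxon assumes
exchangeability of signed differences; cluster p-values license inference
about cluster existence, not exact cluster extent; and all calibration
results are conditional on the generative model above.
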