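# Methods

## The measurement problem

Teams of six people (one per clinical profession) work through a simulated
resuscitation while each member's EEG is recorded by an independent mobile
amplifier (15 passive electrodes on the 10-20 montage — Fp1, Fp2, F3, Fz,
F4, C3, Cz, C4, P7, P3, Pz, P4, P8, O1, O2 — referenced to CPz, digitized at
125 Hz). Two trained raters score every member's teamwork on the five
TeamSTEPPS topics. The question the pipeline answers: does brain-to-brain
synchrony during verbal communications predict the team's TeamSTEPPS
performance?

## Total interdependence (TI)

For two signals x and y, with magnitude-squared coherence C(f) estimated
over K one-second epochs (per-epoch linear detrend, Hann window, DFT; 1-s
epochs put the bins on integer hertz),

    TI(band) = - sum_{f in band} ln(1 - C(f)),

summed over the band's inclusive integer-Hz bins: 1-20 Hz ("all frequency
bands") or 8-12 Hz (alpha). TI is nonnegative and additive over disjoint
bands. Coherence is clipped at 1 - 1e-10 before the log so self-coherence
does not diverge. Any affine rescaling of TI (for instance a 1/(2*pi) or
per-bin bandwidth factor in other formulations) cancels in the
normalization below and does not affect downstream results.

### Permutation normalization

The coherence estimator is biased upward by roughly 1/K under independence,
so raw TI depends on how long a communication lasted. Each pair/band TI is
therefore normalized against a null built by re-pairing one subject's
epochs against the other's with a uniform random permutation (fixed points
allowed), which preserves each subject's spectra while destroying
cross-subject alignment. With n_perm permutations (default 1000, floor
100), the reported statistic is z = (TI_obs - mean_null) / sd_null.
Autospectra are permutation-invariant, so only the cross-spectrum is
recomputed per draw; the permutation draws are shared across bands.

A Lilliefors-corrected Kolmogorov-Smirnov audit flags nulls that reject
normality at alpha = .05 against a normal with the sample's own mean and
SD. The null of band TI is a sum of ~Exp-distributed per-bin terms and is
therefore mildly right-skewed by construction (measured skew ~0.6 for the
20-bin band, ~1.1 for the 5-bin alpha band); with 1000 null samples the
audit detects this essentially always. The flag should accordingly be read
as "the z-scale tail probabilities are approximate", not as an error; the
center and scale of z remain well calibrated (see the null-calibration
test), and the flag rate is reported rather than acted on.

### Seeding

One master seed; each (session, communication, pair) derives its own
substream as `default_rng([seed, session_index, comm_index, a, b])`, so
results are bit-for-bit reproducible and independent of execution order.

## Preprocessing

- Zero-phase 4th-order Butterworth band-pass, 1-40 Hz, applied
  forward-backward (phase matters for cross-spectra). Band edges at or
  above the Nyquist frequency (62.5 Hz at 125 Hz sampling) are rejected.
- Average rereference (per-sample channel mean subtracted). Filtering and
  rereferencing are both linear and commute.
- Region reduction: anterior = {Fp1, Fp2, F3, Fz, F4}, central = {C3, Cz,
  C4}, posterior = {P7, P3, Pz, P4, P8, O1, O2} (a standard lobe partition
  of this montage; configurable). The region series is the mean of its
  member channels, computed before coherence, so each pair yields one TI
  per region. Note that average rereferencing mixes a fraction of every
  region's signal into every channel; genuinely anterior-coupled sources
  therefore leak a weak coherent component into the other regions' series.
  This is a property of the montage algebra, not a bug, and it is visible
  in synthetic studies as small nonzero off-region effects.
- "Golden SD": a per-channel robust scale estimate, 1.4826 x median
  absolute deviation of the filtered recording (>= 30 s required). The MAD
  is insensitive to the sparse large artifacts the rule screens, so the
  threshold is not inflated by them.
- Epoching: contiguous 1-s epochs (trailing partial epoch dropped). An
  epoch is rejected when any sample on any channel exceeds 6x that
  channel's golden SD. Only epochs clean for both members of a pair
  ("commonly clean") enter coherence estimation. Manual ICA-based artifact
  correction used in lab practice is replaced by this amplitude rule alone;
  that is a deliberate fidelity gap of the automated pipeline.

## Alignment

Recorders start independently, so per-subject lags are estimated by
normalized cross-correlation of audio envelopes against a reference subject
(the first, by convention), searched within +-5 s; a peak correlation below
0.2 marks the estimate unreliable. Event windows are shifted onto each
subject's clock (positive lag = that subject's content starts later) and
cut to sample windows [ceil((start-t0)*fs), floor((end-t0)*fs)); windows
shorter than one epoch are invalid communications.

## Aggregation

Communication TI is computed for all 15 subject pairs during every
communication window. A subject's communication TI is the unweighted mean
over the valid pairs containing the subject; the student TI is the
unweighted mean over the subject's valid communications; the group TI is
the mean of the six student TIs, defined only when all six exist
("complete" sessions). A pair-communication TI is valid when K >= 10
commonly clean epochs support it: below ~10 epochs the 1/K bias dominates
the coherence estimate. Pairwise TI is symmetric, so both members of a pair
receive it (no sender/receiver asymmetry).

## TeamSTEPPS scores

Two raters score five topics per profession; topic ranges vary by
profession (instrument metadata, supplied as configuration; defaults
bundled). Processing: average the raters, min-max scale each topic to
[0, 1]; the overall score is the *sum* of the five raw topic scores scaled
against the overall range (the sum of topic ranges), not the mean of scaled
topics; the group score is the mean of the six professions' scaled overall
scores, defined only for complete sessions. Interrater reliability is
ICC(2,1) — two-way random effects, single rater, absolute agreement — from
the ANOVA mean squares:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),  k = 2.

Qualitative labels follow both Cicchetti (excellent >= 0.75, good 0.60-0.74,
fair 0.40-0.59, poor < 0.40; band edges inclusive at the lower bound) and
Koo-Li (< 0.5, 0.5-0.75, 0.75-0.9, > 0.9). Records missing a rater are
dropped, not imputed.

## Inference

The correlation grid always has 36 cases per analysis level: 6 scores (5
topics + overall) x 3 regions x 2 bands. Per case, bivariate outliers in
the (TI, score) cloud are removed by FastMCD (75% support; a point is an
outlier when its robust squared Mahalanobis distance exceeds the
chi-square(2) quantile at 1 - .001 ~ 13.816; deterministic given the seed),
Pearson's r with the exact two-sided t reference is computed on the
survivors, and Benjamini-Hochberg correction is applied across the 36 cases
of that level (individual and group grids corrected separately), with
significance at adjusted P < .05. Cases that cannot be computed (fewer than
3 survivors, zero variance, rank-deficient scatter) are reported undefined
but still count toward the m = 36 family. Note a small-sample caveat the
tests quantify: at n ~ 15-20 the MCD support subset is small and the
best-determinant selection can trim 1-3 unremarkable points, which biases
|r| upward; type-I control of the full procedure is checked empirically by
the null-study calibration rather than assumed.

The minimum detectable correlation uses the Fisher-z power approximation
r = tanh((z_{1-alpha/2} + z_power) / sqrt(n - 3)); at n = 30, power 0.8,
alpha .05 two-sided it is 0.49.

## Synthetic data: what it emulates, and what it does not

No raw recordings are deposited, so a generator with exact ground truth
stands in: 6 subjects x 15 channels x 125 Hz, pink-noise (1/f power) EEG
with controllable band-limited pairwise coherence; planted spike (1-5
samples) and 0.5-s square-drift artifacts at a fixed multiple (> 6) of the
channel's robust SD, each confined to a single known epoch with guard
margins sized so zero-phase filter ringing cannot cross the epoch boundary
(the 1-Hz high-pass settles slowly around drift edges, hence drifts sit
mid-epoch); a communication schedule; per-subject recording lags realized
by slicing a longer master signal (so timestamps must genuinely be
compensated before cross-subject windows align); shared audio envelopes
delayed by the same lags; and two-rater scores from the two-way
random-effects model the ICC assumes (default variance components imply
ICC ~ 0.74, the "good" agreement regime).

Coherence injection draws in-band spectral coefficients through a factor L
of the target coherency matrix G (L L^T = G, G_ij = sqrt of the target
magnitude-squared coherence), on the pink amplitude profile, widened by one
bin so Hann-window leakage does not dilute the band-edge bins, and
pre-compensated for the small attenuation caused by per-channel independent
noise at the region-mean level. For a single pair this is exactly the
mixing rule channel = w*shared + (1-w)*independent with coherency
w^2/(w^2+(1-w)^2); the weight knob is exposed and the measured coherence is
monotone in it.

Study-level simulation: each session's anterior-alpha coherence target is
drawn uniformly from (0, 0.1) by default and the session's latent score is
link_slope times the target's position in that range, plus noise. The
deliberately weak default range keeps the group-level normalized TI at the
magnitude observed in real inter-brain data (z of order 1, matching
reported student-TI values of a few tenths) — strong targets (which the
session-level generator supports, up to ~0.9) would produce z in the tens,
a leverage-dominated session distribution no real study shows, and badly
anti-conservative Pearson p-values. Twenty sessions per study mirrors the
number of sessions with complete six-subject EEG in the emulated design.

What passing tests do **not** show about real data: the generator's epochs
are stationary Gaussian, artifacts are strictly amplitude-defined, event
boundaries are exact, and raters deviate only as the two-way model allows —
real EEG nonstationarity, ocular/muscle artifact structure, annotation
error and rater idiosyncrasies are all absent, so recovery rates here are
upper bounds.

## Problem sizes used in the shipped checks

Calibration and recovery suites run at reduced but statistically adequate
sizes chosen once: null calibration over 200 simulated communications of 60
epochs at the full 1000 permutations; the end-to-end recovery and type-I
experiments at 20 replicates x 20 sessions x three 32-s communications with
120 permutations (the permutation count affects only the Monte-Carlo noise
of z, not its center). The acceptance script's single demonstration study
uses 300 permutations.

## Known limitations

- The exact upstream TI normalization constants are not publicly specified;
  any affine difference cancels in z (documented above, not guessed).
- The KS audit flags the (real) mild skew of the permutation null at high
  n_perm; see the TI section.
- MCD at n ~ 15-20 trims aggressively; the null-study calibration keeps the
  full procedure's type-I rate in view, but small-n grids should be read
  with that caveat.
- Average rereferencing leaks region signals across regions (montage
  algebra); region-level effects are correspondingly conservative
  attributions, not source localizations.
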