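# Methods

`parcelmeg` implements a task-free (resting-state) cortical
electrophysiology analysis in parcel space, together with a synthetic
cohort generator that lets every stage be validated against known ground
truth.  This note records the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Analysis model

### Spectra and band power

Each subject's parcel time courses are standardized (z-transformed per
parcel) and converted to power spectral densities by Welch's method with a
2-s Hann window and 50% overlap (one-sided density normalization), giving a
0.5 Hz frequency grid at the 250 Hz working rate.  Band power is the mean
density over the bins of each canonical band — delta 1–4, theta 4–7, alpha
7–13, beta 13–30, low-gamma 30–48 and high-gamma 52–80 Hz — with half-open
bin assignment `f_lo <= f < f_hi`.  The 48–52 Hz mains gap sits between the
gamma bands by construction.  Mean (rather than integrated) in-band density
was chosen; this affects only the scale of the feature, not any statistic,
because inference is always per band.

### Aperiodic (1/f) parameterization

The PSD between 1 and 70 Hz is decomposed into an aperiodic component and
Gaussian oscillatory peaks:

    log10 PSD(f) = b − χ·log10 f + Σ_k h_k exp(−(f − c_k)² / 2 s_k²)

χ is the aperiodic exponent (χ > 0 slopes downward; lower χ = flatter
spectrum), peaks are Gaussian in linear frequency with heights in log10
power.  Fitting is iterative: (1) a robust line fit of log10 PSD on
log10 f — ordinary least squares followed by two passes that drop bins in
the top 2.5% tail of positive residuals, since oscillations only push power
upward; (2) repeated extraction of the largest residual peak until it falls
below max(2.0 × SD of the flattened residuals, 0.05 log units), each peak
fitted as a bounded Gaussian with reported width (2 × SD) clipped to
0.5–12 Hz; (3) a joint refit of all Gaussians; (4) a final robust aperiodic
refit on the peak-subtracted spectrum.  "Unlimited" peaks are implemented
as a cap of 20 with a warning, guarding against pathological spectra.
Gaussian fits use analytic Jacobians.  Brute-force grid-search oracles in
the test suite confirm that the exponent recovered this way matches a
peak-masked two-parameter search to ±0.05 in the presence of a planted
peak, and ±0.02 on exact power laws.

### Leakage correction and connectivity

Source-space parcel time courses are linear mixtures of underlying
sources, so zero-lag leakage inflates amplitude-envelope correlations and
creates "ghost interactions".  Symmetric multivariate orthogonalization
finds the closest (Frobenius) set of mutually uncorrelated time courses by
alternating a closest-orthonormal-matrix step (polar decomposition via SVD)
with a per-parcel least-squares scaling step, to a relative tolerance of
1e−9 (maximum 100 iterations).  Rows are demeaned first and the iteration
provably stays in the zero-mean subspace, so orthogonality and zero-lag
decorrelation coincide exactly (pairwise |r| at machine precision).  The
correction is applied once, broadband, before any band filtering.

Connectivity per band is the amplitude envelope correlation (AEC): Pearson
correlation between Hilbert envelopes of zero-phase Butterworth (order 5)
band-passed parcel signals, with the first and last second discarded before
correlating (Hilbert edge ringing).  Envelopes are kept at full rate and
are not log-transformed.  Per parcel the AEC matrix is summarized as a
global mean (all other parcels), an intra-hemispheric mean, an
inter-hemispheric mean, and their contrast (inter − intra); by
construction the global mean is the connection-count-weighted average of
the other two.

### Conditioning

When raw-rate input is ingested, the conditioning stage applies mains
notches at 50/100 Hz (IIR, Q = 30, zero-phase), polyphase resampling to
250 Hz, automated bad-segment excision, and a 1–80 Hz band-pass
(Butterworth order 5, zero-phase).  Bad segments are flagged by a robust
outlier rule: non-overlapping 1-s windows whose parcel-average log variance
exceeds the median by more than 5 MADs, merged when adjacent; a recording
with more than the configured fraction of bad windows (default 50%) is
rejected as unusable.  Note the median/MAD rule, like any 50%-breakdown
estimator, can only flag a *minority* of outlying windows; the unusable
threshold is therefore configurable, and the synthetic cohorts (already
clean and at 250 Hz) skip this stage by default.

### Permutation GLM with max-statistic FWE control

Each metric (band power, exponent, AEC summaries) is analysed per parcel ×
band by a separate OLS GLM.  The group design uses ALS and control
indicator columns with a two-tailed ALS − control contrast; score designs
replace the indicators with a single clinical-score column (controls fixed
at 0; scores: 48 − ALSFRS-R, UMN, or δALSFRS-R = (48 − ALSFRS-R)/years
since onset) plus an intercept.  Age, sex and handedness enter as
mean-centered confounds (sex/handedness as centered ±0.5 indicators); a
confound that is constant across the cohort is dropped as uninformative.
Residual degrees of freedom are reported as n − rank(X).

Family-wise error is controlled by the maximum-statistic method: per
permutation the rows of the interest regressors are jointly shuffled
(confounds fixed — simple permutation; the scheme is isolated in one place
and can be swapped), every cell refitted, and max |t| recorded over all
parcels × bands.  Corrected p-values use the (1 + #{null ≥ |t|})/(n_perm+1)
estimator, so p is never exactly 0 and ties count toward the null; the
difference from the raw proportion is at most 1/(n_perm + 1).  An observed
statistic more extreme than exactly 95% of the null maxima receives
p = 0.05 up to that correction.

### Severity prediction

Change-from-baseline ALSFRS-R (48 − ALSFRS-R) is predicted in the patient
group from the full feature set (all pairwise band-wise AEC values, all
per-parcel band powers, all per-parcel exponents) by a random-forest
regressor under nested leave-one-out cross-validation.  Inside each outer
training fold, greedy forward stepwise selection maximizes 5-fold
cross-validated R² (pooled out-of-fold predictions), stopping at the first
non-improving addition with ties broken toward the earlier column.  A full
stepwise search over thousands of raw features per fold is intractable, so
candidates are pre-screened inside each training fold to the `pool_size`
columns most correlated with the training targets (default 50); the screen
never sees the held-out subject.  Forest defaults are 500 trees, √p
features per split, unrestricted depth; a smaller forest may be used for
candidate *scoring* (`selection_estimators`) since selection only ranks
subsets — the per-fold final model always uses the full forest.  Out-of-
fold predictions are pooled and compared with the true targets by linear
regression; the reported R² equals the squared Pearson correlation of the
two vectors.  The result also carries the out-of-fold coefficient of
determination (1 − SS_res/SS_tot), which unlike the squared correlation
goes negative when predictions are worse than the target mean; it is the
right quantity for null checks, because LOOCV predictions on unpredictable
targets are systematically *anti*-correlated with the truth and squaring
that artifact produces a heavy nonnegative tail.  Forward (rather than
backward or bidirectional) selection was chosen as the simplest reading of
"stepwise".

## Synthetic cohort generator

Each parcel time course is

    x_p(t) = Σ_b A_pb · m_pb(t) · c_pb(t) + s · a_p(t)

* **Carriers** `c`: white noise band-passed by a 4th-order Butterworth at
  the canonical band edges, then divided by its instantaneous Hilbert
  amplitude (constant modulus).  The product with the modulator is
  band-passed a second time, because both the constant-modulus step and the
  amplitude modulation regrow spectral sidebands; the re-filter keeps
  cross-band leakage negligible.  Constant-modulus carriers make the band
  envelope equal the modulator itself, which is what makes planted envelope
  correlations up to ~0.9 reachable — with stochastic Rayleigh-like carrier
  envelopes the maximum attainable AEC is only ~0.6.
* **Modulators** `m`: rectified (<1 Hz low-pass, Butterworth order 2)
  Gaussian noises.  Envelope coupling within a group of parcels is induced
  by mixing one shared modulator into each member with weight w; w is
  calibrated by bisection against the *measured* AEC of a miniature
  two-parcel subject that contains all bands and the aperiodic background
  (so neighbor-band and background dilution are accounted for), averaged
  over three fixed-seed 240-s calibration runs and cached per
  configuration.  A target above what the signal model can reach raises an
  error.
* **Aperiodic background** `a`: synthesized in the frequency domain
  (amplitude ∝ f^(−χ/2), uniform random phases) so its spectrum is an exact
  power law.  Content below 1 Hz is omitted: preprocessing high-passes it
  anyway, and including it would let the divergent ultra-slow part of the
  power law swallow the unit-SD normalization, making the in-band
  background (and any planted exponent effect) invisible.
* **Edge handling**: every filtered realization is generated with a 3-s
  burn-in margin at each end which is discarded before normalization.
  Zero-phase filtering of finite records otherwise concentrates large
  transients at the record edges; those transients both steal variance from
  the interior and fall where Welch's window coverage is lowest, which was
  measured to bias band power low by tens of percent with ~60% log-scale
  noise before the margin was introduced.

Default signal parameters emulate a resting MEG spectrum: background
χ = 1.5 with unit in-band SD; band amplitudes delta 0.35, theta 0.30, alpha
0.80, beta 0.60, low-gamma 0.18, high-gamma 0.15 (pronounced alpha peak,
clear beta hump, modest gamma).  Between-subject variability is a 10%
log-normal jitter on each band amplitude and a 0.1 SD normal jitter on χ —
spreads under which the planted effect sizes below are reliably detectable
at the study's sample sizes, consistent with a cohort in which such effects
were in fact found.

Planted effects scale band power multiplicatively (factor per unit of a
driving covariate: group indicator, 48 − ALSFRS-R, or UMN), shift χ
additively, or raise envelope-coupling targets within named ROI groups.
The default "study" effect structure is a 30% sensorimotor beta power
reduction and a 30% frontal high-gamma increase with group, a −0.3 frontal
exponent flattening with group, and temporal theta envelope
hyperconnectivity rising 0.005 per unit of 48 − ALSFRS-R above a 0.05 base.
The ground-truth record distinguishes *primary* affected cells from
*secondary* ones — cells that move as a physical consequence of a planted
effect: an exponent shift redistributes background power across every band
of the affected parcels, and a band-power change alters the parcel's total
variance and hence the relative (z-scored) power of its other bands.
Recovery tests count secondary cells neither as detections nor as false
positives.

Covariate marginals match the emulated cohort: 36 ALS / 51 controls from 92
recruited (4 excluded for missing scans, 1 for an unusable recording); age
~ N(61, 11) truncated to 35–85; 65% male; 91% right-handed; ALSFRS-R ~
round(N(37.6, 7)) clipped to 10–48; UMN ~ round(N(9, 4.4)) clipped at 0;
years from onset log-normal matched to mean 2.1 y, SD 1.3 y.  One master
seed drives everything; per-subject seeds are spawned from
`numpy.random.SeedSequence(seed)` in subject order.

### What the generator does not emulate

No sensor-space physics (forward model, beamformer weights, tSSS
artefacts), no head movement, no genuine spatial leakage between parcels
(leakage is only introduced explicitly in test fixtures), no non-stationary
state switching, no phase coupling, and no realistic artefact families
(blinks, cardiac).  Band oscillations are amplitude-modulated
constant-modulus processes rather than Gaussian — their envelopes are
exactly the modulators, which is a deliberate idealization so that planted
envelope correlations are well-defined.  A passing validation therefore
shows the *analysis machinery* is correct and calibrated under a plausible
signal model; it cannot show robustness to real acquisition artefacts.

## Validation problem sizes

The validation suite scales simulations to desk size; all are package
choices recorded here:

* Family-wise error calibration: 200 exchangeable null cohorts of 16
  subjects (8/8), 6 parcels, 20-s recordings, 500 permutations; the
  fraction of cohorts with any corrected p < 0.05 must fall in the 95%
  binomial band around 0.05 (0.020–0.080).
* Effect recovery: 50 cohorts at the full 36/51 group sizes, 6 parcels,
  26-s recordings, 500 permutations; planted beta and exponent effects must
  be flagged in ≥80% of affected cells, with ≤5% significance among cells
  untouched by any planted effect (primary or secondary).
* Envelope-correlation calibration: 480-s subjects (the study's own
  recording length), one coupled homologue pair at target 0.5 in beta.
* Prediction sanity: 36 subjects × 200 features with a 5-feature
  dominant-weight linear target (mean out-of-fold coefficient of
  determination over 3 seeds ≥ 0.5), and 50 permuted-target runs at 36
  subjects (95th percentile of the determination coefficient < 0.2);
  forests are scaled down (≤150 trees, candidate pools of 3–5) for these
  runs.

Shorter recordings inflate feature noise relative to the 8–10-minute
recordings the defaults emulate, so these runs understate the power
attainable at full length — detection thresholds were chosen to pass with
margin under the scaled conditions, not tuned to them.

## Known limitations

* The Welch design decision of 50% overlap interacts with slowly modulated
  signals through the Hann² weighting comb; with the burn-in fix the
  residual effect is ~2–3% on band power and is ignored.
* Simple permutation (interest columns shuffled, confounds fixed) can
  inflate error slightly when confounds correlate strongly with the
  interest regressor; the scheme is isolated in `permutation_maxt` so a
  Freedman–Lane variant can be dropped in.
* Coupling groups may not overlap within a band (one shared modulator per
  group); overlapping coupling topologies would need a multi-factor
  envelope model.
* The median/MAD bad-segment rule cannot flag a majority-bad recording;
  the unusable-recording error fires relative to the configured
  `max_bad_fraction`.
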