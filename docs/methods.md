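# Methods

This note documents the models and procedures implemented in `biosigkit`,
the defaults that matter, the design choices that were genuinely open, and
what the synthetic test signals do and do not establish.

## File format layer

The GDF-v2 subset is specified field-by-field in `FORMAT.md`: a 256-byte
fixed header, 256 bytes of channel metadata per channel, an optional
tag-length-value (TLV) header carried as opaque blobs, raw data records,
and a trailing event table. All numerics are little-endian; the version
string `GDF 2.20` sits at byte 0 so format detection reads only the
leading bytes. Supported sample types are int16 and float32; anything
else is rejected loudly. Calibration is affine per channel
(`gain = (phys_max − phys_min)/(dig_max − dig_min)`), so int16 round-trips
are exact to one quantization step and float32 round-trips are bit-exact
when the stored values are float32-representable. Event tables come in
mode 1 (position, code) and mode 3 (adding channel and duration); sample
indices are 0-based, epoch windows half-open, times in seconds. The
published GDF 2.x standard does not print every field offset, so this
layout is self-consistent rather than guaranteed bit-compatible with other
GDF readers; the contract verified by the tests is self-roundtrip plus the
structural constants (256-byte headers, 256·n_channels variable header).

EDF reading follows the public EDF specification (ASCII headers, 16-bit
little-endian records); EDF+ annotation channels are skipped and this is
the documented behaviour. Channels may have different samples-per-record
and are calibrated at their own rates — this is why the reader is
implemented here rather than delegated to readers that resample mixed-rate
files onto a common grid. A test cross-checks the layout against MNE's
EDF reader on a single-rate fixture.

`read_segment` serves block-wise access for recordings larger than
memory: it seeks directly to the records containing the requested span,
and a property test asserts that concatenated blocks equal a full read.

## Preprocessing and quality control

Segmentation cuts half-open windows `[pos − pre, pos + post)` around
events; windows that cross a recording edge are dropped and counted.
Event-related averaging is the plain arithmetic mean, so additive
zero-mean noise is suppressed by 1/√n — the test suite verifies the
ratio across n = 4, 16, 64.

Amplitude histograms use equal-width bins over the channel's digital
range when a channel spec is available (observed range otherwise), with
out-of-range samples folded into the edge bins so counts stay conserved.
The Shannon entropy in bits summarizes the distribution; recordings that
clip show mass piled at the extreme bins and depressed entropy, which is
the basis for choosing saturation thresholds when file headers do not
state the true equipment limits. `detect_saturation` flags samples at or
beyond `[lo, hi]`.

The EMG detector evaluates six parameters per analysis window: maximum
absolute slope (max |Δx|·fs), maximum and minimum amplitude, absolute and
relative power above 25 Hz, and the 0.95 spectral edge frequency.
Spectra use a Hann-window Welch estimate with 1-s segments at 50%
overlap. Thresholds are calibrated from 1-s windows of a reference
period (≥10 s) as mean + 3·SD per parameter (mean − 3·SD for the
amplitude minimum); a window is flagged when **any** criterion fires.
Open choices resolved here: the threshold rule (a "subject distribution"
calibration is required but its exact form was open; mean ± 3·SD flags
≈0.13% of same-distribution windows per one-sided criterion for Gaussian
data), the slope definition, the ANY-combination of criteria, and the
0.95 edge fraction. All are configurable module constants.

## EOG regression

The superposition model Y(t) = E(t) + b·O(t) assumes the ocular signal
reaches each EEG electrode by instantaneous volume conduction with
time- and frequency-independent gains. With cortical EEG and ocular
activity uncorrelated, the least-squares solution is
b = ⟨Y·Oᵀ⟩⟨O·Oᵀ⟩⁻¹ and correction is E = Y − b·O; b minimizes the mean
square of E. Channels are demeaned before estimation by default (the
model has no intercept; the textbook formulation leaves this open and
demeaning is the numerically safer choice). The normal equations are
solved by a linear solve, never an explicit inverse, and a condition cap
of 10⁸ on ⟨O·Oᵀ⟩ rejects near-collinear EOG channel sets with the
offending channels named. An optional zero-phase Butterworth band-pass
(e.g. 0.5–35 Hz) can be applied to both Y and O before estimation to
suppress 1/f amplifier drift and high-frequency noise; it is off by
default so the estimator is exactly the formula above. Because estimates
are least biased when ocular activity dominates other noise, coefficients
should be estimated on a high-EOG segment and can then be applied to the
whole recording — the generator provides quiet/active segments to
exercise exactly this.

## Heart rate

The detector band-passes the ECG at 8–20 Hz (a configurable band that
concentrates QRS energy), takes the envelope as the magnitude of the
analytic signal (Hilbert transform), and thresholds it at 0.5× the 95th
envelope percentile with a 0.25-s refractory period (240 bpm
physiological cap). Instantaneous rate is 60/RR bpm at the second peak
of each pair. For event-related averages the irregular rate series is
linearly interpolated onto a uniform 4-Hz grid first. Ectopic-beat
correction is out of scope; outlier RR intervals (>±30% of a running
median) can be masked by the caller if needed.

## Features

Band power integrates a Welch density (Hann, 1-s segments, 50% overlap)
over a half-open band, making band powers additive over partitions and
Parseval-consistent with the variance to ~3%. Hjorth parameters use the
first-difference definitions (activity = var x, mobility =
√(var Δx / var x) in rad/sample with an explicit Hz conversion,
complexity = mobility(Δx)/mobility(x)); for a sampled sinusoid at ω the
mobility is exactly √(2(1 − cos ω)). The spectral edge frequency
interpolates the cumulative trapezoid power linearly between bins; on a
Hann-estimated pure line the result spreads by the ±2-bin main lobe,
which bounds its resolution. AR coefficients delegate to the MVAR
estimator with one channel.

## MVAR connectivity

Estimation is multichannel least squares on the stacked lag regression
(no automatic order selection; the order is user-fixed, and the sample
floor T > 10·K·p guards ill-posed fits). The innovation covariance is
the residual covariance at T − p − K·p degrees of freedom. The
frequency-domain quantities follow the standard factorization
Ā(f) = I − Σ A_k e^(−i2πfk/fs), H = Ā⁻¹, S = HΣHᴴ/fs on a default
128-point grid over [0, fs/2]; Hermitian symmetry of S is enforced by
construction and asserted in tests.

Coherency, partial coherence (via the inverse spectral matrix), DTF
(row-normalized |H|²) and PDC (column-normalized |Ā|) use the standard
normalizations of their source literature; both squared and unsquared
variants are exposed with squared as default, and the generalized
(innovation-weighted) PDC sits behind a flag with the plain form as
default. The index convention is [i, j] = influence of channel j on
channel i. The three-channel chain scenario makes the measure family's
distinctions concrete: ordinary coherence sees the indirect 1–3 path,
partial coherence removes it, DTF reports the cascade 1→3, PDC only the
direct links 1→2 and 2→3. Zero-lag mixed independent sources (a pure
volume-conduction construction) give |C| > 0 with Im C ≈ 0.

## Evaluation

Cohen's kappa is computed unweighted from the confusion matrix. The
Wolpaw information transfer rate log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1))
is a KL divergence against the uniform distribution and therefore
nonnegative — it is zero at chance and rises again below chance, so
below-chance accuracies return the raw value with a `below_chance` flag
and a warning instead of being clamped. AUC uses the mid-rank
Mann-Whitney statistic (tie-safe, equal to the probability a random
positive outranks a random negative). LDA is the pooled-covariance
discriminant with optional shrinkage toward a scaled identity (default
off); ties break toward the lower class index. Leave-one-out
cross-validation is deterministic; folds whose training set loses a class
are excluded and logged. The benchmark pipeline chains segmentation, log
band power and Hjorth features per channel, LDA and LOO-CV, and reports
the confusion matrix, accuracy, kappa and wall-clock (the latter is
informational only).

## Synthetic data: what it shows and what it does not

The generators realize the models the methods assume: the EOG mixture
satisfies the superposition model exactly (band-limited 1–30 Hz EEG,
<5 Hz EOG with quiet/active halves, artifact variance ≈4.25× EEG variance
on both frontal channels during activity, T = 10⁵ at 125 Hz); the ECG is
a noiseless-by-default Gaussian-QRS impulse train (width ~40 ms) with
scripted RR intervals, optionally rate-modulated ±4 bpm around 63 bpm
over a 30-s task period; MVAR scenarios use oscillatory AR(2) diagonals
(poles at radius √0.6) with coupling gains of 0.6 and are
stability-screened via the companion spectral radius; BCI epochs carry a
class-dependent 10 Hz amplitude (1.0 vs 2.0) in unit noise. Problem
sizes (T = 10⁴–10⁵, 60 trials, 100–200 property repetitions) keep the
full suite in seconds while leaving estimator errors well below the
asserted tolerances.

Passing on these fixtures demonstrates correctness of the algorithms
under their own assumptions. It does not demonstrate performance on real
recordings: real EEG has nonstationary spectra, imperfectly bipolar EOG
with cross-contamination from frontal EEG, amplifier and movement noise,
ectopic beats, and volume-conducted mixtures everywhere — which is why,
for example, near-100% EOG reduction here corresponds to roughly 80% in
practice, and the test asserts only the 80% floor. Head-model forward
simulation and real data are explicitly out of scope.

## Known limitations

* The GDF subset is self-consistent, not certified bit-compatible with
  other GDF implementations; EDF is read-only.
* No time-varying (adaptive) feature or MVAR variants; no significance
  testing (surrogates) for coupling measures.
* Classifiers beyond pooled-covariance LDA (SVM, Naive Bayes, sparse
  discriminants) and mutual-information-based evaluation metrics are not
  implemented.
* The heart-rate module has no ectopic-beat correction or filter-bank
  detector; HRV frequency-domain indices are not provided.
* Sparse/nonequidistant sampling, electrode coordinates and MEG sensor
  orientations are not represented in the format layer.
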