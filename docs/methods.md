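# Methods

## Signal model and preprocessing

Input records are raw PPG sample vectors (arbitrary units), one subject
per row, nominally 2,100 samples at 1 kHz (2.1 s).  Preprocessing is a
Chebyshev type-II bandpass — 4th order, 20 dB stopband attenuation,
band edges `fl = 0.4` Hz and `fh = 8` Hz by default, both
user-selectable — followed by a centered moving average.  Three choices
deserve explanation:

* **Zero-phase application.**  The filter is applied forward–backward
  (`sosfiltfilt`).  Landmark *timing* is the package's product; a
  single-pass IIR filter would delay every landmark by a
  frequency-dependent phase lag and bias all time features.
* **Edge handling.**  At `fl = 0.4` Hz the filter's time constant is
  comparable to the record length, so the startup transient of a
  2.1 s record is not negligible.  The record is mirror-extended
  (`padtype="even"`) over several low-edge time constants
  (`3·fs/fl` samples, capped by the record length) before filtering;
  this brings the response of the finite record close to its periodic
  steady state and keeps the pulse-foot minima where the underlying
  waveform has them.
* **Moving averages.**  MATLAB-style centered `movmean` with shrinking
  edge windows: 50 ms on the filtered pulse and 10 ms on each
  derivative after differencing (both configurable,
  `smooth_window_ppg_ms` / `smooth_window_deriv_ms`).  A centered
  window is symmetric and therefore phase-free; 50 ms leaves the
  0.4–8 Hz passband essentially intact while suppressing
  difference-amplified noise.

Derivatives are iterated first differences (`diff`), each assigned to
the left sample index with the final value repeated so that PPG, VPG,
APG and JPG share one index grid.  With no smoothing the interior
samples satisfy the classic identities
`vpg[t] = y[t+1] − y[t]` and `apg[t−1] = y[t+1] + y[t−1] − 2·y[t]`.
The left-aligned difference shifts derivative features earlier by half
a sample per order (≤ 1.5 ms at 1 kHz for the jerk), which is inside
every tolerance used here.

## Quality index and segmentation

The skewness SQI is the biased (divisor-n) third standardized moment;
a clean pulse — fast systolic upstroke, long diastolic decay — is
right-skewed.  Records supplied with an SQI table are admitted at
`Ssqi ≥ 0.41` (boundary inclusive); without a table the index is
computed from the raw samples and any positive value admits the record
(the "skip SQI" path).  A bias-corrected variant is available behind a
flag.

Pulse onsets are local minima of the filtered, smoothed pulse with
prominence at least 5 % of the record's peak-to-peak range and at
least 0.3 s apart (a 200 bpm ceiling).  The analysed beat is the
inclusive slice between the first two onsets (Min1, Min2); both can be
overridden.  Beats longer than 1,200 samples are analysed in full but
truncated in the zero-padded segment export (and flagged).

## Landmark definitions

All extremum searches use strict inequalities with plateau ties
resolved to the leftmost sample.  Segment-relative indices; O is
sample 0 of the beat.

* **S** — global maximum of the pulse segment (first on ties).
* **w / y** — global maximum of the velocity, and its global minimum
  between w and 60 % of the beat (steepest upstroke/downstroke).  The
  global-extremum reading follows the conventional description of
  these waves and is far more noise-robust than "first local
  extremum".
* **x** — the velocity sample aligned with S (the VPG zero at the
  apex).
* **a / b** — largest APG local maximum in the systolic region (first
  40 % of the beat, configurable) and the deepest minimum after it.
* **e / f** — e is the largest APG local maximum in the notch region
  (35–80 % of the beat).  Where weak c/d oscillations exist this
  coincides with the third jerk zero-crossing after b, and the
  equivalent description "second maximum of the APG" motivates the
  direct APG reading, which stays well-posed when the oscillation is
  absent.  f is the first prominent APG minimum after e.  **N = e**
  and **D = f** on the shared grid.
* **z** — first APG zero-crossing after e; if none exists, the second
  velocity maximum.
* **c / d** — three-regime procedure on the region between b and e,
  restricted to its first 80 % (curvature dips belonging to the notch
  complex itself sit immediately before e and are not c/d
  candidates):
  * *Case III* (prominent pair): APG maximum-then-minimum pair with
    drop ≥ 2 % of the APG peak-to-peak range; c is the pair maximum,
    d the following minimum.
  * *Case I* (jerk-visible oscillation): the jerk has a prominent
    negative minimum inside the region (it crosses zero) and a
    maximum after it; c is the first prominent jerk maximum after b
    and d the first jerk zero-crossing after c.
  * *Case II* (monotone rise): the jerk only dips; its first
    prominent minimum m lies midway between c and d, which are placed
    at `m ∓ round(0.025·T)` samples (T the beat wavelength; rounding
    half away from zero).
  Failure to locate the pair is recorded as `cd_present = 0`, never a
  hard error.

"Prominent" throughout means peak prominence at least 5 % of the local
search window's range — residual in-band noise otherwise hijacks every
"first extremum after X" rule.  The broad notch-region extrema (e, f)
and the Case II jerk minimum are additionally refined to the vertex of
a least-squares parabola over a window of ~3 % of the segment length:
for smooth near-quadratic features the vertex is unbiased and averages
noise over the feature's width.  The window is specified as a fraction
of the analysed segment so the same rule applies at any resolution
(including the oversampled ground-truth grid).

## Features and evaluation

The feature table has exactly 30 columns: magnitudes
O, S, N, D, Min2, w, x, y, z, a, b, c, d, e, f on the waveform owning
each landmark, then the 15 corresponding times in seconds from beat
onset (`O_t = 0` by construction; Min2 is the closing onset).  Missing
c/d are NaN in memory and empty CSV cells.

Evaluation matches each detected landmark to the same-named reference
index within a tolerance (10 ms default).  A mislocated point counts
as FP + FN (configurable to FP only); an undetected reference point is
FN; a detection with no reference is FP.  With TFP the total reference
count (14 per complete beat):
`Acc = 100·TP/(TP+FP+FN)`, `Err = 100·(FP+FN)/TFP`,
`S = 100·TP/(TP+FN)`, `PP = 100·TP/(TP+FP)`.  Reports are stratified
by the regime the detector assigned, plus a pooled row from summed
counts.  Display rounding is half-away-from-zero to 2 decimals; raw
doubles are kept in machine output.

## Synthetic data

Beats are sums of Gaussian components, the standard synthetic PPG
construction, with closed-form derivatives.  The default morphology
uses five components — systolic upstroke, systolic peak mass,
late-systolic filler, dicrotic wave, diastolic decay — on a 1.3 s beat
(≈ 46 bpm), one full beat per 2,100-sample record.  Component
placements were chosen once so that (i) every landmark is carried by a
feature whose spectral content lies inside the 0.4–8 Hz passband and
whose local curvature pins it against in-band noise, (ii) the record's
raw skewness clears the 0.41 inclusion threshold, and (iii) a single
knob — the amplitude of a narrow late-systolic bump — moves the beat
through the three c/d regimes (0 → Case II, small → Case I, large →
Case III).

Ground truth applies the landmark definitions above to the *exact*
continuous-model derivatives on a 10×-oversampled grid — never to the
discrete detector path — so sampling, filtering, differencing and
smoothing are all checked against an independent oracle.  Records
place phantom beats beyond both edges so record boundaries look like
ordinary inter-beat joins; onset truth is the continuous model's
minimum near each join.  White Gaussian noise (parametrised as SNR
against the clean AC signal; 20 dB benchmark default), sinusoidal
baseline drift (0.12 a.u. at 0.25 Hz by default, inside the filter's
stopband) and truncation to exactly 2,100 samples complete the record.
Noise and drift never alter the ground truth.

Benchmarks draw each subject's regime multinomially (default
proportions 140/54/25 over Cases I/II/III) and vary subjects by pulse
amplitude (±20 % gain), heart rate (±6 % beat length) and mild
component-amplitude jitter (±2 %).  Gain and tempo dominate real
inter-subject spread and are exactly morphology-preserving; larger
shape jitter would let subjects drift across regime boundaries, making
the reference label itself ambiguous.

What passing synthetic tests does **not** show: robustness to motion
artifacts, arrhythmia, sensor nonlinearities, or morphologies outside
the Gaussian-sum family; the generator's beats are cleaner and more
stereotyped than clinical data, and its noise is white rather than
physiological.

**Known limitation — derivative landmarks under heavy noise.**  The
benchmark's noise condition (white noise at 20 dB SNR relative to the
clean AC signal) is severe for landmarks defined on the second and
third derivatives of a *single* beat.  Differencing multiplies noise
at frequency f by ~(2πf/fs) per order, so the in-band (0.4–8 Hz)
noise that survives the bandpass is amplified exactly where the
subtle c/d oscillation and the notch curvature peak live, and the
localization error of an extremum scales as the ratio of the local
noise slope to the feature's curvature — which the 8 Hz passband caps.
In this regime the c, d and (to a lesser degree) e/N landmarks jitter
by 10–30 ms per beat, and the regime classification statistic (an APG
drop of 2 % of range) has noise of comparable size to its own
threshold, so borderline subjects flip class.  Multi-beat averaging
would remove most of this but is deliberately out of scope (the
method is single-beat).  Consequently, pooled detection accuracy on
the noisy synthetic benchmark at 10 ms tolerance sits well below the
clean-signal performance; the exact value for a given seed is
computed by `scripts/acceptance.py`.  On clean beats the full rule
set recovers every landmark within ±1 ms of the continuous-model
truth.

## Numerical and design notes

* Onset indices and all exported sample indices are converted to
  1-based exactly once, at the CSV boundary; everything internal is
  0-based.
* CSV floats are written as `%.17g` (bit-exact round-trip through
  text).
* The clean-beat recovery check runs the landmark search directly on
  the noiseless sampled beat (no bandpass): with nothing to remove,
  the filter stage only measures its own edge distortion, whereas the
  check's purpose is to verify the discrete landmark rules against the
  continuous-model oracle (within ±3 ms).
* Degenerate inputs: flat or monotone segments are flagged invalid
  (all-NaN feature row) rather than raising; zero-variance records are
  rejected at the SQI stage; a failed beat never aborts a batch run.
* Problem sizes in the test-suite and acceptance runs (219 subjects,
  one analysed beat each, 2,100 samples) mirror the reference dataset
  geometry this package is designed around.
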