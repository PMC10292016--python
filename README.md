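# ppgfid

Fiducial-point extraction and feature tables for photoplethysmography
(PPG) waveforms.

A PPG pulse carries a set of named landmarks that cardiovascular
research builds on: the onset **O**, systolic peak **S**, dicrotic
notch **N** and diastolic peak **D** on the pulse itself; **w, x, y, z**
on the velocity waveform (VPG, first derivative); and the classical
**a–f** waves on the acceleration waveform (APG, second derivative).
Ratios and timings of these points feed estimates of blood pressure,
arterial stiffness and vascular age.  The hard part is the late-systolic
**c** and **d** waves, whose prominence varies strongly between
subjects.  `ppgfid` implements a complete, automated extraction
pipeline for all 14 landmarks:

1. **Preprocessing** — Chebyshev type-II bandpass (4th order, 20 dB,
   0.4–8 Hz by default) applied forward–backward (zero-phase), plus a
   centered moving average; derivatives up to the jerk waveform (JPG)
   as iterated first differences.
2. **Quality gating and segmentation** — records are admitted on the
   skewness signal-quality index `Ssqi = E[((x−μ)/σ)³]` (threshold
   0.41); pulse onsets are prominent local minima, and the analysed
   beat is the slice between the first two onsets (Min1, Min2).
3. **Landmark search** — O/S on the pulse, w/x/y/z on the velocity,
   a/b/e/f on the acceleration, with N = e and D = f on the shared
   index grid.  The c/d waves are located by a three-regime procedure
   on the region between the b and e waves:
   * **Case III** – prominent APG maximum–minimum pair: read off directly;
   * **Case I** – the oscillation survives only in the jerk: c is the
     first jerk maximum after b, d the following jerk zero-crossing;
   * **Case II** – the jerk merely dips: its minimum m lies midway
     between c and d, which are placed at m ± 2.5 % of the beat
     wavelength T.
4. **Features** — a 30-column table per subject: 15 magnitudes
   (O, S, N, D, Min2, w, x, y, z, a–f) and 15 times from beat onset.
5. **Evaluation** — per-point tolerance matching against reference
   annotations and the standard detector metrics
   `Acc = 100·TP/(TP+FP+FN)`, `Err = 100·(FP+FN)/TFP`,
   `S = 100·TP/(TP+FN)`, `PP = 100·TP/(TP+FP)`, stratified by c/d
   regime.
6. **Synthetic data** — a Gaussian-sum beat model with closed-form
   derivatives generates records with analytically known ground truth
   for all 14 landmarks, controllable Case I/II/III morphology, white
   noise and baseline drift, so the whole pipeline is testable without
   any external dataset.

## Worked example

```python
import ppgfid

# a synthetic 12-subject benchmark with known ground truth
dataset, reference = ppgfid.make_benchmark(12, seed=7)

result = ppgfid.extract_dataset(dataset)
print(result.feature_table.loc["S001", ["S_t", "N_t", "a_t", "e_t"]])
# S_t    0.304
# N_t    0.613
# a_t    0.118
# e_t    0.613
# Name: S001, dtype: float64

from ppgfid.evaluation import evaluate_extraction
report = evaluate_extraction(result, reference, tol=0.010)
print(report.round(2))
#          N  TFP   TP  FP  FN  S_pct  PP_pct  Err_pct  Acc_pct
# case
# I       11  154  134  20  20  87.01   87.01    25.97    77.01
# III      1   14   12   2   2  85.71   85.71    28.57    75.00
# pooled  12  168  146  22  22  86.90   86.90    26.19    76.84
```

`S_t = 0.304` s means the systolic peak occurs 304 ms after the beat
onset; `N_t = e_t` because the dicrotic notch is located through the
APG e wave.  The report table gives per-regime and pooled counts (TP,
FP, FN out of 14 reference points per beat) and the four percentages
above.  The default benchmark is deliberately harsh — 20 dB of
additive white noise on single 2.1 s records — and accuracy at a 10 ms
tolerance is dominated by the second- and third-derivative landmarks
(c, d, e), whose localization noise grows with each differentiation;
on clean beats every landmark is recovered to within 1 ms (see
`docs/methods.md`).

The same pipeline is available from the shell:

```bash
ppgfid simulate -n 219 --seed 1 --outdir sim/
ppgfid extract sim/ppg.csv --sqi-csv sim/sqi.csv --outdir out/
ppgfid evaluate out/ sim/reference.csv --tol 0.01
```

`extract` writes the six-file output suite (`PPG_features.csv`,
`PPG_Filtered_HighSQI.csv`, `PPG_Segments.csv`, `APG_Segments.csv`,
`ID_min1_min2.csv`, `c_d_presence.csv`); sample indices in the files
are 1-based.

As a scikit-learn transformer:

```python
from ppgfid import FiducialFeatureExtractor
est = FiducialFeatureExtractor(fs=1000, fl=0.4, fh=8.0)
X30 = est.fit(X).transform(X)   # (n_subjects, 2100) -> (n_subjects, 30)
```

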