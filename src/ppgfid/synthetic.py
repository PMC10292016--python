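"""Synthetic PPG records with analytically known fiducial ground truth.

Beats are modelled as sums of Gaussian pulses — the standard synthetic
PPG construction — so the waveform and its first three derivatives are
available in closed form.  Ground truth for the 14 landmarks is obtained
by applying the definitional landmark rules to the *exact* continuous
derivatives on a grid oversampled 10x relative to the sampling rate,
never by running the discrete detector; the detector's filtering,
differencing and smoothing path is therefore checked against an
independent oracle.

A single knob, the amplitude of a narrow late-systolic bump, steers the
morphology through the three c/d regimes: a large bump leaves prominent
c/d extrema in the acceleration waveform (Case III), a small bump leaves
only a jerk-visible oscillation (Case I), and no bump leaves a monotone
acceleration rise whose jerk merely dips (Case II).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fiducials as _fid
from .errors import ParameterError
from .signal_io import Dataset, SubjectRecord

__all__ = [
    "BeatParams",
    "GroundTruth",
    "case_params",
    "simulate_beat",
    "simulate_record",
    "make_benchmark",
]

OVERSAMPLE = 10
DEFAULT_CASE_MIX = (140 / 219, 54 / 219, 25 / 219)


@dataclass(frozen=True)
class BeatParams:
    """Continuous beat model: Gaussian components on a beat of ``beat_s`` s.

    Each component is ``(amplitude a.u., center as fraction of the beat,
    width sigma as fraction of the beat)``.  ``bump_amplitude`` scales an
    extra narrow late-systolic component controlling c/d prominence.
    """

    components: tuple = (
        (0.8247, 0.1222, 0.0640),   # systolic upstroke (sharp rising edge)
        (0.8334, 0.1880, 0.0971),   # systolic peak mass (slower falling limb)
        (0.2681, 0.3181, 0.1176),   # late-systolic filler
        (0.3927, 0.4918, 0.0644),   # dicrotic (diastolic) wave
        (0.4616, 0.7041, 0.1075),   # diastolic decay reaching the next onset
    )
    beat_s: float = 1.3
    bump_amplitude: float = 0.0
    bump_center_frac: float = 0.2921
    bump_width_frac: float = 0.0685
    seed: int = 0

    def __post_init__(self):
        if len(self.components) < 2:
            raise ParameterError("need at least systolic + dicrotic components")
        centers = [c for _, c, _ in self.components]
        if any(a < 0 for a, _, _ in self.components) or self.bump_amplitude < 0:
            raise ParameterError("component amplitudes must be non-negative")
        if not all(c1 < c2 for c1, c2 in zip(centers, centers[1:])):
            raise ParameterError("component centers must be strictly increasing")
        if self.beat_s <= 0:
            raise ParameterError("beat length must be positive")

    def absolute_components(self, t_offset: float = 0.0) -> list[tuple[float, float, float]]:
        """Components as (amplitude, center s, sigma s) in absolute time."""
        comps = [
            (a, t_offset + c * self.beat_s, w * self.beat_s)
            for a, c, w in self.components
        ]
        if self.bump_amplitude > 0:
            comps.append(
                (
                    self.bump_amplitude,
                    t_offset + self.bump_center_frac * self.beat_s,
                    self.bump_width_frac * self.beat_s,
                )
            )
        return comps


@dataclass
class GroundTruth:
    """Record-coordinate sample indices of the 14 landmarks of one beat."""

    indices: dict = field(default_factory=dict)
    case_label: str = ""
    onset: int = 0
    next_onset: int = 0


def case_params(case: str) -> BeatParams:
    """Archetype beat parameters for the three c/d regimes."""
    if case == "III":
        return BeatParams(bump_amplitude=0.18)
    if case == "I":
        return BeatParams(bump_amplitude=0.08)
    if case == "II":
        return BeatParams(bump_amplitude=0.0)
    raise ParameterError(f"unknown case {case!r}")


def _model(t: np.ndarray, comps: list[tuple[float, float, float]], order: int) -> np.ndarray:
    """Evaluate the Gaussian-sum model or one of its first 3 derivatives."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for amp, mu, sig in comps:
        u = (t - mu) / sig
        g = amp * np.exp(-0.5 * u * u)
        if order == 0:
            out += g
        elif order == 1:
            out += -g * u / sig
        elif order == 2:
            out += g * (u * u - 1.0) / sig**2
        elif order == 3:
            out += g * u * (3.0 - u * u) / sig**3
        else:  # pragma: no cover
            raise ParameterError(f"unsupported derivative order {order}")
    return out


def _truth_from_window(
    comps: list[tuple[float, float, float]],
    t0: float,
    t1: float,
    fs: float,
) -> GroundTruth:
    """Apply the definitional landmark rules to exact derivatives on a
    10x-oversampled grid spanning one beat window [t0, t1]."""
    step = 1.0 / (fs * OVERSAMPLE)
    grid = np.arange(t0, t1 + step / 2, step)
    p = _model(grid, comps, 0)
    v = _model(grid, comps, 1)
    a = _model(grid, comps, 2)
    j = _model(grid, comps, 3)

    def to_sample(i: int) -> int:
        return int(round(grid[i] * fs))

    from .errors import DetectionError

    idx: dict = {name: None for name in _fid.POINT_NAMES}
    idx["O"] = 0
    idx["S"] = int(np.argmax(p))
    case = ""
    # degenerate morphologies (e.g. a lone pulse) legitimately lack the
    # later landmarks; truth is then partial rather than an error
    try:
        idx["a"], idx["b"] = _fid.detect_ab(a)
        idx["e"], idx["f"] = _fid.detect_ef(a, j, idx["b"])
        case = _fid.classify_case(a, j, idx["b"], idx["e"])
        idx["c"], idx["d"], _ = _fid.locate_cd(case, a, j, idx["b"], idx["e"], T=grid.size)
        idx["N"], idx["D"] = _fid.map_ND(idx["e"], idx["f"])
        idx["w"], idx["x"], idx["y"], idx["z"] = _fid.detect_vpg_points(
            v, idx["S"], a, idx["e"]
        )
    except DetectionError:
        pass
    truth = GroundTruth(case_label=case)
    truth.indices = {
        k: (to_sample(i) if i is not None else None) for k, i in idx.items()
    }
    truth.onset = int(round(t0 * fs))
    truth.next_onset = int(round(t1 * fs))
    return truth


def simulate_beat(params: BeatParams, fs: float = 1000.0) -> tuple[np.ndarray, GroundTruth]:
    """One noiseless sampled beat plus its continuous-model ground truth.

    The beat is evaluated standalone on [0, beat_s); its onset is the
    first sample by construction.
    """
    comps = params.absolute_components(0.0)
    n = int(round(params.beat_s * fs))
    t = np.arange(n) / fs
    samples = _model(t, comps, 0)
    if np.ptp(samples) == 0 or np.argmax(samples) in (0, n - 1):
        raise ParameterError("degenerate morphology: beat has no interior pulse")
    truth = _truth_from_window(comps, 0.0, (n - 1) / fs, fs)
    return samples, truth


def simulate_record(
    n_beats: int,
    params: BeatParams,
    noise_sd: float = 0.0,
    drift: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    fs: float = 1000.0,
    total_len: int | None = 2100,
    subject_id: str = "S001",
    lead_s: float = 0.4,
) -> tuple[SubjectRecord, list[GroundTruth]]:
    """A record of ``n_beats`` identical beats with noise and drift.

    Phantom beats are placed before the first and after the last beat so
    the record's edges look like ordinary inter-beat joins; ``lead_s``
    seconds of the leading phantom's tail precede the first onset.  White
    Gaussian noise (``noise_sd``) and a sinusoidal baseline drift
    ``(amplitude, frequency Hz)`` are added on top of the clean model;
    neither changes the ground truth, which is computed from the noiseless
    continuous model.  ``total_len`` pads (with the continuing model tail)
    or truncates to an exact sample count.
    """
    if n_beats < 1:
        raise ParameterError("need at least one beat")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    beat = params.beat_s
    comps: list[tuple[float, float, float]] = []
    for k in range(-1, n_beats + 1):  # includes phantom beats at both ends
        comps.extend(params.absolute_components(lead_s + k * beat))
    n = int(round((2 * lead_s + n_beats * beat) * fs))
    if total_len is not None:
        n = int(total_len)
    t = np.arange(n) / fs
    clean = _model(t, comps, 0)

    # exact onset times: minima of the continuous model around each join
    onset_times = []
    for k in range(n_beats + 1):
        join = lead_s + k * beat
        w0 = max(join - 0.25 * beat, 0.0)
        w1 = join + 0.25 * beat
        g = np.arange(w0, w1, 1.0 / (fs * OVERSAMPLE))
        onset_times.append(float(g[np.argmin(_model(g, comps, 0))]))

    # _truth_from_window works on the absolute time grid, so the indices
    # it returns are already record coordinates
    truths = [
        _truth_from_window(comps, onset_times[k], onset_times[k + 1], fs)
        for k in range(n_beats)
    ]

    samples = clean.copy()
    amp_d, f_d = drift
    if amp_d:
        samples = samples + amp_d * np.sin(2 * np.pi * f_d * t + rng.uniform(0, 2 * np.pi))
    if noise_sd:
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    record = SubjectRecord(subject_id=subject_id, samples=samples, fs=fs)
    return record, truths


def _jitter(params: BeatParams, rng: np.random.Generator) -> BeatParams:
    """Seeded inter-subject variability that preserves the archetype.

    Subjects differ in pulse amplitude (global gain), heart rate (time
    scale) and mild component-amplitude variation.  Gain and tempo are
    the dominant sources of real inter-subject spread and leave the
    waveform's morphology class untouched; per-component shape changes
    are kept small so a subject never drifts across a c/d regime
    boundary.
    """
    gain = 1 + rng.uniform(-0.20, 0.20)
    comps = tuple(
        (gain * a * (1 + rng.uniform(-0.02, 0.02)), c, w)
        for a, c, w in params.components
    )
    return replace(
        params,
        components=comps,
        beat_s=params.beat_s * (1 + rng.uniform(-0.06, 0.06)),
        bump_amplitude=gain * params.bump_amplitude * (1 + rng.uniform(-0.04, 0.04)),
    )


def make_benchmark(
    n_subjects: int,
    case_mix: tuple[float, float, float] = DEFAULT_CASE_MIX,
    seed: int = 0,
    fs: float = 1000.0,
    snr_db: float | None = 20.0,
    drift: tuple[float, float] = (0.12, 0.25),
    n_beats: int = 1,
    total_len: int = 2100,
) -> tuple[Dataset, pd.DataFrame]:
    """A seeded multi-subject dataset plus its reference annotation table.

    Cases are drawn multinomially with probabilities ``case_mix``
    (defaulting to the 140/54/25 proportions of the three regimes).
    ``snr_db`` sets white-noise power relative to the clean AC signal
    power; ``None`` disables noise.  The reference table holds the
    record-coordinate indices of the 14 landmarks of the *first* full
    beat — the one the extraction pipeline analyses — plus the morphology
    regime under ``case``.
    """
    if n_subjects < 1:
        raise ParameterError("need at least one subject")
    if abs(sum(case_mix) - 1.0) > 1e-9 or any(p < 0 for p in case_mix):
        raise ParameterError(f"case mix must be non-negative and sum to 1, got {case_mix}")
    rng = np.random.default_rng(seed)
    labels = np.array(["I", "II", "III"])
    records, rows = [], []
    for i in range(n_subjects):
        case = labels[rng.choice(3, p=case_mix)]
        params = _jitter(case_params(case), rng)
        sid = f"S{i + 1:03d}"
        clean_rec, _ = simulate_record(
            n_beats, params, noise_sd=0.0, drift=(0.0, 0.0),
            seed=0, fs=fs, total_len=total_len, subject_id=sid,
        )
        ac = clean_rec.samples - clean_rec.samples.mean()
        noise_sd = 0.0
        if snr_db is not None:
            noise_sd = float(np.sqrt(np.mean(ac**2)) / 10 ** (snr_db / 20))
        rec, truths = simulate_record(
            n_beats, params, noise_sd=noise_sd, drift=drift,
            seed=int(rng.integers(0, 2**31 - 1)), fs=fs,
            total_len=total_len, subject_id=sid,
        )
        records.append(rec)
        tr = truths[0]
        row = {"subject_id": sid, **tr.indices, "case": tr.case_label}
        rows.append(row)
    reference = pd.DataFrame(rows).set_index("subject_id")
    sqi = {r.subject_id: float(_skew(r.samples)) for r in records}
    return Dataset(records=records, sqi=sqi), reference


def _skew(x: np.ndarray) -> float:
    mu, sd = x.mean(), x.std()
    return float(np.mean(((x - mu) / sd) ** 3)) if sd else 0.0
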