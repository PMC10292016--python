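"""Location of the 14 named landmarks on one beat.

The pulse waveform carries the onset O, systolic peak S, dicrotic notch N
and diastolic peak D.  The velocity waveform carries w (steepest upstroke),
x (the velocity zero at the systolic apex), y (steepest downstroke) and z.
The acceleration waveform carries the classical a-f waves.  N and D are
not searched on the pulse directly: they share indices with the APG e and
f waves, which mark the same systole-to-diastole transition far more
sharply.

The late-systolic c and d waves are the hard part.  Their prominence in
the APG varies between subjects, so three regimes are distinguished in
the region between the b and e waves:

* Case III — c and d are prominent APG extrema and are read off directly;
* Case I   — c and d survive only as a small oscillation: the jerk (JPG)
  crosses zero inside (b, e) and c is taken as the first JPG maximum
  after b with d at the JPG zero-crossing that follows;
* Case II  — the APG rises monotonically from b to e and the oscillation
  survives only as a dip in the jerk: its minimum m sits midway between
  c and d, which are placed at m -/+ 2.5% of the beat wavelength T.

All extremum searches use strict inequalities with plateau ties resolved
to the leftmost sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateBeatError, DetectionError, ParameterError
from .preprocess import DerivativeStack

__all__ = [
    "POINT_NAMES",
    "FiducialSet",
    "local_maxima",
    "local_minima",
    "zero_crossings",
    "refine_extremum",
    "detect_O_S",
    "detect_vpg_points",
    "detect_ab",
    "detect_ef",
    "classify_case",
    "locate_cd",
    "map_ND",
    "extract_fiducials",
]

#: The 14 named fiducial points, in canonical order.
POINT_NAMES = ("O", "S", "N", "D", "w", "x", "y", "z", "a", "b", "c", "d", "e", "f")

#: Waveform owning each point's amplitude.
POINT_WAVEFORM = {
    "O": "ppg", "S": "ppg", "N": "ppg", "D": "ppg",
    "w": "vpg", "x": "vpg", "y": "vpg", "z": "vpg",
    "a": "apg", "b": "apg", "c": "apg", "d": "apg", "e": "apg", "f": "apg",
}

SYSTOLIC_REGION_FRAC_DEFAULT = 0.4
#: Search window for the APG e wave (dicrotic-notch region), as fractions
#: of the segment length.  Separates the notch from the late-systolic
#: c/d region, whose maxima can rival the notch curvature peak.
NOTCH_REGION_DEFAULT = (0.35, 0.80)
#: The steepest-descent (VPG y) search ends at this fraction of the beat.
DESCENT_REGION_END_FRAC = 0.60
CD_PROMINENCE_FRAC_DEFAULT = 0.02
#: c/d candidates are confined to the first part of the b-e interval;
#: curvature dips belonging to the dicrotic-notch complex itself sit
#: just before e and must not masquerade as a d wave.
CD_REGION_FRAC = 0.8
CD_HALF_WIDTH_FRAC = 0.025
#: Minimum prominence (fraction of the searched window's range) for an
#: extremum to count in noise-exposed "first extremum after X" searches.
MIN_PROMINENCE_FRAC = 0.05


@dataclass
class FiducialSet:
    """Indices and amplitudes of the 14 landmarks on one beat segment.

    Indices are segment-relative (0 at the bounding onset).  ``min2`` is
    the index of the closing onset sample, whose pulse amplitude is the
    Min2 magnitude feature.  ``case_label`` records which c/d regime was
    used; ``cd_present`` is 0 when c and d could not be located.
    """

    indices: dict = field(default_factory=dict)
    amplitudes: dict = field(default_factory=dict)
    min2: int = 0
    min2_amplitude: float = np.nan
    case_label: str = ""
    cd_present: int = 0
    valid: bool = True
    message: str = ""


def local_maxima(x: np.ndarray) -> np.ndarray:
    """Strict local maxima; plateaus count once, at their leftmost sample."""
    x = np.asarray(x, dtype=float)
    out = []
    n = x.size
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                out.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def local_minima(x: np.ndarray) -> np.ndarray:
    """Strict local minima with leftmost-of-plateau tie rule."""
    return local_maxima(-np.asarray(x, dtype=float))


def _prominent(x: np.ndarray, idx: np.ndarray, lo: int, hi: int,
               frac: float = MIN_PROMINENCE_FRAC) -> np.ndarray:
    """Filter extremum candidates in (lo, hi) by peak prominence.

    Prominence is measured on the signal restricted to the window and
    compared against ``frac`` of the window's range, which makes
    "first/deepest extremum" searches stable under residual noise.
    """
    from scipy.signal import peak_prominences

    idx = idx[(idx > lo) & (idx < hi)]
    if idx.size == 0 or hi - lo < 3:
        return idx
    window = np.asarray(x[lo : hi + 1], dtype=float)
    thr = frac * np.ptp(window)
    if thr == 0:
        return idx
    prom = peak_prominences(window, idx - lo)[0]
    return idx[prom >= thr]


def refine_extremum(x: np.ndarray, i: int, frac: float = 0.031) -> int:
    """Sub-feature refinement of a broad extremum by parabola vertex.

    Fits a least-squares quadratic over a window of ``+/-frac`` of the
    vector length around the raw arg-extremum and moves the index to
    the vertex.  For smooth, near-quadratic features this is unbiased
    and averages noise over the whole window; the window scales with
    the analysed segment so the rule is resolution-independent.  The
    raw index is kept when the fit is degenerate or the vertex escapes
    the window.
    """
    x = np.asarray(x, dtype=float)
    half = max(4, int(round(frac * x.size)))
    lo, hi = max(0, i - half), min(x.size, i + half + 1)
    if hi - lo < 5:
        return i
    t = np.arange(lo, hi, dtype=float) - i
    coef = np.polyfit(t, x[lo:hi], 2)
    if coef[0] == 0:
        return i
    v = -coef[1] / (2 * coef[0])
    if abs(v) > half:
        return i
    return int(round(i + v))


def zero_crossings(sig: np.ndarray, start: int = 0) -> np.ndarray:
    """Indices i >= start where the sign regime of ``sig`` changes.

    A crossing is reported at the first sample of the new regime.  Exact
    zeros belong to the regime that follows them, so a run of zeros never
    produces more than one crossing.
    """
    x = np.asarray(sig, dtype=float)
    s = np.sign(x)
    # zeros adopt the next nonzero sign (following regime)
    eff = s.copy()
    nxt = 0.0
    for i in range(x.size - 1, -1, -1):
        if eff[i] == 0:
            eff[i] = nxt
        else:
            nxt = eff[i]
    idx = [
        i
        for i in range(max(start, 1), x.size)
        if s[i - 1] != 0 and eff[i] != 0 and eff[i] != s[i - 1]
    ]
    return np.asarray(idx, dtype=int)


def detect_O_S(ppg_segment: np.ndarray) -> tuple[int, int]:
    """Onset and systolic peak of a beat segment.

    The segment is extracted between onsets, so O is its first sample; S
    is the (first) global maximum.
    """
    x = np.asarray(ppg_segment, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        raise DegenerateBeatError("flat or empty beat segment")
    S = int(np.argmax(x))
    if S in (0, x.size - 1):
        raise DegenerateBeatError("no interior systolic peak (monotone segment)")
    return 0, S


def detect_vpg_points(
    vpg: np.ndarray,
    S: int,
    apg: np.ndarray | None = None,
    e: int | None = None,
) -> tuple[int, int, int, int]:
    """The w, x, y, z landmarks on the velocity waveform.

    w is the global maximum (steepest upstroke), x the velocity sample
    aligned with the systolic apex, y the global minimum after w
    (steepest downstroke).  z is the first APG zero-crossing after the
    e wave when e is known, falling back to the second velocity maximum
    otherwise.
    """
    v = np.asarray(vpg, dtype=float)
    mx = local_maxima(v)
    if mx.size == 0:
        raise DetectionError("w")
    w = int(mx[np.argmax(v[mx])])
    x = int(S)
    mn = local_minima(v)
    descent_end = max(w + 2, int(round(DESCENT_REGION_END_FRAC * v.size)))
    mn_after = mn[(mn > w) & (mn < descent_end)]
    if mn_after.size == 0:
        mn_after = mn[mn > w]
    if mn_after.size == 0:
        raise DetectionError("y")
    y = int(mn_after[np.argmin(v[mn_after])])
    z = None
    if apg is not None and e is not None:
        zc = zero_crossings(apg, start=e + 1)
        if zc.size:
            z = int(zc[0])
    if z is None:
        later = mx[mx > w]
        if later.size == 0:
            raise DetectionError("z")
        z = int(later[0])
    return w, x, y, z


def detect_ab(
    apg: np.ndarray,
    systolic_region_frac: float = SYSTOLIC_REGION_FRAC_DEFAULT,
) -> tuple[int, int]:
    """The a and b waves: largest APG maximum in the systolic region and
    the deepest minimum that follows it."""
    a_arr = np.asarray(apg, dtype=float)
    t_end = max(3, int(np.ceil(systolic_region_frac * a_arr.size)))
    mx = local_maxima(a_arr[:t_end])
    if mx.size == 0:
        raise DetectionError("a", "no local maximum in the systolic region of the APG")
    a_idx = int(mx[np.argmax(a_arr[mx])])
    mn = local_minima(a_arr)
    mn = mn[mn > a_idx]
    if mn.size == 0:
        raise DetectionError("b", "no local minimum after the a wave")
    b_idx = int(mn[np.argmin(a_arr[mn])])
    if a_arr[b_idx] >= a_arr[a_idx]:
        raise DetectionError("b", "b wave is not below the a wave")
    return a_idx, b_idx


def detect_ef(
    apg: np.ndarray,
    jpg: np.ndarray,
    b: int,
    notch_region: tuple[float, float] = NOTCH_REGION_DEFAULT,
) -> tuple[int, int]:
    """The e and f waves: the dominant APG maximum in the dicrotic-notch
    region and the first prominent minimum that follows it.

    When weak c/d oscillations exist, e coincides with the third jerk
    zero-crossing after b and f with the fourth; selecting the largest
    APG maximum in the notch region gives the same answer there, stays
    correct when the oscillation (and its two extra crossings) is
    absent, and keeps late-systolic maxima from masquerading as e.
    """
    a_arr = np.asarray(apg, dtype=float)
    n = a_arr.size
    lo = max(b, int(round(notch_region[0] * n)))
    hi = int(round(notch_region[1] * n))
    mx = local_maxima(a_arr)
    cand = mx[(mx > lo) & (mx < hi)]
    if cand.size == 0:
        cand = mx[mx > b]  # degenerate morphology: fall back to anywhere after b
    if cand.size == 0:
        raise DetectionError("e", "no APG maximum after the b wave")
    e_idx = int(cand[np.argmax(a_arr[cand])])
    mn = local_minima(a_arr)
    good = _prominent(-a_arr, mn, e_idx, n - 1)
    after = good[good > e_idx] if good.size else mn[mn > e_idx]
    if after.size == 0:
        after = mn[mn > e_idx]
    if after.size == 0:
        raise DetectionError("f", "no APG minimum after the e wave")
    f_idx = int(after[0])
    # the notch-region extrema are broad; vertex refinement stabilises
    # them against residual in-band noise
    e_idx = refine_extremum(a_arr, e_idx)
    f_idx = refine_extremum(-a_arr, f_idx)
    if not (b < e_idx < f_idx):
        raise DetectionError("f", "refined e/f ordering degenerate")
    return e_idx, f_idx


def classify_case(
    apg: np.ndarray,
    jpg: np.ndarray,
    b: int,
    e: int,
    prominence_frac: float = CD_PROMINENCE_FRAC_DEFAULT,
) -> str:
    """Classify the c/d regime of the region between the b and e waves.

    Case III when the APG itself has a maximum-then-minimum pair strictly
    inside (b, e) whose drop is at least ``prominence_frac`` of the APG
    peak-to-peak range; otherwise Case I when the jerk dips below zero
    inside (b, e) — a prominent, clearly negative jerk minimum followed
    by a jerk maximum before e, i.e. a genuine zero-crossing oscillation
    rather than residual noise or a zero-grazing dip; else Case II.
    """
    if b >= e:
        raise ParameterError(f"need b < e, got b={b}, e={e}")
    a_arr = np.asarray(apg, dtype=float)
    j_arr = np.asarray(jpg, dtype=float)
    thr = prominence_frac * np.ptp(a_arr)
    cd_end = b + int(round(CD_REGION_FRAC * (e - b)))
    mx = local_maxima(a_arr)
    mx = mx[(mx > b) & (mx < cd_end)]
    mn = local_minima(a_arr)
    for m1 in mx:
        later = mn[(mn > m1) & (mn < cd_end)]
        if later.size and a_arr[m1] - a_arr[later[0]] >= thr:
            return "III"
    jn = _prominent(-j_arr, local_minima(j_arr), b, cd_end)
    # the dip must be clearly negative: a zero-grazing dip is Case II
    j_win = j_arr[b : e + 1]
    jn = jn[j_arr[jn] < -MIN_PROMINENCE_FRAC * np.ptp(j_win)]
    if jn.size:
        jm = _prominent(j_arr, local_maxima(j_arr), int(jn[0]), e)
        if jm.size:
            return "I"
    return "II"


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else int(np.ceil(x - 0.5))


def locate_cd(
    case_label: str,
    apg: np.ndarray,
    jpg: np.ndarray,
    b: int,
    e: int,
    T: int,
    prominence_frac: float = CD_PROMINENCE_FRAC_DEFAULT,
) -> tuple[int | None, int | None, int]:
    """Locate the c and d waves according to the classified regime.

    Returns ``(c, d, cd_present)``; a failure to locate the pair is never
    a hard error — it is recorded as ``cd_present = 0`` with both indices
    ``None``.
    """
    a_arr = np.asarray(apg, dtype=float)
    j_arr = np.asarray(jpg, dtype=float)
    c = d = None
    cd_end = b + int(round(CD_REGION_FRAC * (e - b)))
    if case_label == "III":
        mx = local_maxima(a_arr)
        mx = mx[(mx > b) & (mx < cd_end)]
        mn = local_minima(a_arr)
        if mx.size:
            c_cand = int(mx[np.argmax(a_arr[mx])])
            later = mn[(mn > c_cand) & (mn < cd_end)]
            if later.size:
                c, d = c_cand, int(later[0])
    elif case_label == "I":
        jm = local_maxima(j_arr)
        good = _prominent(j_arr, jm, b, cd_end)
        jm = good if good.size else jm[(jm > b) & (jm < cd_end)]
        if jm.size:
            c_cand = int(jm[0])
            zc = zero_crossings(j_arr, start=c_cand + 1)
            zc = zc[zc < e]
            if zc.size:
                c, d = c_cand, int(zc[0])
    elif case_label == "II":
        jn = local_minima(j_arr)
        good = _prominent(-j_arr, jn, b, cd_end)
        jn = good if good.size else jn[(jn > b) & (jn < cd_end)]
        if jn.size:
            m = refine_extremum(-j_arr, int(jn[0]), frac=0.023)
            half = _round_half_away(CD_HALF_WIDTH_FRAC * T)
            c_cand, d_cand = m - half, m + half
            if b < c_cand and d_cand < e:
                c, d = c_cand, d_cand
    else:
        raise ParameterError(f"unknown case label {case_label!r}")
    if c is None or d is None or not (b < c <= d < e):
        return None, None, 0
    return c, d, 1


def map_ND(e: int, f: int) -> tuple[int, int]:
    """The pulse dicrotic notch and diastolic peak share the APG e and f
    wave indices on the common grid."""
    if e >= f:
        raise ParameterError(f"need e < f, got e={e}, f={f}")
    return e, f


def extract_fiducials(
    stack: DerivativeStack,
    min1: int,
    min2: int,
    systolic_region_frac: float = SYSTOLIC_REGION_FRAC_DEFAULT,
    cd_prominence_frac: float = CD_PROMINENCE_FRAC_DEFAULT,
) -> FiducialSet:
    """Run the full landmark search on one beat's derivative stack.

    ``stack`` holds the beat segment (already sliced between onsets) and
    its derivatives; ``min1``/``min2`` are the record-coordinate onsets
    kept for provenance.  A failed beat returns a ``FiducialSet`` with
    ``valid=False`` and a diagnostic message, never raises.
    """
    fid = FiducialSet()
    T = min2 - min1 + 1
    fid.min2 = stack.ppg.size - 1
    try:
        O, S = detect_O_S(stack.ppg)
        a, b = detect_ab(stack.apg, systolic_region_frac)
        e, f = detect_ef(stack.apg, stack.jpg, b)
        case = classify_case(stack.apg, stack.jpg, b, e, cd_prominence_frac)
        c, d, cd_present = locate_cd(case, stack.apg, stack.jpg, b, e, T, cd_prominence_frac)
        N, D = map_ND(e, f)
        w, x, y, z = detect_vpg_points(stack.vpg, S, stack.apg, e)
    except (DegenerateBeatError, DetectionError, ParameterError) as exc:
        fid.valid = False
        fid.message = str(exc)
        return fid
    fid.indices = {
        "O": O, "S": S, "N": N, "D": D,
        "w": w, "x": x, "y": y, "z": z,
        "a": a, "b": b, "c": c, "d": d, "e": e, "f": f,
    }
    waveforms = {"ppg": stack.ppg, "vpg": stack.vpg, "apg": stack.apg, "jpg": stack.jpg}
    fid.amplitudes = {
        name: (float(waveforms[POINT_WAVEFORM[name]][idx]) if idx is not None else np.nan)
        for name, idx in fid.indices.items()
    }
    fid.min2_amplitude = float(stack.ppg[fid.min2])
    fid.case_label = case
    fid.cd_present = cd_present
    return fid
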