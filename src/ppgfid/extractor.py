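"""End-to-end extraction, presented as a scikit-learn style transformer.

:class:`FiducialFeatureExtractor` maps a raw PPG matrix (one subject per
row) to the n x 30 feature matrix: bandpass filter and smooth each
record, gate it on the skewness SQI, cut the first complete beat between
its two onsets, build the derivative stack and locate the 14 landmarks.
``transform`` returns the plain numeric matrix for pipeline composition;
:meth:`extract` returns the full per-subject results (fiducial sets,
beat bounds, filtered waveforms) and the exportable output bundle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import features as _feat
from . import fiducials as _fid
from . import preprocess as _pre
from . import segmentation as _seg
from .errors import PPGError
from .signal_io import SEGMENT_EXPORT_LEN, Dataset, OutputBundle, SubjectRecord

__all__ = ["FiducialFeatureExtractor", "SubjectResult", "ExtractionResult", "extract_dataset"]

logger = logging.getLogger(__name__)


@dataclass
class SubjectResult:
    """Everything the pipeline produced (or not) for one subject."""

    subject_id: str
    ok: bool
    message: str = ""
    sqi: float = np.nan
    min1: int = -1
    min2: int = -1
    filtered: np.ndarray | None = None
    stack: _pre.DerivativeStack | None = None
    fiducials: _fid.FiducialSet = field(default_factory=lambda: _fid.FiducialSet(valid=False))


@dataclass
class ExtractionResult:
    """Per-subject results plus the assembled feature table."""

    results: list[SubjectResult]
    feature_table: pd.DataFrame
    fs: float

    @property
    def n_ok(self) -> int:
        return sum(r.ok for r in self.results)

    def to_bundle(self) -> OutputBundle:
        """Assemble the six-table output bundle (zero-padded segments)."""
        ids, filt, pseg, aseg, idm, cd = [], [], [], [], [], []
        for r in self.results:
            ids.append(r.subject_id)
            filt.append(r.filtered if r.filtered is not None else np.zeros(0))
            seg = np.zeros(SEGMENT_EXPORT_LEN)
            apg = np.zeros(SEGMENT_EXPORT_LEN)
            if r.ok and r.stack is not None:
                m = min(r.stack.ppg.size, SEGMENT_EXPORT_LEN)
                seg[:m] = r.stack.ppg[:m]
                apg[:m] = r.stack.apg[:m]
            pseg.append(seg)
            aseg.append(apg)
            idm.append({"subject_id": r.subject_id, "Min1": r.min1, "Min2": r.min2})
            cd.append(int(r.fiducials.cd_present) if r.ok else 0)
        w = max((f.size for f in filt), default=0)
        filt_mat = np.zeros((len(ids), w))
        for i, f in enumerate(filt):
            filt_mat[i, : f.size] = f
        return OutputBundle(
            subject_ids=ids,
            feature_table=self.feature_table,
            filtered_ppg=filt_mat,
            ppg_segments=np.vstack(pseg) if pseg else np.zeros((0, SEGMENT_EXPORT_LEN)),
            apg_segments=np.vstack(aseg) if aseg else np.zeros((0, SEGMENT_EXPORT_LEN)),
            id_min1_min2=pd.DataFrame(idm, columns=["subject_id", "Min1", "Min2"]),
            c_d_presence=np.asarray(cd, dtype=int),
        )


class FiducialFeatureExtractor(BaseEstimator, TransformerMixin):
    """Locate pulse-wave landmarks and emit the 30-column feature matrix.

    Parameters
    ----------
    fs : float
        Sampling rate of the input rows, Hz.
    fl, fh : float
        Bandpass edges of the Chebyshev type-II filter, Hz.
    sqi_threshold : float
        Minimum skewness SQI for a record supplied with an SQI table.
    skip_sqi : bool
        When no SQI table is given, compute the SQI from the raw samples
        and admit any record with a positive value.
    smooth_window_ppg_ms, smooth_window_deriv_ms : float
        Centered moving-average windows for the pulse and for each
        derivative, in milliseconds.
    onset_prominence_frac, min_beat_spacing_s : float
        Onset-detector settings (fraction of peak-to-peak range; minimum
        inter-onset spacing in seconds).
    systolic_region_frac : float
        Fraction of the beat searched for the APG a wave.
    cd_prominence_frac : float
        APG prominence (fraction of peak-to-peak) separating prominent
        c/d extrema (Case III) from the jerk-based regimes.

    Attributes
    ----------
    n_features_in_ : int
        Record length seen by :meth:`fit`.
    filter_spec_ : FilterSpec
        The realized bandpass design.
    """

    def __init__(
        self,
        fs: float = 1000.0,
        fl: float = 0.4,
        fh: float = 8.0,
        sqi_threshold: float = _seg.SQI_THRESHOLD_DEFAULT,
        skip_sqi: bool = True,
        smooth_window_ppg_ms: float = 50.0,
        smooth_window_deriv_ms: float = 10.0,
        onset_prominence_frac: float = 0.05,
        min_beat_spacing_s: float = 0.3,
        systolic_region_frac: float = _fid.SYSTOLIC_REGION_FRAC_DEFAULT,
        cd_prominence_frac: float = _fid.CD_PROMINENCE_FRAC_DEFAULT,
    ):
        self.fs = fs
        self.fl = fl
        self.fh = fh
        self.sqi_threshold = sqi_threshold
        self.skip_sqi = skip_sqi
        self.smooth_window_ppg_ms = smooth_window_ppg_ms
        self.smooth_window_deriv_ms = smooth_window_deriv_ms
        self.onset_prominence_frac = onset_prominence_frac
        self.min_beat_spacing_s = min_beat_spacing_s
        self.systolic_region_frac = systolic_region_frac
        self.cd_prominence_frac = cd_prominence_frac

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1, ensure_min_features=4)
        self.n_features_in_ = X.shape[1]
        self.filter_spec_ = _pre.design_bandpass(self.fs, self.fl, self.fh)
        return self

    def transform(self, X) -> np.ndarray:
        """Feature matrix (n_subjects, 30); failed rows are NaN."""
        check_is_fitted(self, "filter_spec_")
        X = check_array(X)
        res = self.extract(X)
        return res.feature_table.to_numpy(dtype=float)

    def _window(self, ms: float) -> int:
        return max(1, int(round(ms * self.fs / 1000.0)))

    def _process_record(self, record: SubjectRecord, sqi_value: float | None) -> SubjectResult:
        sid = record.subject_id
        try:
            if sqi_value is not None:
                sqi = float(sqi_value)
                if sqi < self.sqi_threshold:
                    return SubjectResult(sid, False, f"Ssqi {sqi:.3f} below threshold", sqi=sqi)
            else:
                sqi = _seg.skewness_sqi(record.samples)
                if sqi <= 0:
                    return SubjectResult(sid, False, f"non-positive Ssqi {sqi:.3f}", sqi=sqi)
            filtered = _pre.apply_filter(record.samples, self.filter_spec_)
            filtered = _pre.moving_average(filtered, self._window(self.smooth_window_ppg_ms))
            onsets = _seg.detect_onsets(
                filtered, self.fs, self.onset_prominence_frac, self.min_beat_spacing_s
            )
            min1, min2 = int(onsets[0]), int(onsets[1])
            beat = _seg.extract_beat(filtered, min1, min2, sid, self.fs)
            stack = _pre.compute_derivatives(
                beat.samples, self._window(self.smooth_window_deriv_ms), self.fs
            )
            fid = _fid.extract_fiducials(
                stack, min1, min2, self.systolic_region_frac, self.cd_prominence_frac
            )
            ok = fid.valid
            return SubjectResult(
                sid, ok, fid.message, sqi=sqi, min1=min1, min2=min2,
                filtered=filtered, stack=stack, fiducials=fid,
            )
        except PPGError as exc:
            logger.warning("subject %s failed: %s", sid, exc)
            return SubjectResult(sid, False, str(exc))

    def extract(self, X, subject_ids=None, sqi=None) -> ExtractionResult:
        """Full pipeline over a raw matrix or :class:`Dataset`.

        ``sqi`` is an optional subject_id → Ssqi mapping; without it the
        SQI is computed from the raw samples per record (the skip-SQI
        path) when ``skip_sqi`` is set, and no gating occurs otherwise.
        """
        check_is_fitted(self, "filter_spec_")
        if isinstance(X, Dataset):
            records = X.records
            sqi = X.sqi if sqi is None else sqi
        else:
            X = check_array(X)
            ids = subject_ids or [f"S{i + 1:03d}" for i in range(X.shape[0])]
            records = [SubjectRecord(ids[i], X[i], fs=self.fs) for i in range(X.shape[0])]
        results = []
        for rec in records:
            val = sqi.get(rec.subject_id) if sqi else None
            if sqi is None and not self.skip_sqi:
                val = None
            r = self._process_record(rec, val)
            if sqi is None and not self.skip_sqi:
                r.sqi = np.nan
            results.append(r)
            logger.info(
                "subject %s: %s", rec.subject_id, "ok" if r.ok else f"failed ({r.message})"
            )
        rows = [_feat.build_feature_row(r.fiducials, self.fs) for r in results]
        table = _feat.build_feature_table(rows, [r.subject_id for r in results])
        return ExtractionResult(results=results, feature_table=table, fs=self.fs)


def extract_dataset(dataset: Dataset, **params) -> ExtractionResult:
    """Functional wrapper: run the extractor over a dataset."""
    est = FiducialFeatureExtractor(fs=dataset.fs, **params)
    est.fit(dataset.to_matrix())
    return est.extract(dataset)
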