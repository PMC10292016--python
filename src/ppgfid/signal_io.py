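"""Reading raw PPG matrices, SQI tables and reference annotations; writing
the output file suite.

The canonical interchange format is plain CSV (RFC-4180, ``.`` decimal
separator).  Sample indices are 0-based inside the package and converted
to 1-based exactly once, at this I/O boundary, matching the convention of
the original MATLAB tooling the file suite interoperates with.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, ParseError, ParameterError
from .fiducials import POINT_NAMES

__all__ = [
    "SubjectRecord",
    "Dataset",
    "OutputBundle",
    "read_ppg_matrix",
    "read_sqi_table",
    "read_reference_table",
    "write_reference_table",
    "write_outputs",
    "OUTPUT_FILENAMES",
]

logger = logging.getLogger(__name__)

SEGMENT_EXPORT_LEN = 1200

OUTPUT_FILENAMES = (
    "PPG_features.csv",
    "PPG_Filtered_HighSQI.csv",
    "PPG_Segments.csv",
    "APG_Segments.csv",
    "ID_min1_min2.csv",
    "c_d_presence.csv",
)


@dataclass
class SubjectRecord:
    """One raw PPG row: subject id, sample vector (a.u.), sampling rate."""

    subject_id: str
    samples: np.ndarray
    fs: float = 1000.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ParseError(f"record {self.subject_id}: non-finite samples")


@dataclass
class Dataset:
    """An ordered collection of subject records plus optional SQI values."""

    records: list[SubjectRecord] = field(default_factory=list)
    sqi: dict[str, float] | None = None

    def __post_init__(self):
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ConsistencyError("duplicate subject ids in dataset")
        if len({r.fs for r in self.records}) > 1:
            raise ConsistencyError("all records must share one sampling rate")
        if self.sqi is not None:
            missing = set(self.sqi) - set(ids)
            if missing:
                raise ConsistencyError(f"SQI table has unknown subject ids: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def fs(self) -> float:
        if not self.records:
            raise ParameterError("empty dataset has no sampling rate")
        return self.records[0].fs

    def to_matrix(self) -> np.ndarray:
        return np.vstack([r.samples for r in self.records])

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]


@dataclass
class OutputBundle:
    """The six aligned output tables produced for one dataset run.

    Row i of every component refers to the same subject.  Segment
    matrices are zero-padded (trailing) to 1200 columns.
    """

    subject_ids: list[str]
    feature_table: pd.DataFrame          # n x 30, indexed by subject id
    filtered_ppg: np.ndarray             # n x w
    ppg_segments: np.ndarray             # n x 1200
    apg_segments: np.ndarray             # n x 1200
    id_min1_min2: pd.DataFrame           # n x 3: subject id, min1, min2 (0-based here)
    c_d_presence: np.ndarray             # n, values in {0, 1}

    def validate(self) -> None:
        n = len(self.subject_ids)
        shapes = {
            "feature_table": self.feature_table.shape[0],
            "filtered_ppg": self.filtered_ppg.shape[0],
            "ppg_segments": self.ppg_segments.shape[0],
            "apg_segments": self.apg_segments.shape[0],
            "id_min1_min2": self.id_min1_min2.shape[0],
            "c_d_presence": len(self.c_d_presence),
        }
        bad = {k: v for k, v in shapes.items() if v != n}
        if bad:
            raise ConsistencyError(f"row-count mismatch against {n} subjects: {bad}")
        if self.feature_table.shape[1] != 30:
            raise ConsistencyError(
                f"feature table must have exactly 30 columns, got {self.feature_table.shape[1]}"
            )
        for name in ("ppg_segments", "apg_segments"):
            m = getattr(self, name)
            if n and m.shape[1] != SEGMENT_EXPORT_LEN:
                raise ConsistencyError(f"{name} must have {SEGMENT_EXPORT_LEN} columns")
        vals = set(np.asarray(self.c_d_presence).astype(float).tolist())
        if not vals <= {0.0, 1.0}:
            raise ConsistencyError(f"c_d_presence must be binary, found {sorted(vals)}")


def _read_numeric_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty input file") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged rows — {exc}") from exc
    widths = df.notna().sum(axis=1)
    if widths.nunique() > 1:
        raise FormatError(
            f"{path}: ragged rows (row lengths {sorted(widths.unique())})"
        )
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ParseError(f"{path}: non-numeric value {df.iat[r, c]!r} at row {r + 1}, column {c + 1}")
    if num.isna().any().any():
        r, c = np.argwhere(num.isna().values)[0]
        raise ParseError(f"{path}: missing value at row {r + 1}, column {c + 1}")
    return num


def read_ppg_matrix(path: str | Path, fs: float = 1000.0) -> Dataset:
    """Read an r x w raw PPG matrix (one subject per row) from CSV.

    Subjects are named ``S001``, ``S002``, ... in row order unless an id
    table is merged in later.  Rows must be rectangular and fully numeric.
    """
    path = Path(path)
    num = _read_numeric_csv(path)
    records = [
        SubjectRecord(subject_id=f"S{i + 1:03d}", samples=row, fs=fs)
        for i, row in enumerate(num.to_numpy(dtype=float))
    ]
    logger.info("read %d records x %d samples from %s", num.shape[0], num.shape[1], path)
    return Dataset(records=records)


def read_sqi_table(path: str | Path) -> dict[str, float]:
    """Read a two-column (subject id, Ssqi) CSV into a mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty SQI table", path)
        return {}
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected 2 columns (id, Ssqi), got {df.shape[1]}")
    # tolerate a header line such as "subject_id,Ssqi"
    first = str(df.iloc[0, 0]).strip().lower()
    if first in {"subject_id", "id", "subject"}:
        df = df.iloc[1:]
    out: dict[str, float] = {}
    for i, (sid, val) in enumerate(df.itertuples(index=False)):
        v = pd.to_numeric(val, errors="coerce")
        if pd.isna(v):
            raise ParseError(f"{path}: non-numeric Ssqi {val!r} at row {i + 1}")
        if sid in out:
            raise ConsistencyError(f"{path}: duplicate subject id {sid!r}")
        out[str(sid)] = float(v)
    return out


def read_reference_table(path: str | Path) -> pd.DataFrame:
    """Read reference fiducial annotations (subject id + 14 point columns).

    Indices in the file are 1-based; they are converted to the package's
    0-based convention here.  An optional ``case`` column is carried
    through untouched.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise FormatError(f"{path}: missing 'subject_id' column")
    missing = [p for p in POINT_NAMES if p not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing point columns {missing}")
    df = df.set_index("subject_id")
    for p in POINT_NAMES:
        df[p] = pd.to_numeric(df[p], errors="coerce") - 1
    return df


def write_reference_table(reference: pd.DataFrame, path: str | Path) -> Path:
    """Write a reference annotation table, converting indices to 1-based."""
    path = Path(path)
    out = reference.copy()
    for p in POINT_NAMES:
        out[p] = out[p] + 1
    out.to_csv(path, index=True)
    logger.info("wrote %s", path)
    return path


def write_outputs(bundle: OutputBundle, outdir: str | Path, xlsx: bool = False) -> list[Path]:
    """Write the six-file output suite under ``outdir``.

    Consistency across components is checked before anything touches the
    filesystem.  ``xlsx=True`` additionally emits .xlsx copies.
    """
    bundle.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    feats = bundle.feature_table.copy()
    feats.insert(0, "subject_id", bundle.subject_ids)
    p = outdir / "PPG_features.csv"
    feats.to_csv(p, index=False, float_format="%.17g")
    written.append(p)

    for name, mat in (
        ("PPG_Filtered_HighSQI.csv", bundle.filtered_ppg),
        ("PPG_Segments.csv", bundle.ppg_segments),
        ("APG_Segments.csv", bundle.apg_segments),
    ):
        p = outdir / name
        # %.17g guarantees exact float64 round-trip through text
        pd.DataFrame(np.asarray(mat)).to_csv(p, index=False, header=False, float_format="%.17g")
        written.append(p)

    idm = bundle.id_min1_min2.copy()
    idm["Min1"] = idm["Min1"] + 1  # 1-based at the file boundary
    idm["Min2"] = idm["Min2"] + 1
    p = outdir / "ID_min1_min2.csv"
    idm.to_csv(p, index=False)
    written.append(p)

    p = outdir / "c_d_presence.csv"
    pd.DataFrame({"c_d_presence": np.asarray(bundle.c_d_presence, dtype=int)}).to_csv(p, index=False)
    written.append(p)

    if xlsx:
        for path in list(written):
            xp = path.with_suffix(".xlsx")
            pd.read_csv(path).to_excel(xp, index=False)
            written.append(xp)

    for path in written:
        logger.info("wrote %s", path)
    return written
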