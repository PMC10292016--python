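"""The 30-column feature table: 15 magnitudes and 15 time-domain values.

Magnitudes are read off the waveform owning each landmark (pulse for
O/S/N/D and Min2, velocity for w/x/y/z, acceleration for a-f) at the
detected index; times are seconds from the beat onset, so ``O_t`` is 0 by
construction.  Landmarks that could not be located (c/d when
``cd_present`` is 0, or a wholly failed beat) are NaN in memory and empty
cells in CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .fiducials import FiducialSet

__all__ = ["FEATURE_COLUMNS", "build_feature_row", "build_feature_table"]

_MAGNITUDE_ORDER = ("O", "S", "N", "D", "Min2", "w", "x", "y", "z",
                    "a", "b", "c", "d", "e", "f")

#: Frozen column order of the features table.
FEATURE_COLUMNS = tuple(list(_MAGNITUDE_ORDER) + [f"{p}_t" for p in _MAGNITUDE_ORDER])


def build_feature_row(fid: FiducialSet, fs: float) -> dict[str, float]:
    """One subject's 30 feature values from a fiducial set.

    An invalid fiducial set yields an all-NaN row so the subject keeps
    its slot in the table.
    """
    row = {name: np.nan for name in FEATURE_COLUMNS}
    if not fid.valid:
        return row
    for name in _MAGNITUDE_ORDER:
        if name == "Min2":
            idx, amp = fid.min2, fid.min2_amplitude
        else:
            idx = fid.indices.get(name)
            amp = fid.amplitudes.get(name, np.nan)
        if idx is None:
            continue  # leaves NaN (undetected c/d)
        row[name] = amp
        row[f"{name}_t"] = idx / fs
    return row


def build_feature_table(rows: list[dict[str, float]], ids: list[str]) -> pd.DataFrame:
    """Assemble feature rows into the n x 30 table keyed by subject id."""
    if len(rows) != len(ids):
        raise ConsistencyError(f"{len(rows)} rows for {len(ids)} subject ids")
    if len(set(ids)) != len(ids):
        raise ConsistencyError("duplicate subject ids in feature table")
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS), dtype=float)
    df.index = pd.Index(ids, name="subject_id")
    return df
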