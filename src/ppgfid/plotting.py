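"""Static per-beat marker plots: pulse, velocity and acceleration panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .fiducials import POINT_WAVEFORM, FiducialSet
from .preprocess import DerivativeStack


def plot_beat(stack: DerivativeStack, fid: FiducialSet, path: str | Path) -> Path:
    """Render one beat's PPG/VPG/APG with fiducial markers to PNG."""
    path = Path(path)
    t = [i / stack.fs for i in range(stack.ppg.size)]
    fig, axes = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    panels = {"ppg": axes[0], "vpg": axes[1], "apg": axes[2]}
    axes[0].plot(t, stack.ppg, lw=1)
    axes[1].plot(t, stack.vpg, lw=1)
    axes[2].plot(t, stack.apg, lw=1)
    for name, idx in fid.indices.items():
        if idx is None:
            continue
        wf = POINT_WAVEFORM[name]
        ax = panels[wf]
        y = getattr(stack, wf)[idx]
        ax.plot(idx / stack.fs, y, "ro", ms=4)
        ax.annotate(name, (idx / stack.fs, y), textcoords="offset points",
                    xytext=(3, 6), fontsize=8)
    axes[0].set_ylabel("PPG (a.u.)")
    axes[1].set_ylabel("VPG (a.u./sample)")
    axes[2].set_ylabel("APG (a.u./sample$^2$)")
    axes[2].set_xlabel("time from onset (s)")
    axes[0].set_title(f"case {fid.case_label}, c/d {'present' if fid.cd_present else 'absent'}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
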