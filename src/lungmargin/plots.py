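"""Report figures: per-fraction error traces and association scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .error_budget import correlation_error
from .log_io import AXES, AXIS_LABELS, TrackingBundle


def fraction_error_plot(bundle: TrackingBundle, path: str | Path) -> Path:
    """Correlation-model trace, imaging samples and residuals for one fraction."""
    series = correlation_error(bundle)
    fig, axes = plt.subplots(3, 2, figsize=(10, 7), sharex="col",
                             gridspec_kw={"width_ratios": [3, 1]})
    for k, ax_name in enumerate(AXES):
        left, right = axes[k]
        left.plot(bundle.modeler.t, bundle.modeler.pos[:, k], lw=0.4,
                  label="correlation model")
        left.plot(bundle.imaging.t, bundle.imaging.pos[:, k], "k.", ms=5,
                  label="X-ray imaging")
        left.set_ylabel(f"{AXIS_LABELS[ax_name]} (mm)")
        right.hist(series.errors[:, k], bins=15, color="0.4")
        right.set_xlabel("error (mm)")
        if k == 0:
            left.legend(loc="upper right", fontsize=8)
    axes[-1][0].set_xlabel("time (s)")
    fig.suptitle(f"{bundle.patient_id}/{bundle.fraction_id}: correlation error")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def association_plot(df, x_col: str, y_col: str, path: str | Path) -> Path:
    """Scatter of two cohort columns with a least-squares fit line."""
    x = np.asarray(df[x_col], dtype=float)
    y = np.asarray(df[y_col], dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(x, y, "o", ms=4, alpha=0.7)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, slope * grid + intercept, "r-", lw=1,
            label=f"fit: y = {slope:.3f}x + {intercept:.3f}")
    ax.set_xlabel(x_col)
    ax.set_ylabel(y_col)
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
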