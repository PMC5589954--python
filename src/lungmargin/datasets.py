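"""Bundled reference tables and small synthetic fixtures.

The package ships the per-patient error-budget, uncertainty and margin
tables of a 22-patient / 92-fraction fiducial-free lung-tracking reference
cohort (values rounded to the precision they were reported at: 0.1 mm for
per-axis components, 0.01 mm for the assigned segmentation/targeting
constants).  They drive the ``from-budget`` analysis path and the regression
tests; no clinical logs are included.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .log_io import AXES

#: Per-axis end-to-end targeting summary of the reference cohort's delivery
#: system: signed mean and SD (mm) over phantom tests, order (S-I, L-R, A-P).
E2E_MEAN_MM = (-0.13, 0.20, -0.14)
E2E_SD_MM = (0.18, 0.33, 0.25)


def _read(name: str) -> pd.DataFrame:
    with resources.files("lungmargin.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_budget() -> pd.DataFrame:
    """Reference error-budget table: Sigma/sigma components per patient (mm)."""
    return _read("reference_budget.csv")


def load_reference_uncertainty() -> pd.DataFrame:
    """Reference expanded-uncertainty table: U components per patient (mm)."""
    return _read("reference_uncertainty.csv")


def load_reference_margins() -> pd.DataFrame:
    """Reference per-patient margins: van Herk M and combined U per axis (mm)."""
    return _read("reference_margins.csv")


def synthetic_e2e_records(
    n: int = 10,
    mean_mm: tuple[float, float, float] = E2E_MEAN_MM,
    sd_mm: tuple[float, float, float] = E2E_SD_MM,
) -> pd.DataFrame:
    """Synthetic end-to-end phantom test records (stand-in for real QA logs).

    Raw per-test offsets are not part of the reference tables, only their
    per-axis mean and SD.  This constructs ``n`` synthetic records whose
    sample mean and SD (n-1 divisor) match the given summaries exactly, so
    the targeting-budget computation reproduces the reference U_T values
    from record-level input.
    """
    if n < 2:
        raise ValueError("need n >= 2 records")
    base = np.linspace(-1.0, 1.0, n) ** 3 + np.linspace(-0.5, 0.5, n)
    z = (base - base.mean()) / base.std(ddof=1)
    data = {"test": [f"E2E{i + 1:02d}" for i in range(n)]}
    for k, ax in enumerate(AXES):
        data[ax] = mean_mm[k] + sd_mm[k] * z
    return pd.DataFrame(data)


def load_e2e_records(path) -> pd.DataFrame:
    """Read an end-to-end record CSV with per-axis signed offsets (si,lr,ap mm)."""
    df = pd.read_csv(path)
    missing = [ax for ax in AXES if ax not in df.columns]
    if missing:
        raise ValueError(f"E2E record file lacks columns: {missing}")
    return df
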