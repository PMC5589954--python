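"""Cohort-level association analyses.

Two views of a treatment cohort are analysed:

* fraction-level rows (one per treatment fraction): per-axis motion range
  against the within-fraction SD of correlation and prediction errors,
  tested with Pearson correlation;
* patient-level rows (one per patient): motion range (mean over the
  patient's fractions) against the expanded uncertainties, plus two-group
  margin/uncertainty comparisons (lobe, central vs peripheral, size and
  motion subgroups) with the independent two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .log_io import AXES

ALPHA = 0.05


@dataclass(frozen=True)
class Association:
    r: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


@dataclass(frozen=True)
class GroupComparison:
    t: float
    p_value: float
    group_means: dict
    group_sizes: dict

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


def pearson_assoc(table: pd.DataFrame, x_col: str, y_col: str) -> Association:
    """Pearson correlation between two cohort columns.

    Returns r and the two-sided p-value from the t distribution with n - 2
    degrees of freedom.  Requires >= 3 finite pairs; a zero-variance column
    makes the correlation undefined and raises ``ValueError``.
    """
    x = np.asarray(table[x_col], dtype=float)
    y = np.asarray(table[y_col], dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("Pearson correlation needs >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: a column has zero variance")
    r, p = sps.pearsonr(x, y)
    return Association(r=float(r), p_value=float(p), n=int(x.size))


def group_compare(
    table: pd.DataFrame, value_col: str, group_col: str, *, welch: bool = False
) -> GroupComparison:
    """Independent two-sample t-test between the two levels of a grouping column.

    Pooled-variance Student form by default; ``welch=True`` drops the
    equal-variance assumption.  Both groups need >= 2 members.
    """
    levels = sorted(pd.unique(table[group_col].dropna()))
    if len(levels) != 2:
        raise ValueError(f"{group_col!r} must have exactly 2 levels, got {levels}")
    a = np.asarray(table.loc[table[group_col] == levels[0], value_col], dtype=float)
    b = np.asarray(table.loc[table[group_col] == levels[1], value_col], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 members")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        t=float(t),
        p_value=float(p),
        group_means={levels[0]: float(a.mean()), levels[1]: float(b.mean())},
        group_sizes={levels[0]: int(a.size), levels[1]: int(b.size)},
    )


# ---------------------------------------------------------------------------
# cohort table builders


def fraction_table(per_fraction_rows) -> pd.DataFrame:
    """Assemble the fraction-level cohort table from per-fraction summaries.

    ``per_fraction_rows`` is an iterable of dicts with keys ``patient``,
    ``fraction``, ``range_<ax>``, ``sd_corr_<ax>``, ``sd_pred_<ax>`` for ax
    in si/lr/ap (built by the pipeline from the gated error series).
    """
    df = pd.DataFrame(list(per_fraction_rows))
    required = {"patient", "fraction"} | {
        f"{stem}_{ax}" for stem in ("range", "sd_corr", "sd_pred") for ax in AXES
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fraction table lacks columns: {sorted(missing)}")
    return df


def patient_table(
    budgets, metadata: pd.DataFrame | None = None, margins: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble the patient-level cohort table.

    One row per patient: mean motion range across fractions, the correlation
    and prediction expanded uncertainties, and (optionally) metadata labels
    and computed margins.  Binary ``*_group`` labels for size and motion are
    derived by an above/below-cohort-mean split.
    """
    rows = []
    for b in budgets:
        row = {"patient": b.patient_id, "n_fractions": b.n_fractions}
        mean_range = b.motion_range_mm.mean(axis=0)
        for k, ax in enumerate(AXES):
            row[f"range_{ax}"] = float(mean_range[k])
            row[f"U_C_{ax}"] = float(b.U_C[k])
            row[f"U_P_{ax}"] = float(b.U_P[k])
            row[f"sigma_C_{ax}"] = float(b.sigma_C[k])
            row[f"sigma_P_{ax}"] = float(b.sigma_P[k])
        rows.append(row)
    df = pd.DataFrame(rows)
    if metadata is not None:
        df = df.merge(metadata, on="patient", how="left")
    if margins is not None:
        df = df.merge(margins, on="patient", how="left")
    if "volume_cm3" in df.columns:
        df["size_group"] = np.where(
            df["volume_cm3"] > df["volume_cm3"].mean(), "large", "small"
        )
    df["motion_group"] = np.where(
        df["range_si"] > df["range_si"].mean(), "large", "small"
    )
    return df


def association_report(
    frac_df: pd.DataFrame, pat_df: pd.DataFrame
) -> dict:
    """Run the standard association battery and return a JSON-ready report.

    Fraction-level: motion range vs error SD per axis and error kind.
    Patient-level: motion range vs expanded uncertainty per axis and kind,
    plus group comparisons of margins/uncertainties where labels and margin
    columns are present.
    """
    report: dict = {"fraction_level": {}, "patient_level": {}, "group_comparisons": {}}
    for kind, stem in (("correlation", "sd_corr"), ("prediction", "sd_pred")):
        for ax in AXES:
            a = pearson_assoc(frac_df, f"range_{ax}", f"{stem}_{ax}")
            report["fraction_level"][f"{kind}_{ax}"] = {
                "r": round(a.r, 3), "p": a.p_value, "n": a.n,
            }
    for kind, stem in (("correlation", "U_C"), ("prediction", "U_P")):
        for ax in AXES:
            a = pearson_assoc(pat_df, f"range_{ax}", f"{stem}_{ax}")
            report["patient_level"][f"{kind}_{ax}"] = {
                "r": round(a.r, 3), "p": a.p_value, "n": a.n,
            }
    group_cols = [c for c in ("lobe", "location", "size_group", "motion_group")
                  if c in pat_df.columns and pat_df[c].nunique() == 2
                  and pat_df[c].value_counts().min() >= 2]
    value_cols = [c for c in pat_df.columns
                  if c.startswith(("M_", "U_si", "U_lr", "U_ap"))]
    for g in group_cols:
        for v in value_cols:
            cmp = group_compare(pat_df, v, g)
            report["group_comparisons"][f"{v}_by_{g}"] = {
                "t": round(cmp.t, 3), "p": cmp.p_value,
                "means": {k: round(m, 3) for k, m in cmp.group_means.items()},
            }
    return report
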