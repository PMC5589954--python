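"""Systematic/random error decomposition and CTV-to-PTV margin recipes.

Two margin formalisms are implemented, per patient and per axis:

* the van Herk recipe ``M = 2.5*Sigma + beta*(sqrt(sigma^2 + sigma_p^2)
  - sigma_p)``, where Sigma is the quadrature sum of the systematic
  components (segmentation, deformation, correlation, prediction,
  targeting), sigma the quadrature sum of the random components
  (correlation, prediction), ``sigma_p`` the beam penumbra width and
  ``beta`` the prescription-isodose coefficient;
* the expanded-uncertainty (k = 2) budget: each step's expanded uncertainty
  U = mu + 2*sigma is halved to a standard uncertainty, combined in
  quadrature, and re-expanded with k = 2 — algebraically the direct
  Euclidean norm of the five U components.

The decomposition follows the classic intrafraction convention: the random
component sigma is the RMS over fractions of per-fraction sample SDs, and
the systematic component Sigma is the RMS of per-fraction mean shifts about
zero with an N_f - 1 divisor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .log_io import AXES


@dataclass(frozen=True)
class FractionErrorStats:
    """Per-fraction summary feeding the decomposition."""

    fraction_id: str
    mean: float        # mean signed shift <e>_f (mm)
    sd: float          # within-fraction sample SD sigma_f (mm, n-1 divisor)
    n: int             # sample count N_mf

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"fraction {self.fraction_id}: need >= 2 samples")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class MarginParams:
    """Dosimetric constants of the van Herk recipe.

    ``sigma_p`` is the effective penumbra width in lung (mm) and ``beta`` the
    coefficient tied to the prescription isodose level; the defaults
    (6.4 mm, 0.84) correspond to an 80% prescription level with the broad
    lung penumbra.
    """

    sigma_p: float = 6.4
    beta: float = 0.84

    def __post_init__(self):
        if self.sigma_p < 0:
            raise ValueError("sigma_p must be non-negative")
        if not 0 < self.beta <= 1.64:
            raise ValueError("beta must lie in (0, 1.64]")


def decompose(
    samples_by_fraction,
    *,
    fraction_ids=None,
    center_grand_mean: bool = False,
) -> tuple[float, float, list[FractionErrorStats]]:
    """Split per-fraction error samples into systematic and random parts.

    Parameters
    ----------
    samples_by_fraction:
        Sequence of 1-D arrays, one per fraction, of signed error samples on
        a single axis (mm).  Each fraction needs >= 2 samples; >= 2 fractions
        are required for the systematic component to be defined.
    center_grand_mean:
        If True, subtract the grand mean of the fraction means before the
        systematic RMS.  The default (False) takes the RMS of the fraction
        means about zero, i.e. Sigma = sqrt(sum_f <e>_f^2 / (N_f - 1)).

    Returns
    -------
    (Sigma, sigma, stats):
        Systematic SD, random SD (RMS over fractions of the per-fraction
        SDs, N_f divisor), and the per-fraction summaries.
    """
    arrays = [np.asarray(a, dtype=float).ravel() for a in samples_by_fraction]
    if len(arrays) < 2:
        raise ValueError("systematic/random decomposition needs >= 2 fractions")
    if fraction_ids is None:
        fraction_ids = [f"F{i + 1}" for i in range(len(arrays))]
    stats = []
    for fid, a in zip(fraction_ids, arrays):
        if a.size < 2:
            raise ValueError(f"fraction {fid}: need >= 2 samples")
        if not np.isfinite(a).all():
            raise ValueError(f"fraction {fid}: non-finite samples")
        stats.append(
            FractionErrorStats(
                fraction_id=str(fid),
                mean=float(np.mean(a)),
                sd=float(np.std(a, ddof=1)),
                n=int(a.size),
            )
        )
    means = np.array([s.mean for s in stats])
    sds = np.array([s.sd for s in stats])
    n_f = len(stats)
    if center_grand_mean:
        means = means - means.mean()
    sigma_sys = float(np.sqrt(np.sum(means**2) / (n_f - 1)))
    sigma_rand = float(np.sqrt(np.mean(sds**2)))
    return sigma_sys, sigma_rand, stats


def van_herk_margin(
    systematic_mm,
    random_mm,
    params: MarginParams | None = None,
) -> float:
    """Van Herk CTV-to-PTV margin from systematic and random SDs (mm).

    ``systematic_mm`` holds the Sigma components (any number; here
    segmentation, deformation, correlation, prediction, targeting) and
    ``random_mm`` the sigma components (correlation, prediction); each set is
    combined in quadrature.  The penumbra enters only the random term:
    M = 2.5*Sigma + beta*(sqrt(sigma^2 + sigma_p^2) - sigma_p), which is 0
    when every component is 0.
    """
    if params is None:
        params = MarginParams()
    sys_c = np.asarray(systematic_mm, dtype=float).ravel()
    rand_c = np.asarray(random_mm, dtype=float).ravel()
    if np.any(sys_c < 0) or np.any(rand_c < 0):
        raise ValueError("error components must be non-negative")
    big_sigma = float(np.sqrt(np.sum(sys_c**2)))
    small_sigma_sq = float(np.sum(rand_c**2))
    return (
        2.5 * big_sigma
        + params.beta * (np.sqrt(small_sigma_sq + params.sigma_p**2) - params.sigma_p)
    )


def combined_uncertainty(u_components) -> float:
    """Expanded (k = 2) combined uncertainty from per-step expanded U's (mm).

    Each U is halved to a standard uncertainty, the five are combined in
    quadrature and re-expanded with k = 2; the factors cancel, leaving the
    Euclidean norm of the U components.
    """
    u = np.asarray(u_components, dtype=float).ravel()
    if np.any(u < 0):
        raise ValueError("uncertainty components must be non-negative")
    return float(np.sqrt(np.sum(u**2)))


def coverage(margins_mm, global_margin_mm: float) -> float:
    """Percent of patients whose individual margin fits inside a global margin.

    A patient is covered when M <= global_margin_mm; returns
    100 * covered / total.
    """
    m = np.asarray(margins_mm, dtype=float).ravel()
    if m.size == 0:
        raise ValueError("coverage needs at least one margin value")
    return float(100.0 * np.count_nonzero(m <= global_margin_mm) / m.size)


# ---------------------------------------------------------------------------
# table-level drivers


def budget_margin_table(budget: pd.DataFrame, params: MarginParams | None = None) -> pd.DataFrame:
    """Per-patient van Herk margins from an error-budget table.

    Expects one row per patient with columns ``Sigma_S``, ``Sigma_D`` (scalar
    per patient) and per-axis ``Sigma_C_<ax>``, ``sigma_C_<ax>``,
    ``Sigma_P_<ax>``, ``sigma_P_<ax>``, ``Sigma_T_<ax>`` for ax in si/lr/ap.
    Returns a frame with ``M_si``, ``M_lr``, ``M_ap`` in mm.
    """
    out = pd.DataFrame({"patient": budget["patient"]})
    for ax in AXES:
        out[f"M_{ax}"] = [
            van_herk_margin(
                [row["Sigma_S"], row["Sigma_D"], row[f"Sigma_C_{ax}"],
                 row[f"Sigma_P_{ax}"], row[f"Sigma_T_{ax}"]],
                [row[f"sigma_C_{ax}"], row[f"sigma_P_{ax}"]],
                params,
            )
            for _, row in budget.iterrows()
        ]
    return out


def uncertainty_margin_table(u_table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient combined expanded uncertainties from a U-component table.

    Expects columns ``U_S``, ``U_D`` and per-axis ``U_C_<ax>``, ``U_P_<ax>``,
    ``U_T_<ax>``; returns ``U_si``, ``U_lr``, ``U_ap`` in mm.
    """
    out = pd.DataFrame({"patient": u_table["patient"]})
    for ax in AXES:
        out[f"U_{ax}"] = [
            combined_uncertainty(
                [row["U_S"], row["U_D"], row[f"U_C_{ax}"],
                 row[f"U_P_{ax}"], row[f"U_T_{ax}"]]
            )
            for _, row in u_table.iterrows()
        ]
    return out


def coverage_report(margin_table: pd.DataFrame, thresholds) -> dict:
    """Coverage percentages per axis for a list of global-margin thresholds."""
    report = {}
    for thr in thresholds:
        report[f"{float(thr):g}mm"] = {
            ax: round(coverage(margin_table[f"M_{ax}"].to_numpy(), float(thr)), 1)
            for ax in AXES
        }
    return report
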