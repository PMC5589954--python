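"""Per-patient error budgets: the five intrafraction error sources.

Real-time tracking replaces setup error with a chain of residual errors.
For margin purposes the chain is split into five independent steps, each
summarized per axis by a systematic SD (Sigma), where applicable a random SD
(sigma), and an expanded uncertainty U = |mu| + 2*sigma:

1. segmentation — centroid registration between reference projections and
   live X-ray images (assigned from phantom literature, constant);
2. deformation — motion of arbitrary target points relative to the tracked
   centroid (assigned by a motion-range/CTV rule);
3. correlation — live X-ray position minus correlation-model position at the
   imaging times (measured from the logs);
4. prediction — correlation-model position one latency horizon ahead minus
   predictor output (measured from the logs);
5. targeting — machine delivery accuracy from end-to-end phantom tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .log_io import AXES, ModelerTrace, TrackingBundle, axis_index, gate_to_beam_on
from .margins import decompose

#: Assigned segmentation error (mm): mean and SD of the centroid-registration
#: residual, applied to all three axes.
SEGMENTATION_MEAN_MM = 0.38
SEGMENTATION_SD_MM = 0.54

#: Deformation rule (mm): (Sigma_D, U_D) for small-motion-or-inside-CTV
#: targets vs large-motion outside-CTV targets; threshold on the centroid
#: motion range.
DEFORMATION_SMALL = (0.75, 1.5)
DEFORMATION_LARGE = (1.25, 2.5)
DEFORMATION_RANGE_THRESHOLD_MM = 20.0


class FractionExcluded(RuntimeError):
    """A fraction has too few usable samples for the requested statistic."""


@dataclass
class ErrorSeries:
    """Signed per-axis discrepancy samples with timestamps.

    ``kind`` is ``"correlation"`` (imaging minus interpolated modeler, one
    sample per retained imaging time) or ``"prediction"`` (modeler
    interpolated one horizon ahead minus predictor output, one sample per
    retained telemetry time).
    """

    kind: str
    t: np.ndarray
    errors: np.ndarray  # (n, 3) mm, signed
    fraction_id: str = "F0"
    patient_id: str = "P0"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float).reshape(-1, 3)
        if self.kind not in ("correlation", "prediction"):
            raise ValueError(f"kind must be 'correlation' or 'prediction', got {self.kind!r}")
        if self.t.size != self.errors.shape[0]:
            raise ValueError("timestamps and errors disagree in length")
        if not (np.isfinite(self.t).all() and np.isfinite(self.errors).all()):
            raise ValueError("error series must be finite")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def axis(self, axis) -> np.ndarray:
        return self.errors[:, axis_index(axis)]


@dataclass(frozen=True)
class DirectionalErrorSummary:
    """One axis's (|mu|, sigma, U = |mu| + 2*sigma) summary in mm."""

    axis: str
    mu_abs: float
    sd: float

    @property
    def U(self) -> float:
        return self.mu_abs + 2.0 * self.sd


def _interp_trace(trace: ModelerTrace, times: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.interp(times, trace.t, trace.pos[:, k]) for k in range(3)]
    )


def correlation_error(bundle: TrackingBundle) -> ErrorSeries:
    """Correlation-model residual at each imaging time.

    The 26 Hz modeler trace is linearly interpolated at each X-ray imaging
    timestamp and subtracted from the imaged position (imaging minus
    modeler).  Imaging samples outside the modeler's time span are dropped
    with a warning; a fraction with fewer than two usable samples raises
    :class:`FractionExcluded`.
    """
    img, mod = bundle.imaging, bundle.modeler
    if len(mod) < 2:
        raise FractionExcluded(f"{bundle.fraction_id}: modeler trace too short")
    inside = (img.t >= mod.t[0]) & (img.t <= mod.t[-1])
    if not inside.all():
        warnings.warn(
            f"{bundle.fraction_id}: dropped {int((~inside).sum())} imaging sample(s) "
            "outside the modeler time span",
            stacklevel=2,
        )
    t = img.t[inside]
    if t.size < 2:
        raise FractionExcluded(
            f"{bundle.fraction_id}: fewer than 2 usable imaging samples"
        )
    errors = img.pos[inside] - _interp_trace(mod, t)
    return ErrorSeries(
        kind="correlation", t=t, errors=errors,
        fraction_id=bundle.fraction_id, patient_id=bundle.patient_id,
    )


def prediction_error(bundle: TrackingBundle, *, max_gap_s: float | None = None) -> ErrorSeries:
    """Predictor residual at each telemetry time.

    For a predictor sample at time t, the error is the modeler position
    linearly interpolated at t + horizon minus the predictor output.
    Samples within one horizon of the modeler stream's end are dropped
    rather than extrapolated, as are samples whose look-ahead time falls
    across a sampling gap wider than ``max_gap_s`` (default: 3x the median
    modeler step) — after beam gating the modeler has no samples inside
    beam-off blocks, so interpolating across them would fabricate the
    reference position.  An empty result raises :class:`FractionExcluded`.
    """
    mod, pred = bundle.modeler, bundle.predictor
    if len(mod) < 2:
        raise FractionExcluded(f"{bundle.fraction_id}: modeler trace too short")
    steps = np.diff(mod.t)
    if max_gap_s is None:
        max_gap_s = 3.0 * float(np.median(steps))
    horizon_s = pred.horizon_ms / 1000.0
    ahead = pred.t + horizon_s
    keep = (ahead >= mod.t[0]) & (ahead <= mod.t[-1])
    left = np.clip(np.searchsorted(mod.t, ahead, side="right") - 1, 0, len(mod) - 2)
    keep &= steps[left] <= max_gap_s
    if not keep.any():
        raise FractionExcluded(
            f"{bundle.fraction_id}: prediction horizon exceeds the modeler span"
        )
    errors = _interp_trace(mod, ahead[keep]) - pred.pos[keep]
    return ErrorSeries(
        kind="prediction", t=pred.t[keep], errors=errors,
        fraction_id=bundle.fraction_id, patient_id=bundle.patient_id,
    )


def expanded_uncertainty(
    samples, axis="si", *, absolute: str = "signed_mean"
) -> DirectionalErrorSummary:
    """Pool error samples on one axis into (|mu|, sigma, U = |mu| + 2*sigma).

    ``samples`` may be an :class:`ErrorSeries`, a sequence of them (pooled
    across fractions), or a 1-D array.  ``absolute="signed_mean"`` takes the
    absolute value of the signed mean (default); ``"mean_abs"`` averages
    absolute errors instead.
    """
    if isinstance(samples, ErrorSeries):
        x = samples.axis(axis)
    elif isinstance(samples, (list, tuple)) and samples and isinstance(samples[0], ErrorSeries):
        x = np.concatenate([s.axis(axis) for s in samples])
    else:
        x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("expanded uncertainty needs >= 2 samples")
    if absolute == "signed_mean":
        mu = abs(float(np.mean(x)))
    elif absolute == "mean_abs":
        mu = float(np.mean(np.abs(x)))
    else:
        raise ValueError("absolute must be 'signed_mean' or 'mean_abs'")
    ax = AXES[axis_index(axis)] if not isinstance(axis, str) else axis
    return DirectionalErrorSummary(axis=str(ax), mu_abs=mu, sd=float(np.std(x, ddof=1)))


def assign_segmentation(
    mean_mm: float = SEGMENTATION_MEAN_MM, sd_mm: float = SEGMENTATION_SD_MM
) -> tuple[float, float]:
    """Assigned segmentation budget, identical on all axes: (Sigma_S, U_S)."""
    if sd_mm < 0:
        raise ValueError("sd_mm must be non-negative")
    return sd_mm, abs(mean_mm) + 2.0 * sd_mm


def assign_deformation(
    com_motion_range_mm, com_inside_ctv: bool
) -> tuple[float, float]:
    """Deformation budget (Sigma_D, U_D) from the centroid motion range rule.

    Targets whose centroid motion range does not exceed 2 cm, or whose
    centroid stays inside the CTV, get (0.75, 1.5) mm; larger-motion
    outside-CTV targets get (1.25, 2.5) mm, on all axes.
    """
    ranges = np.asarray(com_motion_range_mm, dtype=float).ravel()
    if np.any(ranges < 0):
        raise ValueError("motion ranges must be non-negative")
    small = com_inside_ctv or float(np.max(ranges)) <= DEFORMATION_RANGE_THRESHOLD_MM
    return DEFORMATION_SMALL if small else DEFORMATION_LARGE


def targeting_budget(offsets_mm) -> pd.DataFrame:
    """Targeting budget from end-to-end phantom test offsets.

    ``offsets_mm`` is an (n, 3) array (or DataFrame with si/lr/ap columns) of
    signed per-axis targeting offsets, one row per test.  Returns a frame
    indexed by axis with columns ``mean``, ``Sigma_T`` (the SD) and ``U_T``
    (= |mean| + 2*SD), in mm.
    """
    if isinstance(offsets_mm, pd.DataFrame):
        offsets_mm = offsets_mm[[c for c in offsets_mm.columns if c in AXES]].to_numpy()
    x = np.asarray(offsets_mm, dtype=float).reshape(-1, 3)
    if x.shape[0] < 2:
        raise ValueError("targeting budget needs >= 2 end-to-end records")
    if np.any(np.abs(x) >= 5.0):
        raise ValueError("end-to-end offset beyond the 5 mm sanity bound")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return pd.DataFrame(
        {"mean": mean, "Sigma_T": sd, "U_T": np.abs(mean) + 2.0 * sd}, index=list(AXES)
    )


def motion_range(trace, axis=None) -> float | np.ndarray:
    """1-99% range of target positions along an axis within one fraction.

    The range is the 99th minus the 1st percentile of the per-axis position
    samples (linear interpolation between order statistics), a robust
    peak-to-peak measure that ignores the most extreme 2% of samples.
    """
    pos = trace.pos if isinstance(trace, ModelerTrace) else np.asarray(trace, dtype=float)
    if pos.ndim == 1:
        x = pos
    else:
        if axis is None:
            lo, hi = np.percentile(pos, [1, 99], axis=0)
            return hi - lo
        x = pos[:, axis_index(axis)]
    if x.size == 0:
        raise ValueError("motion range of an empty trace is undefined")
    if x.size < 100:
        warnings.warn("motion range from fewer than 100 samples is noisy", stacklevel=2)
    lo, hi = np.percentile(x, [1, 99])
    return float(hi - lo)


@dataclass
class PatientErrorBudget:
    """All five per-axis error components and uncertainties for one patient.

    Arrays are ordered (S-I, L-R, A-P) in mm.  ``motion_range_mm`` holds one
    row per analysed fraction.
    """

    patient_id: str
    Sigma_S: np.ndarray
    U_S: np.ndarray
    Sigma_D: np.ndarray
    U_D: np.ndarray
    Sigma_C: np.ndarray
    sigma_C: np.ndarray
    U_C: np.ndarray
    Sigma_P: np.ndarray
    sigma_P: np.ndarray
    U_P: np.ndarray
    Sigma_T: np.ndarray
    U_T: np.ndarray
    motion_range_mm: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    n_fractions: int = 0

    def budget_row(self) -> dict:
        """Row in the error-budget table layout (Sigma/sigma components)."""
        row = {
            "patient": self.patient_id,
            "Sigma_S": float(self.Sigma_S[0]),
            "Sigma_D": float(self.Sigma_D[0]),
        }
        for k, ax in enumerate(AXES):
            row[f"Sigma_C_{ax}"] = float(self.Sigma_C[k])
            row[f"sigma_C_{ax}"] = float(self.sigma_C[k])
            row[f"Sigma_P_{ax}"] = float(self.Sigma_P[k])
            row[f"sigma_P_{ax}"] = float(self.sigma_P[k])
            row[f"Sigma_T_{ax}"] = float(self.Sigma_T[k])
        return row

    def uncertainty_row(self) -> dict:
        """Row in the expanded-uncertainty table layout (U components)."""
        row = {
            "patient": self.patient_id,
            "U_S": float(self.U_S[0]),
            "U_D": float(self.U_D[0]),
        }
        for k, ax in enumerate(AXES):
            row[f"U_C_{ax}"] = float(self.U_C[k])
            row[f"U_P_{ax}"] = float(self.U_P[k])
            row[f"U_T_{ax}"] = float(self.U_T[k])
        return row


def compute_patient_budget(
    bundles: list[TrackingBundle],
    *,
    targeting: pd.DataFrame,
    patient_id: str | None = None,
    com_inside_ctv: bool = False,
    segmentation=(SEGMENTATION_MEAN_MM, SEGMENTATION_SD_MM),
    gate: bool = True,
    absolute: str = "signed_mean",
) -> tuple[PatientErrorBudget, dict]:
    """Full five-step error budget for one patient from fraction bundles.

    Gates each bundle to beam-on time, derives correlation and prediction
    error series per fraction, decomposes them into systematic/random parts,
    pools them for the expanded uncertainties, measures per-fraction motion
    ranges from the modeler trace, and applies the assigned segmentation,
    deformation and targeting budgets.  ``targeting`` is the output of
    :func:`targeting_budget`.  Returns the budget plus the per-fraction error
    series for reporting (``{"correlation": [...], "prediction": [...]}``).
    """
    if not bundles:
        raise ValueError("need at least one fraction bundle")
    pid = patient_id or bundles[0].patient_id
    kept, corr_series, pred_series = [], [], []
    for b in bundles:
        g = gate_to_beam_on(b) if gate else b
        if g.excluded:
            warnings.warn(f"{pid}/{b.fraction_id}: excluded ({g.exclusion_reason})",
                          stacklevel=2)
            continue
        try:
            corr_series.append(correlation_error(g))
            pred_series.append(prediction_error(g))
        except FractionExcluded as exc:
            warnings.warn(f"{pid}/{b.fraction_id}: excluded ({exc})", stacklevel=2)
            continue
        kept.append(g)
    if len(kept) < 2:
        raise FractionExcluded(f"{pid}: fewer than 2 analysable fractions")

    sig_c = np.zeros(3)
    rand_c = np.zeros(3)
    u_c = np.zeros(3)
    sig_p = np.zeros(3)
    rand_p = np.zeros(3)
    u_p = np.zeros(3)
    for k in range(3):
        sig_c[k], rand_c[k], _ = decompose(
            [s.errors[:, k] for s in corr_series],
            fraction_ids=[s.fraction_id for s in corr_series],
        )
        sig_p[k], rand_p[k], _ = decompose(
            [s.errors[:, k] for s in pred_series],
            fraction_ids=[s.fraction_id for s in pred_series],
        )
        u_c[k] = expanded_uncertainty(corr_series, axis=k, absolute=absolute).U
        u_p[k] = expanded_uncertainty(pred_series, axis=k, absolute=absolute).U

    ranges = np.vstack([motion_range(b.modeler) for b in kept])
    sigma_s, u_s = assign_segmentation(*segmentation)
    sigma_d, u_d = assign_deformation(ranges.max(axis=0), com_inside_ctv)

    budget = PatientErrorBudget(
        patient_id=pid,
        Sigma_S=np.full(3, sigma_s),
        U_S=np.full(3, u_s),
        Sigma_D=np.full(3, sigma_d),
        U_D=np.full(3, u_d),
        Sigma_C=sig_c,
        sigma_C=rand_c,
        U_C=u_c,
        Sigma_P=sig_p,
        sigma_P=rand_p,
        U_P=u_p,
        Sigma_T=targeting["Sigma_T"].to_numpy(dtype=float),
        U_T=targeting["U_T"].to_numpy(dtype=float),
        motion_range_mm=ranges,
        n_fractions=len(kept),
    )
    return budget, {"correlation": corr_series, "prediction": pred_series}
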