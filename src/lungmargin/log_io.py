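"""Tracking-log containers, open text dialects, frame transform and beam gating.

A robotic tracking treatment leaves four telemetry streams per fraction:

* sparse stereo X-ray localizations of the tumor centroid (imaging stream,
  one sample every ~40 s),
* the correlation-model output mapping external LED surrogates to an
  internal tumor position at 26 Hz (modeler stream),
* the prediction-model output, the tumor position forecast 115 ms ahead to
  compensate robot latency (predictor stream),
* beam-on intervals marking when dose was actually delivered.

Vendor log formats are proprietary, so this package defines plain-text CSV
dialects carrying the same content: position streams are
``time_s,si_mm,lr_mm,ap_mm`` (superior-inferior, left-right,
anterior-posterior, millimetres, patient frame unless tagged otherwise) and
the beam file is ``start_s,end_s``.  Timestamps are seconds from fraction
start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

AXES = ("si", "lr", "ap")
AXIS_LABELS = {"si": "S-I", "lr": "L-R", "ap": "A-P"}

POSITION_COLUMNS = ["time_s", "si_mm", "lr_mm", "ap_mm"]
BEAM_COLUMNS = ["start_s", "end_s"]

IMAGING_FILE = "modelpoints.csv"
MODELER_FILE = "modeler.csv"
PREDICTOR_FILE = "predictor.csv"
BEAM_FILE = "beam.csv"


class LogParseError(ValueError):
    """Raised when a log file violates its dialect (with offending line numbers)."""


class FrameError(ValueError):
    """Raised for an invalid coordinate transform (non-orthonormal rotation)."""


def axis_index(axis: int | str) -> int:
    """Resolve an axis given as index, short name (``"si"``) or label (``"S-I"``)."""
    if isinstance(axis, (int, np.integer)):
        if not 0 <= axis <= 2:
            raise ValueError(f"axis index out of range: {axis}")
        return int(axis)
    key = str(axis).lower().replace("-", "")
    for i, name in enumerate(AXES):
        if key in (name, AXIS_LABELS[name].lower().replace("-", "")):
            return i
    raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")


def _check_time_positions(t: np.ndarray, pos: np.ndarray, what: str) -> None:
    if t.ndim != 1 or pos.shape != (t.size, 3):
        raise ValueError(f"{what}: need t of shape (n,) and positions of shape (n, 3)")
    if not (np.isfinite(t).all() and np.isfinite(pos).all()):
        raise ValueError(f"{what}: non-finite samples")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{what}: timestamps must be strictly increasing")


@dataclass
class ImagingSeries:
    """Sparse X-ray tumor localizations (X_i, Y_i, Z_i at times T_i)."""

    t: np.ndarray
    pos: np.ndarray
    nominal_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        _check_time_positions(self.t, self.pos, "imaging series")
        if self.nominal_interval_s is not None and self.t.size > 2:
            med = float(np.median(np.diff(self.t)))
            if abs(med - self.nominal_interval_s) > 0.5 * self.nominal_interval_s:
                warnings.warn(
                    f"imaging spacing {med:.1f} s deviates >50% from the "
                    f"nominal {self.nominal_interval_s:.1f} s interval",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return self.t.size


@dataclass
class ModelerTrace:
    """Correlation-model tumor positions at the telemetry rate (nominal 26 Hz)."""

    t: np.ndarray
    pos: np.ndarray
    frame: str = "patient"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        _check_time_positions(self.t, self.pos, "modeler trace")
        if self.frame not in ("patient", "robot"):
            raise ValueError(f"frame must be 'patient' or 'robot', got {self.frame!r}")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class PredictorTrace:
    """Prediction-model output: tumor position forecast ``horizon_ms`` ahead."""

    t: np.ndarray
    pos: np.ndarray
    horizon_ms: float = 115.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        _check_time_positions(self.t, self.pos, "predictor trace")
        if self.horizon_ms <= 0:
            raise ValueError("horizon_ms must be positive")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class BeamIntervals:
    """Ordered disjoint (start_s, end_s) intervals of actual dose delivery."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 1] < iv[:, 0]) or np.any(iv < 0):
                raise ValueError("beam intervals must be non-negative with end >= start")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError("beam intervals must be ordered and disjoint")
        self.intervals = iv

    def __len__(self) -> int:
        return self.intervals.shape[0]

    def contains(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask: which timestamps fall inside a beam-on interval."""
        t = np.asarray(t, dtype=float)
        if len(self) == 0:
            return np.zeros(t.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], t, side="right") - 1
        ok = idx >= 0
        mask = np.zeros(t.shape, dtype=bool)
        mask[ok] = t[ok] <= self.intervals[idx[ok], 1]
        return mask

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0])) if len(self) else 0.0


@dataclass
class TrackingBundle:
    """One fraction's four streams on the common patient-frame axis convention."""

    imaging: ImagingSeries
    modeler: ModelerTrace
    predictor: PredictorTrace
    beam: BeamIntervals
    patient_id: str = "P0"
    fraction_id: str = "F0"
    excluded: bool = False
    exclusion_reason: str = ""


def rotate_positions(pos: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Apply a 3x3 rotation to an (n, 3) position block (row vectors)."""
    return np.asarray(pos, dtype=float) @ np.asarray(rotation, dtype=float).T


def _validate_rotation(rotation: np.ndarray) -> np.ndarray:
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3):
        raise FrameError(f"rotation must be 3x3, got shape {r.shape}")
    if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
        raise FrameError("rotation matrix is not orthonormal within 1e-9")
    return r


def to_patient_frame(trace: ModelerTrace, rotation: np.ndarray) -> ModelerTrace:
    """Rotate a robot-frame trace into the patient frame.

    The rotation must be orthonormal (R^T R = I within 1e-9).  Timestamps are
    untouched; the returned trace is tagged ``frame="patient"``.
    """
    r = _validate_rotation(rotation)
    return ModelerTrace(t=trace.t.copy(), pos=rotate_positions(trace.pos, r), frame="patient")


def gate_to_beam_on(bundle: TrackingBundle) -> TrackingBundle:
    """Restrict all position streams to beam-on time.

    Only samples coincident with dose delivery enter any error statistic.
    Gating is idempotent; a bundle left with fewer than two imaging samples
    is flagged ``excluded`` so downstream stages can drop the fraction.
    """
    beam = bundle.beam
    out = {}
    for name in ("imaging", "modeler", "predictor"):
        stream = getattr(bundle, name)
        mask = beam.contains(stream.t)
        kwargs = {"t": stream.t[mask], "pos": stream.pos[mask]}
        if isinstance(stream, ModelerTrace):
            kwargs["frame"] = stream.frame
        elif isinstance(stream, PredictorTrace):
            kwargs["horizon_ms"] = stream.horizon_ms
        elif stream.nominal_interval_s is not None:
            kwargs["nominal_interval_s"] = stream.nominal_interval_s
        out[name] = type(stream)(**kwargs)
    excluded = len(out["imaging"]) < 2 or len(out["modeler"]) == 0
    reason = "fewer than 2 beam-on imaging samples" if excluded else ""
    return TrackingBundle(
        imaging=out["imaging"],
        modeler=out["modeler"],
        predictor=out["predictor"],
        beam=beam,
        patient_id=bundle.patient_id,
        fraction_id=bundle.fraction_id,
        excluded=excluded or bundle.excluded,
        exclusion_reason=reason or bundle.exclusion_reason,
    )


# ---------------------------------------------------------------------------
# dialect I/O


def _write_csv(path: Path, columns: list[str], data: np.ndarray) -> None:
    pd.DataFrame(np.asarray(data, dtype=float).reshape(-1, len(columns)), columns=columns).to_csv(
        path, index=False, float_format="%.6f"
    )


def write_bundle(bundle: TrackingBundle, directory: str | Path) -> dict[str, Path]:
    """Write the four streams of one fraction in the package's CSV dialects."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "imaging": d / IMAGING_FILE,
        "modeler": d / MODELER_FILE,
        "predictor": d / PREDICTOR_FILE,
        "beam": d / BEAM_FILE,
    }
    for name in ("imaging", "modeler", "predictor"):
        s = getattr(bundle, name)
        _write_csv(paths[name], POSITION_COLUMNS, np.column_stack([s.t, s.pos]))
    _write_csv(paths["beam"], BEAM_COLUMNS, bundle.beam.intervals)
    return paths


def _read_numeric_csv(path: Path, columns: list[str]) -> np.ndarray:
    """Read one dialect file, enforcing the <=1% malformed-line contract."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"log file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
        if list(df.columns) != columns or df.isna().any().any():
            raise ValueError("dialect mismatch")
        return df.to_numpy(dtype=float)
    except Exception:  # fall back to a line scan for diagnostics
        return _careful_read(path, columns)


def _careful_read(path: Path, columns: list[str]) -> np.ndarray:
    rows, bad = [], []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or [c.strip() for c in lines[0].split(",")] != columns:
        raise LogParseError(f"{path}: missing or wrong header; expected {','.join(columns)}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(",")
        try:
            vals = [float(p) for p in parts]
            if len(vals) != len(columns) or not all(np.isfinite(vals)):
                raise ValueError
            rows.append(vals)
        except ValueError:
            bad.append(lineno)
    total = len(rows) + len(bad)
    if bad and total and len(bad) / total > 0.01:
        shown = ", ".join(map(str, bad[:10]))
        raise LogParseError(f"{path}: {len(bad)}/{total} malformed lines (lines {shown} ...)")
    if bad:
        warnings.warn(f"{path}: skipped {len(bad)} malformed line(s): {bad}", stacklevel=3)
    return np.asarray(rows, dtype=float).reshape(-1, len(columns))


def parse_bundle(
    directory: str | Path | None = None,
    *,
    imaging_path: str | Path | None = None,
    modeler_path: str | Path | None = None,
    predictor_path: str | Path | None = None,
    beam_path: str | Path | None = None,
    rotation: np.ndarray | None = None,
    modeler_frame: str = "patient",
    horizon_ms: float = 115.0,
    nominal_imaging_interval_s: float | None = 40.0,
    patient_id: str = "P0",
    fraction_id: str = "F0",
) -> TrackingBundle:
    """Parse the four log files of one fraction into a :class:`TrackingBundle`.

    If ``modeler_frame`` is ``"robot"``, the supplied ``rotation`` is applied to
    the modeler and predictor streams so that every stream of the returned
    bundle is in the patient frame.  Malformed lines are tolerated up to 1% of
    a file (skipped with a warning); beyond that a :class:`LogParseError`
    reports the line numbers.
    """
    if directory is not None:
        d = Path(directory)
        imaging_path = imaging_path or d / IMAGING_FILE
        modeler_path = modeler_path or d / MODELER_FILE
        predictor_path = predictor_path or d / PREDICTOR_FILE
        beam_path = beam_path or d / BEAM_FILE
    if None in (imaging_path, modeler_path, predictor_path, beam_path):
        raise ValueError("provide a directory or all four stream paths")

    img = _read_numeric_csv(Path(imaging_path), POSITION_COLUMNS)
    mod = _read_numeric_csv(Path(modeler_path), POSITION_COLUMNS)
    pred = _read_numeric_csv(Path(predictor_path), POSITION_COLUMNS)
    beam = _read_numeric_csv(Path(beam_path), BEAM_COLUMNS)

    modeler = ModelerTrace(t=mod[:, 0], pos=mod[:, 1:], frame=modeler_frame)
    predictor = PredictorTrace(t=pred[:, 0], pos=pred[:, 1:], horizon_ms=horizon_ms)
    if modeler_frame == "robot":
        if rotation is None:
            raise FrameError("robot-frame logs require a rotation matrix")
        modeler = to_patient_frame(modeler, rotation)
        predictor = PredictorTrace(
            t=predictor.t,
            pos=rotate_positions(predictor.pos, _validate_rotation(rotation)),
            horizon_ms=horizon_ms,
        )
    return TrackingBundle(
        imaging=ImagingSeries(
            t=img[:, 0], pos=img[:, 1:], nominal_interval_s=nominal_imaging_interval_s
        ),
        modeler=modeler,
        predictor=predictor,
        beam=BeamIntervals(intervals=beam),
        patient_id=patient_id,
        fraction_id=fraction_id,
    )
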