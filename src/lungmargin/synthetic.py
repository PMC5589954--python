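"""Synthetic respiratory motion and tracking-log generation.

Produces ground-truth quasi-periodic 3-D tumor trajectories and the full
four-stream log bundle with a *known, recoverable* error structure, so every
downstream stage (gating, error series, systematic/random decomposition,
margins) can be validated without any clinical data.

The error model mirrors the clinical chain: the correlation model is the
truth plus a per-fraction systematic offset plus i.i.d. Gaussian residuals;
the predictor is the correlation-model value one latency horizon (115 ms by
default) ahead plus its own residual; imaging samples are exact truth at
sparse (~40 s) intervals; beam-on alternates fixed on/off blocks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .log_io import (
    BeamIntervals,
    ImagingSeries,
    ModelerTrace,
    PredictorTrace,
    TrackingBundle,
    write_bundle,
)


class ConfigurationError(ValueError):
    """A simulation configuration field violates its invariant."""


def _triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class RespiratoryConfig:
    """Parameters of one simulated treatment fraction.

    Defaults follow the study conditions this generator emulates: breathing
    period ~4 s; per-axis peak-to-peak motion of 9.0 / 8.5 / 4.8 mm
    (S-I / L-R / A-P); imaging every 40 s; telemetry at 26 Hz; 115 ms
    prediction horizon; fraction length 1720 s (~29 min, giving ~43 imaging
    samples, inside the typical 30-50 image pairs per fraction).
    """

    period_s: float = 4.0
    amplitude_mm: tuple[float, float, float] = (9.0, 8.5, 4.8)
    baseline_drift_mm_per_min: tuple[float, float, float] = (0.3, 0.1, 0.1)
    cycle_jitter_frac: float = 0.05
    corr_sys_mm: tuple[float, float, float] = (0.3, 0.2, 0.2)
    corr_rand_mm: tuple[float, float, float] = (1.1, 0.8, 1.0)
    pred_rand_mm: tuple[float, float, float] = (0.12, 0.12, 0.08)
    waveform_exponent: int = 1
    imaging_interval_s: float = 40.0
    sample_rate_hz: float = 26.0
    horizon_ms: float = 115.0
    duration_s: float = 1720.0
    beam_on_s: float = 60.0
    beam_off_s: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("amplitude_mm", "baseline_drift_mm_per_min", "corr_sys_mm",
                     "corr_rand_mm", "pred_rand_mm"):
            object.__setattr__(self, name, _triple(getattr(self, name)))
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the first offending field."""
        for name in ("amplitude_mm", "corr_sys_mm", "corr_rand_mm", "pred_rand_mm"):
            if any(v < 0 for v in getattr(self, name)):
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("period_s", "sample_rate_hz", "duration_s", "imaging_interval_s",
                     "beam_on_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.cycle_jitter_frac < 0:
            raise ConfigurationError("cycle_jitter_frac must be non-negative")
        if self.beam_off_s < 0:
            raise ConfigurationError("beam_off_s must be non-negative")
        if self.horizon_ms <= 0:
            raise ConfigurationError("horizon_ms must be positive")
        if self.waveform_exponent < 1:
            raise ConfigurationError("waveform_exponent must be >= 1")
        if self.imaging_interval_s <= 1.0 / self.sample_rate_hz:
            raise ConfigurationError(
                "imaging_interval_s must exceed the telemetry sampling step"
            )


@dataclass
class SimTruth:
    """Ground truth behind one synthetic fraction, kept for recovery tests."""

    t: np.ndarray                       # telemetry time grid (s)
    true_trajectory: np.ndarray         # (n, 3) mm
    injected_corr_offset_mm: tuple[float, float, float]
    injected_noise_sds: dict            # {"correlation": (3,), "prediction": (3,)}
    beam_intervals: np.ndarray          # (k, 2) s
    corr_residuals: np.ndarray          # (n, 3) realized correlation residual draws
    pred_residuals: np.ndarray          # (n, 3) realized predictor residual draws
    config: RespiratoryConfig | None = None

    def to_sidecar(self) -> dict:
        """JSON-serializable summary (scalars and beam intervals, not arrays)."""
        return {
            "injected_corr_offset_mm": list(self.injected_corr_offset_mm),
            "injected_noise_sds": {k: list(v) for k, v in self.injected_noise_sds.items()},
            "beam_intervals": self.beam_intervals.tolist(),
            "n_samples": int(self.t.size),
        }


class _Waveform:
    """Quasi-periodic breathing waveform with cycle-to-cycle period jitter.

    Per axis: position(t) = drift*t + A*(cos^(2p)(pi*phi(t)) - 1/2), where
    phi is the accumulated cycle phase.  cos^(2p) spans [0, 1], so the
    peak-to-peak excursion equals the configured amplitude A exactly; p > 1
    sharpens the inhale peak (asymmetric breathing), p = 1 is a pure cosine.
    """

    def __init__(self, config: RespiratoryConfig, rng: np.random.Generator):
        n_cycles = int(np.ceil(config.duration_s / config.period_s)) + 2
        if config.cycle_jitter_frac > 0:
            factors = 1.0 + config.cycle_jitter_frac * rng.standard_normal(n_cycles)
            factors = np.clip(factors, 0.2, 5.0)
        else:
            factors = np.ones(n_cycles)
        self.periods = config.period_s * factors
        self.boundaries = np.concatenate([[0.0], np.cumsum(self.periods)])
        self.config = config

    def phase(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        k = np.clip(np.searchsorted(self.boundaries, t, side="right") - 1, 0,
                    len(self.periods) - 1)
        return k + (t - self.boundaries[k]) / self.periods[k]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        c = self.config
        phi = self.phase(t)
        shape = np.cos(np.pi * phi) ** (2 * c.waveform_exponent) - 0.5
        drift = np.asarray(c.baseline_drift_mm_per_min) / 60.0
        amp = np.asarray(c.amplitude_mm)
        return np.asarray(t, dtype=float)[:, None] * drift[None, :] + amp[None, :] * shape[:, None]


def _beam_blocks(config: RespiratoryConfig) -> np.ndarray:
    starts = np.arange(0.0, config.duration_s, config.beam_on_s + config.beam_off_s)
    ends = np.minimum(starts + config.beam_on_s, config.duration_s)
    return np.column_stack([starts, ends])


def simulate_fraction(
    config: RespiratoryConfig,
    *,
    rng: np.random.Generator | None = None,
    corr_offset_mm: tuple[float, float, float] | None = None,
    patient_id: str = "P0",
    fraction_id: str = "F0",
) -> tuple[SimTruth, TrackingBundle]:
    """Simulate one treatment fraction: ground truth plus four-stream bundle.

    The modeler stream is truth + systematic offset + N(0, corr_rand) per
    axis; the predictor stream is the (noisy) modeler linearly interpolated
    at t + horizon plus N(0, pred_rand); the imaging stream is exact truth at
    the sparse imaging times.  The systematic offset defaults to
    ``config.corr_sys_mm`` itself; cohort simulation passes per-fraction
    draws via ``corr_offset_mm``.  Identical (config, seed) give identical
    output.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    waveform = _Waveform(config, rng)
    t26 = np.arange(0.0, config.duration_s, 1.0 / config.sample_rate_hz)
    truth = waveform(t26)

    offset = _triple(config.corr_sys_mm if corr_offset_mm is None else corr_offset_mm)
    corr_resid = rng.standard_normal((t26.size, 3)) * np.asarray(config.corr_rand_mm)
    modeler_pos = truth + np.asarray(offset)[None, :] + corr_resid

    horizon_s = config.horizon_ms / 1000.0
    pred_resid = rng.standard_normal((t26.size, 3)) * np.asarray(config.pred_rand_mm)
    ahead = np.column_stack(
        [np.interp(t26 + horizon_s, t26, modeler_pos[:, k]) for k in range(3)]
    )
    predictor_pos = ahead + pred_resid

    t_img = np.arange(config.imaging_interval_s, config.duration_s, config.imaging_interval_s)
    imaging_pos = waveform(t_img)

    beam = _beam_blocks(config)

    truth_rec = SimTruth(
        t=t26,
        true_trajectory=truth,
        injected_corr_offset_mm=offset,
        injected_noise_sds={
            "correlation": config.corr_rand_mm,
            "prediction": config.pred_rand_mm,
        },
        beam_intervals=beam,
        corr_residuals=corr_resid,
        pred_residuals=pred_resid,
        config=config,
    )
    bundle = TrackingBundle(
        imaging=ImagingSeries(t=t_img, pos=imaging_pos,
                              nominal_interval_s=config.imaging_interval_s),
        modeler=ModelerTrace(t=t26, pos=modeler_pos, frame="patient"),
        predictor=PredictorTrace(t=t26, pos=predictor_pos, horizon_ms=config.horizon_ms),
        beam=BeamIntervals(intervals=beam),
        patient_id=patient_id,
        fraction_id=fraction_id,
    )
    return truth_rec, bundle


@dataclass
class PatientSim:
    """One simulated patient: metadata plus per-fraction (truth, bundle) pairs."""

    patient_id: str
    amplitude_mm: tuple[float, float, float]
    lobe: str                 # "upper_middle" | "lower"
    location: str             # "central" | "peripheral"
    volume_cm3: float
    fractions: list  # list of (SimTruth, TrackingBundle)


# Cohort-level dispersion of per-axis motion between patients (mm, SD of the
# peak-to-peak amplitude around the configured mean), and the clinical mix of
# lesion sites emulated by the metadata draws.
AMPLITUDE_BETWEEN_PATIENT_SD_MM = (7.3, 5.6, 3.5)
LOWER_LOBE_FRACTION = 6 / 22
CENTRAL_FRACTION = 13 / 22
VOLUME_MEAN_CM3, VOLUME_SD_CM3 = 12.7, 7.8


def simulate_cohort(
    n_patients: int = 22,
    n_fractions_range: tuple[int, int] = (3, 5),
    base_config: RespiratoryConfig | None = None,
    seed: int = 0,
    *,
    amplitude_between_sd_mm: tuple[float, float, float] = AMPLITUDE_BETWEEN_PATIENT_SD_MM,
    noise_amplitude_coupling: float = 0.5,
    min_amplitude_mm: float = 0.5,
) -> list[PatientSim]:
    """Simulate a treatment cohort with patient-to-patient variability.

    Per-axis amplitudes are drawn for each patient from a normal distribution
    around ``base_config.amplitude_mm`` (SD ``amplitude_between_sd_mm``),
    truncated below at ``min_amplitude_mm`` by redrawing.  The per-fraction
    systematic correlation offset is redrawn each fraction from
    N(0, corr_sys_mm), making the systematic component a recoverable
    quantity.  ``noise_amplitude_coupling`` scales each patient's random
    correlation/prediction residual SDs with relative amplitude
    (sd_patient = sd_base * (1 - c + c*amp/amp_base)), emulating the observed
    association between motion range and tracking-error dispersion; set it to
    0 for amplitude-independent noise.  All draws descend from one seed
    through per-patient/per-fraction spawned substreams, so any subset is
    reproducible.
    """
    if n_patients < 1:
        raise ConfigurationError("n_patients must be >= 1")
    lo, hi = n_fractions_range
    if lo < 1 or hi < lo:
        raise ConfigurationError("n_fractions_range must satisfy 1 <= min <= max")
    if base_config is None:
        base_config = RespiratoryConfig()
    if not 0 <= noise_amplitude_coupling <= 1:
        raise ConfigurationError("noise_amplitude_coupling must be in [0, 1]")

    root = np.random.SeedSequence(seed)
    patient_seeds = root.spawn(n_patients)
    base_amp = np.asarray(base_config.amplitude_mm)
    cohort: list[PatientSim] = []
    for p, ss in enumerate(patient_seeds):
        prng = np.random.default_rng(ss)
        amp = np.empty(3)
        for k in range(3):
            draw = prng.normal(base_amp[k], amplitude_between_sd_mm[k])
            while draw < min_amplitude_mm:
                draw = prng.normal(base_amp[k], amplitude_between_sd_mm[k])
            amp[k] = draw
        rel = float(np.mean(amp / np.maximum(base_amp, 1e-9)))
        scale = 1.0 - noise_amplitude_coupling + noise_amplitude_coupling * rel
        cfg = replace(
            base_config,
            amplitude_mm=tuple(amp),
            corr_rand_mm=tuple(np.asarray(base_config.corr_rand_mm) * scale),
            pred_rand_mm=tuple(np.asarray(base_config.pred_rand_mm) * scale),
        )
        n_frac = int(prng.integers(lo, hi + 1))
        lobe = "lower" if prng.random() < LOWER_LOBE_FRACTION else "upper_middle"
        location = "central" if prng.random() < CENTRAL_FRACTION else "peripheral"
        volume = max(0.5, prng.normal(VOLUME_MEAN_CM3, VOLUME_SD_CM3))
        fractions = []
        for f in range(n_frac):
            frng = np.random.default_rng(ss.spawn(1)[0])
            offset = frng.normal(0.0, np.asarray(base_config.corr_sys_mm))
            truth, bundle = simulate_fraction(
                cfg,
                rng=frng,
                corr_offset_mm=tuple(offset),
                patient_id=f"P{p + 1:02d}",
                fraction_id=f"F{f + 1}",
            )
            fractions.append((truth, bundle))
        cohort.append(
            PatientSim(
                patient_id=f"P{p + 1:02d}",
                amplitude_mm=tuple(amp),
                lobe=lobe,
                location=location,
                volume_cm3=volume,
                fractions=fractions,
            )
        )
    return cohort


def write_cohort(cohort: list[PatientSim], directory: str | Path) -> Path:
    """Write every fraction's log bundle plus a ground-truth JSON sidecar."""
    root = Path(directory)
    for patient in cohort:
        for truth, bundle in patient.fractions:
            d = root / patient.patient_id / bundle.fraction_id
            write_bundle(bundle, d)
            with open(d / "truth.json", "w") as fh:
                json.dump(truth.to_sidecar(), fh, indent=1)
    return root
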