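"""Local size-conformity evaluation of reconstructed feature measurements.

In laparoscopic inspection the quantity that matters is usually a local
one: the size of a target lesion or other salient feature.  Conformity is
quantified by measuring the feature repeatedly in the metric-scaled
reconstruction (Euclidean distance between manually picked endpoints) and
comparing against the physically measured true length D^gt:

    RMSE      = sqrt( (1/N) Σ (D_i − D^gt)² )          [mm]
    rel. RMS  = sqrt( (1/N) Σ r_i² ),  r_i = 100·|D_i − D^gt| / D^gt   [%]

With one shared ground truth the two are related exactly by
``rel_rms = 100 · RMSE / D^gt``; both forms are provided because reports
conventionally print both columns.

All statistics are computed at full precision; rounding (half-to-even,
2 decimal places) happens only in the display helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud_io import MeasurementConfig
from .geometry import InvalidInputError, euclidean_distance

__all__ = [
    "TrialSet",
    "EvaluationReport",
    "measure_trials",
    "rmse",
    "relative_error_rms",
    "evaluate",
    "trial_set_from_config",
]


@dataclass
class TrialSet:
    """Repeated endpoint-pair picks of one feature, in mm, with its true length."""

    trials: list[tuple[np.ndarray, np.ndarray]]
    true_length_mm: float
    label: str = ""

    def __post_init__(self):
        if len(self.trials) < 1:
            raise InvalidInputError("a trial set needs at least one trial")
        if not (self.true_length_mm > 0):
            raise InvalidInputError("true length must be positive")
        self.trials = [
            (np.asarray(a, dtype=float).reshape(3), np.asarray(b, dtype=float).reshape(3))
            for a, b in self.trials
        ]

    @property
    def n(self) -> int:
        return len(self.trials)


def trial_set_from_config(config: MeasurementConfig) -> TrialSet:
    """Build a TrialSet from a measurement config, converting coordinates to mm."""
    return TrialSet(
        trials=config.endpoints_mm(),
        true_length_mm=config.true_length_mm,
        label=config.label,
    )


def measure_trials(trial_set: TrialSet) -> np.ndarray:
    """Per-trial measured lengths D_i (mm), order preserved."""
    return np.array(
        [euclidean_distance(a, b) for a, b in trial_set.trials], dtype=float
    )


def rmse(measured, truth: float) -> float:
    """Root-mean-square error of measurements against a single true length."""
    d = np.asarray(measured, dtype=float)
    if d.size == 0:
        raise InvalidInputError("at least one measurement is required")
    if not (truth > 0):
        raise InvalidInputError("true length must be positive")
    return float(np.sqrt(np.mean((d - truth) ** 2)))


def relative_error_rms(measured, truth: float) -> float:
    """RMS of per-trial relative errors, in percent."""
    d = np.asarray(measured, dtype=float)
    if d.size == 0:
        raise InvalidInputError("at least one measurement is required")
    if not (truth > 0):
        raise InvalidInputError("true length must be positive")
    rel = 100.0 * np.abs(d - truth) / truth
    return float(np.sqrt(np.mean(rel**2)))


@dataclass
class EvaluationReport:
    """Per-trial measurements and errors plus the aggregate RMSE statistics."""

    label: str
    true_length_mm: float
    measured_mm: np.ndarray
    abs_error_mm: np.ndarray
    rel_error_pct: np.ndarray
    rmse_mm: float
    rel_rmse_pct: float
    n: int

    def to_dict(self) -> dict:
        """Full-precision, JSON-serialisable form."""
        return {
            "label": self.label,
            "true_length_mm": self.true_length_mm,
            "n": self.n,
            "measured_mm": [float(v) for v in self.measured_mm],
            "abs_error_mm": [float(v) for v in self.abs_error_mm],
            "rel_error_pct": [float(v) for v in self.rel_error_pct],
            "rmse_mm": self.rmse_mm,
            "rel_rmse_pct": self.rel_rmse_pct,
        }

    def to_markdown(self) -> str:
        """Human-readable table: trial rows with an RMSE footer, 2-dp display."""
        r2 = _round2
        lines = [
            f"Feature: {self.label or '(unlabelled)'} — true length "
            f"{r2(self.true_length_mm):.2f} mm, N = {self.n}",
            "",
            "| Trial | Measured/mm | Absolute Error/mm | Relative Error/% |",
            "|------:|------------:|------------------:|-----------------:|",
        ]
        for i in range(self.n):
            lines.append(
                f"| {i + 1} | {r2(self.measured_mm[i]):.2f} "
                f"| {r2(self.abs_error_mm[i]):.2f} "
                f"| {r2(self.rel_error_pct[i]):.2f} |"
            )
        lines.append(
            f"| RMSE | / | {r2(self.rmse_mm):.2f} | {r2(self.rel_rmse_pct):.2f} |"
        )
        return "\n".join(lines)


def _round2(x: float) -> float:
    # numpy rounds half-to-even, which is the convention used for display
    return float(np.round(x, 2))


def evaluate(trial_set: TrialSet) -> EvaluationReport:
    """Measure every trial and assemble the conformity report."""
    measured = measure_trials(trial_set)
    truth = trial_set.true_length_mm
    abs_err = np.abs(measured - truth)
    rel_err = 100.0 * abs_err / truth
    return EvaluationReport(
        label=trial_set.label,
        true_length_mm=truth,
        measured_mm=measured,
        abs_error_mm=abs_err,
        rel_error_pct=rel_err,
        rmse_mm=rmse(measured, truth),
        rel_rmse_pct=relative_error_rms(measured, truth),
        n=trial_set.n,
    )
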