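"""Evaluation metrics over actual/predicted bpm pairs.

Given per-volunteer (actual, predicted) bpm pairs the report carries:

* per-pair relative error, 100·|actual − predicted| / actual (percent);
* MAE — mean absolute difference in bpm;
* MSE — mean squared difference in bpm²;
* "pipeline accuracy (definition D1)" = 100 − mean error % (a reporting
  convention of this package; the field has no single accuracy definition
  for rate prediction);
* correct fraction — percentage of pairs predicted exactly.

Two benchmark pair sets transcribed from published result tables ship with
the package (``load_benchmark("table3")`` / ``"table4"``). Note that the
published summary MAE/MSE figures for those tables are not arithmetic
consequences of their own printed pairs; this module always reports values
recomputed from the pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

ACCURACY_DEFINITION = "pipeline accuracy (definition D1): 100 - mean error %"


@dataclass(frozen=True)
class RatePair:
    """One volunteer's measured and predicted heart rate."""

    volunteer_id: str
    actual_bpm: int
    predicted_bpm: int

    def __post_init__(self) -> None:
        for name, v in (("actual_bpm", self.actual_bpm),
                        ("predicted_bpm", self.predicted_bpm)):
            if not 20 <= v <= 300:
                raise InputError(f"{name} {v} outside plausible range [20, 300]")


@dataclass
class EvaluationReport:
    pairs: List[RatePair]
    error_percent: np.ndarray
    mae: float
    mse: float
    accuracy_percent: float
    correct_fraction_percent: float

    def to_dict(self) -> dict:
        return {
            "n_pairs": len(self.pairs),
            "mae": self.mae,
            "mse": self.mse,
            "accuracy_percent": self.accuracy_percent,
            "accuracy_definition": ACCURACY_DEFINITION,
            "correct_fraction_percent": self.correct_fraction_percent,
            "max_error_percent": float(self.error_percent.max()),
            "pairs": [
                {
                    "volunteer_id": p.volunteer_id,
                    "actual_bpm": p.actual_bpm,
                    "predicted_bpm": p.predicted_bpm,
                    "error_percent": float(e),
                }
                for p, e in zip(self.pairs, self.error_percent)
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def render_table(self) -> str:
        """Plain-text table mirroring the published layout."""
        lines = [f"{'Volunteer':<10}{'Actual bpm':>11}{'Predicted bpm':>15}"
                 f"{'Error %':>10}"]
        for p, e in zip(self.pairs, self.error_percent):
            lines.append(f"{p.volunteer_id:<10}{p.actual_bpm:>11}"
                         f"{p.predicted_bpm:>15}{e:>10.3f}")
        lines.append("")
        lines.append(f"MAE = {self.mae:.3f} bpm   MSE = {self.mse:.3f} bpm²   "
                     f"accuracy = {self.accuracy_percent:.3f}%   "
                     f"exact = {self.correct_fraction_percent:.1f}%")
        return "\n".join(lines)


def error_percent(actual: float, predicted: float) -> float:
    """Relative error in percent: 100·|actual − predicted| / actual."""
    if actual <= 0:
        raise InputError(f"actual bpm must be > 0, got {actual}")
    return 100.0 * abs(actual - predicted) / actual


def summarize(pairs: Sequence[RatePair]) -> EvaluationReport:
    """Full metric report over a non-empty pair list (full precision)."""
    if len(pairs) == 0:
        raise InputError("no pairs to summarize")
    actual = np.array([p.actual_bpm for p in pairs], dtype=float)
    predicted = np.array([p.predicted_bpm for p in pairs], dtype=float)
    errors = 100.0 * np.abs(actual - predicted) / actual
    diff = actual - predicted
    return EvaluationReport(
        pairs=list(pairs),
        error_percent=errors,
        mae=float(np.abs(diff).mean()),
        mse=float((diff ** 2).mean()),
        accuracy_percent=float(100.0 - errors.mean()),
        correct_fraction_percent=float(100.0 * (diff == 0).mean()),
    )


def read_pairs_csv(path) -> List[RatePair]:
    """Read a volunteer_id,actual_bpm,predicted_bpm CSV (header required)."""
    df = pd.read_csv(path)
    required = {"volunteer_id", "actual_bpm", "predicted_bpm"}
    if not required.issubset(df.columns):
        raise InputError(
            f"CSV {path} must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return [
        RatePair(str(r.volunteer_id), int(r.actual_bpm), int(r.predicted_bpm))
        for r in df.itertuples()
    ]


def load_benchmark(name: str) -> List[RatePair]:
    """Load a bundled benchmark pair set: 'table3' or 'table4'."""
    if name not in {"table3", "table4"}:
        raise InputError(f"unknown benchmark {name!r}")
    ref = resources.files("pulsebeat.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return read_pairs_csv(path)
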