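"""Nucleus-position calibration.

Calibration adjusts the nucleus position ratio P1 until the model's
flexion/extension range of motion matches in-vitro cadaveric targets.  The
agreement score is the relative-error accuracy

    ACC = (1 - |computed - target| / |target|) * 100   [%, clipped at 0]

which equals 100 exactly at the target and penalises overshoot and
undershoot symmetrically.  The loop sweeps an increasing P1 grid, scores
both directions at every step, and stops at the first P1 whose flexion AND
extension accuracies reach the threshold (default 99%); if none qualifies
it reports the best compromise (argmax of the worse of the two accuracies)
with ``converged=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DiscCalibError

__all__ = [
    "RoMEvaluator",
    "CalibrationTargets",
    "CalibrationResult",
    "accuracy",
    "calibrate_p1",
    "sweep_report",
    "default_grid",
    "DEFAULT_THRESHOLD",
]

#: Convergence threshold (percent) at which the published sweep stopped.
DEFAULT_THRESHOLD = 99.0

RoMEvaluator = Callable[[float], tuple[float, float]]


@dataclass(frozen=True)
class CalibrationTargets:
    """In-vitro RoM targets (degrees) at the calibration moment."""

    flexion_deg: float = 16.71
    extension_deg: float = -16.24
    moment_nm: float = 10.0

    def __post_init__(self) -> None:
        if not self.flexion_deg > 0 > self.extension_deg:
            raise ValueError("need flexion target > 0 > extension target")
        if self.moment_nm <= 0:
            raise ValueError("moment must be positive")


@dataclass(frozen=True)
class CalibrationResult:
    calibrated_p1: float
    converged: bool
    threshold: float
    trace: pd.DataFrame  # columns: p1, flexion_deg, extension_deg,
    #          flexion_accuracy, extension_accuracy

    def trace_row(self, p1: float) -> pd.Series:
        t = self.trace
        return t.loc[np.isclose(t["p1"], p1)].iloc[0]


def accuracy(computed: float, target: float) -> float:
    """Percent accuracy of a computed value against a nonzero target.

    (1 - |computed - target| / |target|) * 100, clipped below at 0.  Equals
    100 iff computed == target and falls by one point per percent of
    relative error, regardless of direction.
    """
    if target == 0:
        raise ValueError("accuracy is undefined for a zero target")
    acc = (1.0 - abs(computed - target) / abs(target)) * 100.0
    return max(acc, 0.0)


def _evaluate_grid(
    evaluator: RoMEvaluator, targets: CalibrationTargets, grid: Sequence[float]
) -> pd.DataFrame:
    if len(grid) == 0:
        raise ValueError("calibration grid must be nonempty")
    p1s = sorted(float(p) for p in grid)
    rows = []
    for p1 in p1s:
        try:
            flex, ext = evaluator(p1)
        except DiscCalibError as err:
            raise type(err)(f"evaluator failed at P1={p1}: {err}") from err
        rows.append(
            {
                "p1": p1,
                "flexion_deg": flex,
                "extension_deg": ext,
                "flexion_accuracy": accuracy(flex, targets.flexion_deg),
                "extension_accuracy": accuracy(ext, targets.extension_deg),
            }
        )
    return pd.DataFrame(rows)


def calibrate_p1(
    evaluator: RoMEvaluator,
    targets: CalibrationTargets,
    grid: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD,
) -> CalibrationResult:
    """Sweep the P1 grid and pick the calibrated nucleus position.

    The grid is evaluated in increasing order (input order is irrelevant);
    the calibrated P1 is the smallest grid point whose flexion and extension
    accuracies both reach ``threshold``.  If no point qualifies the result
    carries ``converged=False`` and the P1 maximising min(flexion accuracy,
    extension accuracy).
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    trace = _evaluate_grid(evaluator, targets, grid)
    min_acc = trace[["flexion_accuracy", "extension_accuracy"]].min(axis=1)
    qualifying = trace.index[min_acc >= threshold]
    if len(qualifying) > 0:
        idx = qualifying[0]
        converged = True
    else:
        idx = int(min_acc.idxmax())
        converged = False
    return CalibrationResult(
        calibrated_p1=float(trace.loc[idx, "p1"]),
        converged=converged,
        threshold=float(threshold),
        trace=trace,
    )


def sweep_report(
    evaluator: RoMEvaluator, targets: CalibrationTargets, grid: Sequence[float]
) -> pd.DataFrame:
    """Long-format sweep table: one row per (direction, P1).

    Mirrors the published calibration table layout, with the target in
    degrees, the computed RoM, and its accuracy; CSV-serialisable.
    """
    trace = _evaluate_grid(evaluator, targets, grid)
    rows = []
    for direction, target, rom_col, acc_col in (
        ("flexion", targets.flexion_deg, "flexion_deg", "flexion_accuracy"),
        ("extension", targets.extension_deg, "extension_deg", "extension_accuracy"),
    ):
        for _, r in trace.iterrows():
            rows.append(
                {
                    "direction": direction,
                    "target_deg": target,
                    "p1": r["p1"],
                    "rom_deg": r[rom_col],
                    "accuracy_percent": r[acc_col],
                }
            )
    return pd.DataFrame(rows)


def default_grid(measured_p1: float, n_steps: int = 6, step: float = 0.10) -> list[float]:
    """The canonical sweep grid: start one step below the measured P1 and
    climb in +0.10 increments (the published sequence 1.12 ... 1.62 arises
    from a measured P1 of 1.22)."""
    start = round(measured_p1, 2) - step
    return [round(start + i * step, 10) for i in range(n_steps)]
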