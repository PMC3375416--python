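"""Predicted direction-discrimination thresholds from canal dynamics.

A stimulus is discriminable (75 % correct in the 2AFC task, by the model's
operational convention) once the peak firing-rate deviation it evokes
reaches the afferent noise level.  Because the canal model is linear, the
threshold in peak velocity follows without iteration: scale the stimulus so
its peak response equals the noise level, i.e.

    threshold = noise_level / peak_response(params, unit-peak profile)

The model is deterministic; the probabilistic 75 %-correct semantics live in
:mod:`canalthresh.psychophysics`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .canal_model import CanalParams, peak_response
from .profiles import MotionProfile, peak_acceleration_for

THRESHOLD_CSV_COLUMNS = (
    "condition",
    "shape",
    "frequency_hz",
    "threshold_deg_s",
    "sem_plus",
    "sem_minus",
    "source",
)


@dataclass(frozen=True)
class Condition:
    """One experimental condition: a profile shape at a stimulus period."""

    label: str
    shape: str
    period_s: float
    frequency_hz: Optional[float] = None  # nominal (printed) frequency

    def __post_init__(self) -> None:
        if not self.period_s > 0:
            raise ValueError("period_s must be positive")

    @property
    def frequency(self) -> float:
        """Nominal frequency if given, else 1/period."""
        return self.frequency_hz if self.frequency_hz is not None else 1.0 / self.period_s


class ThresholdDataset:
    """Per-condition thresholds (deg/s) with optional asymmetric SEMs.

    Thin wrapper around a DataFrame with columns ``condition, shape,
    frequency_hz, threshold_deg_s, sem_plus, sem_minus, source`` and one row
    per condition label.
    """

    def __init__(self, data: pd.DataFrame):
        missing = {"condition", "threshold_deg_s"} - set(data.columns)
        if missing:
            raise ValueError(f"threshold table missing columns {sorted(missing)}")
        if data["condition"].duplicated().any():
            raise ValueError("duplicate condition labels in threshold table")
        if not (data["threshold_deg_s"] > 0).all():
            raise ValueError("thresholds must be positive")
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def thresholds(self) -> np.ndarray:
        return self.data["threshold_deg_s"].to_numpy(dtype=float)

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "ThresholdDataset":
        return cls(pd.DataFrame(list(rows)))

    @classmethod
    def from_csv(cls, path) -> "ThresholdDataset":
        return cls(pd.read_csv(path, comment="#"))

    def to_csv(self, path, header_comment: Optional[str] = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.to_csv(fh, index=False)

    def conditions(self) -> list:
        """Reconstruct Condition objects (requires shape and a period source)."""
        out = []
        for _, row in self.data.iterrows():
            period = row["period_s"] if "period_s" in row and np.isfinite(row.get("period_s", np.nan)) else 1.0 / row["frequency_hz"]
            out.append(
                Condition(
                    label=str(row["condition"]),
                    shape=str(row["shape"]),
                    period_s=float(period),
                    frequency_hz=float(row["frequency_hz"]) if "frequency_hz" in row else None,
                )
            )
        return out


ProfileProvider = Callable[[Condition], MotionProfile]


def predict_threshold(params: CanalParams, profile: MotionProfile) -> float:
    """Predicted peak-velocity threshold (deg/s) for one stimulus profile.

    Exact by linearity: threshold = noise_level * v_peak / peak_response(profile).
    Invariant to the stimulus sign and to rescaling of the input profile.
    """
    v_peak = profile.peak_velocity
    if v_peak == 0.0:
        raise ValueError("all-zero profile has no threshold")
    return params.noise_level * v_peak / peak_response(params, profile)


def predict_dataset(
    params: CanalParams,
    conditions: Sequence[Condition],
    profile_provider: ProfileProvider,
) -> ThresholdDataset:
    """Predicted thresholds for every condition (source = 'predicted')."""
    rows = []
    for cond in conditions:
        profile = profile_provider(cond)
        if profile is None:
            raise ValueError(f"no profile resolvable for condition {cond.label!r}")
        rows.append(
            {
                "condition": cond.label,
                "shape": cond.shape,
                "frequency_hz": cond.frequency,
                "period_s": cond.period_s,
                "threshold_deg_s": predict_threshold(params, profile),
                "sem_plus": np.nan,
                "sem_minus": np.nan,
                "source": "predicted",
            }
        )
    return ThresholdDataset(pd.DataFrame(rows, columns=list(THRESHOLD_CSV_COLUMNS) + ["period_s"]))


def threshold_in_acceleration(
    threshold_deg_s: float,
    shape: str,
    period_T: float,
    rise_fraction: float = 0.1,
) -> float:
    """Convert a peak-velocity threshold to the matching peak acceleration.

    For equal velocity thresholds and period, triangular profiles need the
    highest and trapezoidal the lowest peak acceleration (ratio 4 : pi : 2.5).
    """
    if threshold_deg_s == 0.0:
        return 0.0
    return peak_acceleration_for(shape, period_T, threshold_deg_s, rise_fraction)
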