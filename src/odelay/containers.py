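"""Data containers shared by the measurement, analysis and I/O layers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ODTrace", "FlowSample", "CompoundRecord"]


@dataclass
class ODTrace:
    """One optical-density time series with its condition metadata.

    ``times_min`` are minutes since inoculation (strictly increasing,
    1-min sampling by default); ``od`` are dimensionless OD readings.
    """

    sample_id: str
    times_min: np.ndarray
    od: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times_min.shape != self.od.shape:
            raise ValueError(
                f"times and od must have equal length, got "
                f"{len(self.times_min)} vs {len(self.od)}"
            )
        if len(self.times_min) and np.any(np.diff(self.times_min) <= 0):
            raise ValueError(f"times must be strictly increasing in {self.sample_id!r}")
        if np.any(self.od < 0):
            raise ValueError(f"negative OD value in {self.sample_id!r}")

    def __len__(self) -> int:
        return len(self.times_min)

    @property
    def t_hours(self) -> np.ndarray:
        return self.times_min / 60.0

    @property
    def dt_min(self) -> float:
        """Median sampling interval, minutes."""
        if len(self.times_min) < 2:
            return 1.0
        return float(np.median(np.diff(self.times_min)))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_id, "time_min": self.times_min, "od": self.od}
        )
        for key, val in self.metadata.items():
            df[key] = val
        return df

    def replace_od(self, od: np.ndarray) -> "ODTrace":
        return ODTrace(
            sample_id=self.sample_id,
            times_min=self.times_min.copy(),
            od=np.asarray(od, dtype=float),
            metadata=dict(self.metadata),
        )


@dataclass
class FlowSample:
    """Flow-cytometry event counts per gate at one time point.

    Gates are plain names such as ``green_live``/``green_dead`` (competition
    labels x viability) or ``dyed``/``undyed`` (vital staining).
    """

    sample_id: str
    t: float  # h
    counts: dict[str, int]

    def __post_init__(self) -> None:
        for gate, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for gate {gate!r} must be a non-negative integer")
        self.counts = {g: int(c) for g, c in self.counts.items()}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, gate: str) -> float:
        if self.total == 0:
            raise ValueError(f"sample {self.sample_id!r} has zero total events")
        return self.counts.get(gate, 0) / self.total


@dataclass(frozen=True)
class CompoundRecord:
    """One compound's medium memberships and candidate-criterion annotations.

    The three criterion flags record whether the compound *fails* the
    corresponding candidate requirement: a true candidate leaves the
    post-delay growth rate unchanged, has little effect in the presence of
    glucose, and causes a shorter delay in already-adapted cells.
    """

    compound: str
    in_mm: bool = False  # detected in fresh glucose-free minimal medium
    in_wt_cm: bool = False  # detected in wild-type conditioned medium
    in_fbp1_cm: bool = False  # detected in fbp1-deletion conditioned medium
    changes_postdelay_growth: bool | None = None
    affects_growth_with_glucose: bool | None = None
    delays_adapted_cells: bool | None = None
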