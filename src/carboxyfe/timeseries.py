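"""Culture time-series container shared by the simulator and the balance module."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns a culture table may carry.  ``time_h`` is mandatory; everything
#: else is optional (a glauconite run, for instance, has no acetate column).
KNOWN_COLUMNS = (
    "time_h",
    "cells_per_ml",
    "CO_mmol",
    "H2_mmol",
    "CO2_mmol",
    "lactate_mM",
    "acetate_mM",
    "Fe2_mM",
    "Eh_mV",
)


@dataclass
class CultureTimeseries:
    """A simulated or measured culture trajectory.

    Wraps a :class:`pandas.DataFrame` whose rows are sampling times and whose
    columns are the metabolite pools (mM or mmol per bottle), cell density and
    redox potential.  Time must be strictly increasing.
    """

    data: pd.DataFrame
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "time_h" not in self.data.columns:
            raise ValueError("time-series requires a 'time_h' column")
        t = np.asarray(self.data["time_h"], dtype=float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        unknown = set(self.data.columns) - set(KNOWN_COLUMNS)
        if unknown:
            raise ValueError(f"unknown columns: {sorted(unknown)}")

    @property
    def time(self) -> np.ndarray:
        return np.asarray(self.data["time_h"], dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def has(self, column: str) -> bool:
        return column in self.data.columns

    def column(self, name: str) -> np.ndarray:
        return np.asarray(self.data[name], dtype=float)

    def value_at(self, column: str, t: float) -> float:
        """Linearly interpolated value of *column* at time *t* (hours)."""
        return float(np.interp(t, self.time, self.column(column)))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "CultureTimeseries":
        df = pd.read_csv(path)
        df = df[[c for c in KNOWN_COLUMNS if c in df.columns]]
        return cls(df, label=label or str(path))
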