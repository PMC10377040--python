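"""Time-indexed solution container shared by both models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Trajectory"]


@dataclass(frozen=True)
class Trajectory:
    """Sampled ODE solution.

    ``states`` has one row per time point; ``labels`` names the columns
    (e.g. ``["x", "y", "z"]`` or ``["z", "x_1", ..., "y_9"]``).
    """

    times: np.ndarray
    states: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.states.shape != (len(self.times), len(self.labels)):
            raise ValueError(
                f"states shape {self.states.shape} inconsistent with "
                f"{len(self.times)} times x {len(self.labels)} labels"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states must be finite")

    def __getitem__(self, label: str) -> np.ndarray:
        try:
            j = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no component {label!r}; have {self.labels}") from None
        return self.states[:, j]

    def columns(self, prefix: str) -> np.ndarray:
        """All components whose label starts with ``prefix + '_'``, in
        label order (e.g. ``columns('y')`` -> the per-class antibody block)."""
        idx = [j for j, lab in enumerate(self.labels)
               if lab.startswith(prefix + "_")]
        if not idx:
            raise KeyError(f"no components with prefix {prefix!r}")
        return self.states[:, idx]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.labels))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        """Write time + components at full double precision."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, float_precision="round_trip")
        if df.columns[0] != "time":
            raise ValueError("trajectory CSV must start with a 'time' column")
        return cls(
            times=df["time"].to_numpy(),
            states=df.iloc[:, 1:].to_numpy(),
            labels=tuple(df.columns[1:]),
        )
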