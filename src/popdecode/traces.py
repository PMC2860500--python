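"""Tabular result containers shared by the decoding and information analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CorrelationTrace", "InfoTrace"]


@dataclass
class CorrelationTrace:
    """Per-time-bin mean +/- SEM correlation of the decoded pattern with the
    previous pattern, the current pattern, and the difference pattern.

    ``time_ms`` are bin centers relative to the transition; ``n`` is the
    number of transitions averaged; SEM = sd / sqrt(n).
    """

    time_ms: np.ndarray
    mean_previous: np.ndarray
    mean_current: np.ndarray
    mean_difference: np.ndarray
    sem_previous: np.ndarray
    sem_current: np.ndarray
    sem_difference: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "corr_previous": self.mean_previous,
                "corr_current": self.mean_current,
                "corr_difference": self.mean_difference,
                "sem_previous": self.sem_previous,
                "sem_current": self.sem_current,
                "sem_difference": self.sem_difference,
                "n": self.n,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CorrelationTrace":
        return cls(
            time_ms=frame["time_ms"].to_numpy(float),
            mean_previous=frame["corr_previous"].to_numpy(float),
            mean_current=frame["corr_current"].to_numpy(float),
            mean_difference=frame["corr_difference"].to_numpy(float),
            sem_previous=frame["sem_previous"].to_numpy(float),
            sem_current=frame["sem_current"].to_numpy(float),
            sem_difference=frame["sem_difference"].to_numpy(float),
            n=int(frame["n"].iloc[0]),
        )

    @classmethod
    def from_csv(cls, path) -> "CorrelationTrace":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class InfoTrace:
    """Mean bias-corrected mutual information (bits) across included sites,
    per time bin, about the current and the previous stimulus."""

    time_ms: np.ndarray
    info_current_bits: np.ndarray
    info_previous_bits: np.ndarray
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "info_current_bits": self.info_current_bits,
                "info_previous_bits": self.info_previous_bits,
                "n_sites": self.n_sites,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
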