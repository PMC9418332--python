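"""Categorical per-sector states shared by the renderer and the analyzers."""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd


class CellState(enum.IntEnum):
    """State of one ring sector in one frame.

    OPEN marks a transient inter-subunit breakage (sector at membrane
    level); the conformational states order PRE_I < PRE_II < PORE and are
    irreversible once a transition has begun.
    """

    OPEN = -1
    PRE_I = 0
    PRE_II = 1
    PORE = 2


@dataclass
class StateMatrix:
    """frames x 16 categorical state labels for one ring."""

    states: np.ndarray
    frame_interval: float
    ring_id: int = 0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[1] != 16:
            raise ValueError("states must be a frames x 16 matrix")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    def monotone_violations(self) -> np.ndarray:
        """Per-column count of decreases of the conformational state index
        (OPEN frames ignored).  Violations are flagged, never silently fixed."""
        s = self.states.astype(float)
        s[s == CellState.OPEN] = np.nan
        out = np.zeros(16, dtype=int)
        for j in range(16):
            col = s[:, j]
            col = col[~np.isnan(col)]
            out[j] = int(np.sum(np.diff(col) < 0))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        frames, sectors = np.meshgrid(
            np.arange(self.n_frames), np.arange(16), indexing="ij"
        )
        return pd.DataFrame(
            {
                "ring_id": self.ring_id,
                "frame": frames.ravel(),
                "sector": sectors.ravel(),
                "state": self.states.ravel(),
            }
        )
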