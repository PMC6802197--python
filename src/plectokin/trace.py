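"""Core in-memory containers for magnetic-tweezers recordings.

A :class:`Trace` is a uniformly sampled extension time series with the
commanded magnet state; an :class:`EventLog` holds the ground-truth events of
a simulated trace (used to benchmark recovery by the analysis chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace", "EventLog"]


@dataclass
class Trace:
    """Uniformly sampled magnetic-tweezers extension trace.

    All arrays have equal length; ``time_s`` increases strictly at
    1/sampling_rate spacing.
    """

    time_s: np.ndarray
    extension_nm: np.ndarray
    magnet_turns: np.ndarray
    force_pN: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.extension_nm = np.asarray(self.extension_nm, dtype=float)
        self.magnet_turns = np.asarray(self.magnet_turns, dtype=float)
        self.force_pN = np.asarray(self.force_pN, dtype=float)
        n = self.time_s.size
        if not (
            self.extension_nm.size == n
            and self.magnet_turns.size == n
            and self.force_pN.size == n
        ):
            raise ValueError("trace channels must have equal length")
        if n >= 2:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                raise ValueError(f"time not strictly increasing at sample {bad}")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("trace is not uniformly sampled")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def sampling_rate_hz(self) -> float:
        if len(self) < 2:
            raise ValueError("sampling rate undefined for traces shorter than 2")
        return 1.0 / (self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "extension_nm": self.extension_nm,
                "magnet_turns": self.magnet_turns,
                "force_pN": self.force_pN,
            }
        )


@dataclass
class EventLog:
    """Ground truth of a simulated trace: what happened, when, how big.

    ``kinds`` label the events (bind, unbind, step, strand-transfer,
    loop-release, rupture); ``values`` carry the signed step size in nm (or
    turns for supercoil release, recorded in ``metadata['value_unit']``);
    ``dwells_s`` is the time since the previous event (NaN for the first).
    """

    times_s: np.ndarray
    kinds: np.ndarray
    values: np.ndarray
    dwells_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        self.dwells_s = np.asarray(self.dwells_s, dtype=float)
        n = self.times_s.size
        if not (self.kinds.size == n and self.values.size == n and self.dwells_s.size == n):
            raise ValueError("event log columns must have equal length")
        if n >= 2 and np.any(np.diff(self.times_s) < 0):
            raise ValueError("event log must be chronologically sorted")

    def __len__(self) -> int:
        return self.times_s.size

    def of_kind(self, kind: str) -> "EventLog":
        m = self.kinds == kind
        return EventLog(
            self.times_s[m], self.kinds[m], self.values[m], self.dwells_s[m],
            dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "kind": self.kinds,
                "value": self.values,
                "dwell_s": self.dwells_s,
            }
        )
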