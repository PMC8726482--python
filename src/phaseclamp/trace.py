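"""Uniformly sampled signal container shared by every analysis stage.

All recordings handled by this package — voltage-clamp currents, current-clamp
membrane potentials, and MEA field potentials — are represented as a
:class:`SampledTrace`: a uniformly sampled array with an explicit start time,
sampling interval, and signal kind. Units follow the conventions of the
recording modality: membrane potential in mV, membrane current in pA, field
potential in µV. Time is always seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SIGNAL_KINDS = ("membrane_potential", "membrane_current", "field_potential")

#: display unit per signal kind
SIGNAL_UNITS = {
    "membrane_potential": "mV",
    "membrane_current": "pA",
    "field_potential": "uV",
}


@dataclass
class SampledTrace:
    """A uniformly sampled signal.

    Parameters
    ----------
    t0 : float
        Time of the first sample, seconds.
    dt : float
        Sampling interval, seconds (strictly positive).
    values : numpy.ndarray
        Sample values; at least two finite samples.
    signal_kind : str
        One of ``membrane_potential`` (mV), ``membrane_current`` (pA),
        ``field_potential`` (µV).
    """

    t0: float
    dt: float
    values: np.ndarray
    signal_kind: str = "membrane_current"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(
                f"unknown signal_kind {self.signal_kind!r}; expected one of {SIGNAL_KINDS}"
            )

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Time spanned from first to last sample, seconds."""
        return self.dt * (self.values.size - 1)

    @property
    def rate_hz(self) -> float:
        return 1.0 / self.dt

    def index_at(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.values.size - 1)

    def window(self, t_start: float, t_stop: float) -> np.ndarray:
        """Samples with ``t_start <= t < t_stop`` (view, may be empty)."""
        i0 = max(int(np.ceil((t_start - self.t0) / self.dt - 1e-9)), 0)
        i1 = min(int(np.ceil((t_stop - self.t0) / self.dt - 1e-9)), self.values.size)
        return self.values[i0:i1]

    def same_timebase(self, other: "SampledTrace", rtol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and abs(self.dt - other.dt) <= rtol * self.dt
            and abs(self.t0 - other.t0) <= rtol * max(1.0, abs(self.t0))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "value": self.values})

    def to_csv(self, path) -> None:
        """Write as a two-column CSV (time_s, value)."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, signal_kind: str = "membrane_current") -> "SampledTrace":
        """Read a delimited time-series file (columns: time in s, signal).

        The first column is taken as time, the second as the signal; sampling
        must be uniform to within 1 ppm of the median interval.
        """
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected at least two columns (time, value)")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        dts = np.diff(t)
        dt = float(np.median(dts))
        if dt <= 0 or np.max(np.abs(dts - dt)) > 1e-6 * dt * max(1.0, len(t)):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        return cls(t0=float(t[0]), dt=dt, values=v, signal_kind=signal_kind)
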