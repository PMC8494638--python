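"""Current-clamp sweep container and HDF5 I/O.

A :class:`Sweep` holds one current-clamp epoch: a voltage trace (mV), the
commanded current trace (pA), the stimulus window, and amplifier metadata.
Sweep sets are stored in an HDF5 container with one group per sweep
(``sweep_000``, ``sweep_001``, ...) holding ``voltage`` and ``current``
datasets and scalar attributes ``sampling_rate_hz``, ``stim_start_s``,
``stim_end_s``, ``stim_amplitude_pa``, ``bridge_mohm`` and ``bias_pa``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["Sweep", "write_sweep_set", "read_sweep_set"]


@dataclass
class Sweep:
    sampling_rate: float  # Hz
    voltage: np.ndarray  # mV
    current: np.ndarray  # pA
    stim_start: float  # s
    stim_end: float  # s
    stim_amplitude: float  # pA
    bridge_balance: float | None = None  # MOhm
    bias_current: float | None = None  # pA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.voltage.shape != self.current.shape:
            raise ValueError("voltage and current must have equal length")
        dur = self.duration
        if not (0 <= self.stim_start < self.stim_end <= dur + 1e-9):
            raise ValueError(
                f"invalid stimulus window [{self.stim_start}, {self.stim_end}] "
                f"for sweep of duration {dur}"
            )

    @property
    def n_samples(self) -> int:
        return self.voltage.size

    @property
    def duration(self) -> float:
        return self.voltage.size / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def index_of(self, time_s: float) -> int:
        """Sample index of a time point (floor, clipped into range)."""
        i = int(math.floor(time_s * self.sampling_rate))
        return min(max(i, 0), self.n_samples - 1)

    @property
    def stim_slice(self) -> slice:
        i0 = int(round(self.stim_start * self.sampling_rate))
        i1 = int(round(self.stim_end * self.sampling_rate))
        return slice(i0, i1)


def write_sweep_set(path, sweeps: list[Sweep]) -> None:
    with h5py.File(path, "w") as f:
        for i, sw in enumerate(sweeps):
            g = f.create_group(f"sweep_{i:03d}")
            g.create_dataset("voltage", data=sw.voltage)
            g.create_dataset("current", data=sw.current)
            g.attrs["sampling_rate_hz"] = sw.sampling_rate
            g.attrs["stim_start_s"] = sw.stim_start
            g.attrs["stim_end_s"] = sw.stim_end
            g.attrs["stim_amplitude_pa"] = sw.stim_amplitude
            if sw.bridge_balance is not None:
                g.attrs["bridge_mohm"] = sw.bridge_balance
            if sw.bias_current is not None:
                g.attrs["bias_pa"] = sw.bias_current
            for k, v in sw.meta.items():
                g.attrs[k] = v


def read_sweep_set(path) -> list[Sweep]:
    sweeps = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            attrs = dict(g.attrs)
            known = {
                "sampling_rate_hz",
                "stim_start_s",
                "stim_end_s",
                "stim_amplitude_pa",
                "bridge_mohm",
                "bias_pa",
            }
            sweeps.append(
                Sweep(
                    sampling_rate=float(attrs["sampling_rate_hz"]),
                    voltage=g["voltage"][...],
                    current=g["current"][...],
                    stim_start=float(attrs["stim_start_s"]),
                    stim_end=float(attrs["stim_end_s"]),
                    stim_amplitude=float(attrs["stim_amplitude_pa"]),
                    bridge_balance=(
                        float(attrs["bridge_mohm"]) if "bridge_mohm" in attrs else None
                    ),
                    bias_current=(
                        float(attrs["bias_pa"]) if "bias_pa" in attrs else None
                    ),
                    meta={k: v for k, v in attrs.items() if k not in known},
                )
            )
    return sweeps
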