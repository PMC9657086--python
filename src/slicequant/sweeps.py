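"""Containers and I/O for extracellular field-potential sweep series.

A recording session is an ordered list of :class:`Sweep` objects (one pair of
stimuli per sweep, delivered every ~20 s) plus the time of the high-frequency
stimulation (HFS) used to induce LTP.  Sessions round-trip through HDF5 and,
for small recordings, wide delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = ["Sweep", "SweepSeries", "ProtocolSpec", "read_sweeps_hdf5", "write_sweeps_hdf5"]


@dataclass
class ProtocolSpec:
    """HFS induction protocol: trains of pulses at a fixed within-train rate."""

    n_trains: int = 3
    train_interval: float = 20.0  # s between train onsets
    pulses_per_train: int = 100
    train_rate: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if min(self.n_trains, self.pulses_per_train) < 1 or min(self.train_interval, self.train_rate) <= 0:
            raise ValueError("all protocol fields must be positive")

    @property
    def train_duration(self) -> float:
        return self.pulses_per_train / self.train_rate

    @property
    def total_duration(self) -> float:
        """Time from first pulse of first train to last pulse of last train (s)."""
        return (self.n_trains - 1) * self.train_interval + self.train_duration


@dataclass
class Sweep:
    """One stimulus-response sweep.

    ``samples`` are voltages in mV at ``sampling_rate`` Hz; ``t0`` is the sweep
    start in experiment time (s); ``stim_times`` are stimulus onsets in seconds
    from sweep start.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float
    stim_times: tuple[float, ...]
    isi: float = 50.0  # ms
    pulse_width: float = 0.1  # ms

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("sweep samples must be 1D")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        st = tuple(float(t) for t in self.stim_times)
        if list(st) != sorted(st):
            raise ValueError("stim_times must be sorted")
        if len(st) >= 2:
            gap_ms = (st[1] - st[0]) * 1e3
            if abs(gap_ms - self.isi) > 1e3 / self.sampling_rate:
                raise ValueError(
                    f"paired stimuli are {gap_ms:.3f} ms apart but isi={self.isi} ms"
                )
        self.stim_times = st

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in s from sweep start."""
        return np.arange(self.samples.size) * self.dt


@dataclass
class SweepSeries:
    """Time-ordered sweeps around one LTP induction."""

    sweeps: list[Sweep]
    hfs_time: float  # s, onset of the first HFS train in experiment time
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)

    def __post_init__(self) -> None:
        t0s = [s.t0 for s in self.sweeps]
        if any(b <= a for a, b in zip(t0s, t0s[1:])):
            raise ValueError("sweeps must be strictly time-ordered")
        if self.sweeps and not (t0s[0] <= self.hfs_time <= t0s[-1]):
            raise ValueError(
                f"hfs_time={self.hfs_time} s outside the recorded span [{t0s[0]}, {t0s[-1]}] s"
            )

    @property
    def hfs_end(self) -> float:
        """End of the last HFS train (s); the reference t = 0 for LTP timecourses."""
        return self.hfs_time + self.protocol.total_duration


def write_sweeps_hdf5(series: SweepSeries, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["hfs_time"] = series.hfs_time
        p = series.protocol
        f.attrs["protocol"] = [p.n_trains, p.train_interval, p.pulses_per_train, p.train_rate]
        for i, sw in enumerate(series.sweeps):
            g = f.create_group(f"sweep{i:05d}")
            g.create_dataset("samples", data=sw.samples, compression=None)
            g.attrs["sampling_rate"] = sw.sampling_rate
            g.attrs["t0"] = sw.t0
            g.attrs["stim_times"] = list(sw.stim_times)
            g.attrs["isi"] = sw.isi
            g.attrs["pulse_width"] = sw.pulse_width
    return path


def read_sweeps_hdf5(path: str | Path) -> SweepSeries:
    with h5py.File(path, "r") as f:
        nt, ti, ppt, tr = f.attrs["protocol"]
        proto = ProtocolSpec(int(nt), float(ti), int(ppt), float(tr))
        sweeps = []
        for name in sorted(k for k in f.keys() if k.startswith("sweep")):
            g = f[name]
            sweeps.append(
                Sweep(
                    samples=g["samples"][:],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    t0=float(g.attrs["t0"]),
                    stim_times=tuple(g.attrs["stim_times"]),
                    isi=float(g.attrs["isi"]),
                    pulse_width=float(g.attrs["pulse_width"]),
                )
            )
        return SweepSeries(sweeps, float(f.attrs["hfs_time"]), proto)
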