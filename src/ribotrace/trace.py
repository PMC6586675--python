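"""Force-trace container and plain-text / HDF5 serialization.

A trace is a uniformly sampled force time series in piconewtons.  On disk
the canonical format is a two-column TSV (``time_s``, ``force_pN``) with
``#key=value`` metadata header lines; an HDF5 container with identical
content is supported for large cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ForceTrace", "read_trace_tsv", "write_trace_tsv",
           "read_trace_hdf5", "write_trace_hdf5"]


@dataclass
class ForceTrace:
    """Uniformly sampled force-vs-time record from a passive-mode experiment.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, uniformly spaced at ``1/fs``.
    force : array of float
        Measured force in pN at each sample.
    fs : float
        Sampling rate in Hz.
    metadata : dict
        Free-form experiment metadata (construct, seed, scheme, ...).
    """

    time: np.ndarray
    force: np.ndarray
    fs: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have the same shape")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def slice_time(self, t_start: float, t_stop: float | None = None) -> "ForceTrace":
        """Return the sub-trace with ``t_start <= t < t_stop``."""
        mask = self.time >= t_start
        if t_stop is not None:
            mask &= self.time < t_stop
        return ForceTrace(self.time[mask], self.force[mask], self.fs,
                          dict(self.metadata))


def write_trace_tsv(trace: ForceTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#fs={trace.fs!r}\n")
        for key, val in sorted(trace.metadata.items()):
            fh.write(f"#{key}={val}\n")
        fh.write("time_s\tforce_pN\n")
        for t, f in zip(trace.time, trace.force):
            fh.write(f"{t:.9g}\t{f:.9g}\n")


def read_trace_tsv(path) -> ForceTrace:
    meta: dict = {}
    times: list[float] = []
    forces: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            elif line[0].isdigit() or line[0] in "-+.":
                t, f = line.split("\t")
                times.append(float(t))
                forces.append(float(f))
    fs = float(meta.pop("fs"))
    return ForceTrace(np.array(times), np.array(forces), fs, meta)


def write_trace_hdf5(trace: ForceTrace, path, group: str = "trace") -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        grp = fh.create_group(group)
        grp.create_dataset("time_s", data=trace.time)
        grp.create_dataset("force_pN", data=trace.force)
        grp.attrs["fs"] = trace.fs
        for key, val in trace.metadata.items():
            grp.attrs[key] = str(val)


def read_trace_hdf5(path, group: str = "trace") -> ForceTrace:
    import h5py

    with h5py.File(path, "r") as fh:
        grp = fh[group]
        attrs = dict(grp.attrs)
        fs = float(attrs.pop("fs"))
        return ForceTrace(np.asarray(grp["time_s"]), np.asarray(grp["force_pN"]),
                          fs, {k: str(v) for k, v in attrs.items()})
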