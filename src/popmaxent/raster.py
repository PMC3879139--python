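"""Spike raster container and data plumbing.

A :class:`SpikeRaster` is a binary (neurons x time-bins) matrix with repeat
structure: the recording consists of ``n_repeats`` presentations of the same
stimulus, each spanning ``bins_per_repeat`` time bins of width ``dt`` seconds.
Columns are ordered repeat-major: bin ``t`` of repeat ``r`` lives at column
``r * bins_per_repeat + t``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SpikeRaster",
    "bin_spike_times",
    "sample_subgroups",
    "split_repeats",
    "shuffle_raster",
    "read_raster",
    "write_raster",
    "read_event_list",
]


@dataclasses.dataclass(frozen=True)
class SpikeRaster:
    """Binary population activity with repeat structure.

    Parameters
    ----------
    values
        ``(n_neurons, n_repeats * bins_per_repeat)`` array with entries in
        {0, 1}.
    n_repeats, bins_per_repeat
        Repeat structure; their product must equal ``values.shape[1]``.
    dt
        Bin width in seconds (must be positive).
    neuron_ids
        Unique opaque labels, one per row; defaults to ``0..n-1`` as strings.
    """

    values: np.ndarray
    n_repeats: int
    bins_per_repeat: int
    dt: float
    neuron_ids: tuple = None  # type: ignore[assignment]

    def __post_init__(self):
        values = np.ascontiguousarray(np.asarray(self.values, dtype=np.uint8))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D (neurons x bins) array")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        if self.dt <= 0:
            raise ValueError("bin width dt must be positive")
        if self.n_repeats * self.bins_per_repeat != values.shape[1]:
            raise ValueError(
                f"n_repeats * bins_per_repeat = {self.n_repeats * self.bins_per_repeat}"
                f" does not match {values.shape[1]} columns"
            )
        ids = self.neuron_ids
        if ids is None:
            ids = tuple(str(i) for i in range(values.shape[0]))
        else:
            ids = tuple(str(i) for i in ids)
        if len(ids) != values.shape[0]:
            raise ValueError("one neuron id per row required")
        if len(set(ids)) != len(ids):
            raise ValueError("neuron ids must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def by_repeat(self) -> np.ndarray:
        """View as ``(n_neurons, n_repeats, bins_per_repeat)``."""
        return self.values.reshape(self.n_neurons, self.n_repeats, self.bins_per_repeat)

    def subset(self, rows: Sequence[int]) -> "SpikeRaster":
        rows = np.asarray(rows, dtype=int)
        return SpikeRaster(
            self.values[rows], self.n_repeats, self.bins_per_repeat, self.dt,
            tuple(self.neuron_ids[i] for i in rows),
        )

    def words(self) -> np.ndarray:
        """Time-major ``(n_bins, n_neurons)`` view of the population words."""
        return self.values.T


def bin_spike_times(
    events: Iterable[tuple],
    dt: float,
    n_repeats: int,
    repeat_duration: float,
    neuron_ids: Sequence = None,
) -> tuple:
    """Bin (neuron_id, spike_time_s) events into a binary raster.

    Bins are half-open ``[t*dt, (t+1)*dt)``, 0-based; a bin holding more than
    one spike is recorded as 1.  Spike times must satisfy
    ``0 <= t < n_repeats * repeat_duration``; offending events are dropped and
    counted.

    Returns
    -------
    (SpikeRaster, n_rejected)
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    events = list(events)
    if neuron_ids is None:
        neuron_ids = sorted({str(e[0]) for e in events})
    neuron_ids = [str(i) for i in neuron_ids]
    index = {nid: i for i, nid in enumerate(neuron_ids)}

    bins_per_repeat = int(np.floor(repeat_duration / dt + 1e-12))
    total_bins = n_repeats * bins_per_repeat
    values = np.zeros((len(neuron_ids), total_bins), dtype=np.uint8)
    n_rejected = 0
    t_max = n_repeats * repeat_duration
    for nid, t in events:
        nid = str(nid)
        if nid not in index:
            raise KeyError(f"unknown neuron id {nid!r}")
        if not (0.0 <= t < t_max):
            n_rejected += 1
            continue
        r = int(t // repeat_duration)
        within = t - r * repeat_duration
        b = int(within // dt)
        if b >= bins_per_repeat:  # spike in the truncated tail of a repeat
            n_rejected += 1
            continue
        values[index[nid], r * bins_per_repeat + b] = 1
    raster = SpikeRaster(values, n_repeats, bins_per_repeat, dt, tuple(neuron_ids))
    return raster, n_rejected


def sample_subgroups(raster: SpikeRaster, sizes: Sequence[int], n_groups: int, seed: int):
    """Random neuron subgroups: ``n_groups`` per size, rows drawn without
    replacement within a group (groups may overlap across draws)."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    for size in sizes:
        if size > raster.n_neurons:
            raise ValueError(f"subgroup size {size} exceeds {raster.n_neurons} neurons")
        groups = []
        for _ in range(n_groups):
            rows = np.sort(rng.choice(raster.n_neurons, size=size, replace=False))
            groups.append(raster.subset(rows))
        out[int(size)] = groups
    return out


def split_repeats(raster: SpikeRaster, n_test: int, seed: int):
    """Withhold ``n_test`` random repeats as a test set; the rest train."""
    R = raster.n_repeats
    if not 0 < n_test < R:
        raise ValueError(f"need 0 < n_test < {R}, got {n_test}")
    rng = np.random.default_rng(seed)
    test_r = np.sort(rng.choice(R, size=n_test, replace=False))
    train_r = np.setdiff1d(np.arange(R), test_r)
    cube = raster.by_repeat()
    B = raster.bins_per_repeat

    def _make(reps):
        vals = cube[:, reps, :].reshape(raster.n_neurons, len(reps) * B)
        return SpikeRaster(vals, len(reps), B, raster.dt, raster.neuron_ids)

    return _make(train_r), _make(test_r)


def shuffle_raster(raster: SpikeRaster, seed: int) -> SpikeRaster:
    """Permute each neuron's time series independently over all (repeat, bin)
    slots, preserving per-neuron spike counts and destroying cross-neuron
    alignment."""
    rng = np.random.default_rng(seed)
    values = raster.values.copy()
    for i in range(raster.n_neurons):
        values[i] = values[i, rng.permutation(raster.n_bins)]
    return SpikeRaster(values, raster.n_repeats, raster.bins_per_repeat,
                       raster.dt, raster.neuron_ids)


# ---------------------------------------------------------------------------
# on-disk formats


def write_raster(raster: SpikeRaster, path) -> None:
    """Dense text raster (one row per neuron, 0/1) plus a ``.meta`` sidecar."""
    path = Path(path)
    np.savetxt(path, raster.values, fmt="%d")
    meta = path.with_suffix(path.suffix + ".meta")
    with open(meta, "w") as fh:
        fh.write(f"dt\t{float(raster.dt)!r}\n")
        fh.write(f"n_repeats\t{raster.n_repeats}\n")
        fh.write(f"bins_per_repeat\t{raster.bins_per_repeat}\n")
        fh.write("neuron_ids\t" + ",".join(raster.neuron_ids) + "\n")


def read_raster(path) -> SpikeRaster:
    path = Path(path)
    values = np.loadtxt(path, dtype=np.uint8, ndmin=2)
    meta = path.with_suffix(path.suffix + ".meta")
    kv = {}
    with open(meta) as fh:
        for line in fh:
            if line.strip():
                key, _, val = line.rstrip("\n").partition("\t")
                kv[key] = val
    return SpikeRaster(
        values,
        int(kv["n_repeats"]),
        int(kv["bins_per_repeat"]),
        float(kv["dt"]),
        tuple(kv["neuron_ids"].split(",")),
    )


def read_event_list(path):
    """Read a tab-separated event list: ``neuron_id  time_s  repeat_index``
    with a header line.  ``time_s`` is the time within its repeat; the global
    time is reconstructed when binning.

    Returns a list of (neuron_id, time_within_repeat, repeat_index).
    """
    out = []
    with open(path) as fh:
        header = fh.readline()
        if "neuron_id" not in header:
            raise ValueError("event list must start with a header line")
        for line in fh:
            if not line.strip():
                continue
            nid, t, r = line.split("\t")
            out.append((nid, float(t), int(r)))
    return out
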