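"""Data model and I/O for MEG epochs and trial-averaged evoked responses.

Conventions
-----------
* An evoked (or epoch) matrix has one row per channel and one column per
  time sample; sample ``k`` sits at ``tmin + k / sfreq`` seconds relative to
  stimulus onset (closed start, implied end).  A window declared as
  [-0.2, 1.2) s at 200 Hz therefore holds 280 samples covering
  [-0.2, 1.195] s.
* Gradiometer amplitudes are in T/m unless another unit tag is supplied.
* All recordings entering the comICA pipeline must share the same channels
  in the same order; :func:`align_channels` reorders by channel name instead
  of trusting file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SensorArray",
    "EvokedRecording",
    "EpochSet",
    "EmptyEpochSetError",
    "reject_epochs_ptp",
    "equalize_epoch_counts",
    "average_epochs",
    "baseline_correct",
    "align_channels",
    "save_evoked",
    "load_evoked",
    "export_evoked_csv",
    "read_fif_evoked",
]


class EmptyEpochSetError(ValueError):
    """Raised when an operation would leave an epoch set with no epochs."""


@dataclass(frozen=True)
class SensorArray:
    """A labelled set of sensors.

    Parameters
    ----------
    channel_ids : tuple of str
        Unique channel labels, in data-row order.
    channel_unit : str
        Physical unit tag of the signal (planar gradiometers record T/m).
    """

    channel_ids: tuple
    channel_unit: str = "T/m"

    def __post_init__(self):
        ids = tuple(str(c) for c in self.channel_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("channel_ids must be unique")
        if len(ids) == 0:
            raise ValueError("need at least one channel")
        object.__setattr__(self, "channel_ids", ids)

    @property
    def n_sens(self) -> int:
        return len(self.channel_ids)

    @classmethod
    def generic(cls, n_sens: int, unit: str = "T/m") -> "SensorArray":
        """A default array with labels ``CH000, CH001, ...``."""
        return cls(tuple(f"CH{i:03d}" for i in range(n_sens)), unit)


@dataclass
class EvokedRecording:
    """One recording's trial-averaged sensor data.

    ``data`` has shape ``(n_sens, n_times)``; ``sfreq`` is the sampling
    frequency in Hz and ``tmin`` the time of the first sample in seconds
    relative to stimulus onset.
    """

    data: np.ndarray
    sfreq: float
    tmin: float
    sensors: SensorArray
    n_trials_averaged: int = 0
    comment: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("evoked data must be 2-D (channels x time)")
        if self.data.shape[0] != self.sensors.n_sens:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but sensor array has "
                f"{self.sensors.n_sens} channels"
            )
        if self.data.shape[1] < 1:
            raise ValueError("need at least one time sample")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.n_trials_averaged < 0:
            raise ValueError("n_trials_averaged must be nonnegative")

    @property
    def n_sens(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``tmin + k / sfreq``."""
        return self.tmin + np.arange(self.n_times) / self.sfreq

    def copy(self, **changes) -> "EvokedRecording":
        out = replace(self, **changes)
        out.data = out.data.copy()
        return out


@dataclass
class EpochSet:
    """Single-trial segments, shape ``(n_epochs, n_sens, n_times)``."""

    data: np.ndarray
    sfreq: float
    tmin: float
    sensors: SensorArray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x time)")
        if self.data.shape[0] < 1:
            raise EmptyEpochSetError("epoch set contains no epochs")
        if self.data.shape[1] != self.sensors.n_sens:
            raise ValueError("epoch channel count does not match sensor array")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq


def reject_epochs_ptp(epochs: EpochSet, threshold: float):
    """Drop epochs whose peak-to-peak amplitude exceeds ``threshold``.

    An epoch is rejected when *any* channel's max-minus-min over time exceeds
    the threshold (per-channel criterion, the common artifact-rejection
    practice; a typical gradiometer threshold is ``3e-16`` T/m).  Order of the
    surviving epochs is preserved.

    Returns
    -------
    kept : EpochSet
    n_rejected : int

    Raises
    ------
    EmptyEpochSetError
        If every epoch exceeds the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # (n_epochs, n_sens)
    keep = ~(ptp > threshold).any(axis=1)
    n_rejected = int((~keep).sum())
    if not keep.any():
        raise EmptyEpochSetError(
            f"all {epochs.n_epochs} epochs exceed the peak-to-peak threshold "
            f"{threshold!r}"
        )
    kept = EpochSet(epochs.data[keep], epochs.sfreq, epochs.tmin, epochs.sensors)
    return kept, n_rejected


def equalize_epoch_counts(sets):
    """Trim every epoch set to the smallest count among them.

    Comparable recordings should average the same number of trials, so the
    per-condition epoch counts are equalized across recordings before
    averaging.  Which epochs are dropped is a free choice; here the
    *first* ``min(counts)`` epochs of each set are kept (drop-from-end),
    which is deterministic and order-preserving.
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("need at least two epoch sets to equalize")
    n_min = min(s.n_epochs for s in sets)
    return [
        EpochSet(s.data[:n_min], s.sfreq, s.tmin, s.sensors) for s in sets
    ]


def average_epochs(epochs: EpochSet) -> EvokedRecording:
    """Arithmetic mean over the epoch axis -> evoked response."""
    return EvokedRecording(
        data=epochs.data.mean(axis=0),
        sfreq=epochs.sfreq,
        tmin=epochs.tmin,
        sensors=epochs.sensors,
        n_trials_averaged=epochs.n_epochs,
    )


def baseline_correct(evoked: EvokedRecording, baseline_window) -> EvokedRecording:
    """Subtract each channel's mean over ``baseline_window`` from its trace.

    ``baseline_window`` is a ``(start, stop)`` interval in seconds; samples
    with ``start <= t <= stop`` are used.  The window must overlap the
    recording.
    """
    start, stop = baseline_window
    if stop < start:
        raise ValueError("baseline window start must not exceed stop")
    mask = (evoked.times >= start) & (evoked.times <= stop)
    if not mask.any():
        raise ValueError(
            f"baseline window [{start}, {stop}] s contains no samples of the "
            f"recording [{evoked.times[0]:.4f}, {evoked.times[-1]:.4f}] s"
        )
    base = evoked.data[:, mask].mean(axis=1, keepdims=True)
    return evoked.copy(data=evoked.data - base)


def align_channels(recordings):
    """Reorder every recording's rows to the first recording's channel names.

    Raises if any recording is missing a channel (or has extras), naming it.
    """
    recordings = list(recordings)
    if not recordings:
        return []
    ref = recordings[0].sensors.channel_ids
    out = []
    for idx, rec in enumerate(recordings):
        ids = rec.sensors.channel_ids
        if set(ids) != set(ref):
            raise ValueError(
                f"recording {idx} channel set differs from recording 0 "
                f"(missing: {sorted(set(ref) - set(ids))[:5]}, "
                f"extra: {sorted(set(ids) - set(ref))[:5]})"
            )
        order = [ids.index(c) for c in ref]
        out.append(
            rec.copy(
                data=rec.data[order],
                sensors=SensorArray(ref, rec.sensors.channel_unit),
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O: HDF5 container + delimited-text export, optional FIF adapter
# ---------------------------------------------------------------------------

def save_evoked(path, evoked: EvokedRecording) -> None:
    """Write an evoked recording to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=evoked.data)
        f.attrs["sfreq"] = float(evoked.sfreq)
        f.attrs["tmin"] = float(evoked.tmin)
        f.attrs["n_trials_averaged"] = int(evoked.n_trials_averaged)
        f.attrs["channel_unit"] = evoked.sensors.channel_unit
        f.attrs["comment"] = evoked.comment
        f.create_dataset(
            "channel_ids",
            data=np.array(evoked.sensors.channel_ids, dtype="S"),
        )


def load_evoked(path) -> EvokedRecording:
    """Read an evoked recording from an HDF5 container written by :func:`save_evoked`."""
    import h5py

    with h5py.File(path, "r") as f:
        ids = tuple(c.decode() for c in f["channel_ids"][()])
        return EvokedRecording(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            tmin=float(f.attrs["tmin"]),
            sensors=SensorArray(ids, str(f.attrs.get("channel_unit", "T/m"))),
            n_trials_averaged=int(f.attrs.get("n_trials_averaged", 0)),
            comment=str(f.attrs.get("comment", "")),
        )


def export_evoked_csv(path, evoked: EvokedRecording) -> None:
    """Delimited-text export (one row per channel, one column per sample)."""
    import pandas as pd

    df = pd.DataFrame(
        evoked.data,
        index=list(evoked.sensors.channel_ids),
        columns=[f"{t:.6f}" for t in evoked.times],
    )
    df.index.name = "channel"
    df.to_csv(path)


def read_fif_evoked(path, condition=0, gradiometers_only=True) -> EvokedRecording:
    """Adapter: read an averaged evoked from a FIF neuromagnetic file.

    Requires ``mne``; imported lazily so the core package never depends on it.
    """
    import mne

    ev = mne.read_evokeds(path, condition=condition, verbose="error")
    if gradiometers_only:
        ev = ev.copy().pick("grad")
    unit = "T/m" if gradiometers_only else "T"
    return EvokedRecording(
        data=ev.data,
        sfreq=float(ev.info["sfreq"]),
        tmin=float(ev.times[0]),
        sensors=SensorArray(tuple(ev.ch_names), unit),
        n_trials_averaged=int(getattr(ev, "nave", 0) or 0),
        comment=str(ev.comment or ""),
    )
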