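"""Recording container and minimal deterministic preprocessing.

The preprocessing chain mirrors a conventional resting-state EEG pipeline:
a zero-phase FIR high-pass to remove slow drifts, followed by re-referencing
to the common average.  Artifact handling (ICA, bad-channel interpolation,
manual segment marking) is assumed to have happened upstream; clean-segment
boundaries are carried on the :class:`Recording` and honoured by the
spectral estimators, which never place an analysis window across a boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class Recording:
    """Multichannel time series with montage and clean-segment metadata.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal in microvolts.
    sfreq : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names.
    coords : ndarray, shape (n_channels, 3)
        Montage positions (arbitrary but consistent units).
    segments : list of (int, int)
        Ordered half-open sample intervals ``[start, end)`` marking
        artifact-free data.  Defaults to the whole record.
    """

    data: np.ndarray
    sfreq: float
    labels: list[str]
    coords: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_samples, n_channels)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.data.shape[1], 3):
            raise ValueError("coords must be (n_channels, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if not self.segments:
            self.segments = [(0, self.data.shape[0])]
        self._check_segments()

    def _check_segments(self) -> None:
        n = self.data.shape[0]
        prev_end = 0
        for start, end in self.segments:
            if not (0 <= start < end <= n):
                raise ValueError(f"segment [{start}, {end}) outside record of {n} samples")
            if start < prev_end:
                raise ValueError("segments must be ordered and non-overlapping")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


def highpass_fir(rec: Recording, cutoff: float = 1.0, order: int = 1536) -> Recording:
    """Zero-phase (forward-backward) Hamming-window FIR high-pass.

    The filter is a linear-phase windowed-sinc design of the stated order
    (``order + 1`` taps), applied in both directions so that the effective
    response is the squared magnitude with no phase distortion.  DC is
    removed exactly; passband amplitudes are preserved.
    """
    if cutoff <= 0 or cutoff >= rec.sfreq / 2:
        raise ValueError("cutoff must lie in (0, sfreq/2)")
    required = 3 * order + 1
    if rec.n_samples <= required:
        raise ValueError(
            f"record too short for order-{order} forward-backward filtering: "
            f"need more than {required} samples, got {rec.n_samples}"
        )
    # spectral inversion of a unity-DC-gain lowpass: DC is nulled exactly
    lowpass = signal.firwin(order + 1, cutoff, window="hamming", fs=rec.sfreq)
    taps = -lowpass
    taps[order // 2] += 1.0
    filtered = signal.filtfilt(taps, [1.0], rec.data, axis=0)
    return replace(rec, data=filtered)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel.

    After referencing, the channel mean is zero at every sample (to machine
    precision); the operation is idempotent.
    """
    if rec.n_channels < 2:
        raise ValueError("common average reference requires at least 2 channels")
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return replace(rec, data=data)


def save_recording(rec: Recording, directory) -> None:
    """Write a recording as a .npy array plus channels table and metadata."""
    import json
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "data.npy", rec.data)
    with open(out / "channels.tsv", "w") as fh:
        fh.write("label\tx\ty\tz\n")
        for label, (x, y, z) in zip(rec.labels, rec.coords):
            fh.write(f"{label}\t{x:.8g}\t{y:.8g}\t{z:.8g}\n")
    meta = {"sfreq": rec.sfreq, "segments": [list(s) for s in rec.segments]}
    (out / "meta.json").write_text(json.dumps(meta))


def load_recording(directory) -> Recording:
    """Read a recording written by :func:`save_recording`."""
    import json
    from pathlib import Path

    src = Path(directory)
    data = np.load(src / "data.npy")
    labels, coords = [], []
    with open(src / "channels.tsv") as fh:
        next(fh)
        for line in fh:
            label, x, y, z = line.split("\t")
            labels.append(label)
            coords.append([float(x), float(y), float(z)])
    meta = json.loads((src / "meta.json").read_text())
    return Recording(
        data=data,
        sfreq=meta["sfreq"],
        labels=labels,
        coords=np.array(coords),
        segments=[tuple(s) for s in meta["segments"]],
    )


def read_bdf(path, montage: str = "biosemi32") -> Recording:
    """Optional ingestion of a BioSemi BDF file via :mod:`mne`.

    Channels not present in the named standard montage (EOG, mastoids,
    status) are dropped.  Returned data are in microvolts with a single
    whole-record clean segment; artifact segmentation is the caller's job.
    """
    import mne

    raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    std = mne.channels.make_standard_montage(montage)
    keep = [ch for ch in raw.ch_names if ch in std.ch_names]
    raw.pick(keep)
    raw.set_montage(std)
    pos = std.get_positions()["ch_pos"]
    coords = np.array([pos[ch] for ch in raw.ch_names])
    data = raw.get_data().T * 1e6  # volts -> microvolts
    return Recording(data=data, sfreq=raw.info["sfreq"], labels=list(raw.ch_names), coords=coords)
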