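"""Montage helpers: standard electrode coordinates and leakage mixing."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.spatial.distance import pdist, squareform


@lru_cache(maxsize=4)
def _standard_montage(name: str) -> tuple[tuple[str, ...], tuple[tuple[float, float, float], ...]]:
    import mne

    mont = mne.channels.make_standard_montage(name)
    pos = mont.get_positions()["ch_pos"]
    labels = tuple(pos)
    coords = tuple(tuple(float(v) for v in pos[ch]) for ch in labels)
    return labels, coords


def biosemi32() -> tuple[list[str], np.ndarray]:
    """Labels and 3-D positions of the standard 32-channel BioSemi cap."""
    labels, coords = _standard_montage("biosemi32")
    return list(labels), np.array(coords)


def ring_montage(n_channels: int, radius: float = 0.1) -> tuple[list[str], np.ndarray]:
    """Generic circular montage for small test problems."""
    theta = 2 * np.pi * np.arange(n_channels) / n_channels
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_channels)]
    )
    labels = [f"ch{i:02d}" for i in range(n_channels)]
    return labels, coords


def leakage_mixing(coords: np.ndarray, strength: float = 0.3, scale: float = 0.05) -> np.ndarray:
    """Symmetric distance-decaying volume-conduction (leakage) matrix.

    ``M = I + strength * exp(-d_ij / scale)`` off the diagonal: each sensor
    picks up an exponentially decaying share of its neighbours' signals, an
    instantaneous (zero-lag) real mixing of the kind lagged coherence is
    designed to ignore.  ``strength = 0`` gives the identity.

    Parameters
    ----------
    coords : (n, 3) montage positions.
    strength : peak leakage fraction between coincident sensors.
    scale : decay length in the units of ``coords`` (metres for standard
        montages; 0.05 m is a typical scalp inter-electrode distance).
    """
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    mix = strength * np.exp(-d / scale)
    np.fill_diagonal(mix, 1.0)
    return mix
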