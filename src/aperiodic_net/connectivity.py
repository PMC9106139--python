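"""Cross-spectra and lagged-coherence functional connectivity.

Lagged coherence measures phase coupling between two channels while
discarding the instantaneous (zero-lag) component of their coherency:

    LC_ij(f) = Im(S_ij)^2 / (S_ii * S_jj - Re(S_ij)^2)

where S is the cross-spectral matrix.  Any real (instantaneous) mixing of
underlying sources — the signature of volume conduction in sensor-space
EEG — contributes only to Re(S_ij) and is removed by the normalisation, so
LC responds to genuinely time-lagged coupling only.  Values lie in [0, 1].

Cross-spectra are estimated with the same Hamming-tapered, 50 %-overlap,
segment-aware windowing as the PSD, giving 1 Hz resolution with the
default 1-s window at 512 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Recording
from .spectral import windowed_fft

_REL_EPS = 1e-12


@dataclass
class CrossSpectrum:
    """Hermitian cross-spectral matrix per frequency bin."""

    freqs: np.ndarray  # (n_freqs,) Hz
    S: np.ndarray  # (n_freqs, n, n) complex, Hermitian per frequency
    labels: list[str]

    def freq_index(self, f: float) -> int:
        i = int(np.argmin(np.abs(self.freqs - f)))
        if abs(self.freqs[i] - f) > 1e-9:
            raise ValueError(f"frequency {f} Hz not on the computed grid")
        return i

    def channel_index(self, ch) -> int:
        if isinstance(ch, str):
            try:
                return self.labels.index(ch)
            except ValueError:
                raise KeyError(f"unknown channel {ch!r}") from None
        return int(ch)


@dataclass
class ConnectivityMatrix:
    """Symmetric band-averaged connectivity in [0, 1], zero diagonal."""

    values: np.ndarray  # (n, n)
    labels: list[str]
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v)):
            raise ValueError("entries must be finite and in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def channel_index(self, ch: str) -> int:
        try:
            return self.labels.index(ch)
        except ValueError:
            raise KeyError(f"unknown channel {ch!r}") from None


def cross_spectrum(
    rec: Recording,
    window_seconds: float = 1.0,
    overlap_fraction: float = 0.5,
    fmin: float = 1.0,
    fmax: float = 35.0,
) -> CrossSpectrum:
    """Welch-style cross-spectral matrix over ``[fmin, fmax]`` Hz.

    The diagonal equals the Welch PSD estimate (same taper, windows, and
    density scaling).  Windows respect clean-segment boundaries.
    """
    freqs, X, scale = windowed_fft(rec, window_seconds, overlap_fraction)
    keep = (freqs >= fmin) & (freqs <= fmax)
    if not keep.any():
        raise ValueError(f"no frequency bins in [{fmin}, {fmax}] Hz")
    Xk = X[:, :, keep]  # (n_win, n_ch, n_f)
    # scipy csd convention: S_ij = E[conj(X_i) X_j]
    S = scale * np.einsum("wif,wjf->fij", np.conj(Xk), Xk) / X.shape[0]
    return CrossSpectrum(freqs=freqs[keep], S=S, labels=list(rec.labels))


def _lc_matrix(S_f: np.ndarray) -> np.ndarray:
    """Lagged-coherence matrix at one frequency; degenerate pairs -> 0."""
    p = np.real(np.diag(S_f))
    num = S_f.imag**2
    den = p[:, None] * p[None, :] - S_f.real**2
    floor = _REL_EPS * np.maximum(p[:, None] * p[None, :], np.finfo(float).tiny)
    with np.errstate(invalid="ignore", divide="ignore"):
        lc = np.where(den > floor, num / np.where(den > floor, den, 1.0), 0.0)
    lc = np.clip(lc, 0.0, 1.0)
    np.fill_diagonal(lc, 0.0)
    return lc


def lagged_coherence(S: CrossSpectrum, i, j, f: float) -> float:
    """Lagged coherence between channels ``i`` and ``j`` at frequency ``f``.

    Channels may be given as labels or indices.  Returns 0 (with a warning)
    when the denominator is degenerate, i.e. the coherency is perfectly
    real so no lagged coupling is identifiable.
    """
    ii, jj = S.channel_index(i), S.channel_index(j)
    if ii == jj:
        raise ValueError("lagged coherence is undefined for a channel with itself")
    k = S.freq_index(f)
    S_f = S.S[k]
    p_i, p_j = np.real(S_f[ii, ii]), np.real(S_f[jj, jj])
    if p_i <= 0 or p_j <= 0:
        raise ValueError("auto-spectra must be positive")
    den = p_i * p_j - S_f[ii, jj].real ** 2
    if den <= _REL_EPS * p_i * p_j:
        warnings.warn(
            "degenerate (perfectly real) coherency: lagged coherence set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(np.clip(S_f[ii, jj].imag ** 2 / den, 0.0, 1.0))


def band_fc(S: CrossSpectrum, band: tuple[float, float]) -> ConnectivityMatrix:
    """Entrywise mean of per-frequency lagged coherence over band bins (inclusive)."""
    lo, hi = band
    if lo < S.freqs[0] or hi > S.freqs[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] Hz outside computed range "
            f"[{S.freqs[0]}, {S.freqs[-1]}] Hz"
        )
    bins = np.flatnonzero((S.freqs >= lo) & (S.freqs <= hi))
    if bins.size == 0:
        raise ValueError("band contains no frequency bins")
    acc = np.mean([_lc_matrix(S.S[k]) for k in bins], axis=0)
    acc = 0.5 * (acc + acc.T)  # exact symmetry against fp noise
    return ConnectivityMatrix(values=acc, labels=list(S.labels), band=(lo, hi))


def seed_profile(C: ConnectivityMatrix, seed_channel: str) -> pd.Series:
    """Connectivity between one seed channel and every other channel.

    Returns a Series indexed by the remaining channel labels (the seed's
    own, undefined, entry is dropped).
    """
    i = C.channel_index(seed_channel)
    row = C.values[i]
    labels = [ch for k, ch in enumerate(C.labels) if k != i]
    return pd.Series(np.delete(row, i), index=labels, name=seed_channel)


def fc_table(C: ConnectivityMatrix) -> pd.DataFrame:
    """Square DataFrame with channel-label headers (for TSV export)."""
    return pd.DataFrame(C.values, index=C.labels, columns=C.labels)
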