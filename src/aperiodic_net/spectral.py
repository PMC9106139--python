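"""Welch spectra, robust aperiodic-slope estimation, and band power.

The aperiodic (1/f-like) component of an EEG spectrum is summarised by the
slope of a line fitted in log10-frequency vs log10-power space over
2-45 Hz.  Oscillatory peaks (alpha, beta bumps) would bias a plain fit, so
a three-step procedure is used:

1. robust line fit (iteratively reweighted least squares, bisquare
   weights) on a logarithmically resampled grid;
2. grid points whose residual exceeds one median absolute deviation of the
   residuals are flagged as oscillatory peaks, and each flagged run is
   extended over the contiguous surrounding points with positive residuals
   (the base of the bump);
3. an ordinary least-squares refit on the surviving points.  The slope of
   this second line, with its sign, is the spectral slope: more negative
   means a steeper spectrum.

Band power is reported both raw (mean PSD over the band) and
slope-corrected (mean log10 residual around the fitted line), the latter
isolating oscillatory power from broadband shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import Recording


@dataclass
class Spectrum:
    """Per-channel one-sided Welch PSD on a uniform frequency grid."""

    freqs: np.ndarray  # (n_freqs,) Hz, ascending
    power: np.ndarray  # (n_channels, n_freqs) density, microvolt^2/Hz
    labels: list[str]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power must be finite and non-negative")


@dataclass
class SlopeFit:
    """Aperiodic fit per channel on the log-resampled grid."""

    slope: np.ndarray  # (n_channels,) log10-power per log10-Hz, signed
    intercept: np.ndarray  # (n_channels,) log10 power at log10 f = 0
    fit_range: tuple[float, float]
    log_freqs: np.ndarray  # (n_points,) Hz, log-spaced fit grid
    excluded_mask: np.ndarray  # (n_channels, n_points) True = flagged peak bin
    residuals: np.ndarray  # (n_channels, n_points) log10 residual about final line
    labels: list[str]

    @property
    def n_excluded(self) -> np.ndarray:
        return self.excluded_mask.sum(axis=1)


@dataclass
class BandPower:
    """Raw and slope-corrected mean power over one frequency band."""

    band: tuple[float, float]
    raw: np.ndarray  # (n_channels,) mean PSD over band bins
    residual: np.ndarray  # (n_channels,) mean log10 residual over band bins
    labels: list[str]


def _segment_window_starts(
    segments: list[tuple[int, int]], nperseg: int, step: int
) -> np.ndarray:
    starts = []
    for seg_start, seg_end in segments:
        pos = seg_start
        while pos + nperseg <= seg_end:
            starts.append(pos)
            pos += step
    return np.asarray(starts, dtype=int)


def windowed_fft(
    rec: Recording, window_seconds: float = 1.0, overlap_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray, float]:
    """Hamming-tapered short-time FFTs respecting clean-segment boundaries.

    Windows are laid out independently within every clean segment, so none
    straddles a boundary; pooling all windows weights each segment by its
    window count.  Returns ``(freqs, X, scale)`` where ``X`` has shape
    (n_windows, n_channels, n_freqs) and ``scale * |X|**2`` is a one-sided
    PSD density (DC/Nyquist doubling not yet applied).
    """
    nperseg = int(round(window_seconds * rec.sfreq))
    step = nperseg - int(round(overlap_fraction * nperseg))
    if step <= 0:
        raise ValueError("overlap_fraction must be < 1")
    starts = _segment_window_starts(rec.segments, nperseg, step)
    if starts.size == 0:
        raise ValueError(
            f"no clean segment is at least one {nperseg}-sample window long"
        )
    win = signal.get_window("hamming", nperseg)
    idx = starts[:, None] + np.arange(nperseg)[None, :]
    # (n_windows, nperseg, n_channels) -> taper along samples
    chunks = rec.data[idx] * win[None, :, None]
    X = np.fft.rfft(chunks, axis=1).transpose(0, 2, 1)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / rec.sfreq)
    scale = 2.0 / (rec.sfreq * np.sum(win**2))
    return freqs, X, scale


def welch_psd(
    rec: Recording, window_seconds: float = 1.0, overlap_fraction: float = 0.5
) -> Spectrum:
    """Segment-aware Welch PSD (Hamming taper, 50 % overlap by default).

    With the default 1-s window at 512 Hz the grid has 1 Hz resolution.
    """
    freqs, X, scale = windowed_fft(rec, window_seconds, overlap_fraction)
    power = scale * np.mean(np.abs(X) ** 2, axis=0)
    power[:, 0] /= 2.0
    if freqs[-1] == rec.sfreq / 2:
        power[:, -1] /= 2.0
    return Spectrum(freqs=freqs, power=power, labels=list(rec.labels))


def log_resample(
    spec: Spectrum,
    fmin: float = 2.0,
    fmax: float = 45.0,
    n_points: int = 256,
    interp_log_power: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a spectrum onto log10-equally spaced frequencies.

    By default interpolation is linear in (log10 f, log10 P) space, so an
    exact power law stays exactly on its line; ``interp_log_power=False``
    interpolates the raw power instead (still over log10 f), the other
    reading of "up-sampled with logarithmic bins".  The endpoints are
    reproduced exactly either way.  Returns ``(freqs, power)`` with power
    in linear units.
    """
    if fmin <= 0:
        raise ValueError("fmin must be positive")
    pos = spec.freqs > 0
    f_avail = spec.freqs[pos]
    if fmin < f_avail[0] or fmax > f_avail[-1]:
        raise ValueError(
            f"[{fmin}, {fmax}] Hz outside available range "
            f"[{f_avail[0]}, {f_avail[-1]}] Hz"
        )
    in_range = (f_avail >= fmin) & (f_avail <= fmax)
    if np.any(spec.power[:, pos][:, in_range] <= 0):
        raise ValueError("power must be positive on the resampling range")
    grid = np.logspace(np.log10(fmin), np.log10(fmax), n_points)
    logf = np.log10(f_avail)
    if interp_log_power:
        with np.errstate(divide="ignore"):
            logp = np.log10(spec.power[:, pos])
        out = np.vstack([np.interp(np.log10(grid), logf, row) for row in logp])
        return grid, 10.0**out
    p = spec.power[:, pos]
    out = np.vstack([np.interp(np.log10(grid), logf, row) for row in p])
    return grid, out


def _robust_line(x: np.ndarray, y: np.ndarray, tune: float = 4.685, max_iter: int = 50,
                 tol: float = 1e-10) -> tuple[float, float]:
    """Bisquare IRLS line fit (slope, intercept), MATLAB-robustfit style."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    for _ in range(max_iter):
        resid = y - A @ coef
        s = np.median(np.abs(resid - np.median(resid))) / 0.6745
        if s <= 0:
            break
        u = resid / (tune * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
        Aw = A * w[:, None]
        new, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)
        if np.max(np.abs(new - coef)) < tol * (1 + np.max(np.abs(coef))):
            coef = new
            break
        coef = new
    return float(coef[0]), float(coef[1])


def _extend_flags(flags: np.ndarray, resid: np.ndarray) -> np.ndarray:
    """Extend each flagged point over its contiguous positive-residual base."""
    out = flags.copy()
    n = flags.size
    for i in np.flatnonzero(flags):
        j = i - 1
        while j >= 0 and resid[j] > 0 and not out[j]:
            out[j] = True
            j -= 1
        j = i + 1
        while j < n and resid[j] > 0 and not out[j]:
            out[j] = True
            j += 1
    return out


def fit_slope(
    spec: Spectrum,
    fmin: float = 2.0,
    fmax: float = 45.0,
    n_points: int = 256,
    mad_centered: bool = True,
    min_points: int = 10,
) -> SlopeFit:
    """Three-step robust aperiodic-slope fit per channel.

    ``mad_centered`` chooses whether the MAD of the stage-1 residuals is
    taken about their median (default, the standard MAD) or about zero.
    The MAD is unscaled (no normal-consistency factor): the flagging rule
    is literally ``residual > 1 * MAD``, positive residuals only, since
    oscillations only add power.
    """
    grid, power = log_resample(spec, fmin, fmax, n_points)
    x = np.log10(grid)
    n_ch = power.shape[0]
    slope = np.empty(n_ch)
    intercept = np.empty(n_ch)
    excluded = np.zeros((n_ch, n_points), dtype=bool)
    residuals = np.empty((n_ch, n_points))
    for c in range(n_ch):
        y = np.log10(power[c])
        b1, a1 = _robust_line(x, y)
        resid1 = y - (b1 * x + a1)
        center = np.median(resid1) if mad_centered else 0.0
        mad = np.median(np.abs(resid1 - center))
        # absolute floor keeps fp noise on an exact power law from being flagged
        flags = resid1 > mad + 1e-9 * max(1.0, np.max(np.abs(y)))
        flags = _extend_flags(flags, resid1)
        keep = ~flags
        if keep.sum() < min_points:
            raise ValueError(
                f"channel {spec.labels[c]!r}: only {int(keep.sum())} grid points "
                f"survive peak exclusion (minimum {min_points})"
            )
        b2, a2 = np.polyfit(x[keep], y[keep], 1)
        slope[c] = b2
        intercept[c] = a2
        excluded[c] = flags
        residuals[c] = y - (b2 * x + a2)
    return SlopeFit(
        slope=slope,
        intercept=intercept,
        fit_range=(fmin, fmax),
        log_freqs=grid,
        excluded_mask=excluded,
        residuals=residuals,
        labels=list(spec.labels),
    )


def band_power(
    spec: Spectrum, fit: SlopeFit | None, band: tuple[float, float] = (13.0, 30.0)
) -> BandPower:
    """Raw and slope-corrected mean power over ``band`` (edges inclusive).

    Raw power averages the PSD over the original uniform bins inside the
    band.  The residual (slope-corrected) variant averages the log10
    deviation of those bins from the fitted aperiodic line, so a purely
    aperiodic spectrum scores 0 and an oscillatory bump scores its mean
    log-excess.  Pass ``fit=None`` to compute raw power only.
    """
    lo, hi = band
    if lo >= hi:
        raise ValueError("band must satisfy f_lo < f_hi")
    bins = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not bins.any():
        raise ValueError(f"band [{lo}, {hi}] Hz outside the spectrum")
    raw = spec.power[:, bins].mean(axis=1)
    if fit is None:
        residual = np.full(raw.shape, np.nan)
    else:
        if lo < fit.fit_range[0] or hi > fit.fit_range[1]:
            raise ValueError("band must lie within the slope fit range")
        if np.any(spec.power[:, bins] <= 0):
            raise ValueError("power must be positive in the band for the residual variant")
        logf = np.log10(spec.freqs[bins])
        logp = np.log10(spec.power[:, bins])
        line = fit.intercept[:, None] + fit.slope[:, None] * logf[None, :]
        residual = (logp - line).mean(axis=1)
    return BandPower(band=(lo, hi), raw=raw, residual=residual, labels=list(spec.labels))


def slope_table(fit: SlopeFit) -> "object":
    """Per-channel slope summary as a DataFrame (channel, slope, intercept, n_excluded)."""
    import pandas as pd

    ss_res = (fit.residuals**2).sum(axis=1)
    centered = fit.residuals + fit.slope[:, None] * np.log10(fit.log_freqs)[None, :]
    ss_tot = ((centered - centered.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ss_res / ss_tot
    return pd.DataFrame(
        {
            "channel": fit.labels,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "n_excluded": fit.n_excluded,
            "r_squared": r2,
        }
    )
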