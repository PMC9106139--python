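"""Synthetic multichannel EEG with known aperiodic, oscillatory and coupling truth.

Every recording is synthesised in the frequency domain: the aperiodic
background is a random-phase spectrum with amplitude proportional to
``f**(-beta/2)`` (so its PSD follows ``f**(-beta)`` exactly in expectation),
oscillations are Gaussian-profile narrowband noise bumps riding on that
background, and phase-lagged coupling is realised by injecting a shared
narrowband source into both members of a channel pair, phase-rotated by the
stated lag in the second.  An instantaneous leakage (volume-conduction)
matrix is applied last, so tests can distinguish zero-lag mixing from true
lagged coupling.  Everything is deterministic given the seed.

A two-condition cohort draws per-subject parameters once and applies the
condition effects additively, recording the complete ground truth so every
downstream stage of the pipeline can be checked against known values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import montage as _montage
from .preprocess import Recording

#: Reference background PSD level (microvolt^2/Hz at 1 Hz); sets the overall
#: amplitude scale of synthesised recordings to a realistic EEG magnitude.
BACKGROUND_PSD_AT_1HZ = 20.0


@dataclass(frozen=True)
class Oscillation:
    """Narrowband spectral bump: Gaussian PSD profile on a channel subset.

    ``amplitude`` is the peak PSD of the bump relative to the aperiodic
    background PSD at the centre frequency (e.g. 5.0 means the bump crests
    at five times the background level); ``bandwidth`` is the Gaussian
    standard deviation of the PSD profile in Hz.
    """

    freq: float
    bandwidth: float
    amplitude: float
    channels: tuple[str, ...]


@dataclass(frozen=True)
class Coupling:
    """Phase-lagged shared narrowband source between one channel pair.

    ``strength`` in [0, 1] is the fraction of in-band spectral content that
    the pair shares: within ``band`` each channel keeps ``sqrt(1-strength)``
    of its own background and receives ``sqrt(strength)`` of a common
    source, phase-rotated by ``lag`` radians in the second channel.  A
    strength of 1 with a quarter-cycle lag yields near-perfect lagged
    coherence; strength 0 is no coupling.
    """

    pair: tuple[str, str]
    band: tuple[float, float]
    lag: float
    strength: float


@dataclass
class SyntheticTruth:
    """Full generative description of one synthetic recording."""

    n_channels: int = 32
    sfreq: float = 512.0
    duration: float = 180.0
    aperiodic_exponent: float | np.ndarray = 1.5
    oscillations: list[Oscillation] = field(default_factory=list)
    couplings: list[Coupling] = field(default_factory=list)
    mixing: np.ndarray | None = None
    labels: list[str] | None = None
    coords: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.labels is None or self.coords is None:
            if self.n_channels == 32:
                self.labels, self.coords = _montage.biosemi32()
            else:
                self.labels, self.coords = _montage.ring_montage(self.n_channels)
        if len(self.labels) != self.n_channels:
            raise ValueError("labels must match n_channels")
        self.coords = np.asarray(self.coords, dtype=float)
        beta = np.broadcast_to(
            np.asarray(self.aperiodic_exponent, dtype=float), (self.n_channels,)
        ).copy()
        if not np.all(np.isfinite(beta)) or np.any(beta < 0):
            raise ValueError("aperiodic exponent must be finite and >= 0")
        self.aperiodic_exponent = beta
        for osc in self.oscillations:
            if not (0 < osc.freq < self.sfreq / 2):
                raise ValueError(f"oscillation frequency {osc.freq} outside (0, Nyquist)")
            if osc.bandwidth <= 0 or osc.amplitude < 0:
                raise ValueError("oscillation bandwidth must be > 0 and amplitude >= 0")
            for ch in osc.channels:
                self._index(ch)
        for cpl in self.couplings:
            if not (0 <= cpl.strength <= 1):
                raise ValueError("coupling strength must be in [0, 1]")
            lo, hi = cpl.band
            if not (0 < lo < hi < self.sfreq / 2):
                raise ValueError("coupling band must lie inside (0, Nyquist)")
            a, b = cpl.pair
            if self._index(a) == self._index(b):
                raise ValueError("coupling pair must be two distinct channels")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if self.mixing.shape != (self.n_channels, self.n_channels):
                raise ValueError("mixing must be n_channels x n_channels")
            if not np.all(np.isfinite(self.mixing)):
                raise ValueError("mixing rows must be finite")

    def _index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValueError(f"unknown channel label {label!r}") from None


def generate_recording(truth: SyntheticTruth) -> Recording:
    """Synthesise one recording from its generative description.

    The spectrum is built channel by channel (background, then oscillation
    bumps, then coupling injections), inverse-FFT'd to the time domain, and
    finally passed through the mixing matrix.  Deterministic given
    ``truth.seed``.
    """
    n = int(round(truth.duration * truth.sfreq))
    nperseg = int(round(truth.sfreq))  # one 1-s Welch window
    if n < nperseg:
        raise ValueError(
            f"duration {truth.duration} s too short: need at least one "
            f"{nperseg}-sample analysis window"
        )
    rng = np.random.default_rng(truth.seed)
    freqs = np.fft.rfftfreq(n, 1.0 / truth.sfreq)
    n_freq = freqs.size
    beta = truth.aperiodic_exponent
    # amplitude scale such that the one-sided PSD equals
    # BACKGROUND_PSD_AT_1HZ * f**(-beta)
    scale = np.sqrt(BACKGROUND_PSD_AT_1HZ * truth.sfreq * n / 2.0)

    with np.errstate(divide="ignore"):
        bg_amp = freqs[None, :] ** (-beta[:, None] / 2.0)
    bg_amp[:, 0] = 0.0
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(truth.n_channels, n_freq))
    spec = scale * bg_amp * np.exp(1j * phases)

    for osc in truth.oscillations:
        # restrict to bins where the Gaussian profile is non-negligible
        half_width = osc.bandwidth * np.sqrt(4.0 * np.log(1e12))
        mask = np.abs(freqs - osc.freq) <= half_width
        profile = np.exp(-((freqs[mask] - osc.freq) ** 2) / (4.0 * osc.bandwidth**2))
        for ch in osc.channels:
            i = truth._index(ch)
            peak = np.sqrt(osc.amplitude) * scale * osc.freq ** (-beta[i] / 2.0)
            ph = rng.uniform(0.0, 2.0 * np.pi, size=int(mask.sum()))
            spec[i, mask] += peak * profile * np.exp(1j * ph)

    for cpl in truth.couplings:
        lo, hi = cpl.band
        mask = (freqs >= lo) & (freqs <= hi)
        shared_ph = rng.uniform(0.0, 2.0 * np.pi, size=int(mask.sum()))
        i, j = (truth._index(c) for c in cpl.pair)
        keep = np.sqrt(1.0 - cpl.strength)
        take = np.sqrt(cpl.strength)
        for idx, extra in ((i, 0.0), (j, -cpl.lag)):
            src_amp = scale * freqs[mask] ** (-beta[idx] / 2.0)
            spec[idx, mask] = keep * spec[idx, mask] + take * src_amp * np.exp(
                1j * (shared_ph + extra)
            )

    data = np.fft.irfft(spec, n=n, axis=1).T
    if truth.mixing is not None:
        data = data @ truth.mixing.T
    return Recording(
        data=data,
        sfreq=truth.sfreq,
        labels=list(truth.labels),
        coords=truth.coords.copy(),
    )


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass(frozen=True)
class SlopeEffect:
    """Additive exponent offset applied to condition B on a channel subset."""

    channels: tuple[str, ...]
    delta: float


@dataclass(frozen=True)
class CouplingEffect:
    """Additive coupling-strength offset applied to condition B."""

    pairs: tuple[tuple[str, str], ...]
    band: tuple[float, float]
    delta: float


def _default_oscillations() -> list[Oscillation]:
    # alpha over parieto-occipital, beta over central sensors: the canonical
    # resting-state topography, and the bumps the peak-exclusion step must
    # survive.
    return [
        Oscillation(10.0, 1.5, 4.0, ("P3", "P4", "Pz", "P7", "P8", "O1", "O2", "Oz", "PO3", "PO4")),
        Oscillation(20.0, 2.0, 2.0, ("C3", "C4", "Cz", "FC1", "FC2", "CP1", "CP2")),
    ]


def _default_couplings() -> list[Coupling]:
    # baseline centro-parietal / frontal beta coupling with a quarter-cycle lag
    return [
        Coupling(("C3", "Pz"), (13.0, 30.0), np.pi / 2, 0.3),
        Coupling(("Fz", "Pz"), (13.0, 30.0), np.pi / 2, 0.3),
        Coupling(("C4", "CP2"), (13.0, 30.0), np.pi / 2, 0.3),
    ]


@dataclass
class CohortSpec:
    """Two-condition cohort design with planted, recorded effects.

    The defaults mirror a 15-subject medication ON/OFF resting-state study:
    32 channels, 512 Hz, 180 s per recording, condition B ("ON") with a
    steeper aperiodic exponent over left-central channels.  Per-subject
    parameters are drawn once from the master seed; condition effects are
    purely additive, so the truth table fully determines every recording.
    """

    n_subjects: int = 15
    conditions: tuple[str, str] = ("OFF", "ON")
    n_channels: int = 32
    sfreq: float = 512.0
    duration: float = 180.0
    base_exponent: float = 1.5
    sd_exponent: float = 0.2
    sd_coupling: float = 0.1
    oscillations: list[Oscillation] = field(default_factory=_default_oscillations)
    couplings: list[Coupling] = field(default_factory=_default_couplings)
    slope_effect: SlopeEffect | None = SlopeEffect(
        ("C3", "CP1", "CP5", "FC1", "FC5"), 0.5
    )
    coupling_effect: CouplingEffect | None = None
    mixing_strength: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("exactly two distinct conditions required")
        if self.sd_exponent < 0 or self.sd_coupling < 0:
            raise ValueError("between-subject SDs must be >= 0")
        if self.slope_effect is not None and len(self.slope_effect.channels) == 0:
            raise ValueError("slope-effect channel subset is empty")
        if self.coupling_effect is not None and len(self.coupling_effect.pairs) == 0:
            raise ValueError("coupling-effect pair set is empty")
        labels = self._labels()
        if self.slope_effect is not None:
            for ch in self.slope_effect.channels:
                if ch not in labels:
                    raise ValueError(f"slope-effect channel {ch!r} not in montage")
        if self.coupling_effect is not None:
            for a, b in self.coupling_effect.pairs:
                if a not in labels or b not in labels:
                    raise ValueError(f"coupling-effect pair ({a}, {b}) not in montage")

    def _labels(self) -> list[str]:
        if self.n_channels == 32:
            return _montage.biosemi32()[0]
        return _montage.ring_montage(self.n_channels)[0]


class Cohort:
    """Lazy container of (subject, condition) recordings plus ground truth.

    Recordings are synthesised on demand from stored per-recording
    :class:`SyntheticTruth` objects, so a full cohort costs no memory until
    iterated; repeated access to the same cell is bit-identical.
    """

    def __init__(self, spec: CohortSpec, truths: dict[tuple[str, str], SyntheticTruth]):
        self.spec = spec
        self.truths = truths
        self.subjects = sorted({s for s, _ in truths})
        self.conditions = list(spec.conditions)
        first = next(iter(truths.values()))
        self.labels = list(first.labels)
        self.coords = np.asarray(first.coords)

    def recording(self, subject: str, condition: str) -> Recording:
        return generate_recording(self.truths[(subject, condition)])

    def items(self):
        for subject in self.subjects:
            for condition in self.conditions:
                yield (subject, condition), self.recording(subject, condition)

    def truth_table(self) -> pd.DataFrame:
        """Per-(subject, condition, channel) aperiodic exponent."""
        rows = []
        for (subject, condition), truth in self.truths.items():
            for ch, beta in zip(truth.labels, truth.aperiodic_exponent):
                rows.append(
                    {"subject": subject, "condition": condition, "channel": ch, "beta": beta}
                )
        return pd.DataFrame(rows).sort_values(["subject", "condition", "channel"]).reset_index(
            drop=True
        )

    def coupling_table(self) -> pd.DataFrame:
        """Per-(subject, condition) coupling strengths."""
        rows = []
        for (subject, condition), truth in self.truths.items():
            for cpl in truth.couplings:
                rows.append(
                    {
                        "subject": subject,
                        "condition": condition,
                        "pair": "-".join(cpl.pair),
                        "f_lo": cpl.band[0],
                        "f_hi": cpl.band[1],
                        "lag": cpl.lag,
                        "strength": cpl.strength,
                    }
                )
        return pd.DataFrame(rows)


def cohort_spec_to_json(spec: CohortSpec, path) -> None:
    """Serialise a cohort specification as a JSON config file."""
    import dataclasses
    import json

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    payload = {
        k: encode(getattr(spec, k)) for k in CohortSpec.__dataclass_fields__
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def cohort_spec_from_json(path) -> CohortSpec:
    """Load a cohort specification written by :func:`cohort_spec_to_json`."""
    import json

    with open(path) as fh:
        payload = json.load(fh)

    def tup(seq):
        return tuple(seq) if seq is not None else None

    payload["conditions"] = tup(payload["conditions"])
    payload["oscillations"] = [
        Oscillation(o["freq"], o["bandwidth"], o["amplitude"], tup(o["channels"]))
        for o in payload["oscillations"]
    ]
    payload["couplings"] = [
        Coupling(tup(c["pair"]), tup(c["band"]), c["lag"], c["strength"])
        for c in payload["couplings"]
    ]
    if payload["slope_effect"] is not None:
        e = payload["slope_effect"]
        payload["slope_effect"] = SlopeEffect(tup(e["channels"]), e["delta"])
    if payload["coupling_effect"] is not None:
        e = payload["coupling_effect"]
        payload["coupling_effect"] = CouplingEffect(
            tuple(tup(p) for p in e["pairs"]), tup(e["band"]), e["delta"]
        )
    return CohortSpec(**payload)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort: subject parameters once, condition effects additively."""
    rng = np.random.default_rng(spec.seed)
    labels = spec._labels()
    if spec.n_channels == 32:
        _, coords = _montage.biosemi32()
    else:
        _, coords = _montage.ring_montage(spec.n_channels)
    mixing = (
        _montage.leakage_mixing(coords, strength=spec.mixing_strength)
        if spec.mixing_strength > 0
        else None
    )

    base = np.full(spec.n_channels, spec.base_exponent, dtype=float)
    subj_beta = np.clip(
        base[None, :] + rng.normal(0.0, spec.sd_exponent, size=(spec.n_subjects, spec.n_channels)),
        0.0,
        None,
    )
    subj_strength = np.clip(
        np.array([c.strength for c in spec.couplings])[None, :]
        + rng.normal(0.0, spec.sd_coupling, size=(spec.n_subjects, len(spec.couplings))),
        0.0,
        1.0,
    )
    rec_seeds = rng.integers(0, 2**31 - 1, size=(spec.n_subjects, 2))

    slope_idx = (
        [labels.index(ch) for ch in spec.slope_effect.channels]
        if spec.slope_effect is not None
        else []
    )
    effect_pairs = (
        {tuple(sorted(p)) for p in spec.coupling_effect.pairs}
        if spec.coupling_effect is not None
        else set()
    )

    truths: dict[tuple[str, str], SyntheticTruth] = {}
    for s in range(spec.n_subjects):
        subject = f"sub-{s + 1:02d}"
        for c, condition in enumerate(spec.conditions):
            beta = subj_beta[s].copy()
            strengths = subj_strength[s].copy()
            if c == 1:  # condition B gets the planted effects
                if spec.slope_effect is not None:
                    beta[slope_idx] = np.clip(beta[slope_idx] + spec.slope_effect.delta, 0.0, None)
                if spec.coupling_effect is not None:
                    for k, cpl in enumerate(spec.couplings):
                        if tuple(sorted(cpl.pair)) in effect_pairs:
                            strengths[k] = np.clip(
                                strengths[k] + spec.coupling_effect.delta, 0.0, 1.0
                            )
            couplings = [
                Coupling(cpl.pair, cpl.band, cpl.lag, float(strengths[k]))
                for k, cpl in enumerate(spec.couplings)
            ]
            truths[(subject, condition)] = SyntheticTruth(
                n_channels=spec.n_channels,
                sfreq=spec.sfreq,
                duration=spec.duration,
                aperiodic_exponent=beta,
                oscillations=list(spec.oscillations),
                couplings=couplings,
                mixing=mixing,
                seed=int(rec_seeds[s, c]),
            )
    return Cohort(spec, truths)
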