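"""Synthetic EEG + respiration sessions with meditation/control structure.

The generator emulates the statistical features the downstream analysis
measures: per-band, per-region EEG power differences between conditions,
optional cross-region phase coupling, a slower dominant breathing frequency
during meditation, and injectable ocular / high-voltage / flat-channel
artifacts.

EEG synthesis model
-------------------
Each channel is a superposition of narrowband stochastic rhythms plus a
1/f background, all generated as spectrally shaped Gaussian noise:

* theta: spectral peak at 6.0 Hz (sigma 0.7 Hz),
* alpha: narrow eyes-closed peak at 9.5 Hz (sigma 0.4 Hz),
* beta:  broad 12-30 Hz band,
* background: power ~ 1/f^2 between 0.5 Hz and 40 Hz.

The per-condition ``band_power`` multipliers scale each rhythm's
*variance*, so doubling a multiplier doubles that band's PSD. When
``coupling_strength`` is positive, a session-wide shared component in the
coupled band is mixed into every channel with coefficient ``c`` (the
independent part is scaled by sqrt(1-c^2), keeping the band variance
calibrated), which raises cross-region phase locking monotonically in
``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    BANDS,
    CHANNELS,
    CONDITIONS,
    REGION_MAP,
    REGIONS,
    Recording,
    rng_from,
)

# Spectral shape of each rhythm: (kind, params)
_RHYTHM_SHAPES = {
    "theta": ("peak", 6.0, 0.7),
    "alpha": ("peak", 9.5, 0.4),
    "beta": ("band", 12.0, 30.0),
}

# Baseline (control) standard deviation in microvolts of each rhythm per
# region. Invented, but ordered like resting eyes-closed scalp EEG:
# occipital alpha dominance, frontal theta presence, low-amplitude beta.
_BASE_STD = {
    "alpha": {
        "frontal": 4.0, "central": 3.0, "parietal": 5.0,
        "occipital": 8.0, "right temporal": 5.5, "left temporal": 5.5,
    },
    "theta": {
        "frontal": 5.0, "central": 2.5, "parietal": 4.0,
        "occipital": 6.0, "right temporal": 5.0, "left temporal": 5.0,
    },
    "beta": {
        "frontal": 3.0, "central": 2.5, "parietal": 2.8,
        "occipital": 3.5, "right temporal": 3.2, "left temporal": 3.2,
    },
}

#: Default meditation/control variance ratios. Meditation raises theta and
#: beta power in (almost) all regions and alpha mainly over occipital and
#: right-temporal sites; the frontal theta ratio is essentially 1.
DEFAULT_MEDITATION_MULTIPLIERS = {
    "alpha": {
        "frontal": 1.05, "central": 1.14, "parietal": 0.97,
        "occipital": 1.10, "right temporal": 1.25, "left temporal": 1.05,
    },
    "beta": {
        "frontal": 1.25, "central": 1.56, "parietal": 1.43,
        "occipital": 1.43, "right temporal": 1.38, "left temporal": 1.33,
    },
    "theta": {
        "frontal": 1.00, "central": 1.52, "parietal": 1.21,
        "occipital": 1.70, "right temporal": 1.78, "left temporal": 1.27,
    },
}


def default_band_power() -> dict:
    """Condition -> band -> region -> variance multiplier (defaults)."""
    return {
        "control": {b: {r: 1.0 for r in REGIONS} for b in BANDS},
        "meditation": {
            b: dict(DEFAULT_MEDITATION_MULTIPLIERS[b]) for b in BANDS
        },
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    ``resp_rate`` holds the mean breathing frequency per condition in Hz;
    meditation breathing is slower. ``coupling_strength`` is the mixing
    coefficient of the shared coupled-band component per condition.
    """

    n_channels: int = 32
    fs_native: float = 256.0
    duration: float = 900.0
    band_power: dict = field(default_factory=default_band_power)
    coupling_strength: dict = field(
        default_factory=lambda: {"meditation": 0.9, "control": 0.3}
    )
    coupled_band: str = "alpha"
    resp_rate: dict = field(
        default_factory=lambda: {"meditation": 0.13, "control": 0.25}
    )
    #: sd (Hz) of the per-session offset of the breathing rate.
    resp_rate_jitter: float = 0.03
    noise_floor: float = 1.0
    #: sd of the per-subject log-amplitude trait per band (shared by both
    #: conditions of a subject).
    subject_power_sd: float = 0.15
    #: sd of the per-session log-amplitude wobble (nonstationarity between
    #: repeated sessions of the same subject and condition).
    session_power_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_channels <= len(CHANNELS):
            raise ValueError(f"n_channels must be in 1..{len(CHANNELS)}")
        if self.fs_native <= 0 or self.duration <= 0:
            raise ValueError("fs_native and duration must be positive")
        n = self.duration * self.fs_native
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs_native must be an integer")
        for cond, bands in self.band_power.items():
            for band, regions in bands.items():
                for region, mult in regions.items():
                    if mult <= 0:
                        raise ValueError(
                            f"band_power[{cond}][{band}][{region}] must be > 0"
                        )
        for cond, c in self.coupling_strength.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling_strength[{cond}] must be in [0,1]")
        for cond, r in self.resp_rate.items():
            if not 0 < r < self.fs_native / 2:
                raise ValueError(f"resp_rate[{cond}] outside (0, Nyquist)")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")
        # highest synthesized band edge must sit below Nyquist
        top = max(hi for _, (lo, hi) in BANDS.items())
        if top >= self.fs_native / 2:
            raise ValueError(
                f"Nyquist {self.fs_native / 2} Hz below top band edge {top} Hz"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs_native))

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return CHANNELS[: self.n_channels]

    @property
    def region_map(self) -> dict[str, str]:
        return {c: REGION_MAP[c] for c in self.channel_labels}


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  shape: np.ndarray) -> np.ndarray:
    """Unit-variance Gaussian noise with amplitude spectrum ``shape``."""
    x = rng.standard_normal(n)
    y = np.fft.irfft(np.fft.rfft(x) * shape, n=n)
    sd = y.std()
    if sd == 0:
        return y
    return y / sd


def _rhythm_shape(band: str, freqs: np.ndarray) -> np.ndarray:
    kind, a, b = _RHYTHM_SHAPES[band]
    if kind == "peak":
        return np.exp(-0.5 * ((freqs - a) / b) ** 2)
    lo, hi = a, b
    shape = ((freqs >= lo) & (freqs < hi)).astype(float)
    # soften edges by ~0.5 Hz to avoid ringing
    edge = 0.5
    ramp_lo = (freqs >= lo - edge) & (freqs < lo)
    ramp_hi = (freqs >= hi) & (freqs < hi + edge)
    shape[ramp_lo] = (freqs[ramp_lo] - (lo - edge)) / edge
    shape[ramp_hi] = 1.0 - (freqs[ramp_hi] - hi) / edge
    return shape


def _background_shape(freqs: np.ndarray) -> np.ndarray:
    shape = np.zeros_like(freqs)
    sel = (freqs >= 0.5) & (freqs <= 40.0)
    shape[sel] = 1.0 / freqs[sel]
    return shape


def generate_session(
    config: SyntheticConfig,
    subject_id: str,
    condition: str,
    session: int = 0,
) -> tuple[Recording, Recording]:
    """Generate one labelled session.

    Returns ``(eeg, respiration)`` recordings at ``config.fs_native``.
    Identical ``(config.seed, subject_id, condition, session)`` yield
    bit-identical output. ``session`` distinguishes repeated recordings of
    the same subject and condition.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    n = config.n_samples
    fs = config.fs_native
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    labels = config.channel_labels
    region_map = config.region_map

    rng = rng_from(config.seed, subject_id, condition, session)
    trait_rng = rng_from(config.seed, subject_id, "trait")
    # per-subject trait gain per band (std units, shared across conditions)
    trait_gain = {
        b: float(np.exp(trait_rng.normal(0.0, config.subject_power_sd)))
        for b in BANDS
    }

    c = float(config.coupling_strength.get(condition, 0.0))
    coupled = config.coupled_band
    shapes = {b: _rhythm_shape(b, freqs) for b in BANDS}
    shared = _shaped_noise(rng, n, fs, shapes[coupled]) if c > 0 else None

    data = np.zeros((len(labels), n))
    mult = config.band_power[condition]
    for i, label in enumerate(labels):
        region = region_map[label]
        for band in BANDS:
            std = (
                _BASE_STD[band][region]
                * trait_gain[band]
                * np.sqrt(mult[band][region])
                * np.exp(rng.normal(0.0, config.session_power_jitter))
            )
            comp = _shaped_noise(rng, n, fs, shapes[band])
            if band == coupled and shared is not None:
                comp = np.sqrt(1.0 - c * c) * comp + c * shared
            data[i] += std * comp
        if config.noise_floor > 0:
            data[i] += (
                3.0
                * config.noise_floor
                * _shaped_noise(rng, n, fs, _background_shape(freqs))
            )

    eeg = Recording(
        samples=data,
        fs=fs,
        channel_labels=labels,
        region_map=region_map,
        condition=condition,
        subject_id=subject_id,
    )

    resp = _generate_respiration(config, condition, rng, n, fs)
    resp = Recording(
        samples=resp[None, :],
        fs=fs,
        channel_labels=("Resp",),
        region_map={},
        condition=condition,
        subject_id=subject_id,
    )
    return eeg, resp


def _generate_respiration(
    config: SyntheticConfig,
    condition: str,
    rng: np.random.Generator,
    n: int,
    fs: float,
) -> np.ndarray:
    """Quasi-sinusoidal breathing with slow amplitude/frequency jitter."""
    rate0 = float(config.resp_rate[condition])
    rate0 = max(0.05, rate0 + rng.normal(0.0, config.resp_rate_jitter))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    # slow modulators (< 0.02 Hz)
    slow_shape = np.exp(-0.5 * (freqs / 0.01) ** 2)
    slow_shape[0] = 0.0
    freq_mod = _shaped_noise(rng, n, fs, slow_shape)
    amp_mod = _shaped_noise(rng, n, fs, slow_shape)
    inst_rate = rate0 * (1.0 + 0.05 * freq_mod)
    phase = 2.0 * np.pi * np.cumsum(inst_rate) / fs
    # slower breathing is deeper: belt excursion grows as the rate drops
    # (tidal-volume compensation), referenced to 0.25 Hz resting breathing
    depth = (0.25 / rate0) ** 0.5
    breath = depth * (1.0 + 0.15 * amp_mod) * np.sin(phase)
    noise_shape = np.zeros_like(freqs)
    noise_shape[(freqs > 0) & (freqs < 5.0)] = 1.0
    return breath + 0.05 * _shaped_noise(rng, n, fs, noise_shape)


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

#: Relative blink amplitude by channel-name prefix (frontal-dominant).
_BLINK_WEIGHTS = (
    ("Fp", 1.0), ("AF", 0.7), ("FC", 0.15), ("F", 0.4),
)


def _blink_weight(label: str) -> float:
    for prefix, w in _BLINK_WEIGHTS:
        if label.startswith(prefix):
            return w
    return 0.05


def blink_template(fs: float, duration: float = 0.5) -> np.ndarray:
    """Raised-cosine blink transient of unit peak amplitude."""
    n = max(3, int(round(duration * fs)))
    t = np.arange(n) / (n - 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def inject_artifacts(
    rec: Recording,
    blink_rate: float = 0.0,
    hv_segments: list[tuple[float, float, float]] | None = None,
    flat_channels: list[str] | None = None,
    blink_amplitude: float = 300.0,
    seed: int | None = None,
) -> Recording:
    """Add stereotyped artifacts to an EEG recording.

    Parameters
    ----------
    blink_rate
        Eye blinks per minute; blinks are 0.5-s raised-cosine transients
        with a frontal-dominant spatial pattern.
    hv_segments
        ``(start_s, duration_s, amplitude_uV)`` rectangular high-voltage
        excursions added to every channel.
    flat_channels
        Channel labels rescaled below the 2-microvolt flat threshold.
    """
    if blink_rate < 0 or blink_amplitude < 0:
        raise ValueError("rates and amplitudes must be non-negative")
    hv_segments = hv_segments or []
    flat_channels = flat_channels or []
    out = rec.copy_with(samples=rec.samples.copy())
    x = out.samples
    n, fs = rec.n_samples, rec.fs

    if blink_rate > 0:
        rng = np.random.default_rng(seed)
        n_blinks = rng.poisson(blink_rate * rec.duration / 60.0)
        tmpl = blink_template(fs)
        weights = np.array([_blink_weight(c) for c in rec.channel_labels])
        for _ in range(n_blinks):
            start = rng.integers(0, max(1, n - tmpl.size))
            x[:, start : start + tmpl.size] += (
                blink_amplitude * np.outer(weights, tmpl)
            )

    for start_s, dur_s, amp in hv_segments:
        if amp < 0:
            raise ValueError("segment amplitude must be non-negative")
        i0 = int(round(start_s * fs))
        i1 = int(round((start_s + dur_s) * fs))
        if start_s < 0 or i1 > n:
            raise ValueError(
                f"segment [{start_s}, {start_s + dur_s}] s outside recording"
            )
        x[:, i0:i1] += amp

    for label in flat_channels:
        idx = rec.channel_labels.index(label)
        peak = np.max(np.abs(x[idx]))
        if peak > 0:
            x[idx] *= 1.0 / peak  # max abs amplitude 1 uV, below 2 uV bound
    return out


def generate_cohort(
    config: SyntheticConfig,
    n_subjects: int,
    sessions_per_condition: int = 1,
):
    """Yield ``(subject_id, condition, session, eeg, resp)`` tuples."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for s in range(n_subjects):
        sid = f"s{s + 1:02d}"
        for condition in CONDITIONS:
            for k in range(sessions_per_condition):
                eeg, resp = generate_session(config, sid, condition, session=k)
                yield sid, condition, k, eeg, resp
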