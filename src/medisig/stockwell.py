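"""Stockwell (S-) transform and the respiration condition contrast.

The S-transform of a discrete signal x[m] at frequency f (cycles/sample)
and time index n is

    S(f, n] = sum_m x[m] (|f| / sqrt(2 pi)) exp(-(n-m)^2 f^2 / 2)
                     exp(-i 2 pi f m)

i.e. a Gaussian-windowed Fourier analysis whose window standard deviation
is 1/f samples, giving wavelet-like multiresolution with absolutely
referenced phase. Frequencies passed to :func:`stransform` are in Hz and
converted internally (f_cycles = f_hz / fs). The implementation evaluates
the sum as one linear convolution per frequency using zero-padded FFTs
(no circular wrap-around); it matches the direct double summation to
floating-point accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len

from .spectral import AnovaResult, boxcox_normalize, rm_anova

#: (fmin, fmax, df) grids in Hz.
EEG_PHASE_GRID = (4.0, 32.0, 1.0)
EEG_FEATURE_GRID = (4.0, 32.0, 0.25)
RESP_GRID = (0.0625, 16.0, 0.0625)


@dataclass
class TimeFrequencyMap:
    """Complex S-transform coefficients indexed (frequency, time)."""

    coefficients: np.ndarray  # (n_freqs, n_samples) complex
    frequencies: np.ndarray  # Hz
    fs: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.coefficients.shape[0] != self.frequencies.size:
            raise ValueError("coefficient rows must match frequency grid")
        if np.any(self.frequencies <= 0) or np.any(self.frequencies > self.fs / 2):
            raise ValueError("frequency grid must lie in (0, fs/2]")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    def save(self, path) -> Path:
        """Persist as a binary container with a JSON header."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            coefficients=self.coefficients,
            frequencies=self.frequencies,
        )
        header = {"fs": self.fs, "channel": self.channel,
                  "n_freqs": int(self.frequencies.size),
                  "n_samples": int(self.coefficients.shape[1])}
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "TimeFrequencyMap":
        path = Path(path)
        header = json.loads(path.with_suffix(".json").read_text())
        arrays = np.load(path.with_suffix(".npz"))
        return cls(
            coefficients=arrays["coefficients"],
            frequencies=arrays["frequencies"],
            fs=header["fs"],
            channel=header.get("channel", ""),
        )


def frequency_grid(fmin: float, fmax: float, df: float) -> np.ndarray:
    """Inclusive Hz grid fmin, fmin+df, ..., fmax."""
    n_steps = (fmax - fmin) / df
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"df={df} does not divide [{fmin}, {fmax}] evenly")
    return fmin + df * np.arange(int(round(n_steps)) + 1)


class STPlan:
    """Reusable S-transform machinery for a fixed signal length and grid.

    Precomputes the FFT of the wrapped Gaussian window and the complex
    demodulator per grid frequency, so transforming many equally sized
    signals (channels, surrogates) costs two FFTs per frequency each.
    """

    def __init__(self, n: int, fs: float, freqs: np.ndarray,
                 chunk_bytes: int = 256_000_000):
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs <= 0) or np.any(freqs > fs / 2.0):
            raise ValueError("grid frequencies must lie in (0, fs/2]")
        self.n = int(n)
        self.fs = float(fs)
        self.freqs = freqs
        f_cyc = freqs / fs
        # zero-pad beyond the widest Gaussian tail -> linear convolution
        pad = int(np.ceil(10.0 / f_cyc.min()))
        self.npad = next_fast_len(self.n + pad)
        m = np.arange(self.npad)
        dist = np.minimum(m, self.npad - m).astype(float)
        fc = f_cyc[:, None]
        g = fc / np.sqrt(2.0 * np.pi) * np.exp(-0.5 * (dist[None, :] * fc) ** 2)
        self._G = fft(g, axis=1)
        self._demod = np.exp(-2j * np.pi * fc * np.arange(self.n)[None, :])
        self._rows = max(1, int(chunk_bytes / (self.npad * 32)))

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Return the (n_freqs, n) complex coefficient matrix."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"expected a signal of {self.n} samples")
        out = np.empty((self.freqs.size, self.n), dtype=complex)
        for s in range(0, self.freqs.size, self._rows):
            h = x[None, :] * self._demod[s : s + self._rows]
            H = fft(h, n=self.npad, axis=1)
            out[s : s + self._rows] = ifft(H * self._G[s : s + self._rows],
                                           axis=1)[:, : self.n]
        return out


def stransform(
    x: np.ndarray,
    fs: float,
    fmin: float,
    fmax: float,
    df: float,
    channel: str = "",
) -> TimeFrequencyMap:
    """S-transform of a 1-D signal on an evenly spaced Hz grid."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("stransform expects a 1-D signal")
    if not 0.0 < fmin <= fmax <= fs / 2.0:
        raise ValueError(f"need 0 < fmin <= fmax <= fs/2, got [{fmin},{fmax}] at fs={fs}")
    freqs = frequency_grid(fmin, fmax, df)
    plan = STPlan(x.size, fs, freqs)
    return TimeFrequencyMap(plan.transform(x), freqs, fs, channel=channel)


def dominant_frequency(tfmap: TimeFrequencyMap) -> float:
    """Frequency whose time-averaged amplitude is maximal."""
    return float(tfmap.frequencies[np.argmax(tfmap.amplitude.mean(axis=1))])


def amplitude_spectrum(tfmap: TimeFrequencyMap) -> pd.DataFrame:
    """Time-averaged amplitude per frequency."""
    return pd.DataFrame({
        "frequency": tfmap.frequencies,
        "amplitude": tfmap.amplitude.mean(axis=1),
    })


def respiration_tfa_contrast(
    resp_maps: dict[str, dict[str, TimeFrequencyMap]],
    boxcox: bool = True,
    unit: str = "subject",
) -> tuple[AnovaResult, pd.DataFrame]:
    """One-factor (Condition) within-subject ANOVA on S-coefficients.

    ``resp_maps`` maps subject -> condition -> time-frequency map of the
    respiration channel. With the default ``unit="subject"`` the analysed
    observation is the subject's mean coefficient amplitude (over time
    and frequency), giving the condition effect on (1, n-1) degrees of
    freedom; ``unit="frequency"`` instead keeps per-frequency time means
    as within-subject replicates. Amplitudes are Box-Cox transformed
    before the ANOVA when non-normal. Returns the condition effect and
    the per-condition mean amplitude spectra.
    """
    rows = []
    for subject, by_cond in resp_maps.items():
        missing = {"meditation", "control"} - set(by_cond)
        if missing:
            raise ValueError(f"subject {subject!r} missing condition(s) {missing}")
        for condition, tfmap in by_cond.items():
            amp = tfmap.amplitude.mean(axis=1)
            for f, a in zip(tfmap.frequencies, amp):
                rows.append({"subject": subject, "condition": condition,
                             "frequency": f, "amplitude": a})
    df = pd.DataFrame(rows)
    spectra = (
        df.groupby(["condition", "frequency"], as_index=False)["amplitude"].mean()
    )
    if unit == "subject":
        df = df.groupby(["subject", "condition"], as_index=False)["amplitude"].mean()
        block = "subject"
    elif unit == "frequency":
        df["unit"] = df["subject"].astype(str) + "@" + df["frequency"].astype(str)
        block = "unit"
    else:
        raise ValueError(f"unknown unit {unit!r}")
    lam = None
    if boxcox:
        values, lam, _ = boxcox_normalize(df["amplitude"].to_numpy())
        df = df.assign(amplitude=values)
    (result,) = rm_anova(df, dv="amplitude", within=("condition",),
                         subject=block)
    result.boxcox_lambda = lam
    return result, spectra


def export_heatmap(tfmap: TimeFrequencyMap, path, cmap: str = "magma"):
    """Save an amplitude heatmap (time x frequency) as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    t = np.arange(tfmap.coefficients.shape[1]) / tfmap.fs
    ax.pcolormesh(t, tfmap.frequencies, tfmap.amplitude,
                  shading="auto", cmap=cmap)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(tfmap.channel or "S-transform amplitude")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
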