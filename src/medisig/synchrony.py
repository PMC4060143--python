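"""Phase-lock value synchrony with surrogate-based thresholding.

The phase-lock value between channels i and j at frequency f is the
modulus of the rectangular-windowed average of the unit phasor of their
S-transform phase difference:

    PLV(f, n] = (1/L) | sum_m e^{j theta(f, m]} v[n - m] |

with L the window length (2 s) and theta the wrapped phase difference.
PLV is 1 for perfectly locked phases and ~1/sqrt(L_eff) for asynchronous
signals. The decision threshold is the 0.9 quantile of PLVs pooled from
500 pairs of phase-randomized surrogate signals, which share the
reference's power spectrum but carry independent uniform Fourier phases.
Synchronous electrode pairs (cross-region only) are counted per band and
condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import BANDS, Recording
from .stockwell import EEG_PHASE_GRID, STPlan, frequency_grid

#: PLV window length in seconds.
WINDOW_S = 2.0
N_SURROGATE_PAIRS = 500
CONFIDENCE = 0.9


def phase_difference(phase_i: np.ndarray, phase_j: np.ndarray) -> np.ndarray:
    """Pairwise phase difference wrapped to (-pi, pi]."""
    phase_i = np.asarray(phase_i)
    phase_j = np.asarray(phase_j)
    if phase_i.shape != phase_j.shape:
        raise ValueError(
            f"phase grids differ: {phase_i.shape} vs {phase_j.shape}"
        )
    theta = phase_i - phase_j
    wrapped = np.mod(-theta + np.pi, 2.0 * np.pi)
    return -(wrapped - np.pi)


def plv(theta: np.ndarray, window_length: int) -> np.ndarray:
    """Sliding-window PLV of a phase-difference series.

    ``theta`` has shape ``(..., n)``; the result has shape
    ``(..., n - window_length + 1)`` with one value per full window
    position, each in [0, 1].
    """
    theta = np.asarray(theta)
    n = theta.shape[-1]
    if not 0 < window_length <= n:
        raise ValueError(f"window of {window_length} invalid for {n} samples")
    z = np.exp(1j * theta)
    cs = np.cumsum(z, axis=-1)
    lead = cs[..., window_length - 1 :]
    lag = np.concatenate(
        [np.zeros(theta.shape[:-1] + (1,), dtype=complex),
         cs[..., : n - window_length]],
        axis=-1,
    )
    values = np.abs(lead - lag) / window_length
    return np.clip(values, 0.0, 1.0)


def phase_randomized_surrogate(
    amplitude_spectrum: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Real signal with the given rFFT amplitude and iid uniform phases."""
    phases = rng.uniform(-np.pi, np.pi, size=amplitude_spectrum.shape)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    return np.fft.irfft(amplitude_spectrum * np.exp(1j * phases), n=n)


@dataclass
class SurrogateThreshold:
    """PLV decision threshold with its provenance."""

    threshold: float
    confidence: float
    n_pairs: int
    seed: int
    method: str = "phase-randomization"
    histogram: np.ndarray | None = None
    bin_edges: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")

    def quantile(self, q: float) -> float:
        """Empirical quantile of the pooled surrogate PLV histogram."""
        if self.histogram is None:
            raise ValueError("no histogram stored")
        cdf = np.cumsum(self.histogram) / self.histogram.sum()
        idx = int(np.searchsorted(cdf, q, side="left"))
        idx = min(idx, len(self.bin_edges) - 2)
        return float(self.bin_edges[idx + 1])


def surrogate_threshold(
    reference: Recording | np.ndarray,
    fs: float | None = None,
    n_pairs: int = N_SURROGATE_PAIRS,
    confidence: float = CONFIDENCE,
    seed: int = 0,
    grid: tuple[float, float, float] = EEG_PHASE_GRID,
    window_s: float = WINDOW_S,
    n_bins: int = 2000,
) -> SurrogateThreshold:
    """Pool PLVs over phase-randomized surrogate pairs; take a quantile.

    Each surrogate preserves the reference's amplitude spectrum exactly;
    PLV is computed from S-transform phases on ``grid`` with
    ``window_s``-second rectangular windows, every window position of
    every pair and frequency entering one pooled histogram.
    """
    if isinstance(reference, Recording):
        if reference.n_channels != 1:
            raise ValueError("pass a single-channel reference")
        x = reference.samples[0]
        fs = reference.fs
    else:
        x = np.asarray(reference, dtype=float)
        if fs is None:
            raise ValueError("fs required with an array reference")
    if n_pairs < 50:
        warnings.warn(
            f"n_pairs={n_pairs} < 50: quantile estimate unstable", stacklevel=2
        )
    if not 0.0 <= confidence <= 1.0:
        raise ValueError("confidence must lie in [0, 1]")

    n = x.size
    window = int(round(window_s * fs))
    freqs = frequency_grid(*grid)
    plan = STPlan(n, fs, freqs)
    amp = np.abs(np.fft.rfft(x))
    rng = np.random.default_rng(seed)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist = np.zeros(n_bins)
    for _ in range(n_pairs):
        s1 = phase_randomized_surrogate(amp, n, rng)
        s2 = phase_randomized_surrogate(amp, n, rng)
        theta = np.angle(plan.transform(s1)) - np.angle(plan.transform(s2))
        values = plv(theta, window)
        hist += np.histogram(values.ravel(), bins=edges)[0]

    result = SurrogateThreshold(
        threshold=0.0, confidence=confidence, n_pairs=n_pairs, seed=seed,
        histogram=hist, bin_edges=edges,
    )
    if confidence <= 0.0:
        nz = np.flatnonzero(hist)
        result.threshold = float(edges[nz[0]]) if nz.size else 0.0
    else:
        result.threshold = result.quantile(confidence)
    return result


def cross_region_pairs(
    channel_labels, region_map: dict[str, str]
) -> list[tuple[str, str]]:
    """All electrode pairs whose channels belong to different regions."""
    mapped = [c for c in channel_labels if c in region_map]
    return [
        (a, b)
        for a, b in combinations(mapped, 2)
        if region_map[a] != region_map[b]
    ]


def session_band_plv(
    eeg: Recording,
    grid: tuple[float, float, float] = EEG_PHASE_GRID,
    window_s: float = WINDOW_S,
    pairs: list[tuple[str, str]] | None = None,
    bands: dict[str, tuple[float, float]] = BANDS,
) -> pd.DataFrame:
    """Per-pair, per-band PLV summary for one preprocessed session.

    For each admissible (cross-region) pair the band PLV series is the
    mean over the band's grid frequencies of the sliding-window PLV; the
    summary keeps its median over window positions plus the fraction of
    windows above any later threshold (stored as the full series median
    and mean here).
    """
    freqs = frequency_grid(*grid)
    plan = STPlan(eeg.n_samples, eeg.fs, freqs)
    window = int(round(window_s * eeg.fs))
    if pairs is None:
        pairs = cross_region_pairs(eeg.channel_labels, eeg.region_map)
    phases = {
        label: np.angle(plan.transform(eeg.channel(label)))
        for label in {c for p in pairs for c in p}
    }
    band_sel = {
        band: (freqs >= lo) & (freqs < hi) for band, (lo, hi) in bands.items()
    }
    rows = []
    for a, b in pairs:
        theta = phase_difference(phases[a], phases[b])
        series = plv(theta, window)  # (F, W)
        for band, sel in band_sel.items():
            if not sel.any():
                continue
            band_series = series[sel].mean(axis=0)
            rows.append({
                "channel_i": a, "channel_j": b, "band": band,
                "plv_median": float(np.median(band_series)),
                "plv_mean": float(band_series.mean()),
            })
    return pd.DataFrame(rows)


def count_synchronous_pairs(
    band_plv: pd.DataFrame,
    threshold: float,
    statistic: str = "plv_median",
) -> pd.DataFrame:
    """Count pairs whose band PLV summary exceeds the threshold.

    A pair counts once per band when its median-over-windows PLV exceeds
    ``threshold``. Also reports the exceedance fraction among admissible
    pairs.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = []
    for band, sub in band_plv.groupby("band", sort=False):
        above = int((sub[statistic] > threshold).sum())
        out.append({
            "band": band,
            "count": above,
            "n_pairs": len(sub),
            "fraction": above / len(sub) if len(sub) else np.nan,
        })
    return pd.DataFrame(out)
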