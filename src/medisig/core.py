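"""Shared containers and constants for the EEG/respiration meditation pipeline.

Everything downstream works on :class:`Recording` objects: a labelled
multichannel time series with a sampling rate, a channel->scalp-region map
and a condition label (``"meditation"`` or ``"control"``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

CONDITIONS = ("meditation", "control")

#: Scalp regions used for spatial averaging (six regions).
REGIONS = (
    "frontal",
    "central",
    "parietal",
    "occipital",
    "right temporal",
    "left temporal",
)

#: 32-channel montage (10-20 extension) used throughout.
CHANNELS = (
    "Fp1", "AF3", "F7", "F3", "FC1", "FC5", "T7", "C3",
    "CP1", "CP5", "P7", "P3", "Pz", "PO3", "O1", "Oz",
    "O2", "PO4", "P4", "P8", "CP6", "CP2", "C4", "T8",
    "FC6", "FC2", "F4", "F8", "AF4", "Fp2", "Fz", "Cz",
)

#: Default channel -> region assignment.
REGION_MAP = {
    "Fp1": "frontal", "Fp2": "frontal", "AF3": "frontal", "AF4": "frontal",
    "F3": "frontal", "F4": "frontal", "Fz": "frontal",
    "FC1": "central", "FC2": "central", "C3": "central", "C4": "central",
    "Cz": "central", "CP1": "central", "CP2": "central",
    "P3": "parietal", "P4": "parietal", "Pz": "parietal",
    "PO3": "parietal", "PO4": "parietal",
    "O1": "occipital", "Oz": "occipital", "O2": "occipital",
    "F7": "left temporal", "FC5": "left temporal", "T7": "left temporal",
    "CP5": "left temporal", "P7": "left temporal",
    "F8": "right temporal", "FC6": "right temporal", "T8": "right temporal",
    "CP6": "right temporal", "P8": "right temporal",
}

#: Frequency bands in Hz, left-closed / right-open intervals.
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}

#: Band order used in tables and reports.
BAND_NAMES = tuple(BANDS)


@dataclass
class Recording:
    """A labelled multichannel time series.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array. EEG is in microvolts,
        respiration in arbitrary units.
    fs
        Sampling rate in Hz.
    channel_labels
        One label per row of ``samples``.
    region_map
        Maps each EEG channel label to one scalp region. May be empty for
        non-EEG modalities.
    condition
        ``"meditation"`` or ``"control"`` (or ``None`` when unlabelled).
    subject_id
        Free-form subject identifier.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    region_map: dict[str, str] = field(default_factory=dict)
    condition: str | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[None, :]
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        self.channel_labels = tuple(self.channel_labels)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for label, region in self.region_map.items():
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r} for {label!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        return self.samples[self.channel_labels.index(label)]

    def copy_with(self, **changes) -> "Recording":
        """Return a copy with selected fields replaced."""
        if "samples" not in changes:
            changes["samples"] = self.samples.copy()
        return replace(self, **changes)


def stable_seed(*parts) -> int:
    """Derive a deterministic child seed (< 2**31) from mixed parts.

    Strings are hashed with CRC32 so the derivation is stable across
    interpreter runs (unlike ``hash``). Used to fan a master seed out to
    stages / subjects / conditions without correlated streams.
    """
    ints = []
    for p in parts:
        if isinstance(p, str):
            ints.append(zlib.crc32(p.encode()))
        else:
            ints.append(int(p) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def rng_from(*parts) -> np.random.Generator:
    """A ``numpy`` generator seeded deterministically from ``parts``."""
    return np.random.default_rng(stable_seed(*parts))
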