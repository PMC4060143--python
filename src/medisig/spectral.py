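"""Bartlett spectral analysis and within-subject ANOVA.

The PSD estimator averages modified periodograms of consecutive
non-overlapping segments tapered with a 4-term Blackman-Harris window:

    P(w) = (1/K) sum_k (1/N) | sum_n x_k[n] w[n] e^{-jwn} |^2

No window-power or rate normalization is applied beyond the 1/N factor,
so values are comparable across conditions but carry arbitrary absolute
units. Band powers average the PSD over left-closed/right-open frequency
bands (theta [4,8), alpha [8,12), beta [12,30) Hz) and over the channels
of each scalp region.

The repeated-measures ANOVA is computed from sums of squares with the
standard within-subject error strata: the condition effect is tested
against the condition-by-subject stratum on (1, n-1) degrees of freedom
and the condition-by-location interaction against its own stratum on
(5, 5(n-1)) for six locations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal.windows import blackmanharris

from .core import BANDS, Recording
from .preprocess import ArtifactMask


@dataclass
class PSDEstimate:
    """Bartlett PSD per channel on a common frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    segment_length: int
    n_segments: np.ndarray  # per channel
    channel_labels: tuple[str, ...]
    fs: float

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")


def bartlett_psd(
    rec: Recording,
    segment_length: int = 256,
    mask: ArtifactMask | None = None,
) -> PSDEstimate:
    """Average Blackman-Harris-tapered periodograms of length-N segments.

    Segments are formed only inside spans the artifact mask keeps, so
    rejected intervals never leak into the estimate.
    """
    n = segment_length
    if n < 2 or n > rec.n_samples:
        raise ValueError(f"segment_length {n} invalid for {rec.n_samples} samples")
    w = blackmanharris(n, sym=False)
    freqs = np.fft.rfftfreq(n, 1.0 / rec.fs)
    power = np.zeros((rec.n_channels, freqs.size))
    counts = np.zeros(rec.n_channels, dtype=int)
    for i, row in enumerate(rec.samples):
        if mask is not None:
            spans = _kept_spans(mask.keep[i])
        else:
            spans = [(0, rec.n_samples)]
        acc = np.zeros(freqs.size)
        k = 0
        for start, stop in spans:
            n_seg = (stop - start) // n
            if n_seg == 0:
                continue
            seg = row[start : start + n_seg * n].reshape(n_seg, n)
            spec = np.abs(np.fft.rfft(seg * w, axis=1)) ** 2 / n
            acc += spec.sum(axis=0)
            k += n_seg
        if k == 0:
            raise ValueError(
                f"no usable segment of {n} samples on channel "
                f"{rec.channel_labels[i]!r}"
            )
        power[i] = acc / k
        counts[i] = k
    return PSDEstimate(
        frequencies=freqs,
        power=power,
        segment_length=n,
        n_segments=counts,
        channel_labels=rec.channel_labels,
        fs=rec.fs,
    )


def _kept_spans(keep: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.r_[False, keep, False]))
    return list(zip(edges[::2], edges[1::2]))


def band_region_power(
    psd: PSDEstimate,
    region_map: dict[str, str],
    bands: dict[str, tuple[float, float]] = BANDS,
    per_frequency: bool = False,
) -> pd.DataFrame:
    """Aggregate a PSD into band x region mean powers.

    With ``per_frequency=True`` rows are kept per band frequency (the
    region average only), for analyses that treat frequencies as
    within-subject replicates.
    """
    regions: dict[str, list[int]] = {}
    for i, label in enumerate(psd.channel_labels):
        if label in region_map:
            regions.setdefault(region_map[label], []).append(i)
    rows = []
    for band, (lo, hi) in bands.items():
        sel = (psd.frequencies >= lo) & (psd.frequencies < hi)
        if not sel.any():
            raise ValueError(f"no PSD frequencies inside {band} [{lo},{hi})")
        for region, idx in regions.items():
            region_spec = psd.power[idx][:, sel].mean(axis=0)
            if per_frequency:
                for f, p in zip(psd.frequencies[sel], region_spec):
                    rows.append({"band": band, "region": region,
                                 "frequency": f, "power": p})
            else:
                rows.append({"band": band, "region": region,
                             "power": float(region_spec.mean())})
    return pd.DataFrame(rows)


def cohort_power_table(
    records: list[tuple[str, str, PSDEstimate]],
    region_map: dict[str, str],
    per_frequency: bool = False,
) -> pd.DataFrame:
    """Stack (subject, condition, PSD) triples into one long table."""
    frames = []
    for subject, condition, psd in records:
        df = band_region_power(psd, region_map, per_frequency=per_frequency)
        df.insert(0, "condition", condition)
        df.insert(0, "subject", subject)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def boxcox_normalize(values, alpha: float = 0.05):
    """Box-Cox transform applied when a normality pre-test fails.

    Returns ``(transformed, lambda_or_None, shapiro_p)``. Lambda is chosen
    by profile maximum likelihood; the transform is skipped when the
    Shapiro-Wilk test does not reject normality at ``alpha``.
    """
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values")
    sample = x if x.size <= 5000 else np.random.default_rng(0).choice(x, 5000, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.shapiro(sample).pvalue) if sample.size >= 3 else 1.0
    if p >= alpha:
        return x, None, p
    y, lam = stats.boxcox(x)
    return y, float(lam), p


def boxcox_transform(values, lam: float) -> np.ndarray:
    """The Box-Cox map at a fixed lambda ((x^l - 1)/l, log at l=0)."""
    x = np.asarray(values, dtype=float)
    if lam == 0.0:
        return np.log(x)
    return (x ** lam - 1.0) / lam


@dataclass
class AnovaResult:
    """One tested effect of a within-subject ANOVA."""

    effect: str
    F: float
    df: tuple[int, int]
    p: float
    ss_effect: float
    ss_error: float
    boxcox_lambda: float | None = None
    cell_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.F < 0 or not (0.0 <= self.p <= 1.0):
            raise ValueError("invalid F or p")


def rm_anova(
    df: pd.DataFrame,
    dv: str = "power",
    within=("condition",),
    subject: str = "subject",
) -> list[AnovaResult]:
    """Within-subject ANOVA (one or two factors) from sums of squares.

    Requires a complete balanced design with one observation per
    subject x factor-level cell (aggregate replicates first).
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise ValueError("one or two within-subject factors supported")
    piv = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if piv.isna().any().any():
        raise ValueError("missing cells in the within-subject design")
    n = piv.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")

    if len(within) == 1:
        y = piv.to_numpy()  # (n, a)
        a = y.shape[1]
        grand = y.mean()
        ss_A = n * np.sum((y.mean(axis=0) - grand) ** 2)
        ss_S = a * np.sum((y.mean(axis=1) - grand) ** 2)
        ss_tot = np.sum((y - grand) ** 2)
        ss_AS = ss_tot - ss_A - ss_S
        df1, df2 = a - 1, (a - 1) * (n - 1)
        return [_f_result(within[0], ss_A, ss_AS, df1, df2,
                          _cell_means(piv, within), scale=ss_tot)]

    levels_a = piv.columns.get_level_values(0).unique()
    levels_b = piv.columns.get_level_values(1).unique()
    a, b = len(levels_a), len(levels_b)
    y = piv.to_numpy().reshape(n, a, b)
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_A = n * b * np.sum((m_a - grand) ** 2)
    ss_B = n * a * np.sum((m_b - grand) ** 2)
    ss_AB = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_S = a * b * np.sum((m_s - grand) ** 2)
    ss_AS = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_BS = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_ABS = ss_tot - (ss_A + ss_B + ss_AB + ss_S + ss_AS + ss_BS)

    cells = _cell_means(piv, within)
    return [
        _f_result(within[0], ss_A, ss_AS, a - 1, (a - 1) * (n - 1), cells,
                  scale=ss_tot),
        _f_result(within[1], ss_B, ss_BS, b - 1, (b - 1) * (n - 1), cells,
                  scale=ss_tot),
        _f_result(
            f"{within[0]} x {within[1]}",
            ss_AB, ss_ABS, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1),
            cells, scale=ss_tot,
        ),
    ]


def _cell_means(piv: pd.DataFrame, within) -> dict:
    return {
        (key if isinstance(key, tuple) else (key,)): float(piv[key].mean())
        for key in piv.columns
    }


def _f_result(effect, ss_eff, ss_err, df1, df2, cells,
              scale: float = 0.0) -> AnovaResult:
    # sums of squares below numerical noise (relative to the table's total
    # variation) are true zeros, not evidence
    tol = 1e-12 * max(scale, 1e-6)
    ss_err = max(ss_err, 0.0)
    if ss_eff <= tol:
        ss_eff = 0.0
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2 if df2 > 0 else np.nan
    if ms_err == 0 or not np.isfinite(ms_err):
        f = 0.0 if ss_eff == 0.0 else np.inf
    elif ss_err <= tol and ss_eff > 0:
        f = np.inf
    else:
        f = ms_eff / ms_err
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return AnovaResult(
        effect=str(effect),
        F=float(max(f, 0.0)) if np.isfinite(f) else float("inf"),
        df=(df1, df2),
        p=p,
        ss_effect=float(ss_eff),
        ss_error=float(ss_err),
        cell_means=cells,
    )


def band_power_anova(
    table: pd.DataFrame,
    band: str,
    unit: str = "cell-mean",
    boxcox: bool = True,
) -> list[AnovaResult]:
    """Condition x Location ANOVA of one band's power table.

    ``unit="cell-mean"`` aggregates to one value per subject, condition
    and region. ``unit="per-frequency"`` treats each band frequency as a
    within-subject replicate by using (subject, frequency) as the blocking
    unit, which inflates the error degrees of freedom accordingly.
    """
    sub = table[table["band"] == band].copy()
    if sub.empty:
        raise ValueError(f"band {band!r} not present in table")
    lam = None
    if boxcox:
        values, lam, _ = boxcox_normalize(sub["power"].to_numpy())
        sub["power"] = values
    if unit == "cell-mean":
        results = rm_anova(sub, dv="power",
                           within=("condition", "region"), subject="subject")
    elif unit == "per-frequency":
        if "frequency" not in sub.columns:
            raise ValueError("per-frequency unit needs a per-frequency table")
        sub["unit"] = (
            sub["subject"].astype(str) + "@" + sub["frequency"].astype(str)
        )
        results = rm_anova(sub, dv="power",
                           within=("condition", "region"), subject="unit")
    else:
        raise ValueError(f"unknown unit {unit!r}")
    for r in results:
        r.boxcox_lambda = lam
    return results
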