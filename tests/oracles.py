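"""Deliberately naive reference implementations used as test oracles.

Each function evaluates its defining formula directly (double loops,
per-window recomputation, explicit generalized eigenproblems) without any
of the FFT/cumulative-sum acceleration used by the package, so agreement
is evidence the fast paths implement the same mathematics.
"""

import numpy as np
from scipy import linalg


def stransform_direct(x, fs, freqs):
    """S-transform by direct double summation over time and samples."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.empty((len(freqs), n), dtype=complex)
    m = np.arange(n)
    for i, f_hz in enumerate(freqs):
        fc = f_hz / fs
        win_row = fc / np.sqrt(2 * np.pi)
        phase = np.exp(-2j * np.pi * fc * m)
        for t in range(n):
            gauss = np.exp(-0.5 * ((t - m) * fc) ** 2)
            out[i, t] = np.sum(x * win_row * gauss * phase)
    return out


def bartlett_psd_direct(x, fs, seg_len, window):
    """Averaged windowed periodograms by explicit DFT summation."""
    x = np.asarray(x, dtype=float)
    k_segs = x.size // seg_len
    n = seg_len
    n_freqs = n // 2 + 1
    power = np.zeros(n_freqs)
    t = np.arange(n)
    for k in range(k_segs):
        seg = x[k * n : (k + 1) * n] * window
        for j in range(n_freqs):
            w = 2.0 * np.pi * j / n
            coef = np.sum(seg * np.exp(-1j * w * t))
            power[j] += np.abs(coef) ** 2 / n
    freqs = np.arange(n_freqs) * fs / n
    return freqs, power / k_segs


def plv_naive(theta, window_length):
    """Sliding-window PLV recomputed independently per window position."""
    theta = np.atleast_2d(theta)
    n = theta.shape[-1]
    n_windows = n - window_length + 1
    out = np.empty(theta.shape[:-1] + (n_windows,))
    for idx in np.ndindex(theta.shape[:-1]):
        for w in range(n_windows):
            seg = theta[idx][w : w + window_length]
            out[idx][w] = np.abs(np.mean(np.exp(1j * seg)))
    return out


def rm_anova_hand(y):
    """Two-factor within-subject ANOVA by explicit marginal-mean loops.

    ``y`` has shape (subjects, a, b); returns dict of (F, df1, df2).
    """
    y = np.asarray(y, dtype=float)
    ns, a, b = y.shape
    grand = y.mean()

    def mean_over(**fix):
        total, count = 0.0, 0
        for s in range(ns):
            for i in range(a):
                for j in range(b):
                    if fix.get("s", s) == s and fix.get("i", i) == i \
                            and fix.get("j", j) == j:
                        total += y[s, i, j]
                        count += 1
        return total / count

    ss_a = sum(ns * b * (mean_over(i=i) - grand) ** 2 for i in range(a))
    ss_b = sum(ns * a * (mean_over(j=j) - grand) ** 2 for j in range(b))
    ss_s = sum(a * b * (mean_over(s=s) - grand) ** 2 for s in range(ns))
    ss_ab = sum(
        ns * (mean_over(i=i, j=j) - mean_over(i=i) - mean_over(j=j) + grand) ** 2
        for i in range(a) for j in range(b)
    )
    ss_as = sum(
        b * (mean_over(s=s, i=i) - mean_over(s=s) - mean_over(i=i) + grand) ** 2
        for s in range(ns) for i in range(a)
    )
    ss_bs = sum(
        a * (mean_over(s=s, j=j) - mean_over(s=s) - mean_over(j=j) + grand) ** 2
        for s in range(ns) for j in range(b)
    )
    ss_tot = ((y - grand) ** 2).sum()
    ss_abs = ss_tot - ss_a - ss_b - ss_s - ss_ab - ss_as - ss_bs

    def f(ss_eff, ss_err, df1, df2):
        return (ss_eff / df1) / (ss_err / df2), df1, df2

    return {
        "A": f(ss_a, ss_as, a - 1, (a - 1) * (ns - 1)),
        "B": f(ss_b, ss_bs, b - 1, (b - 1) * (ns - 1)),
        "AB": f(ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (ns - 1)),
    }


def kcca_naive(x, y, kappa, width_x, width_y):
    """First regularized kernel canonical correlation via the explicit
    block generalized eigenproblem."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    n = x.shape[0]

    def gram(z, width):
        sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(-1)
        k = np.exp(-sq / (2 * width * width))
        h = np.eye(n) - 1.0 / n
        return h @ k @ h

    kx, ky = gram(x, width_x), gram(y, width_y)
    zero = np.zeros((n, n))
    a_mat = np.block([[zero, kx @ ky / n], [ky @ kx / n, zero]])
    dx = kx @ kx / n + (kappa + 1e-10) * np.eye(n)
    dy = ky @ ky / n + (kappa + 1e-10) * np.eye(n)
    b_mat = np.block([[dx, zero], [zero, dy]])
    ev = linalg.eig(a_mat, b_mat, right=False)
    return float(np.clip(np.max(ev.real), 0.0, 1.0))
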