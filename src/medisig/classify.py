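"""S-transform features, KCCA downsampling and RBF-SVM classification.

Feature vectors are per-time-sample concatenations of S-transform
amplitudes over channels: z_n = [z_1n; ...; z_Cn] with
z_cn = (|S_c(f_1, n]|, ..., |S_c(f_F, n]|). Consecutive vectors are
strongly dependent, so the sequence is thinned by the factor L at which
the kernel canonical correlation between {z_n} and {z_{n-l}} reaches its
first local minimum in the lag l:

    I_KCCA = sup_{g_x, g_y}  cov(g_x(x), g_y(y)) /
             sqrt((var g_x(x) + kappa ||g_x||^2)(var g_y(y) + kappa ||g_y||^2))

estimated as the largest regularized kernel canonical correlation with
Gaussian kernels. The thinned vectors are min-max normalized per group
and classified with an RBF-kernel SVM under block-wise 10-fold
cross-validation; hyperparameters (kernel width sigma, penalty c) are
selected on validation data held out of each training split, and the
cross-validated accuracy is the reported figure of merit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances, rbf_kernel
from sklearn.svm import SVC

from .stockwell import TimeFrequencyMap


@dataclass
class FeatureSet:
    """Labelled feature vectors plus their provenance.

    ``block`` identifies the contiguous recording block each sample came
    from; cross-validation folds never split a block.
    """

    X: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray | None = None
    block: np.ndarray | None = None
    frequency_grids: tuple = ()
    channels: tuple = ()
    downsampling_factor: int = 1
    normalization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        for name in ("labels", "block"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != self.X.shape[0]:
                    raise ValueError(f"{name} length must match X")
                setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take(self, idx) -> "FeatureSet":
        return replace(
            self,
            X=self.X[idx],
            labels=None if self.labels is None else self.labels[idx],
            block=None if self.block is None else self.block[idx],
        )


def extract_features(
    tf_maps: list[TimeFrequencyMap],
    labels=None,
    block=None,
) -> FeatureSet:
    """Stack per-channel S-transform amplitude spectra into z_n vectors."""
    if not tf_maps:
        raise ValueError("no time-frequency maps given")
    n = tf_maps[0].coefficients.shape[1]
    grid = tf_maps[0].frequencies
    for m in tf_maps[1:]:
        if m.coefficients.shape[1] != n:
            raise ValueError("channels disagree on the time grid")
        if not np.array_equal(m.frequencies, grid):
            raise ValueError("channels disagree on the frequency grid")
    X = np.concatenate([m.amplitude for m in tf_maps], axis=0).T
    return FeatureSet(
        X=X,
        labels=labels,
        block=block,
        frequency_grids=(tuple(grid),) * len(tf_maps),
        channels=tuple(m.channel for m in tf_maps),
    )


@dataclass
class KccaIndex:
    """First regularized kernel canonical correlation."""

    value: float
    kappa: float
    kernel_width: tuple[float, float]
    lag: int | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("index must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def _median_width(x: np.ndarray, rng: np.random.Generator) -> float:
    sub = x if len(x) <= 300 else x[rng.choice(len(x), 300, replace=False)]
    d = euclidean_distances(sub)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    return med if med > 0 else 1.0


def kcca_dependency(
    x: np.ndarray,
    y: np.ndarray,
    kappa: float = 0.02,
    kernel_width: float | None = None,
    max_n: int = 500,
    seed: int = 0,
) -> KccaIndex:
    """Kernel-CCA dependency index between paired samples.

    Solves the regularized generalized eigenproblem on centred Gaussian
    Gram matrices; the returned value is the largest canonical
    correlation, clipped to [0, 1]. Gram matrices are subsampled to at
    most ``max_n`` paired points.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    if y.shape[0] == 1:
        y = y.T
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must be paired")
    n_total = x.shape[0]
    if n_total < 20:
        raise ValueError("need at least 20 paired samples")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = np.random.default_rng(seed)
    if n_total > max_n:
        idx = np.sort(rng.choice(n_total, max_n, replace=False))
        x, y = x[idx], y[idx]
    n = x.shape[0]

    if x.std(axis=0).max() == 0 or y.std(axis=0).max() == 0:
        warnings.warn("degenerate (constant) input; index = 0", stacklevel=2)
        return KccaIndex(0.0, kappa, (np.nan, np.nan))

    wx = kernel_width if kernel_width is not None else _median_width(x, rng)
    wy = kernel_width if kernel_width is not None else _median_width(y, rng)
    Kx = _centered_gram(rbf_kernel(x, gamma=1.0 / (2.0 * wx * wx)))
    Ky = _centered_gram(rbf_kernel(y, gamma=1.0 / (2.0 * wy * wy)))

    # coefficient-ridge regularization: var(g) + kappa ||alpha||^2
    eps = 1e-10
    Dx = Kx @ Kx / n + (kappa + eps) * np.eye(n)
    Dy = Ky @ Ky / n + (kappa + eps) * np.eye(n)
    Cxy = Kx @ Ky / n
    rho2 = _largest_eig_product(Dx, Dy, Cxy, rng)
    value = float(np.sqrt(np.clip(rho2, 0.0, 1.0)))
    return KccaIndex(value, kappa, (wx, wy))


def _centered_gram(K: np.ndarray) -> np.ndarray:
    """Double-center a Gram matrix (equivalent to H K H) in O(n^2)."""
    row = K.mean(axis=0, keepdims=True)
    col = K.mean(axis=1, keepdims=True)
    return K - row - col + K.mean()


def _largest_eig_product(Dx, Dy, Cxy, rng, max_iter=300, tol=1e-11):
    """Largest eigenvalue of Dx^-1 Cxy Dy^-1 Cxy' by power iteration.

    The operator is similar to a symmetric positive semidefinite matrix,
    so its spectrum is real and non-negative and power iteration applies.
    The two regularized inverses are applied once as dense solves, after
    which each iteration is a single matrix-vector product.
    """
    from scipy.linalg import cho_factor, cho_solve

    cx = cho_factor(Dx, check_finite=False)
    cy = cho_factor(Dy, check_finite=False)
    A = cho_solve(cx, Cxy, check_finite=False)
    B = cho_solve(cy, Cxy.T, check_finite=False)
    M = A @ B
    v = rng.standard_normal(M.shape[0])
    v /= np.linalg.norm(v)
    lam_prev = 0.0
    for _ in range(max_iter):
        w = M @ v
        lam = float(v @ w)
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0
        v = w / norm
        if abs(lam - lam_prev) <= tol * max(abs(lam), 1e-12):
            break
        lam_prev = lam
    return max(lam, 0.0)


def kcca_lag_curve(
    features: FeatureSet,
    max_lag: int,
    kappa: float = 0.02,
    max_n: int = 500,
    seed: int = 0,
    include_zero: bool = True,
) -> dict[int, float]:
    """I_KCCA(l) between {z_n} and {z_{n-l}} for l = 0 .. max_lag + 1.

    One common anchor subsample and one common kernel width are used for
    every lag, so the curve's lag-to-lag variation reflects dependency,
    not estimator resampling noise.
    """
    if max_lag < 2:
        raise ValueError("max_lag must be >= 2")
    X = features.X
    n = X.shape[0]
    if n - (max_lag + 1) < 20:
        raise ValueError(f"not enough samples at lag {max_lag + 1}")
    rng = np.random.default_rng(seed)
    anchors = np.arange(max_lag + 1, n)
    if anchors.size > max_n:
        anchors = np.sort(rng.choice(anchors, max_n, replace=False))
    width = _median_width(X[anchors], rng)
    curve: dict[int, float] = {}
    lags = ([0] if include_zero else []) + list(range(1, max_lag + 2))
    for lag in lags:
        idx = kcca_dependency(X[anchors], X[anchors - lag], kappa=kappa,
                              kernel_width=width, max_n=anchors.size,
                              seed=seed)
        curve[lag] = idx.value
    return curve


def select_downsampling_factor(
    features: FeatureSet,
    max_lag: int = 10,
    kappa: float = 0.02,
    max_n: int = 500,
    seed: int = 0,
    tol: float = 0.4,
) -> tuple[int, dict[int, float]]:
    """Smallest positive first local minimizer of I_KCCA(l).

    Returns ``(L, curve)`` where L satisfies I(L-1) > I(L) <= I(L+1).
    The upturn comparison carries a slack of ``tol / sqrt(n_anchors)``,
    the scale of the index's finite-sample jitter, so noise on a flat
    curve does not mask or fabricate a minimum. When no lag up to
    ``max_lag`` qualifies, ``max_lag`` is returned with a warning.
    """
    curve = kcca_lag_curve(features, max_lag, kappa=kappa, max_n=max_n,
                           seed=seed)
    n_anchors = min(max_n, features.X.shape[0] - (max_lag + 1))
    slack = tol / np.sqrt(n_anchors)
    for lag in range(1, max_lag + 1):
        if curve[lag - 1] > curve[lag] <= curve[lag + 1] + slack:
            return lag, curve
    warnings.warn(
        f"no local minimum of I_KCCA within {max_lag} lags; using {max_lag}",
        stacklevel=2,
    )
    return max_lag, curve


def downsample_features(features: FeatureSet, factor: int) -> FeatureSet:
    """Retain z_1, z_{1+L}, ..., floor(N/L) vectors."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    keep = features.X.shape[0] // factor
    idx = np.arange(keep) * factor
    out = features.take(idx)
    out.downsampling_factor = factor
    return out


def minmax_normalize(
    features: FeatureSet,
    split_assignment: np.ndarray | None = None,
    mode: str = "per-group",
) -> FeatureSet:
    """Min-max normalize features to [0, 1].

    ``mode="per-group"`` rescales each split group (train/test/...)
    independently by its own per-feature extremes;
    ``mode="train-bounds"`` computes bounds on the group named ``train``
    and applies them everywhere (the leakage-safe alternative).
    Zero-range features map to 0 with a warning.
    """
    X = features.X.copy()
    if split_assignment is None:
        split_assignment = np.zeros(X.shape[0], dtype=int)
    split_assignment = np.asarray(split_assignment)
    bounds = {}
    if mode == "per-group":
        for g in np.unique(split_assignment):
            sel = split_assignment == g
            X[sel], b = _minmax_apply(X[sel])
            bounds[str(g)] = b
    elif mode == "train-bounds":
        train = split_assignment == "train"
        if not train.any():
            raise ValueError('train-bounds mode needs a "train" group')
        lo = X[train].min(axis=0)
        hi = X[train].max(axis=0)
        X, b = _minmax_apply(X, lo, hi)
        bounds["train"] = b
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = replace(features, X=X)
    out.normalization = {"mode": mode, "bounds": bounds}
    return out


def _minmax_apply(X, lo=None, hi=None):
    lo = X.min(axis=0) if lo is None else lo
    hi = X.max(axis=0) if hi is None else hi
    span = hi - lo
    flat = span <= 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-range feature(s) mapped to 0",
            stacklevel=3,
        )
    safe = np.where(flat, 1.0, span)
    Y = (X - lo) / safe
    Y[:, flat] = 0.0
    return np.clip(Y, None, None), (lo, hi)


@dataclass
class ClassifierReport:
    """Cross-validated RBF-SVM performance for one feature set."""

    accuracy: float
    sigma: float
    c: float
    fold_accuracies: np.ndarray
    fold_assignment: np.ndarray
    decision_values: np.ndarray
    classes: tuple[str, str]
    modality: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def _build_folds(features: FeatureSet, folds: int, fold_mode: str,
                 rng: np.random.Generator) -> np.ndarray:
    n = features.n_samples
    if folds > n:
        raise ValueError(f"{folds} folds for {n} samples")
    if fold_mode == "random":
        order = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        assignment[order] = np.arange(n) % folds
        return assignment
    if fold_mode != "blocked":
        raise ValueError(f"unknown fold_mode {fold_mode!r}")
    if features.block is not None:
        blocks = features.block
        uniq = list(dict.fromkeys(blocks.tolist()))
        # interleave blocks by label so every training set keeps both
        if features.labels is not None:
            by_label: dict = {}
            for b in uniq:
                lab = features.labels[blocks == b][0]
                by_label.setdefault(lab, []).append(b)
            interleaved = []
            lists = list(by_label.values())
            for i in range(max(len(v) for v in lists)):
                for v in lists:
                    if i < len(v):
                        interleaved.append(v[i])
            uniq = interleaved
        # contiguous chunks of the label-interleaved block list, so each
        # fold holds (near-)equally many blocks of every class
        fold_of_block = {b: i * folds // len(uniq) for i, b in enumerate(uniq)}
        return np.array([fold_of_block[b] for b in blocks])
    # contiguous chunks
    return np.minimum(np.arange(n) * folds // n, folds - 1)


def train_eval_svm(
    features: FeatureSet,
    folds: int = 10,
    sigma_factors: np.ndarray | None = None,
    c_grid: np.ndarray | None = None,
    fold_mode: str = "blocked",
    normalization: str = "train-bounds",
    selection: str = "validation",
    seed: int = 0,
    modality: str = "",
) -> ClassifierReport:
    """Cross-validated RBF-SVM with (sigma, c) grid selection.

    With ``selection="validation"`` (default) each fold is split into
    train / validation / test groups: the grid is scored on the
    validation group only, the winning pair is refit on train+validation
    and evaluated once on the held-out test fold, so the reported
    accuracy is untouched by hyperparameter selection.
    ``selection="cv-max"`` instead reports the grid pair maximizing the
    pooled cross-validated accuracy (optimistic under selection noise).
    Per-sample decision-function values are collected from the folds in
    which each sample was held out (the candidate "meditation depth"
    score).
    """
    if features.labels is None:
        raise ValueError("labelled features required")
    classes = tuple(sorted(set(features.labels.tolist())))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if sigma_factors is None:
        sigma_factors = 2.0 ** np.arange(-4, 5)
    if c_grid is None:
        c_grid = 2.0 ** np.arange(-2, 7)

    rng = np.random.default_rng(seed)
    assignment = _build_folds(features, folds, fold_mode, rng)
    for k in range(folds):
        train_labels = set(features.labels[assignment != k].tolist())
        if len(train_labels) < 2:
            raise ValueError(f"training folds for fold {k} miss a class")

    med = _median_width(features.X, rng)
    sigmas = np.asarray(sigma_factors, dtype=float) * med
    c_grid = np.asarray(c_grid, dtype=float)
    y = (features.labels == classes[1]).astype(int)
    grid = [(s, c) for s in sigmas for c in c_grid]

    def _norm_X(groups: np.ndarray) -> np.ndarray:
        mode = "per-group" if normalization == "per-group" else "train-bounds"
        return minmax_normalize(features, groups, mode=mode).X

    decisions = np.zeros(features.n_samples)
    fold_accs, chosen = [], []
    if selection == "validation":
        if folds < 3:
            raise ValueError("validation selection needs >= 3 folds")
        for k in range(folds):
            test = assignment == k
            val = assignment == (k + 1) % folds
            train = ~(test | val)
            groups = np.where(test, "test", np.where(val, "validation", "train"))
            X = _norm_X(groups)
            best = None
            for sigma, c in grid:
                clf = SVC(C=c, gamma=1.0 / (2 * sigma * sigma), kernel="rbf")
                clf.fit(X[train], y[train])
                acc = float(np.mean(clf.predict(X[val]) == y[val]))
                if best is None or acc > best[0]:
                    best = (acc, sigma, c)
            _, sigma, c = best
            # refit on train+validation with the selected pair
            groups = np.where(test, "test", "train")
            X = _norm_X(groups)
            clf = SVC(C=c, gamma=1.0 / (2 * sigma * sigma), kernel="rbf")
            clf.fit(X[~test], y[~test])
            fold_accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
            decisions[test] = clf.decision_function(X[test])
            chosen.append((sigma, c))
        mean_acc = float(np.mean(fold_accs))
        counts = np.bincount([grid.index(p) for p in chosen])
        sigma, c = grid[int(np.argmax(counts))]  # modal selection
    elif selection == "cv-max":
        fold_data = []
        for k in range(folds):
            test = assignment == k
            X = _norm_X(np.where(test, "test", "train"))
            fold_data.append((X, test))
        best = None
        for sigma, c in grid:
            accs = []
            dec = np.zeros(features.n_samples)
            for X, test in fold_data:
                clf = SVC(C=c, gamma=1.0 / (2 * sigma * sigma), kernel="rbf")
                clf.fit(X[~test], y[~test])
                accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
                dec[test] = clf.decision_function(X[test])
            mean = float(np.mean(accs))
            if best is None or mean > best[0]:
                best = (mean, sigma, c, accs, dec.copy())
        mean_acc, sigma, c, fold_accs, decisions = best
    else:
        raise ValueError(f"unknown selection {selection!r}")

    return ClassifierReport(
        accuracy=mean_acc,
        sigma=float(sigma),
        c=float(c),
        fold_accuracies=np.asarray(fold_accs),
        fold_assignment=assignment,
        decision_values=decisions,
        classes=classes,
        modality=modality,
    )


def build_joint_features(
    eeg_features: FeatureSet,
    resp_features: FeatureSet,
    tol: float = 0.02,
) -> FeatureSet:
    """Concatenate EEG and respiration vectors sample by sample.

    Inputs must be time-aligned (equal sample counts up to ``tol``
    relative truncation); the joint sequence is meant to be re-subjected
    to KCCA downsampling afterwards.
    """
    n1, n2 = eeg_features.n_samples, resp_features.n_samples
    if n1 == 0 or n2 == 0:
        raise ValueError("empty feature set")
    n = min(n1, n2)
    if max(n1, n2) - n > tol * max(n1, n2):
        raise ValueError(f"unalignable sample counts {n1} vs {n2}")
    a, b = eeg_features.take(np.arange(n)), resp_features.take(np.arange(n))
    if a.labels is not None and b.labels is not None:
        if not np.array_equal(a.labels, b.labels):
            raise ValueError("label sequences disagree")
    return FeatureSet(
        X=np.concatenate([a.X, b.X], axis=1),
        labels=a.labels if a.labels is not None else b.labels,
        block=a.block if a.block is not None else b.block,
        frequency_grids=a.frequency_grids + b.frequency_grids,
        channels=a.channels + b.channels,
    )
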