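"""Single-trial classification of active vs. rest trials.

Features are log bandpower values in four bands (mu 7-13, low-beta 13-19,
mid-beta 19-25, high-beta 25-30 Hz) on the two bipolar channels, extracted
with the same end-labelled 1 s / 50 ms sliding-window convention as the
average spectral analysis (100 time-points per trial).  At each time-point a
Gaussian naive Bayes classifier is evaluated with stratified 10-fold
cross-validation; the accuracy time-course is smoothed with a 500 ms sliding
mean, and significance is assessed with a max-statistic familywise
randomization test (label shuffles, recording the best smoothed accuracy per
permutation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import Epochs
from .spectral import sliding_window_power

__all__ = [
    "BANDS",
    "FeatureTensor",
    "GaussianNBModel",
    "AccuracyTimecourse",
    "FamilywisePermResult",
    "extract_bandpower",
    "nb_fit",
    "nb_predict",
    "crossval_accuracy",
    "familywise_permutation_test",
    "band_restricted_classification",
    "smooth_timecourse",
]

logger = logging.getLogger(__name__)

#: Analysis bands, Hz.  Bins are assigned half-open: lo <= f < hi.
BANDS: dict[str, tuple[float, float]] = {
    "mu": (7.0, 13.0),
    "low-beta": (13.0, 19.0),
    "mid-beta": (19.0, 25.0),
    "high-beta": (25.0, 30.0),
}

_VAR_FLOOR_EPS = 1e-6


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureTensor:
    """Per-trial log bandpower features, (n_trials, n_times, n_features)."""

    values: np.ndarray
    times: np.ndarray  # offset-relative seconds, window end-labelled
    feature_names: list[str]  # e.g. "C3':mu"
    conditions: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def select_bands(self, bands: list[str]) -> "FeatureTensor":
        """Restrict to the listed bands (keeping all channels)."""
        if not bands:
            raise ValueError("band subset must be non-empty")
        idx = [
            i for i, name in enumerate(self.feature_names)
            if name.split(":", 1)[1] in bands
        ]
        if not idx:
            raise ValueError(f"no features match bands {bands}")
        return FeatureTensor(
            self.values[:, :, idx], self.times,
            [self.feature_names[i] for i in idx], self.conditions,
        )

    def select_trials(self, idx) -> "FeatureTensor":
        idx = np.asarray(idx)
        return FeatureTensor(
            self.values[idx], self.times, list(self.feature_names),
            self.conditions[idx],
        )


def extract_bandpower(
    epochs: Epochs,
    bands: dict[str, tuple[float, float]] | None = None,
    window_sec: float = 1.0,
    step_sec: float = 0.05,
    n_windows: int = 100,
) -> FeatureTensor:
    """Sliding-window STFT log bandpower features from bipolar epochs.

    Power is summed over the FFT bins falling in each band (half-open
    ``lo <= f < hi``) and natural-log transformed.  With the defaults this
    yields 8 features (2 channels x 4 bands) at 100 time-points per trial.
    """
    if epochs.montage != "bipolar":
        raise ValueError("bandpower features are defined on the bipolar montage (C3'/C4')")
    bands = bands or BANDS
    power, freqs = sliding_window_power(
        epochs.data, epochs.sfreq, window_sec, step_sec, n_windows=n_windows
    )  # (trials, channels, freqs, times)
    win_len = int(round(window_sec * epochs.sfreq))
    step = int(round(step_sec * epochs.sfreq))
    times = epochs.tmin + (np.arange(power.shape[-1]) * step + win_len) / epochs.sfreq

    feats, names = [], []
    for ci, ch in enumerate(epochs.ch_names):
        for band_name, (lo, hi) in bands.items():
            sel = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
            if not sel.any():
                raise ValueError(f"band {band_name} contains no FFT bins")
            bp = power[:, ci, sel, :].sum(axis=1)  # (trials, times)
            feats.append(np.log(np.maximum(bp, np.finfo(float).tiny)))
            names.append(f"{ch}:{band_name}")
    values = np.stack(feats, axis=-1)  # (trials, times, features)
    return FeatureTensor(values, times, names, epochs.conditions.copy())


# ---------------------------------------------------------------------------
# Gaussian naive Bayes
# ---------------------------------------------------------------------------

@dataclass
class GaussianNBModel:
    """Per-class, per-feature normal densities with class priors."""

    classes: np.ndarray  # (2,)
    means: np.ndarray  # (2, n_features)
    sds: np.ndarray  # (2, n_features)
    priors: np.ndarray  # (2,)


def nb_fit(features: np.ndarray, labels: np.ndarray) -> GaussianNBModel:
    """Fit per-class feature means and SDs; priors from class frequencies.

    SDs are floored at ``1e-6 * pooled SD`` (per feature) so constant
    features cannot produce degenerate densities.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"exactly 2 classes required, got {len(classes)}")
    means, sds, priors = [], [], []
    pooled_sd = features.std(axis=0, ddof=1)
    floor = np.maximum(_VAR_FLOOR_EPS * pooled_sd, np.finfo(float).tiny)
    for c in classes:
        x = features[labels == c]
        if len(x) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 trials")
        means.append(x.mean(axis=0))
        sds.append(np.maximum(x.std(axis=0, ddof=1), floor))
        priors.append(len(x) / len(features))
    return GaussianNBModel(
        classes=classes,
        means=np.asarray(means),
        sds=np.asarray(sds),
        priors=np.asarray(priors),
    )


def _log_joint(model: GaussianNBModel, features: np.ndarray) -> np.ndarray:
    """log prior + sum of per-feature normal log densities, (n, 2)."""
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    z = (x[:, None, :] - model.means[None]) / model.sds[None]
    ll = -0.5 * (z**2 + np.log(2 * np.pi)) - np.log(model.sds[None])
    return ll.sum(axis=-1) + np.log(model.priors)[None]


def nb_predict(
    model: GaussianNBModel, features: np.ndarray, tie_break: str = "rest"
) -> tuple[np.ndarray, np.ndarray]:
    """Predict classes and posteriors; exact ties go to ``tie_break``.

    Accepts a single feature vector or an ``(n, n_features)`` batch; returns
    ``(labels, posteriors)`` with posteriors of shape ``(n, 2)`` in the order
    of ``model.classes``.
    """
    single = np.asarray(features).ndim == 1
    lj = _log_joint(model, features)
    shifted = lj - lj.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)

    winner = np.argmax(lj, axis=1)
    tie = lj[:, 0] == lj[:, 1]
    if tie.any() and tie_break in model.classes:
        winner[tie] = int(np.flatnonzero(model.classes == tie_break)[0])
    labels = model.classes[winner]
    if single:
        return labels[0], post[0]
    return labels, post


# ---------------------------------------------------------------------------
# Cross-validated accuracy time-courses
# ---------------------------------------------------------------------------

@dataclass
class AccuracyTimecourse:
    raw: np.ndarray  # (n_times,) mean accuracy over folds
    smoothed: np.ndarray  # (n_times,) 500 ms sliding mean of raw
    fold_accuracies: np.ndarray  # (k, n_times)
    times: np.ndarray
    n_per_class: dict[str, int] = field(default_factory=dict)

    @property
    def max_smoothed(self) -> tuple[float, float]:
        """(accuracy, time) of the smoothed maximum."""
        i = int(np.argmax(self.smoothed))
        return float(self.smoothed[i]), float(self.times[i])

    @property
    def max_raw(self) -> tuple[float, float]:
        i = int(np.argmax(self.raw))
        return float(self.raw[i]), float(self.times[i])

    def to_dict(self) -> dict:
        return {
            "times_s": self.times.tolist(),
            "raw": self.raw.tolist(),
            "smoothed": self.smoothed.tolist(),
            "n_per_class": self.n_per_class,
        }


def smooth_timecourse(x: np.ndarray, width: int = 11) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    ``width`` = 11 points = 500 ms at the 50 ms feature step.
    """
    kernel = np.ones(width)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator, max_redraw: int = 100
) -> list[np.ndarray]:
    """Seeded stratified k-fold partition; every fold sees both classes."""
    classes = np.unique(labels)
    for attempt in range(max_redraw):
        folds: list[list[int]] = [[] for _ in range(k)]
        for c in classes:
            idx = rng.permutation(np.flatnonzero(labels == c))
            # rotate the starting fold so remainders spread across folds
            start = int(rng.integers(k))
            for j, trial in enumerate(idx):
                folds[(start + j) % k].append(int(trial))
        if all(len(np.unique(labels[f])) == len(classes) and len(f) > 0 for f in folds):
            if attempt:
                logger.info("re-drew CV folds %d time(s)", attempt)
            return [np.array(sorted(f)) for f in folds]
    raise RuntimeError("could not build stratified folds with both classes per fold")


def _cv_raw_accuracy(
    values: np.ndarray, y: np.ndarray, folds: list[np.ndarray], tie_break: str = "rest"
) -> np.ndarray:
    """Vectorised CV: per-fold Gaussian NB at every time-point at once.

    ``values`` is (n_trials, n_times, n_features); returns (k, n_times) fold
    accuracies.
    """
    n, n_times, n_feat = values.shape
    classes = np.unique(y)
    class_masks = {c: y == c for c in classes}
    rest_like = int(np.flatnonzero(classes == tie_break)[0]) if tie_break in classes else None
    fold_acc = np.empty((len(folds), n_times))
    all_idx = np.arange(n)
    for fi, test in enumerate(folds):
        train_mask = np.ones(n, bool)
        train_mask[test] = False
        train = all_idx[train_mask]
        xtr = values[train]
        ytr = y[train]
        pooled_sd = xtr.std(axis=0, ddof=1)
        floor = np.maximum(_VAR_FLOOR_EPS * pooled_sd, np.finfo(float).tiny)
        lj = np.zeros((len(test), n_times, 2))
        for ki, c in enumerate(classes):
            xc = xtr[ytr == c]
            mu = xc.mean(axis=0)
            sd = np.maximum(xc.std(axis=0, ddof=1), floor)
            z = (values[test] - mu) / sd
            lj[:, :, ki] = (
                -0.5 * (z**2).sum(axis=-1)
                - np.log(sd).sum(axis=-1)
                + np.log(len(xc) / len(train))
            )
        pred = np.argmax(lj, axis=-1)
        if rest_like is not None:
            tie = lj[:, :, 0] == lj[:, :, 1]
            pred[tie] = rest_like
        truth = np.searchsorted(classes, y[test])[:, None]
        fold_acc[fi] = (pred == truth).mean(axis=0)
    return fold_acc


def crossval_accuracy(
    features: FeatureTensor,
    labels: np.ndarray | None = None,
    k: int = 10,
    seed: int = 0,
    smooth_width: int = 11,
) -> AccuracyTimecourse:
    """Stratified k-fold CV accuracy at every time-point, plus 500 ms smoothing.

    Folds are drawn once per call (seeded); each trial is tested exactly once.
    The raw accuracy at a time-point is the mean over folds of the fold
    accuracy; the smoothed course is its centred ``smooth_width``-point moving
    average with shrinking edge windows.
    """
    y = features.conditions if labels is None else np.asarray(labels)
    if features.n_trials < k:
        raise ValueError(f"need at least k={k} trials")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    fold_acc = _cv_raw_accuracy(features.values, y, folds)
    raw = fold_acc.mean(axis=0)
    classes, counts = np.unique(y.astype(str), return_counts=True)
    return AccuracyTimecourse(
        raw=raw,
        smoothed=smooth_timecourse(raw, smooth_width),
        fold_accuracies=fold_acc,
        times=features.times.copy(),
        n_per_class=dict(zip(classes.tolist(), counts.tolist())),
    )


# ---------------------------------------------------------------------------
# Familywise max-statistic randomization test
# ---------------------------------------------------------------------------

@dataclass
class FamilywisePermResult:
    observed: AccuracyTimecourse
    null_max: np.ndarray  # (n_perm,) max smoothed accuracy per shuffle
    p: np.ndarray  # (n_times,)
    alpha: float
    sig_mask: np.ndarray  # p < alpha

    @property
    def any_significant(self) -> bool:
        return bool(self.sig_mask.any())

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "p": self.p.tolist(),
            "sig_mask": self.sig_mask.astype(bool).tolist(),
            "null_max_quantiles": {
                q: float(np.quantile(self.null_max, float(q)))
                for q in ("0.5", "0.95", "0.975", "0.99")
            },
            "observed": self.observed.to_dict(),
        }


def familywise_permutation_test(
    features: FeatureTensor,
    labels: np.ndarray | None = None,
    k: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.025,
    seed: int = 0,
    smooth_width: int = 11,
) -> FamilywisePermResult:
    """Max-statistic randomization test of the smoothed accuracy time-course.

    Each permutation shuffles the class labels, re-runs the full stratified
    k-fold CV, and records the maximum smoothed accuracy across time-points;
    these maxima form the familywise null.  ``p(t) = (1 + #{null >=
    smoothed(t)}) / (1 + n_perm)``, one-tailed, significant where
    ``p < alpha``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable null tail", stacklevel=2)
    y = features.conditions if labels is None else np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    fold_acc = _cv_raw_accuracy(features.values, y, folds)
    raw = fold_acc.mean(axis=0)
    smoothed = smooth_timecourse(raw, smooth_width)

    null_max = np.empty(n_perm)
    for pi in range(n_perm):
        y_perm = rng.permutation(y)
        folds_p = _stratified_folds(y_perm, k, rng)
        raw_p = _cv_raw_accuracy(features.values, y_perm, folds_p).mean(axis=0)
        null_max[pi] = smooth_timecourse(raw_p, smooth_width).max()

    p = (1 + (null_max[None, :] >= smoothed[:, None]).sum(axis=1)) / (1 + n_perm)
    classes, counts = np.unique(y.astype(str), return_counts=True)
    observed = AccuracyTimecourse(
        raw=raw,
        smoothed=smoothed,
        fold_accuracies=fold_acc,
        times=features.times.copy(),
        n_per_class=dict(zip(classes.tolist(), counts.tolist())),
    )
    return FamilywisePermResult(
        observed=observed,
        null_max=null_max,
        p=p,
        alpha=alpha,
        sig_mask=p < alpha,
    )


def band_restricted_classification(
    features: FeatureTensor,
    bands_subset: list[str],
    labels: np.ndarray | None = None,
    k: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.025,
    seed: int = 0,
) -> tuple[AccuracyTimecourse, FamilywisePermResult]:
    """Run the identical classification pipeline on a subset of bands.

    With all four bands this reproduces the full analysis; with e.g.
    ``['high-beta']`` only 2 features (one per bipolar channel) remain.
    """
    sub = features.select_bands(list(bands_subset))
    result = familywise_permutation_test(
        sub, labels=labels, k=k, n_perm=n_perm, alpha=alpha, seed=seed
    )
    return result.observed, result
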