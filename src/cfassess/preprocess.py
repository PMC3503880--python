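"""Preprocessing: filtering, resampling, epoching, artifact rejection,
bipolar re-referencing and trial-count matching.

The default chain (``preprocess_recording``) is: anti-aliased resampling to
100 Hz, zero-phase least-squares FIR band-pass 1-40 Hz, segmentation into 6 s
epochs time-locked to instruction onset (relabelled to offset-relative time),
automated artifact rejection, and derivation of the two bipolar channels
C3' = FC3 - CP3 and C4' = FC4 - CP4.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import EPOCH_LENGTH, EPOCH_TMIN, Epochs, RawRecording

__all__ = [
    "bandpass_filter",
    "resample",
    "epoch",
    "reject_artifacts",
    "rereference_bipolar",
    "match_trial_counts",
    "preprocess_recording",
    "RejectionReport",
]

logger = logging.getLogger(__name__)

#: Bipolar derivations: output label -> (anode, cathode).
BIPOLAR_PAIRS = {"C3'": ("FC3", "CP3"), "C4'": ("FC4", "CP4")}


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _firls_taps(order: int) -> int:
    taps = order + 1
    return taps if taps % 2 == 1 else taps + 1  # type-I (odd-length) FIR


def _design_highpass(sfreq: float, lo: float) -> np.ndarray:
    order = 3 * int(sfreq // lo)
    taps = _firls_taps(order)
    nyq = sfreq / 2
    trans = min(lo * 0.35, lo * 0.9)
    return signal.firls(taps, [0, lo - trans, lo, nyq], [0, 0, 1, 1], fs=sfreq)


def _design_lowpass(sfreq: float, hi: float) -> np.ndarray:
    order = max(3 * int(sfreq // (hi * 0.25)), 15)
    taps = _firls_taps(order)
    nyq = sfreq / 2
    trans = min(hi * 0.15, (nyq - hi) * 0.9)
    return signal.firls(taps, [0, hi, hi + trans, nyq], [1, 1, 0, 0], fs=sfreq)


def bandpass_filter(raw: RawRecording, lo: float = 1.0, hi: float = 40.0) -> RawRecording:
    """Zero-phase band-pass: least-squares FIR high-pass at ``lo`` followed by
    low-pass at ``hi``, each applied forward-backward (filtfilt).

    Filter orders follow the 3-cycles-of-cutoff heuristic of common EEG
    toolboxes; the two-way application squares the magnitude response and
    cancels the phase.
    """
    if raw.sfreq <= 2 * hi:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    hp = _design_highpass(raw.sfreq, lo)
    lp = _design_lowpass(raw.sfreq, hi)
    min_len = 3 * max(len(hp), len(lp))
    if raw.n_samples <= min_len:
        raise ValueError(
            f"recording too short to filter: {raw.n_samples} samples, "
            f"need > {min_len}"
        )
    data = signal.filtfilt(hp, [1.0], raw.data, axis=-1)
    data = signal.filtfilt(lp, [1.0], data, axis=-1)
    return RawRecording(data, raw.sfreq, list(raw.ch_names), raw.events.copy())


def resample(raw: RawRecording, target: float = 100.0) -> RawRecording:
    """Anti-aliased rational-ratio resampling (25/64 for 256 -> 100 Hz).

    Event onsets are remapped by ``round(onset * target / sfreq)`` with ties
    rounded half away from zero.
    """
    if target >= raw.sfreq:
        raise ValueError("target rate must be below the current rate")
    frac = Fraction(target / raw.sfreq).limit_denominator(1000)
    data = signal.resample_poly(raw.data, frac.numerator, frac.denominator, axis=-1)
    ratio = target / raw.sfreq
    onsets = raw.events["onset_sample"].to_numpy()
    # round half away from zero for determinism across platforms
    remapped = np.floor(onsets * ratio + 0.5).astype(np.int64)
    events = raw.events.copy()
    events["onset_sample"] = remapped
    n = data.shape[1]
    keep = remapped < n
    if not keep.all():
        logger.warning("dropping %d events beyond resampled bounds", (~keep).sum())
        events = events[keep].reset_index(drop=True)
    return RawRecording(data, target, list(raw.ch_names), events)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch(raw: RawRecording, length: float = EPOCH_LENGTH, tmin: float = EPOCH_TMIN) -> Epochs:
    """Segment into ``length``-second epochs starting at each instruction onset.

    The time axis is relabelled to offset-relative seconds (onset at ``tmin``,
    half-open window).  Events with insufficient data to the recording end are
    dropped with a warning.
    """
    n_samp = int(round(length * raw.sfreq))
    onsets = raw.events["onset_sample"].to_numpy()
    conds = raw.events["condition"].to_numpy()
    ok = onsets + n_samp <= raw.n_samples
    if not ok.all():
        warnings.warn(
            f"dropping {(~ok).sum()} trial(s) too close to the recording end",
            stacklevel=2,
        )
    onsets, conds = onsets[ok], conds[ok]
    data = np.stack([raw.data[:, o: o + n_samp] for o in onsets]) if len(onsets) else \
        np.empty((0, raw.n_channels, n_samp))
    return Epochs(data, raw.sfreq, list(raw.ch_names), conds, tmin=tmin)


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionReport:
    """Audit trail of the automated artifact rejection."""

    kept: np.ndarray
    rejected: np.ndarray
    kept_per_condition: dict[str, int]
    rejected_per_condition: dict[str, int]
    params: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return len(self.kept) + len(self.rejected)

    def to_dict(self) -> dict:
        return {
            "kept": [int(i) for i in self.kept],
            "rejected": [int(i) for i in self.rejected],
            "kept_per_condition": self.kept_per_condition,
            "rejected_per_condition": self.rejected_per_condition,
            "params": self.params,
        }


def reject_artifacts(
    epochs: Epochs,
    ptp_threshold: float = 150.0,
    var_zmax: float = 5.0,
) -> tuple[Epochs, RejectionReport]:
    """Remove trials with excessive amplitude or outlying variance.

    A trial is rejected if, on any channel, its peak-to-peak amplitude exceeds
    ``ptp_threshold`` µV, or its variance z-score (per channel, computed
    robustly across trials via median/MAD) exceeds ``var_zmax``.  This is an
    automated stand-in for visual inspection; the criterion is recorded in the
    report for auditability.
    """
    if ptp_threshold <= 0 or var_zmax <= 0:
        raise ValueError("rejection thresholds must be positive")
    data = epochs.data
    ptp = data.max(axis=2) - data.min(axis=2)  # (trials, channels)
    bad_ptp = (ptp > ptp_threshold).any(axis=1)

    var = data.var(axis=2)  # (trials, channels)
    med = np.median(var, axis=0)
    mad = np.median(np.abs(var - med), axis=0)
    scale = np.where(mad > 0, 1.4826 * mad, 1.0)
    z = (var - med) / scale
    bad_var = (z > var_zmax).any(axis=1)

    bad = bad_ptp | bad_var
    if bad.all() and epochs.n_trials > 0:
        raise RuntimeError("artifact rejection removed every trial")
    kept = np.flatnonzero(~bad)
    rejected = np.flatnonzero(bad)

    def per_cond(idx):
        labels, counts = np.unique(epochs.conditions[idx].astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    report = RejectionReport(
        kept=kept,
        rejected=rejected,
        kept_per_condition=per_cond(kept),
        rejected_per_condition=per_cond(rejected),
        params={"ptp_threshold": ptp_threshold, "var_zmax": var_zmax},
    )
    for ti in rejected:
        logger.info("rejected trial %d (%s)", ti, epochs.conditions[ti])
    return epochs.select_trials(kept), report


# ---------------------------------------------------------------------------
# Re-referencing and trial matching
# ---------------------------------------------------------------------------

def rereference_bipolar(epochs: Epochs, pairs: dict | None = None) -> Epochs:
    """Derive the bipolar channels C3' = FC3 - CP3 and C4' = FC4 - CP4.

    Lookup is label-based, so channel order is irrelevant.  The derivation is
    reference-free: any signal common to all monopolar channels cancels.
    """
    pairs = pairs or BIPOLAR_PAIRS
    for label, (a, b) in pairs.items():
        for ch in (a, b):
            if ch not in epochs.ch_names:
                raise ValueError(f"missing electrode {ch!r} required for {label}")
    out = np.stack(
        [
            epochs.data[:, epochs.ch_names.index(a)] - epochs.data[:, epochs.ch_names.index(b)]
            for a, b in pairs.values()
        ],
        axis=1,
    )
    return Epochs(
        out, epochs.sfreq, list(pairs.keys()), epochs.conditions.copy(),
        tmin=epochs.tmin, montage="bipolar",
    )


def match_trial_counts(epochs: Epochs, target_counts: dict[str, int], seed: int = 0) -> Epochs:
    """Randomly subsample each condition (without replacement) to the target
    counts, preserving trial order.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cond, target in target_counts.items():
        idx = np.flatnonzero(epochs.conditions == cond)
        if len(idx) < target:
            raise ValueError(
                f"condition {cond!r}: need {target} trials, only {len(idx)} available "
                f"(deficit {target - len(idx)})"
            )
        keep.extend(rng.choice(idx, size=target, replace=False).tolist())
    keep = sorted(keep)
    return epochs.select_trials(keep)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def preprocess_recording(
    raw: RawRecording,
    target_sfreq: float = 100.0,
    band: tuple[float, float] = (1.0, 40.0),
    resample_first: bool = True,
    ptp_threshold: float = 150.0,
    var_zmax: float = 5.0,
    target_counts: dict[str, int] | None = None,
    seed: int = 0,
    reject: bool = True,
) -> tuple[Epochs, RejectionReport | None]:
    """Run the full preprocessing chain and return bipolar epochs.

    ``resample_first`` selects between resample-then-filter (default, the
    stated order; the resampler's own anti-alias filter guards aliasing) and
    filter-then-resample.
    """
    if resample_first:
        raw = resample(raw, target_sfreq)
        raw = bandpass_filter(raw, *band)
    else:
        raw = bandpass_filter(raw, *band)
        raw = resample(raw, target_sfreq)
    epochs = epoch(raw)
    epochs = rereference_bipolar(epochs)
    report = None
    if reject:
        epochs, report = reject_artifacts(epochs, ptp_threshold, var_zmax)
    if target_counts:
        epochs = match_trial_counts(epochs, target_counts, seed=seed)
    return epochs, report
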