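"""Synthetic sensorimotor EEG with controllable ERD/ERS ground truth.

The simulator produces the block-structured instruction task (blocks of 36
trials, 12 per instruction, at most three consecutive repeats, 2 s spoken
instruction followed by 4-7 s of silence) and a 9-channel 256 Hz recording
built from 1/f background noise, band-limited mu/beta oscillators and
event-locked multiplicative amplitude modulations (ERD/ERS) whose band,
latency, duration, laterality and depth are configurable.  Optional broadband
muscle-artifact bursts are injected and annotated so the automatic artifact
rejection stage can be validated against ground truth.

Instructions are represented purely as markers (onset sample + condition);
the audio itself plays no role in any analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import (
    CHANNELS_9,
    CONDITIONS,
    EPOCH_LENGTH,
    LEFT_CHANNELS,
    RIGHT_CHANNELS,
    RawRecording,
    events_frame,
)

__all__ = [
    "ScheduleEntry",
    "InstructionSchedule",
    "Oscillator",
    "NoiseSpec",
    "EffectSpec",
    "SimConfig",
    "SimulationResult",
    "generate_schedule",
    "simulate_recording",
]


# ---------------------------------------------------------------------------
# Instruction schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleEntry:
    condition: str
    onset_time: float  # seconds from schedule start
    instruction_duration: float = 2.0
    silence_duration: float = 5.5


@dataclass
class InstructionSchedule:
    """Pseudorandom instruction sequence honouring the task constraints."""

    entries: list[ScheduleEntry]
    block_size: int = 36
    n_blocks: int = 1

    @property
    def n_trials(self) -> int:
        return len(self.entries)

    @property
    def conditions(self) -> np.ndarray:
        return np.array([e.condition for e in self.entries], dtype=object)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_time for e in self.entries])

    @property
    def duration(self) -> float:
        """Time from the first onset to the end of the last silent period."""
        last = self.entries[-1]
        return last.onset_time + last.instruction_duration + last.silence_duration

    def max_run_length(self) -> int:
        run = best = 0
        prev = None
        for e in self.entries:
            run = run + 1 if e.condition == prev else 1
            prev = e.condition
            best = max(best, run)
        return best


def _block_order(rng: np.random.Generator, block_size: int, max_run: int) -> list[str]:
    """Shuffle a balanced block until no condition repeats more than max_run."""
    per = block_size // len(CONDITIONS)
    labels = np.repeat(np.array(CONDITIONS, dtype=object), per)
    while True:
        rng.shuffle(labels)
        run = 1
        ok = True
        for a, b in zip(labels, labels[1:]):
            run = run + 1 if a == b else 1
            if run > max_run:
                ok = False
                break
        if ok:
            return labels.tolist()


def generate_schedule(
    n_blocks: int,
    seed: int | np.random.Generator = 0,
    block_size: int = 36,
    instruction_duration: float = 2.0,
    silence_range: tuple[float, float] = (4.0, 7.0),
    max_run: int = 3,
) -> InstructionSchedule:
    """Generate a balanced pseudorandom instruction schedule.

    Each block holds ``block_size`` trials split equally among left, right and
    rest instructions, ordered so that no more than ``max_run`` consecutive
    trials share a condition (rejection sampling; always feasible for the
    12/12/12 composition).  Consecutive onsets are separated by the 2 s
    instruction plus a silence drawn uniformly from ``silence_range``.
    Deterministic for a given seed.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if block_size % len(CONDITIONS):
        raise ValueError("block_size must be divisible by the number of conditions")
    rng = np.random.default_rng(seed)

    labels: list[str] = []
    for _ in range(n_blocks):
        # max-run constraint applies within blocks; a cross-block run of up to
        # 2 * max_run is impossible anyway for max_run=3 with 12/12/12 blocks,
        # but we also re-draw the block if the boundary would create a long run
        while True:
            block = _block_order(rng, block_size, max_run)
            joined = labels[-max_run:] + block[: max_run + 1]
            run = 1
            ok = True
            for a, b in zip(joined, joined[1:]):
                run = run + 1 if a == b else 1
                if run > max_run:
                    ok = False
                    break
            if ok:
                break
        labels.extend(block)

    silences = rng.uniform(*silence_range, size=len(labels))
    entries = []
    t = 0.0
    for cond, sil in zip(labels, silences):
        entries.append(ScheduleEntry(cond, t, instruction_duration, float(sil)))
        t += instruction_duration + float(sil)
    return InstructionSchedule(entries, block_size=block_size, n_blocks=n_blocks)


# ---------------------------------------------------------------------------
# Simulation specs
# ---------------------------------------------------------------------------

#: Default projection of a sensorimotor source onto the electrode rows.
#: Frontocentral sites see the source most strongly and centroparietal sites
#: weakly, so the bipolar derivations FC3-CP3 / FC4-CP4 retain the rhythm.
_DEFAULT_ROW_WEIGHTS = {"FC": 1.0, "C": 0.7, "CP": 0.2}


def _default_weights(ch_names: list[str]) -> dict[str, float]:
    out = {}
    for ch in ch_names:
        row = ch.rstrip("z34")
        out[ch] = _DEFAULT_ROW_WEIGHTS.get(row, 0.5)
    return out


@dataclass
class Oscillator:
    """Band-limited noise oscillator projected onto the scalp."""

    center: float  # Hz
    bandwidth: float  # Hz (full width)
    amplitude: float  # µV RMS of the source
    channel_weights: dict[str, float] | None = None  # label -> gain

    @property
    def band(self) -> tuple[float, float]:
        return (self.center - self.bandwidth / 2, self.center + self.bandwidth / 2)


@dataclass
class NoiseSpec:
    """Background activity: 1/f noise + white noise + rhythmic oscillators."""

    one_over_f_exponent: float = 1.0
    one_over_f_sd: float = 4.0  # µV, per channel
    broadband_sd: float = 1.0  # µV white noise, per channel
    oscillators: list[Oscillator] = field(
        default_factory=lambda: [
            Oscillator(10.0, 4.0, 4.0),  # mu
            Oscillator(27.5, 5.0, 2.5),  # high-beta
        ]
    )
    #: per-channel multiplier of extra 1-4 Hz power (models pathological
    #: lateralised delta); 1.0 means no boost
    delta_boost: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.one_over_f_sd < 0 or self.broadband_sd < 0:
            raise ValueError("noise amplitudes must be >= 0")
        for osc in self.oscillators:
            if osc.amplitude < 0:
                raise ValueError("oscillator amplitudes must be >= 0")


@dataclass
class EffectSpec:
    """Event-locked multiplicative ERD/ERS on matching oscillators.

    ``depth`` is the fractional amplitude change at the plateau: +0.5 means a
    50% amplitude increase (ERS), -0.5 a 50% decrease (ERD).  ``latency`` is
    measured from the instruction *offset*.  Laterality follows the
    convention that a left-hand trial modulates left-hemisphere channels when
    ``channel_side='ipsilateral'``.
    """

    condition: str  # 'left' or 'right'
    band: tuple[float, float]  # Hz
    depth: float
    channel_side: str = "ipsilateral"  # 'ipsilateral' | 'contralateral' | 'both'
    latency: float = 1.0  # s after instruction offset
    duration: float = 1.0  # s at plateau (including ramps)
    ramp: float = 0.25  # s linear ramp on each side

    def __post_init__(self) -> None:
        if self.condition not in ("left", "right"):
            raise ValueError("effect condition must be 'left' or 'right'")
        if self.channel_side not in ("ipsilateral", "contralateral", "both"):
            raise ValueError(f"unknown channel_side {self.channel_side!r}")
        if self.depth <= -1:
            raise ValueError("depth must be > -1 (amplitude cannot go negative)")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < f_lo < f_hi")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def channels_for(self, ch_names: list[str]) -> list[str]:
        left = [c for c in ch_names if c in LEFT_CHANNELS]
        right = [c for c in ch_names if c in RIGHT_CHANNELS]
        if self.channel_side == "both":
            return left + right
        same = left if self.condition == "left" else right
        other = right if self.condition == "left" else left
        return same if self.channel_side == "ipsilateral" else other


@dataclass
class SimConfig:
    """Full simulation configuration (deterministic given ``seed``)."""

    n_blocks: int = 1
    sampling_rate: float = 256.0
    ch_names: list[str] = field(default_factory=lambda: list(CHANNELS_9))
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    effects: list[EffectSpec] = field(default_factory=list)
    artifact_rate: float = 0.0
    seed: int = 0
    block_size: int = 36
    instruction_duration: float = 2.0
    silence_range: tuple[float, float] = (4.0, 7.0)
    pad: float = 2.0  # s of plain background before/after the task

    def __post_init__(self) -> None:
        for osc in self.noise.oscillators:
            if osc.band[1] * 2 > self.sampling_rate:
                raise ValueError(
                    f"oscillator at {osc.center} Hz exceeds Nyquist for "
                    f"{self.sampling_rate} Hz sampling"
                )
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")


@dataclass
class SimulationResult:
    """Recording plus ground-truth annotations."""

    recording: RawRecording
    schedule: InstructionSchedule
    artifact_trials: np.ndarray  # indices into the event table
    config: SimConfig


# ---------------------------------------------------------------------------
# Signal generation
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng, n, sfreq, exponent):
    """Unit-SD noise with power spectrum ~ 1/f**exponent (f >= 1 Hz flat-capped)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    # cap below 1 Hz so variance stays finite for exponent >= 1
    shaped = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    shaped[0] = 0.0
    out = np.fft.irfft(spec * shaped, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _bandlimited_noise(rng, n, sfreq, band, order=4):
    """Unit-SD Gaussian noise band-passed to ``band`` (Butterworth)."""
    lo, hi = band
    nyq = sfreq / 2
    lo = max(lo, 0.01)
    hi = min(hi, nyq * 0.999)
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    out = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = out.std()
    return out / sd if sd > 0 else out


def _trapezoid_envelope(times, start, duration, ramp, depth):
    """Multiplicative envelope: 1 outside, 1+depth at plateau, linear ramps.

    ``duration`` spans the whole event including both ramps; the plateau is
    ``duration - 2*ramp`` long (clipped at 0, degenerating to a triangle).
    """
    env = np.ones_like(times)
    ramp = min(ramp, duration / 2)
    rise = np.clip((times - start) / max(ramp, 1e-9), 0.0, 1.0)
    fall = np.clip((start + duration - times) / max(ramp, 1e-9), 0.0, 1.0)
    shape = np.minimum(rise, fall)
    env += depth * shape
    return env


def simulate_recording(config: SimConfig) -> SimulationResult:
    """Simulate a continuous recording realising ``config``.

    Returns the recording (with its event table), the schedule, and the
    indices of trials carrying injected artifacts.  Bit-identical output for
    identical configs.
    """
    rng = np.random.default_rng(config.seed)
    # independent streams so adding an effect never perturbs the noise draw
    ss = np.random.SeedSequence(config.seed)
    sched_rng, noise_rng, artifact_rng = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )
    del rng

    schedule = generate_schedule(
        config.n_blocks,
        seed=sched_rng,
        block_size=config.block_size,
        instruction_duration=config.instruction_duration,
        silence_range=config.silence_range,
    )

    # validate effects against the oscillator bank up front
    for eff in config.effects:
        if not _matching_oscillators(config.noise.oscillators, eff):
            raise ValueError(
                f"effect band {eff.band} overlaps no configured oscillator band"
            )

    sfreq = config.sampling_rate
    total = config.pad + schedule.duration + config.pad
    n = int(round(total * sfreq))
    times = np.arange(n) / sfreq
    n_ch = len(config.ch_names)
    data = np.zeros((n_ch, n))

    spec = config.noise
    for ci in range(n_ch):
        if spec.one_over_f_sd > 0:
            data[ci] += spec.one_over_f_sd * _one_over_f_noise(
                noise_rng, n, sfreq, spec.one_over_f_exponent
            )
        if spec.broadband_sd > 0:
            data[ci] += spec.broadband_sd * noise_rng.standard_normal(n)

    if spec.delta_boost:
        for ch, mult in spec.delta_boost.items():
            if ch not in config.ch_names:
                continue
            extra = (mult - 1.0) * spec.one_over_f_sd
            if extra > 0:
                ci = config.ch_names.index(ch)
                data[ci] += extra * _bandlimited_noise(noise_rng, n, sfreq, (1.0, 4.0))

    onsets_abs = config.pad + schedule.onsets  # seconds
    conditions = schedule.conditions

    # oscillators with event-locked multiplicative envelopes
    for osc in spec.oscillators:
        source = osc.amplitude * _bandlimited_noise(noise_rng, n, sfreq, osc.band)
        weights = osc.channel_weights or _default_weights(config.ch_names)
        envelopes = np.ones((n_ch, n))
        for eff in config.effects:
            if not _bands_overlap(osc.band, eff.band):
                continue
            targets = eff.channels_for(config.ch_names)
            trial_mask = conditions == eff.condition
            env = np.ones(n)
            for onset in onsets_abs[trial_mask]:
                start = onset + config.instruction_duration + eff.latency
                env *= _trapezoid_envelope(times, start, eff.duration, eff.ramp, eff.depth)
            for ch in targets:
                envelopes[config.ch_names.index(ch)] *= env
        for ci, ch in enumerate(config.ch_names):
            w = weights.get(ch, 0.0)
            if w:
                data[ci] += w * source * envelopes[ci]

    # broadband muscle-artifact bursts on randomly chosen trials
    background_sd = float(np.median(data.std(axis=1)))
    artifact_trials = np.flatnonzero(
        artifact_rng.uniform(size=schedule.n_trials) < config.artifact_rate
    )
    hi_band = (20.0, min(100.0, sfreq / 2 * 0.95))
    for ti in artifact_trials:
        dur = artifact_rng.uniform(0.5, 1.5)
        start = onsets_abs[ti] + artifact_rng.uniform(0.0, EPOCH_LENGTH - dur)
        gain = artifact_rng.uniform(5.0, 10.0) * background_sd
        i0 = int(round(start * sfreq))
        i1 = min(int(round((start + dur) * sfreq)), n)
        burst_len = i1 - i0
        taper = signal.windows.tukey(burst_len, 0.25)
        for ci in range(n_ch):
            burst = _bandlimited_noise(artifact_rng, burst_len, sfreq, hi_band)
            data[ci, i0:i1] += gain * taper * burst

    onset_samples = np.round(onsets_abs * sfreq).astype(np.int64)
    recording = RawRecording(
        data, sfreq, list(config.ch_names), events_frame(onset_samples, conditions)
    )
    if len(artifact_trials) == 0 and config.artifact_rate > 0.25:
        warnings.warn("artifact_rate > 0 but no artifact trials drawn", stacklevel=2)
    return SimulationResult(recording, schedule, artifact_trials, config)


def _bands_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _matching_oscillators(oscillators, effect: EffectSpec):
    return [o for o in oscillators if _bands_overlap(o.band, effect.band)]
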