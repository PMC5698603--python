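"""Simulated auditory-oddball EEG recordings.

This module generates continuous 64-channel, 256 Hz recordings for the
six-direction auditory oddball paradigm: each session presents ~180 short
stimuli (100 ms white-noise bursts from one of six virtual directions), the
subject attends one *target* direction, and every target stimulus evokes a
P300-like positive deflection 250-700 ms after onset, concentrated over
centro-parietal channels and superimposed on 1/f background noise.

The stimulus schedule is pseudorandomized in blocks of six: within every
aligned block of six trials each direction occurs exactly once, so exactly
one trial in six is a target, and two target stimuli are never presented
consecutively (the constraint is enforced across block and session
boundaries).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FS = 256.0  # sampling rate, Hz
N_CHANNELS = 64
EPOCH_MS = 1100.0  # post-onset window every downstream stage uses


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionSpec:
    """One experimental session: a run of trials with a fixed target direction.

    ``n_trials`` must be a positive multiple of ``n_directions`` (the schedule
    is built from blocks in which each direction occurs once).
    ``trial_length_ms`` is stimulus (100 ms) plus silence; the study used
    500, 400 and 300 ms.
    """

    n_trials: int = 180
    n_directions: int = 6
    target_direction: int = 1
    trial_length_ms: float = 500.0
    stimulus_ms: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_trials % self.n_directions:
            raise ValueError(
                f"n_trials={self.n_trials} must be a positive multiple of "
                f"n_directions={self.n_directions} (block design)"
            )
        if self.n_directions < 2:
            raise ValueError(
                "n_directions must be >= 2: with a single direction every "
                "trial is a target and consecutive targets cannot be avoided"
            )
        if not 1 <= self.target_direction <= self.n_directions:
            raise ValueError(
                f"target_direction={self.target_direction} outside "
                f"1..{self.n_directions}"
            )
        if self.trial_length_ms <= self.stimulus_ms:
            raise ValueError("trial_length_ms must exceed stimulus_ms")


@dataclass(frozen=True)
class P300Params:
    """Shape of the simulated P300 deflection.

    A Gaussian positive bump of ``amplitude`` microvolts peaking
    ``peak_latency_ms`` after a target stimulus (sigma = ``width_ms`` / 2),
    with per-event latency jitter, distributed over channels by
    ``spatial_weights`` (nonnegative, sums to 1; None selects the bundled
    centro-parietal prior).
    """

    amplitude: float = 5.0
    peak_latency_ms: float = 400.0
    latency_jitter_ms: float = 30.0
    width_ms: float = 150.0
    spatial_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if not 250.0 <= self.peak_latency_ms <= 700.0:
            warnings.warn(
                f"peak_latency_ms={self.peak_latency_ms} lies outside the "
                "250-700 ms window expected of a P300; allowed for ablation",
                stacklevel=2,
            )
        if self.spatial_weights is not None:
            w = np.asarray(self.spatial_weights, dtype=float)
            if w.shape != (N_CHANNELS,) or (w < 0).any():
                raise ValueError("spatial_weights must be 64 nonnegative values")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("spatial_weights must sum to 1")
            object.__setattr__(self, "spatial_weights", w)


@dataclass(frozen=True)
class NoiseParams:
    """Background activity: 1/f Gaussian noise, slow drift, optional alpha."""

    background_sd: float = 10.0   # uV, broadband
    spectral_exponent: float = 1.0  # power ~ 1/f^exponent
    drift_amplitude: float = 5.0  # uV, <0.1 Hz wander
    alpha_amplitude: float = 1.0  # uV, 10 Hz rhythm (0 disables)

    def __post_init__(self) -> None:
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")


@dataclass
class RawRecording:
    """Continuous multichannel signal plus its event table.

    ``signal`` is (64, n_samples) in microvolts at 256 Hz; ``events`` has one
    row per trial with columns onset_sample, direction, is_target, session.
    """

    signal: np.ndarray
    events: pd.DataFrame
    channel_names: list[str]
    fs: float = FS
    trial_length_ms: float = 500.0

    def __post_init__(self) -> None:
        if self.signal.shape[0] != N_CHANNELS:
            raise ValueError("signal must have 64 channel rows")
        if len(self.events):
            first = int(self.events.onset_sample.iloc[0])
            last = int(self.events.onset_sample.iloc[-1])
            if first < int(0.1 * self.fs):
                raise ValueError("recording must start >=100 ms before first onset")
            if self.signal.shape[1] - last < int(EPOCH_MS / 1000 * self.fs) + 1:
                raise ValueError("recording must extend >=1100 ms past last onset")


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

def generate_session_sequence(spec: SessionSpec) -> pd.DataFrame:
    """Pseudorandomized direction schedule for one session.

    Returns a DataFrame with columns ``onset_sample`` (at 256 Hz, first onset
    at sample 0 — the caller offsets into the recording), ``direction``,
    ``is_target`` and ``session``. Every aligned block of six trials is a
    permutation of the six directions, and no two consecutive trials are
    targets; with one target per block this can only happen at block
    boundaries, so each block's permutation is redrawn until its first trial
    is not a target whenever the previous block ended with one.
    """
    rng = np.random.default_rng(spec.seed)
    n_blocks = spec.n_trials // spec.n_directions
    directions = np.empty(spec.n_trials, dtype=np.int64)
    prev_was_target = False
    for b in range(n_blocks):
        while True:
            perm = rng.permutation(spec.n_directions) + 1
            if not (prev_was_target and perm[0] == spec.target_direction):
                break
        directions[b * spec.n_directions:(b + 1) * spec.n_directions] = perm
        prev_was_target = perm[-1] == spec.target_direction

    step = int(round(spec.trial_length_ms / 1000.0 * FS))
    return pd.DataFrame(
        {
            "onset_sample": np.arange(spec.n_trials, dtype=np.int64) * step,
            "direction": directions,
            "is_target": directions == spec.target_direction,
            "session": np.zeros(spec.n_trials, dtype=np.int64),
        }
    )


# ---------------------------------------------------------------------------
# P300 template and spatial prior
# ---------------------------------------------------------------------------

def p300_template(t_ms: np.ndarray, p300: P300Params,
                  peak_shift_ms: float = 0.0) -> np.ndarray:
    """Evaluate the P300 waveform on a post-onset time grid (ms).

    Gaussian bump: ``amplitude * exp(-((t - peak)^2) / (2 sigma^2))`` with
    ``sigma = width_ms / 2``, zeroed outside [0, 1100] ms. ``peak_shift_ms``
    implements per-event latency jitter.
    """
    t = np.asarray(t_ms, dtype=float)
    if p300.amplitude == 0:
        return np.zeros_like(t)
    sigma = p300.width_ms / 2.0
    peak = p300.peak_latency_ms + peak_shift_ms
    wave = p300.amplitude * np.exp(-0.5 * ((t - peak) / sigma) ** 2)
    wave[(t < 0) | (t > EPOCH_MS)] = 0.0
    return wave


def default_spatial_weights(layout=None) -> np.ndarray:
    """Centro-parietal spatial prior: Gaussian falloff on the electrode grid.

    The potential peaks around the Cz/Pz midline neighbourhood, where P300 is
    classically largest; weights decay with squared grid distance from the
    centro-parietal cell and are normalized to sum to 1.
    """
    from .input_builder import load_layout  # local import avoids cycle

    lay = layout if layout is not None else load_layout()
    rows = np.array([lay.cells[name][0] for name in lay.channel_names], float)
    cols = np.array([lay.cells[name][1] for name in lay.channel_names], float)
    # (5.5, 5) sits between Cz (4,5) and Pz (6,5) in the bundled layout
    d2 = (rows - 5.5) ** 2 + (cols - 5.0) ** 2
    w = np.exp(-d2 / (2 * 2.0 ** 2))
    return w / w.sum()


# ---------------------------------------------------------------------------
# continuous signal synthesis
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      sd: float, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent, std = sd."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / FS)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    shaped = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    shaped *= sd / shaped.std(axis=1, keepdims=True)
    return shaped


def synthesize_recording(
    specs: list[SessionSpec],
    p300: P300Params | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    inter_session_gap_s: float = 2.0,
    channel_names: list[str] | None = None,
) -> RawRecording:
    """Concatenate sessions into one continuous recording with events.

    All sessions must share ``trial_length_ms``. The signal is background
    noise + drift (+ alpha) with, for every target event, a positive P300
    template scaled per channel by the spatial weights and jittered in
    latency. Sessions are separated by a silent-schedule gap
    (``inter_session_gap_s``); 1 s of signal precedes the first onset and
    1.5 s follow the last.
    """
    p300 = p300 if p300 is not None else P300Params()
    noise = noise if noise is not None else NoiseParams()
    lengths = {s.trial_length_ms for s in specs}
    if len(lengths) > 1:
        raise ValueError(f"sessions mix trial lengths {sorted(lengths)}")
    trial_length_ms = lengths.pop()

    rng = np.random.default_rng(seed)
    # schedule: per-session sequences, offset into one continuous timeline
    pre = int(1.0 * FS)
    gap = int(inter_session_gap_s * FS)
    step = int(round(trial_length_ms / 1000.0 * FS))
    frames = []
    cursor = pre
    for sid, spec in enumerate(specs, start=1):
        ev = generate_session_sequence(spec)
        ev["onset_sample"] += cursor
        ev["session"] = sid
        frames.append(ev)
        cursor = int(ev.onset_sample.iloc[-1]) + step + gap
    events = pd.concat(frames, ignore_index=True)

    # enforce no-consecutive-target across session boundaries as well
    for i in range(1, len(specs)):
        lo = sum(s.n_trials for s in specs[:i])
        if events.is_target.iloc[lo - 1] and events.is_target.iloc[lo]:
            # redraw the first block of session i with a shifted seed until
            # its first trial is a nontarget (rare: sessions are generated
            # independently so the boundary needs its own pass)
            spec = specs[i]
            bump = 1
            while events.is_target.iloc[lo]:
                ev = generate_session_sequence(replace(spec, seed=spec.seed + 7919 * bump))
                block = ev.iloc[: spec.n_directions]
                if not block.is_target.iloc[0]:
                    cols = ["direction", "is_target"]
                    events.loc[lo : lo + spec.n_directions - 1, cols] = block[cols].to_numpy()
                bump += 1

    n_samples = int(events.onset_sample.iloc[-1]) + int(1.5 * FS)

    signal = _one_over_f_noise(
        rng, N_CHANNELS, n_samples, noise.background_sd, noise.spectral_exponent
    )
    t = np.arange(n_samples) / FS
    if noise.drift_amplitude > 0:
        drift_f = rng.uniform(0.02, 0.08, size=N_CHANNELS)
        drift_ph = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
        signal += noise.drift_amplitude * np.sin(
            2 * np.pi * drift_f[:, None] * t[None, :] + drift_ph[:, None]
        )
    if noise.alpha_amplitude > 0:
        alpha_ph = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
        signal += noise.alpha_amplitude * np.sin(
            2 * np.pi * 10.0 * t[None, :] + alpha_ph[:, None]
        )

    weights = (
        p300.spatial_weights
        if p300.spatial_weights is not None
        else default_spatial_weights()
    )
    # scale so the peak channel sees the full template amplitude
    ch_gain = weights / weights.max() if weights.max() > 0 else weights
    win = int(EPOCH_MS / 1000.0 * FS) + 1
    t_ms = np.arange(win) / FS * 1000.0
    target_onsets = events.loc[events.is_target, "onset_sample"].to_numpy()
    jitters = rng.normal(0.0, p300.latency_jitter_ms, size=target_onsets.size)
    for onset, jit in zip(target_onsets, jitters):
        wave = p300_template(t_ms, p300, peak_shift_ms=jit)
        stop = min(onset + win, n_samples)
        signal[:, onset:stop] += ch_gain[:, None] * wave[None, : stop - onset]

    if channel_names is None:
        from .input_builder import load_layout

        channel_names = list(load_layout().channel_names)
    return RawRecording(
        signal=signal,
        events=events,
        channel_names=channel_names,
        trial_length_ms=trial_length_ms,
    )


def subject_session_specs(
    trial_length_ms: float = 500.0,
    n_sessions: int = 12,
    n_trials: int = 180,
    seed: int = 0,
) -> list[SessionSpec]:
    """The study's session plan: target direction rotating 1..6, 1..6."""
    return [
        SessionSpec(
            n_trials=n_trials,
            target_direction=(s % 6) + 1,
            trial_length_ms=trial_length_ms,
            seed=seed * 1000 + s,
        )
        for s in range(n_sessions)
    ]


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_recording(rec: RawRecording, out_dir) -> None:
    """Persist a recording: signal.npy + sidecar JSON + events.tsv."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.save(out / "signal.npy", rec.signal)
    rec.events.to_csv(out / "events.tsv", sep="\t", index=False)
    meta = {
        "fs": rec.fs,
        "channel_names": rec.channel_names,
        "trial_length_ms": rec.trial_length_ms,
        "units": "uV",
    }
    (out / "signal.json").write_text(json.dumps(meta, indent=1))


def read_recording(in_dir) -> RawRecording:
    from pathlib import Path

    src = Path(in_dir)
    meta = json.loads((src / "signal.json").read_text())
    return RawRecording(
        signal=np.load(src / "signal.npy"),
        events=pd.read_csv(src / "events.tsv", sep="\t"),
        channel_names=meta["channel_names"],
        fs=meta["fs"],
        trial_length_ms=meta["trial_length_ms"],
    )
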