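"""Preprocessing: baseline correction, bandpass filtering, decimation, epoching.

The pipeline, applied identically to target and nontarget trials:

1. bandpass the *continuous* recording (Butterworth 0.1-8 Hz, zero phase) —
   filtering before epoching keeps filter edge artifacts out of the 1100 ms
   windows;
2. per trial, subtract a Savitzky-Golay-smoothed baseline trend estimated
   from 100 ms before stimulus onset to the end of the trial (stimulus +
   silence);
3. extract a 1100 ms post-onset window and decimate by 10 (256 Hz ->
   25.6 Hz), keeping source samples 10, 20, ..., 280 relative to onset —
   exactly 28 samples per epoch, one per eventual feature map.

Epochs are 1100 ms regardless of trial length, so for 300-500 ms trials each
window deliberately overlaps the following trials.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .synthetic_eeg import EPOCH_MS, FS, RawRecording

logger = logging.getLogger(__name__)

DECIMATION_FACTOR = 10
N_TIME = 28  # samples per epoch after decimation
PRE_MS = 100.0  # baseline window starts this far before onset


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth bandpass, 0.1-8 Hz at order 4 by default."""

    low_cut_hz: float = 0.1
    high_cut_hz: float = 8.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ValueError("need 0 < low_cut_hz < high_cut_hz")


@dataclass
class Epoch:
    """One trial's classifier-ready window: (64, 28) in microvolts."""

    data: np.ndarray
    t0: int  # onset sample in the source recording
    is_target: bool
    meta: dict = field(default_factory=dict)


def baseline_correct(
    segment: np.ndarray,
    trial_end: int,
    pre_samples: int = int(PRE_MS / 1000 * FS),
    polyorder: int = 3,
) -> np.ndarray:
    """Subtract a Savitzky-Golay trend estimated over [-100 ms, trial end].

    ``segment`` is (channels, time) with the stimulus onset at index
    ``pre_samples`` and the trial ending at index ``trial_end``; the segment
    may extend past the trial end (the 1100 ms window does). The trend is a
    Savitzky-Golay smooth (window = half the baseline span, forced odd;
    polynomial order 3) of the [0, trial_end) span, subtracted there; past
    the trial end the trend's final value is carried forward so the
    correction introduces no step.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 2:
        raise ValueError("segment must be (channels, time)")
    if pre_samples < int(PRE_MS / 1000 * FS):
        missing = int(PRE_MS / 1000 * FS) - pre_samples
        raise ValueError(
            f"segment starts {missing} samples too late: need >= "
            f"{PRE_MS:.0f} ms before stimulus onset"
        )
    if trial_end > seg.shape[1]:
        raise ValueError("trial_end lies beyond the provided segment")

    span = trial_end  # [-100 ms, trial end] in segment indices
    # window = the whole baseline span (odd-forced): the trend can then only
    # track components slower than the span, sparing ERP-scale deflections
    window = span if span % 2 else span - 1
    window = max(window, polyorder + 2 + (polyorder % 2))
    trend = savgol_filter(seg[:, :span], window, polyorder, axis=1)

    out = seg.copy()
    out[:, :span] -= trend
    if span < seg.shape[1]:
        out[:, span:] -= trend[:, -1:]
    return out


def bandpass(signal: np.ndarray, fs: float = FS,
             spec: FilterSpec | None = None) -> np.ndarray:
    """Butterworth bandpass along time (last axis), zero-phase by default."""
    spec = spec if spec is not None else FilterSpec()
    if fs <= 2 * spec.high_cut_hz:
        raise ValueError(
            f"fs={fs} must exceed twice the high cutoff ({spec.high_cut_hz} Hz)"
        )
    sos = butter(
        spec.order,
        [spec.low_cut_hz, spec.high_cut_hz],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    if spec.zero_phase:
        return sosfiltfilt(sos, signal, axis=-1)
    from scipy.signal import sosfilt

    return sosfilt(sos, signal, axis=-1)


def decimate(signal: np.ndarray, factor: int = DECIMATION_FACTOR) -> np.ndarray:
    """Integer decimation along time: keep samples factor, 2*factor, ...

    Relative to an array whose first element is one sample after the
    reference point, this retains source indices ``factor-1, 2*factor-1, ...``
    — the convention under which a (0, 1100] ms post-onset window at 256 Hz
    (281 samples) yields exactly 28 samples. The 8 Hz bandpass upstream is
    the anti-alias guard (new Nyquist 12.8 Hz).
    """
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    return np.asarray(signal)[..., factor - 1 :: factor]


def epoch_trials(
    recording: RawRecording,
    filter_spec: FilterSpec | None = None,
    window_ms: float = EPOCH_MS,
    baseline: bool = True,
) -> list[Epoch]:
    """Run the full pipeline on a recording -> list of (64, 28) epochs.

    One epoch per event; events with less than ``window_ms`` of signal
    remaining are skipped with a warning. Labels are copied from the event
    table; the numerical path never looks at them.
    """
    fs = recording.fs
    filtered = bandpass(recording.signal, fs=fs, spec=filter_spec)
    pre = int(PRE_MS / 1000 * fs)
    win = int(window_ms / 1000 * fs)  # 281 samples for 1100 ms
    trial_samples = int(round(recording.trial_length_ms / 1000 * fs))

    epochs: list[Epoch] = []
    n_skipped = 0
    for row in recording.events.itertuples(index=False):
        onset = int(row.onset_sample)
        if onset + win > filtered.shape[1]:
            n_skipped += 1
            continue
        seg = filtered[:, onset - pre : onset + win]
        if baseline:
            seg = baseline_correct(seg, trial_end=pre + trial_samples, pre_samples=pre)
        post = seg[:, pre + 1 : pre + 1 + win]  # (0, 1100] ms
        data = decimate(post)
        if data.shape[1] != N_TIME:
            raise AssertionError(
                f"decimation yielded {data.shape[1]} samples, expected {N_TIME}"
            )
        epochs.append(
            Epoch(
                data=data,
                t0=onset,
                is_target=bool(row.is_target),
                meta={
                    "session": int(row.session),
                    "trial_length_ms": recording.trial_length_ms,
                },
            )
        )
    if n_skipped:
        msg = f"skipped {n_skipped} trial(s) with <{window_ms:.0f} ms of signal left"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return epochs


def write_epochs(epochs: list[Epoch], out_path) -> None:
    """Persist epochs as an .npz tensor container plus a JSON sidecar."""
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack([ep.data for ep in epochs])
    labels = np.array([ep.is_target for ep in epochs], dtype=np.int64)
    t0 = np.array([ep.t0 for ep in epochs], dtype=np.int64)
    np.savez(out, data=data, labels=labels, t0=t0)
    meta = epochs[0].meta if epochs else {}
    out.with_suffix(".json").write_text(
        json.dumps({"n_epochs": len(epochs), **meta}, indent=1)
    )


def read_epochs(in_path) -> list[Epoch]:
    src = Path(in_path)
    with np.load(src) as npz:
        data, labels, t0 = npz["data"], npz["labels"], npz["t0"]
    meta_path = src.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    meta = {k: v for k, v in meta.items() if k != "n_epochs"}
    return [
        Epoch(data=d, t0=int(t), is_target=bool(l), meta=dict(meta))
        for d, t, l in zip(data, t0, labels)
    ]
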