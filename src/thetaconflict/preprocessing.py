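"""Continuous-data conditioning and epoch-level artifact control.

Order of operations mirrors a standard ERP workflow: downsample, high-pass
filter (0.1 Hz half-amplitude Butterworth), average-reference over scalp
channels, cut stimulus- or response-locked epochs, baseline-correct, reject
trials by moving-window peak-to-peak amplitude, and drop participants with
too many rejected trials.

Filters are zero-phase (forward-backward) Butterworth. A digital Butterworth
designed at cutoff f_c has |H(f_c)| = 1/sqrt(2); after the two passes the
amplitude response is |H|^2, which equals exactly 1/2 at f_c — so designing
at the requested half-amplitude cutoff honors it without pre-warping.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.signal

from thetaconflict.containers import ContinuousRecording, EpochSet
from thetaconflict.exceptions import InvalidInputError


def butterworth_filter(recording: ContinuousRecording, kind: str,
                       half_amp_cutoff_hz: float, order: int = 2) -> ContinuousRecording:
    """Zero-phase Butterworth high- or low-pass on the continuous signal.

    ``order`` is per pass; the forward-backward application doubles the
    effective order and places the half-amplitude (-6 dB) point at the
    requested cutoff.
    """
    if kind not in ("highpass", "lowpass"):
        raise InvalidInputError(f"kind must be highpass/lowpass, got {kind!r}")
    nyq = recording.rate_hz / 2.0
    if not 0 < half_amp_cutoff_hz < nyq:
        raise InvalidInputError(
            f"cutoff {half_amp_cutoff_hz} Hz outside (0, Nyquist={nyq}) Hz")
    sos = scipy.signal.butter(order, half_amp_cutoff_hz, btype=kind,
                              fs=recording.rate_hz, output="sos")
    out = recording.copy()
    out.signal = scipy.signal.sosfiltfilt(sos, out.signal, axis=1)
    return out


def filter_array(data: np.ndarray, rate_hz: float, kind: str,
                 half_amp_cutoff_hz: float, order: int = 2,
                 axis: int = -1) -> np.ndarray:
    """Same zero-phase Butterworth, for bare arrays (e.g. averaged ERPs)."""
    sos = scipy.signal.butter(order, half_amp_cutoff_hz, btype=kind,
                              fs=rate_hz, output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=axis)


def downsample(recording: ContinuousRecording, target_hz: float) -> ContinuousRecording:
    """Anti-alias and decimate to ``target_hz`` (integer factor only).

    Event sample indices are rescaled by floor division.
    """
    factor = recording.rate_hz / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise InvalidInputError(
            f"rate {recording.rate_hz} not an integer multiple of {target_hz}")
    factor = int(round(factor))
    out = recording.copy()
    if factor == 1:
        return out
    out.signal = scipy.signal.decimate(out.signal, factor, ftype="fir",
                                       zero_phase=True, axis=1)
    out.rate_hz = target_hz
    out.events["sample"] = out.events["sample"] // factor
    return out


def rereference_average(recording: ContinuousRecording,
                        scalp_channels: list[str] | None = None) -> ContinuousRecording:
    """Subtract the mean over scalp channels from every scalp channel.

    EOG channels are excluded by default (any channel whose name starts with
    "EOG"). After the operation the scalp-channel mean is zero at every
    sample; channel differences are preserved exactly.
    """
    if scalp_channels is None:
        scalp_channels = [c for c in recording.channel_names
                          if not c.upper().startswith("EOG")]
    if not scalp_channels:
        raise InvalidInputError("empty scalp-channel set")
    idx = [recording.channel_index(c) for c in scalp_channels]
    out = recording.copy()
    ref = out.signal[idx].mean(axis=0)
    out.signal[idx] -= ref
    return out


def extract_epochs(recording: ContinuousRecording, lock: str,
                   window_ms: tuple[float, float],
                   conditions: tuple[str, ...] | None = None) -> EpochSet:
    """Cut fixed-length epochs around every lock event.

    The window is half-open [start, end) in ms; sample offsets use
    floor(ms * rate / 1000) so that (-500, 2000) at 512 Hz gives exactly
    1280 samples. Events whose window would leave the recording are dropped
    with a warning.
    """
    start_ms, end_ms = window_ms
    if start_ms >= end_ms:
        raise InvalidInputError("epoch window start must precede end")
    if lock not in ("stimulus", "response"):
        raise InvalidInputError(f"unknown lock {lock!r}")
    rate = recording.rate_hz
    start_off = int(np.floor(start_ms * rate / 1000.0))
    n_samp = int(np.floor(end_ms * rate / 1000.0)) - start_off
    ev = recording.events[recording.events["kind"] == lock]
    if conditions is not None:
        ev = ev[ev["condition"].isin(conditions)]
    data, conds, tids = [], [], []
    n_dropped = 0
    for _, row in ev.iterrows():
        a = int(row["sample"]) + start_off
        if a < 0 or a + n_samp > recording.n_samples:
            n_dropped += 1
            continue
        data.append(recording.signal[:, a:a + n_samp])
        conds.append(row["condition"])
        tids.append(row["trial_id"])
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} events whose epoch window left "
                      "the recording", stacklevel=2)
    if not data:
        raise InvalidInputError("no events produced a full epoch")
    return EpochSet(np.stack(data), start_off * 1000.0 / rate, rate, lock,
                    list(recording.channel_names),
                    np.array(conds, dtype=object), np.array(tids),
                    participant_id=recording.participant_id)


def baseline_correct(epochs: EpochSet,
                     window_ms: tuple[float, float]) -> EpochSet:
    """Subtract each trial's per-channel mean over the baseline window."""
    sl = epochs.sample_window(*window_ms)
    out = epochs.copy()
    out.data -= out.data[:, :, sl].mean(axis=2, keepdims=True)
    return out


def peak_to_peak_reject(epochs: EpochSet, threshold_uv: float,
                        window_width_ms: float = 100.0,
                        window_step_ms: float = 50.0,
                        channels: list[str] | None = None) -> EpochSet:
    """Flag trials whose peak-to-peak range within any moving window exceeds
    the threshold on any monitored channel.

    Flags are only ever set, never cleared. ``window_step_ms`` defaults to
    half the width; pass ``1000/rate`` for the exact dense (every-sample)
    scan. Monitored channels default to all non-EOG channels.
    """
    if threshold_uv <= 0:
        raise InvalidInputError("threshold must be positive")
    rate = epochs.rate_hz
    width = int(round(window_width_ms * rate / 1000.0))
    step = max(1, int(round(window_step_ms * rate / 1000.0)))
    if width > epochs.n_samples:
        raise InvalidInputError("window wider than epoch")
    if channels is None:
        channels = [c for c in epochs.channel_names
                    if not c.upper().startswith("EOG")]
    ci = [epochs.channel_index(c) for c in channels]
    out = epochs.copy()
    data = out.data[:, ci, :]
    starts = np.arange(0, epochs.n_samples - width + 1, step)
    if starts[-1] != epochs.n_samples - width:
        starts = np.append(starts, epochs.n_samples - width)  # cover the tail
    windows = np.lib.stride_tricks.sliding_window_view(data, width, axis=2)[:, :, starts, :]
    ptp = windows.max(axis=3) - windows.min(axis=3)
    out.rejected |= (ptp > threshold_uv).any(axis=(1, 2))
    return out


def calibrate_threshold(epochs: EpochSet, target_fraction: float = 0.15,
                        candidates_uv: np.ndarray | None = None,
                        **reject_kwargs) -> float:
    """Pick the rejection threshold whose realized rejection rate is closest
    to ``target_fraction`` (individual-threshold helper)."""
    if candidates_uv is None:
        candidates_uv = np.arange(40.0, 301.0, 10.0)
    best, best_gap = float(candidates_uv[0]), np.inf
    for thr in candidates_uv:
        flagged = peak_to_peak_reject(epochs, float(thr), **reject_kwargs)
        gap = abs(flagged.rejected.mean() - target_fraction)
        if gap < best_gap:
            best, best_gap = float(thr), gap
    return best


def exclude_participants(epoch_sets: dict[str, EpochSet],
                         max_rejected_fraction: float = 0.25):
    """Split participants into (kept, excluded) by rejected-trial fraction.

    A participant is excluded iff rejected/total is *strictly* greater than
    the cutoff (the >25% rule). Returns (kept_ids, excluded_ids, report)
    where report is a DataFrame suitable for CSV export.
    """
    rows, kept, excluded = [], [], []
    for pid, ep in epoch_sets.items():
        frac = float(ep.rejected.mean())
        out = frac > max_rejected_fraction
        (excluded if out else kept).append(pid)
        rows.append({"participant_id": pid, "n_trials": ep.n_trials,
                     "n_rejected": int(ep.rejected.sum()),
                     "fraction": frac, "excluded": out})
    return kept, excluded, pd.DataFrame(rows)
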