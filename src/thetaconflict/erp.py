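"""ERP averaging and N2 / CRN / LPC component quantification.

Components follow their standard definitions: N2 is the negative peak
250-350 ms post-stimulus at FCz; CRN is the negative peak from 50 ms before
to 50 ms after the response at FCz (response-locked); LPC is the mean
amplitude 650-750 ms post-stimulus at Pz. Peaks are simple windowed extrema
(no local-peak requirement); an extremum sitting on a window boundary is
flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from thetaconflict.containers import EpochSet
from thetaconflict.exceptions import InvalidInputError
from thetaconflict.preprocessing import filter_array
from thetaconflict.task_design import PairedTestResult, paired_t_test

COMPONENT_DEFS = {
    "N2": {"lock": "stimulus", "channel": "FCz", "window_ms": (250.0, 350.0),
           "measure": "negative_peak"},
    "CRN": {"lock": "response", "channel": "FCz", "window_ms": (-50.0, 50.0),
            "measure": "negative_peak"},
    "LPC": {"lock": "stimulus", "channel": "Pz", "window_ms": (650.0, 750.0),
            "measure": "mean_amplitude"},
}


@dataclass
class ERPWaveform:
    values: np.ndarray  # channels x samples, microvolts
    times_ms: np.ndarray
    lock: str
    condition: str
    channel_names: list[str]
    n_trials_averaged: int
    rate_hz: float
    participant_id: str = "P00"

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.values[self.channel_names.index(name)]
        except ValueError:
            raise InvalidInputError(f"channel {name!r} not in ERP") from None

    def window(self, start_ms: float, end_ms: float) -> slice:
        t = self.times_ms
        if start_ms >= end_ms:
            raise InvalidInputError("window start must precede end")
        idx = np.flatnonzero((t >= start_ms - 1e-9) & (t < end_ms - 1e-9))
        if idx.size == 0:
            raise InvalidInputError(
                f"window [{start_ms}, {end_ms}) ms outside epoch "
                f"[{t[0]:.1f}, {t[-1]:.1f}] ms")
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class ComponentMeasure:
    component: str
    condition: str
    amplitude_uv: float
    latency_ms: float | None  # None for mean-amplitude measures
    channel: str
    window_ms: tuple[float, float]
    boundary: bool = False
    participant_id: str = "P00"


def average_erp(epochs: EpochSet, condition: str,
                lowpass_hz: float | None = 30.0,
                filter_order: int = 2) -> ERPWaveform:
    """Pointwise mean over the condition's non-rejected trials, then (by
    default) a 30 Hz half-amplitude zero-phase low-pass on the average."""
    m = epochs.mask(condition)
    if not m.any():
        raise InvalidInputError(f"no usable trials for condition {condition!r}")
    avg = epochs.data[m].mean(axis=0)
    if lowpass_hz is not None:
        avg = filter_array(avg, epochs.rate_hz, "lowpass", lowpass_hz,
                           order=filter_order)
    return ERPWaveform(avg, epochs.times_ms, epochs.lock, condition,
                       list(epochs.channel_names), int(m.sum()),
                       epochs.rate_hz, epochs.participant_id)


def quantify_peak(erp: ERPWaveform, channel: str,
                  window_ms: tuple[float, float], polarity: str = "negative",
                  component: str = "") -> ComponentMeasure:
    """Windowed extremum amplitude and its latency; ties break earliest.

    ``polarity="negative"`` takes the minimum (N2/CRN convention). Extrema on
    the first or last window sample are flagged as boundary cases.
    """
    if polarity not in ("negative", "positive"):
        raise InvalidInputError(f"unknown polarity {polarity!r}")
    sl = erp.window(*window_ms)
    seg = erp.channel(channel)[sl]
    i = int(np.argmin(seg) if polarity == "negative" else np.argmax(seg))
    times = erp.times_ms[sl]
    return ComponentMeasure(
        component or f"{polarity}_peak", erp.condition, float(seg[i]),
        float(times[i]), channel, tuple(window_ms),
        boundary=(i == 0 or i == seg.size - 1),
        participant_id=erp.participant_id)


def mean_amplitude(erp: ERPWaveform, channel: str,
                   window_ms: tuple[float, float],
                   component: str = "") -> ComponentMeasure:
    """Arithmetic mean amplitude over the window; no latency (LPC convention)."""
    sl = erp.window(*window_ms)
    seg = erp.channel(channel)[sl]
    return ComponentMeasure(component or "mean_amplitude", erp.condition,
                            float(seg.mean()), None, channel,
                            tuple(window_ms), participant_id=erp.participant_id)


def measure_component(erp: ERPWaveform, component: str) -> ComponentMeasure:
    """Apply a standard component definition (N2, CRN or LPC) to a waveform."""
    try:
        spec = COMPONENT_DEFS[component]
    except KeyError:
        raise InvalidInputError(f"unknown component {component!r}") from None
    if erp.lock != spec["lock"]:
        raise InvalidInputError(
            f"{component} is {spec['lock']}-locked, waveform is {erp.lock}-locked")
    if spec["measure"] == "negative_peak":
        return quantify_peak(erp, spec["channel"], spec["window_ms"],
                             "negative", component)
    return mean_amplitude(erp, spec["channel"], spec["window_ms"], component)


def measures_table(measures: list[ComponentMeasure]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": m.participant_id, "condition": m.condition,
        "component": m.component, "amplitude_uV": m.amplitude_uv,
        "latency_ms": m.latency_ms, "boundary_flag": m.boundary,
    } for m in measures])


def compare_components(measures: list[ComponentMeasure], which: str = "amplitude",
                       condition_a: str = "AV-AV",
                       condition_b: str = "AP-AP") -> PairedTestResult:
    """Two-sided paired t-test on a component measure across participants."""
    if which not in ("amplitude", "latency"):
        raise InvalidInputError(f"which must be amplitude/latency, got {which!r}")
    tab = measures_table(measures)
    col = "amplitude_uV" if which == "amplitude" else "latency_ms"
    if which == "latency" and tab[col].isna().any():
        raise InvalidInputError("latency comparison on a latency-free measure")
    wide = tab.pivot(index="participant_id", columns="condition", values=col)
    if wide.isna().any().any():
        raise InvalidInputError("unpaired participants in component table")
    return paired_t_test(wide[condition_a].to_numpy(),
                         wide[condition_b].to_numpy(), tail="two_sided")
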