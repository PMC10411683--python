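"""Synthetic EEG + behavior generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: 1/f
background noise, stimulus-locked theta bursts at FCz whose power is higher
on avoidance-avoidance (AV-AV) than approach-approach (AP-AP) trials,
trial-level theta variability negatively coupled to reaction time (more
strongly in AV-AV), evoked ERP deflections, and occasional high-amplitude
transient artifacts. Every injected quantity is returned as ground truth so
recovery can be tested.

The generator runs natively at 512 Hz (the pipeline's post-downsampling
rate); a 2048 Hz mode exists to exercise the downsampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from thetaconflict.containers import ContinuousRecording
from thetaconflict.exceptions import ConfigurationError
from thetaconflict.task_design import TrialSpec, build_trial_sequence, CharacteristicSet

#: epoch span the time-frequency stage cuts around each stimulus (ms)
TF_EPOCH_MS = (-1000.0, 4000.0)


def default_characteristics() -> tuple[CharacteristicSet, CharacteristicSet]:
    """Placeholder 7+7 characteristic sets (labels are configurable strings)."""
    pos = CharacteristicSet(tuple(f"pos{i}" for i in range(1, 8)), "positive")
    neg = CharacteristicSet(tuple(f"neg{i}" for i in range(1, 8)), "negative")
    return pos, neg


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic cohort.

    Reaction-time intercepts default to the task's condition means
    (AV-AV 5774 ms, AP-AP 4601 ms); theta->RT slopes default to the scale of
    the single-trial effect (about -205 ms/dB in AV-AV, -94 in AP-AP). The
    theta dB gap between conditions and the noise scale are free parameters
    of the generator, chosen so the condition effect is detectable in a
    cohort of 29 (see docs/methods.md).
    """

    n_participants: int = 29
    n_blocks: int = 7
    sampling_rate_hz: float = 512.0
    channels: tuple[str, ...] = ("Fz", "FCz", "Cz", "Pz", "EOG")
    noise_exponent: float = 1.0
    noise_scale_uv: float = 10.0
    theta_center_hz: float = 5.5
    theta_mean_db: dict = field(default_factory=lambda: {"AV-AV": 4.0, "AP-AP": 0.0})
    theta_trial_sd_db: float = 2.0
    theta_base_amp_uv: float = 10.0
    theta_onset_ms: float = 0.0
    theta_offset_ms: float = 3000.0
    rt_intercept_ms: dict = field(default_factory=lambda: {"AV-AV": 5774.0, "AP-AP": 4601.0})
    rt_theta_slope_ms_per_db: dict = field(default_factory=lambda: {"AV-AV": -205.0, "AP-AP": -94.0})
    rt_noise_sd_ms: float = 1000.0
    rt_participant_sd_ms: float = 1000.0
    rt_effect_sd_ms: float = 800.0
    rt_floor_ms: float = 200.0
    erp_components: tuple = ((300.0, 40.0, -2.0, "FCz"), (700.0, 60.0, 2.5, "Pz"))
    artifact_rate: float = 0.05
    artifact_amp_uv: float = 200.0
    artifact_duration_ms: float = 150.0
    min_onset_gap_ms: float = 5200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 2 * 40:
            raise ConfigurationError("sampling rate must exceed 80 Hz (2 x 40 Hz)")
        if not 0 <= self.artifact_rate <= 1:
            raise ConfigurationError("artifact_rate must be in [0, 1]")
        if self.theta_center_hz >= self.sampling_rate_hz / 2:
            raise ConfigurationError("theta center above Nyquist")
        for name in ("FCz", "Pz"):
            if name not in self.channels:
                raise ConfigurationError(f"channels must include {name}")
        span = TF_EPOCH_MS[1] - TF_EPOCH_MS[0]
        if self.min_onset_gap_ms < span:
            raise ConfigurationError(
                f"min_onset_gap_ms ({self.min_onset_gap_ms}) shorter than the "
                f"time-frequency epoch span ({span} ms)")
        if self.theta_offset_ms <= self.theta_onset_ms:
            raise ConfigurationError("theta envelope must have positive duration")

    def null(self) -> "SimConfig":
        """Copy with no condition effects (for calibration simulations)."""
        mid_theta = float(np.mean(list(self.theta_mean_db.values())))
        mid_rt = float(np.mean(list(self.rt_intercept_ms.values())))
        return replace(
            self,
            theta_mean_db={"AV-AV": mid_theta, "AP-AP": mid_theta},
            rt_intercept_ms={"AV-AV": mid_rt, "AP-AP": mid_rt},
            rt_theta_slope_ms_per_db={"AV-AV": 0.0, "AP-AP": 0.0},
            rt_effect_sd_ms=0.0,
        )


@dataclass
class GroundTruth:
    """Injected per-trial quantities, aligned 1:1 with emitted trials."""

    participant_id: str
    trial_ids: np.ndarray
    conditions: np.ndarray
    theta_db: np.ndarray  # injected single-trial theta level (dB)
    rt_ms: np.ndarray
    artifact: np.ndarray  # bool per trial
    condition_mean_theta_db: dict = field(default_factory=dict)
    condition_mean_rt_ms: dict = field(default_factory=dict)


def pink_noise(n_samples: int, rate_hz: float, exponent: float,
               rms_uv: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise (seeded phases)."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    scale = np.ones_like(f)
    nonzero = f > 0
    scale[nonzero] = f[nonzero] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n_samples)
    x *= rms_uv / max(x.std(), 1e-12)
    return x


def _draw_trial_effects(config: SimConfig, conditions: np.ndarray,
                        rng: np.random.Generator):
    """Ground-truth theta level (dB) and RT (ms) for each trial."""
    n = conditions.size
    theta = np.empty(n)
    rt = np.empty(n)
    intercept_shift = rng.normal(0.0, config.rt_participant_sd_ms)
    effect_shift = rng.normal(0.0, config.rt_effect_sd_ms) if config.rt_effect_sd_ms else 0.0
    for cond in ("AP-AP", "AV-AV"):
        m = conditions == cond
        theta[m] = config.theta_mean_db[cond] + config.theta_trial_sd_db * rng.standard_normal(m.sum())
        sign = 0.5 if cond == "AV-AV" else -0.5
        intercept = (config.rt_intercept_ms[cond] + intercept_shift
                     + sign * effect_shift)
        # slope acts on the within-condition theta deviation, so the
        # configured intercept stays the condition's expected mean RT
        rt[m] = (intercept
                 + config.rt_theta_slope_ms_per_db[cond] * (theta[m] - config.theta_mean_db[cond])
                 + config.rt_noise_sd_ms * rng.standard_normal(m.sum()))
    np.maximum(rt, config.rt_floor_ms, out=rt)
    return theta, rt


def simulate_recording(
    config: SimConfig,
    trials: list[TrialSpec],
    participant_id: str = "P00",
    rng: np.random.Generator | None = None,
) -> tuple[ContinuousRecording, pd.DataFrame, GroundTruth]:
    """Simulate one participant's continuous recording and behavior.

    The continuous signal is pink noise on every channel, plus per-trial
    theta bursts at FCz (raised-cosine envelope over the configured window,
    amplitude 10^(dB/20) x base amplitude), Gaussian ERP deflections, and
    square artifact transients on a seeded subset of trials. Stimulus and
    response events are marked; RTs follow the configured linear
    theta-coupling model.
    """
    if not trials:
        raise ConfigurationError("no trials to simulate")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.sampling_rate_hz
    conditions = np.array([t.condition for t in trials], dtype=object)
    theta_db, rt_ms = _draw_trial_effects(config, conditions, rng)

    # sequential timeline; the onset-to-onset gap is floored at
    # min_onset_gap_ms (>= the TF epoch span) by stretching the ITI
    pad_ms = -TF_EPOCH_MS[0] + 1500.0
    onsets_ms = np.empty(len(trials))
    t = pad_ms
    for i, tr in enumerate(trials):
        onset = t + tr.fixation_ms
        onsets_ms[i] = onset
        t = max(onset + rt_ms[i] + tr.iti_ms, onset + config.min_onset_gap_ms)
    total_ms = onsets_ms[-1] + rt_ms[-1] + TF_EPOCH_MS[1] + 1500.0
    n_samples = int(np.ceil(total_ms * rate / 1000.0))

    signal = np.empty((len(config.channels), n_samples))
    for c in range(len(config.channels)):
        signal[c] = pink_noise(n_samples, rate, config.noise_exponent,
                               config.noise_scale_uv, rng)

    fcz = config.channels.index("FCz")
    onset_samples = np.round(onsets_ms * rate / 1000.0).astype(int)
    env_n = int(round((config.theta_offset_ms - config.theta_onset_ms) * rate / 1000.0))
    envelope = 0.5 * (1 - np.cos(2 * np.pi * np.arange(env_n) / env_n))  # raised cosine
    env_start = int(round(config.theta_onset_ms * rate / 1000.0))
    tt = np.arange(env_n) / rate
    artifact = rng.random(len(trials)) < config.artifact_rate
    art_n = int(round(config.artifact_duration_ms * rate / 1000.0))
    for i, s0 in enumerate(onset_samples):
        amp = config.theta_base_amp_uv * 10.0 ** (theta_db[i] / 20.0)
        phase = rng.uniform(0, 2 * np.pi)
        burst = amp * envelope * np.cos(2 * np.pi * config.theta_center_hz * tt + phase)
        a = s0 + env_start
        signal[fcz, a:a + env_n] += burst[: max(0, n_samples - a)]
        for lat_ms, width_ms, amp_uv, chan in config.erp_components:
            if chan not in config.channels:
                continue
            ci = config.channels.index(chan)
            g_t = np.arange(int(-4 * width_ms * rate / 1000), int(4 * width_ms * rate / 1000))
            bump = amp_uv * np.exp(-0.5 * (g_t / (width_ms * rate / 1000.0)) ** 2)
            b = s0 + int(round(lat_ms * rate / 1000.0)) + g_t[0]
            signal[ci, b:b + bump.size] += bump[: max(0, n_samples - b)]
        if artifact[i]:
            off = int(round(rng.uniform(0, 1000) * rate / 1000.0))
            a0 = s0 + off
            signal[fcz, a0:a0 + art_n] += config.artifact_amp_uv
            signal[config.channels.index("Pz"), a0:a0 + art_n] += config.artifact_amp_uv

    response_samples = onset_samples + np.round(rt_ms * rate / 1000.0).astype(int)
    trial_ids = np.arange(len(trials))
    events = pd.DataFrame({
        "sample": np.concatenate([onset_samples, response_samples]),
        "kind": ["stimulus"] * len(trials) + ["response"] * len(trials),
        "condition": np.concatenate([conditions, conditions]),
        "trial_id": np.concatenate([trial_ids, trial_ids]),
    }).sort_values("sample", kind="stable").reset_index(drop=True)

    recording = ContinuousRecording(signal, rate, list(config.channels),
                                    events, participant_id)
    behavior = pd.DataFrame({
        "participant_id": participant_id,
        "trial_id": trial_ids,
        "block": [t.block_index for t in trials],
        "condition": conditions,
        "rt_ms": rt_ms,
        "included": True,
    })
    truth = GroundTruth(
        participant_id, trial_ids, conditions, theta_db, rt_ms, artifact,
        {c: float(theta_db[conditions == c].mean()) for c in np.unique(conditions)},
        {c: float(rt_ms[conditions == c].mean()) for c in np.unique(conditions)},
    )
    return recording, behavior, truth


def inject_artifacts(recording: ContinuousRecording, trial_indices,
                     amp_uv: float, duration_ms: float = 150.0,
                     offset_ms: float = 300.0) -> ContinuousRecording:
    """Add a square transient inside each listed trial's epoch window.

    Applied to all non-EOG channels, starting ``offset_ms`` after the trial's
    stimulus onset. Amplitude 0 returns an identical copy.
    """
    out = recording.copy()
    stim = out.events[out.events["kind"] == "stimulus"].set_index("trial_id")
    n = int(round(duration_ms * out.rate_hz / 1000.0))
    off = int(round(offset_ms * out.rate_hz / 1000.0))
    scalp = [i for i, c in enumerate(out.channel_names) if not c.upper().startswith("EOG")]
    for tid in trial_indices:
        s0 = int(stim.loc[tid, "sample"]) + off
        out.signal[np.ix_(scalp, range(s0, min(s0 + n, out.n_samples)))] += amp_uv
    return out


def simulate_cohort(config: SimConfig, trials: list[TrialSpec] | None = None):
    """Simulate all participants; yields (recording, behavior, truth) tuples.

    Each participant gets an independently seeded RNG stream (spawned from
    ``config.seed``) and, unless a fixed trial list is supplied, a fresh
    seeded trial randomization.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    pos, neg = default_characteristics()
    for p, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        ptrials = trials if trials is not None else build_trial_sequence(
            pos, neg, n_blocks=config.n_blocks,
            rng_seed=int(ss.generate_state(1)[0] % (2**31)))
        yield simulate_recording(config, ptrials, f"P{p:02d}", rng)


def simulate_behavior_cohort(config: SimConfig,
                             n_trials_per_condition: int | None = None) -> pd.DataFrame:
    """Ground-truth-level cohort: per-trial theta (dB) and RT, no EEG.

    Fast path for behavioral statistics and mixed-model recovery; uses the
    exact same trial-effect model as :func:`simulate_recording`.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    if n_trials_per_condition is None:
        n_trials_per_condition = config.n_blocks * 21
    conditions = np.array(["AP-AP", "AV-AV"] * n_trials_per_condition, dtype=object)
    frames = []
    for p, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        theta, rt = _draw_trial_effects(config, conditions, rng)
        frames.append(pd.DataFrame({
            "participant_id": f"P{p:02d}",
            "trial_id": np.arange(conditions.size),
            "condition": conditions,
            "theta_db": theta,
            "rt_ms": rt,
            "included": True,
        }))
    return pd.concat(frames, ignore_index=True)
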