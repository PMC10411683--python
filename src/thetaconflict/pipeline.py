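"""End-to-end pipeline: simulate -> preprocess -> TF -> ERP -> stats.

Configuration is one mapping with per-stage sections; unknown keys are
rejected before any stage runs. The pipeline is deterministic under a fixed
config + seed: the consolidated report contains no timestamps and its JSON
is written with sorted keys.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from thetaconflict import erp as erp_mod
from thetaconflict import preprocessing as pp
from thetaconflict import simulate as sim
from thetaconflict import stats as stats_mod
from thetaconflict import time_frequency as tfr_mod
from thetaconflict.exceptions import ConfigurationError, PipelineError

log = logging.getLogger("thetaconflict")


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ConfigurationError(
            f"unknown keys in config section {section!r}: {sorted(unknown)}")


@dataclass
class PreprocessConfig:
    target_rate_hz: float = 512.0
    highpass_hz: float = 0.1
    filter_order: int = 2
    erp_lowpass_hz: float = 30.0
    erp_epoch_ms: tuple = (-500.0, 2000.0)
    erp_baseline_ms: tuple = (-500.0, 0.0)
    tf_epoch_ms: tuple = (-1000.0, 4000.0)
    response_epoch_ms: tuple = (-500.0, 500.0)
    reject_threshold_uv: float = 100.0
    reject_width_ms: float = 100.0
    reject_step_ms: float = 50.0
    auto_threshold: bool = False
    auto_target_fraction: float = 0.15
    max_rejected_fraction: float = 0.25


@dataclass
class TFRConfig:
    f_min: float = 3.0
    f_max: float = 40.0
    n_freqs: int = 38
    c_min: float = 3.0
    c_max: float = 8.0
    baseline_ms: tuple = (-1000.0, 0.0)
    band_hz: tuple = (3.2, 7.7)
    window_ms: tuple = (0.0, 3000.0)
    per_trial_baseline: bool = False


@dataclass
class StatsConfig:
    n_permutations: int = 1000
    cluster_forming_alpha: float = 0.05
    cluster_decimate: int = 1  # keep every k-th timepoint of the theta time course
    rt_outlier_k_sd: float = 3.0


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: sim.SimConfig = field(default_factory=sim.SimConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    tfr: TFRConfig = field(default_factory=TFRConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        _check_keys("<root>", d, {"seed", "simulate", "preprocess", "tfr", "stats"})
        sections = {}
        for name, klass in (("simulate", sim.SimConfig),
                            ("preprocess", PreprocessConfig),
                            ("tfr", TFRConfig), ("stats", StatsConfig)):
            given = dict(d.get(name, {}))
            _check_keys(name, given, [f.name for f in dataclasses.fields(klass)])
            for key, val in given.items():
                if isinstance(val, list):
                    given[key] = tuple(val)
            sections[name] = klass(**given)
        cfg = cls(seed=int(d.get("seed", 0)), **sections)
        cfg.simulate.seed = cfg.seed
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def preprocess_participant(recording, cfg: PreprocessConfig):
    """Filter, re-reference, epoch, baseline and artifact-flag one recording.

    Returns (erp_epochs, tf_epochs, response_epochs) with shared rejection
    flags: a trial flagged on the stimulus-locked ERP epochs is flagged on
    all three sets.
    """
    if recording.rate_hz != cfg.target_rate_hz:
        recording = pp.downsample(recording, cfg.target_rate_hz)
    recording = pp.butterworth_filter(recording, "highpass", cfg.highpass_hz,
                                      cfg.filter_order)
    recording = pp.rereference_average(recording)

    erp_epochs = pp.extract_epochs(recording, "stimulus", cfg.erp_epoch_ms)
    erp_epochs = pp.baseline_correct(erp_epochs, cfg.erp_baseline_ms)
    threshold = cfg.reject_threshold_uv
    if cfg.auto_threshold:
        threshold = pp.calibrate_threshold(
            erp_epochs, cfg.auto_target_fraction,
            window_width_ms=cfg.reject_width_ms,
            window_step_ms=cfg.reject_step_ms)
    erp_epochs = pp.peak_to_peak_reject(
        erp_epochs, threshold, cfg.reject_width_ms, cfg.reject_step_ms)

    tf_epochs = pp.extract_epochs(recording, "stimulus", cfg.tf_epoch_ms)
    resp_epochs = pp.extract_epochs(recording, "response", cfg.response_epoch_ms)
    resp_epochs = pp.baseline_correct(
        resp_epochs, (cfg.response_epoch_ms[0], cfg.response_epoch_ms[1]))

    flagged = set(erp_epochs.trial_ids[erp_epochs.rejected])
    for eps in (tf_epochs, resp_epochs):
        eps.rejected |= np.isin(eps.trial_ids, list(flagged))
    return erp_epochs, tf_epochs, resp_epochs


def analyze_participant_tf(tf_epochs, cfg: TFRConfig):
    """Wavelet decomposition at FCz -> per-trial theta values and
    condition-level summaries for one participant."""
    bank = tfr_mod.build_wavelet_bank(tf_epochs.rate_hz, cfg.f_min, cfg.f_max,
                                      cfg.n_freqs, cfg.c_min, cfg.c_max)
    keep = ~tf_epochs.rejected
    if not keep.any():
        raise PipelineError("time-frequency stage: all trials rejected")
    kept = tf_epochs.copy()
    kept.data = kept.data[keep]
    kept.conditions = kept.conditions[keep]
    kept.trial_ids = kept.trial_ids[keep]
    kept.rejected = np.zeros(keep.sum(), dtype=bool)
    raw = tfr_mod.morlet_power(kept, "FCz", bank)
    per_trial_db = tfr_mod.db_normalize(raw, cfg.baseline_ms,
                                        per_trial=cfg.per_trial_baseline)
    trial_summary = tfr_mod.theta_summary(per_trial_db, cfg.band_hz, cfg.window_ms)
    cond_db = tfr_mod.db_normalize(tfr_mod.condition_average(raw), cfg.baseline_ms)
    cond_summary = tfr_mod.theta_summary(cond_db, cfg.band_hz, cfg.window_ms)
    return trial_summary, cond_summary


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full simulated-cohort analysis and return the run report."""
    report: dict = {"config_hash": config.hash(), "seed": config.seed}
    scfg = config.simulate

    log.info("stage simulate: %d participants", scfg.n_participants)
    cohort = list(sim.simulate_cohort(scfg))
    report["n_participants_simulated"] = len(cohort)
    report["n_trials_per_participant"] = int(len(cohort[0][1]))

    log.info("stage preprocess")
    erp_sets, tf_sets, resp_sets = {}, {}, {}
    behavior_frames = []
    try:
        for recording, behavior, _truth in cohort:
            pid = recording.participant_id
            e, t, r = preprocess_participant(recording, config.preprocess)
            erp_sets[pid], tf_sets[pid], resp_sets[pid] = e, t, r
            behavior_frames.append(behavior)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"preprocess stage failed for participant "
                            f"{recording.participant_id}: {exc}") from exc

    kept, excluded, reject_report = pp.exclude_participants(
        erp_sets, config.preprocess.max_rejected_fraction)
    report["participants_kept"] = kept
    report["participants_excluded"] = excluded
    report["rejection"] = reject_report.to_dict(orient="records")
    if len(kept) < 2:
        raise PipelineError("exclusion stage: no participants remain "
                            f"(kept {len(kept)}, need >= 2)")

    log.info("stage behavior: %d participants kept", len(kept))
    behavior = pd.concat(behavior_frames, ignore_index=True)
    behavior = behavior[behavior["participant_id"].isin(kept)]
    behavior = behavior[behavior["rt_ms"] > 0]
    from thetaconflict.task_design import exclude_rt_outliers, excluded_fraction
    behavior = exclude_rt_outliers(behavior, config.stats.rt_outlier_k_sd)
    report["rt_excluded_fraction"] = excluded_fraction(behavior)
    inc = behavior[behavior["included"]]
    means = inc.groupby(["participant_id", "condition"])["rt_ms"].mean().unstack()
    rt_test = stats_mod.paired_t_test(means["AV-AV"].to_numpy(),
                                      means["AP-AP"].to_numpy(), "one_sided")
    report["behavior"] = {
        "rt_mean_ms": {c: float(inc[inc.condition == c].rt_ms.mean())
                       for c in ("AP-AP", "AV-AV")},
        "rt_sd_ms": {c: float(means[c].std(ddof=1)) for c in ("AP-AP", "AV-AV")},
        "paired_t": json.loads(rt_test.to_json("rt_av_vs_ap")),
    }

    log.info("stage time-frequency")
    trial_rows, cond_rows, courses = [], [], {"AP-AP": [], "AV-AV": []}
    course_t = None
    for pid in kept:
        trial_summary, cond_summary = analyze_participant_tf(tf_sets[pid], config.tfr)
        trial_rows.append(trial_summary.per_trial)
        for cond in ("AP-AP", "AV-AV"):
            cond_rows.append({"participant_id": pid, "condition": cond,
                              "theta_sum_db": cond_summary.sum_db[cond]})
            courses[cond].append(cond_summary.time_course[cond])
        course_t = cond_summary.time_course_ms
    theta_trials = pd.concat(trial_rows, ignore_index=True)
    theta_conditions = pd.DataFrame(cond_rows)

    log.info("stage stats: theta tests")
    theta_test = stats_mod.theta_condition_test(theta_conditions)
    report["theta"] = {
        "condition_sum_db": {
            c: float(theta_conditions[theta_conditions.condition == c]
                     .theta_sum_db.mean()) for c in ("AP-AP", "AV-AV")},
        "paired_t": json.loads(theta_test.to_json("theta_av_vs_ap")),
    }
    dec = max(1, config.stats.cluster_decimate)
    cluster = stats_mod.cluster_permutation_paired(
        np.stack(courses["AV-AV"])[:, ::dec], np.stack(courses["AP-AP"])[:, ::dec],
        course_t[::dec], config.stats.n_permutations,
        config.stats.cluster_forming_alpha, seed=config.seed)
    report["cluster_test"] = cluster.to_dict()

    log.info("stage ERP")
    measures = []
    for pid in kept:
        for cond in ("AP-AP", "AV-AV"):
            stim_erp = erp_mod.average_erp(erp_sets[pid], cond,
                                           config.preprocess.erp_lowpass_hz)
            resp_erp = erp_mod.average_erp(resp_sets[pid], cond,
                                           config.preprocess.erp_lowpass_hz)
            measures.append(erp_mod.measure_component(stim_erp, "N2"))
            measures.append(erp_mod.measure_component(stim_erp, "LPC"))
            measures.append(erp_mod.measure_component(resp_erp, "CRN"))
    erp_table = erp_mod.measures_table(measures)
    report["erp"] = {}
    for comp in ("N2", "CRN", "LPC"):
        sub = [m for m in measures if m.component == comp]
        entry = {"mean_amplitude_uV": {
            c: float(np.mean([m.amplitude_uv for m in sub if m.condition == c]))
            for c in ("AP-AP", "AV-AV")}}
        entry["amplitude_t"] = json.loads(
            erp_mod.compare_components(sub, "amplitude").to_json(f"{comp}_amplitude"))
        if comp != "LPC":
            entry["latency_t"] = json.loads(
                erp_mod.compare_components(sub, "latency").to_json(f"{comp}_latency"))
        report["erp"][comp] = entry

    log.info("stage stats: single-trial mixed model")
    merged = theta_trials.merge(
        behavior[behavior["included"]][["participant_id", "trial_id", "rt_ms"]],
        on=["participant_id", "trial_id"], how="inner")
    lmm = stats_mod.fit_random_intercept_lmm(merged, theta_col="theta_mean_db")
    slopes = stats_mod.per_condition_slopes(merged, theta_col="theta_mean_db")
    report["lmm"] = {
        "coefficients": lmm.params.to_dict(orient="records"),
        "random_intercept_variance": lmm.random_intercept_variance,
        "residual_variance": lmm.residual_variance,
        "n_obs": lmm.n_obs, "n_groups": lmm.n_groups,
        "per_condition_theta_slope": {
            c: float(f.coef("theta")["estimate"]) for c, f in slopes.items()},
    }

    if out_dir is not None:
        from pathlib import Path

        from thetaconflict.io import write_report
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        theta_trials.to_csv(out / "theta_trials.csv", index=False)
        theta_conditions.to_csv(out / "theta_conditions.csv", index=False)
        erp_table.to_csv(out / "erp_components.csv", index=False)
        reject_report.to_csv(out / "rejection_report.csv", index=False)
        behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
        write_report(report, out / "report.json")
    return report
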