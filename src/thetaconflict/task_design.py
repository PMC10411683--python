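"""Motivational-conflict task structure and behavioral statistics.

The task pits two same-valence personal characteristics against each other:
a pair of desirable ones forms an approach-approach (AP-AP) conflict, a pair
of undesirable ones an avoidance-avoidance (AV-AV) conflict. With seven
characteristics per valence every unordered pair appears once per block
(21 + 21 = 42 trials), and seven blocks give 294 trials.

Behavioral analysis: per-participant reaction-time outlier exclusion
(±k s.d.), paired t-tests with Cohen's d for paired data, and an a-priori
power analysis via the noncentral t distribution.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from thetaconflict.exceptions import DegenerateInputError, InvalidInputError

ITI_CHOICES_MS = (1500, 2000, 2500)
FIXATION_MS = 750


@dataclass(frozen=True)
class CharacteristicSet:
    """A valenced set of personal-characteristic labels (e.g. "Smart", "Rich")."""

    labels: tuple[str, ...]
    valence: str  # "positive" or "negative"

    def __post_init__(self) -> None:
        if self.valence not in ("positive", "negative"):
            raise InvalidInputError(f"valence must be positive/negative, got {self.valence!r}")
        if len(self.labels) < 2:
            raise InvalidInputError("need at least 2 characteristic labels")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidInputError("characteristic labels must be unique")
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def condition(self) -> str:
        return "AP-AP" if self.valence == "positive" else "AV-AV"


@dataclass(frozen=True)
class TrialSpec:
    """One trial: a left/right pair of labels plus its timing parameters."""

    block_index: int  # 1-based
    trial_index: int  # 1-based within block
    condition: str  # "AP-AP" or "AV-AV"
    left_label: str
    right_label: str
    fixation_ms: int = FIXATION_MS
    iti_ms: int = 2000

    def __post_init__(self) -> None:
        if self.left_label == self.right_label:
            raise InvalidInputError("left and right labels must differ")
        if self.condition not in ("AP-AP", "AV-AV"):
            raise InvalidInputError(f"unknown condition {self.condition!r}")


@dataclass
class PairedTestResult:
    """Paired t-test output with Cohen's d for paired samples."""

    t_statistic: float
    df: int
    p_value: float
    cohens_d: float
    tail: str  # "one_sided" or "two_sided"
    n: int

    def to_json(self, test: str = "paired_t") -> str:
        return json.dumps({"test": test, "t": self.t_statistic, "df": self.df,
                           "p": self.p_value, "d": self.cohens_d,
                           "tail": self.tail, "n": self.n})


def generate_conflict_pairs(characteristics: CharacteristicSet) -> list[tuple[str, str]]:
    """All C(n, 2) unordered label pairs, in lexicographic order.

    Seven characteristics yield the task's 21 conflicts per valence.
    """
    labels = sorted(characteristics.labels)
    return list(itertools.combinations(labels, 2))


def build_trial_sequence(
    positive: CharacteristicSet,
    negative: CharacteristicSet,
    n_blocks: int = 7,
    rng_seed: int = 0,
) -> list[TrialSpec]:
    """Seeded-random trial sequence: every pair of both valences once per block.

    Within a block the AP-AP and AV-AV pairs are interleaved by a uniform
    shuffle; left/right placement is an independent fair coin; the
    inter-trial interval is drawn uniformly from {1500, 2000, 2500} ms.
    """
    if positive.valence != "positive" or negative.valence != "negative":
        raise InvalidInputError("pass (positive, negative) characteristic sets")
    if n_blocks < 1:
        raise InvalidInputError("n_blocks must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ap_pairs = generate_conflict_pairs(positive)
    av_pairs = generate_conflict_pairs(negative)
    trials: list[TrialSpec] = []
    for block in range(1, n_blocks + 1):
        block_pairs = [("AP-AP", p) for p in ap_pairs] + [("AV-AV", p) for p in av_pairs]
        order = rng.permutation(len(block_pairs))
        for idx, k in enumerate(order, start=1):
            condition, (a, b) = block_pairs[k]
            if rng.random() < 0.5:
                a, b = b, a
            trials.append(TrialSpec(
                block_index=block, trial_index=idx, condition=condition,
                left_label=a, right_label=b,
                iti_ms=int(rng.choice(ITI_CHOICES_MS)),
            ))
    return trials


def trials_to_events_tsv(trials: list[TrialSpec], path,
                         response_times_ms=None) -> pd.DataFrame:
    """Serialize a trial sequence as a BIDS-style events table (TSV).

    Onsets (seconds) accumulate fixation + response time + ITI; response time
    falls back to "n/a" when not supplied.
    """
    rows = []
    t = 0.0
    for i, tr in enumerate(trials):
        t += tr.fixation_ms / 1000.0
        rt = None if response_times_ms is None else float(response_times_ms[i])
        rows.append({
            "onset": round(t, 4),
            "duration": "n/a" if rt is None else round(rt / 1000.0, 4),
            "trial_type": tr.condition,
            "response_time": "n/a" if rt is None else round(rt / 1000.0, 4),
            "block": tr.block_index,
        })
        t += (0.0 if rt is None else rt / 1000.0) + tr.iti_ms / 1000.0
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return frame


def exclude_rt_outliers(table: pd.DataFrame, k_sd: float = 3.0) -> pd.DataFrame:
    """Flag trials whose RT deviates more than ``k_sd`` s.d. from the
    participant's mean RT.

    Single pass: the mean/s.d. are computed once per participant over that
    participant's currently-included rows; the returned copy has ``included``
    set False for flagged rows. Participants with fewer than two included
    trials are kept untouched (s.d. undefined) with a warning.
    """
    if table.empty:
        raise InvalidInputError("behavioral table is empty")
    for col in ("participant_id", "rt_ms"):
        if col not in table.columns:
            raise InvalidInputError(f"behavioral table missing column {col!r}")
    out = table.copy()
    if "included" not in out.columns:
        out["included"] = True
    for pid, grp in out.groupby("participant_id", sort=False):
        inc = grp[grp["included"]]
        if len(inc) < 2:
            warnings.warn(
                f"participant {pid}: <2 included trials, s.d. undefined; "
                "keeping all trials", stacklevel=2)
            continue
        mu = inc["rt_ms"].mean()
        sd = inc["rt_ms"].std(ddof=1)
        if sd == 0:
            continue
        bad = inc.index[(inc["rt_ms"] - mu).abs() > k_sd * sd]
        out.loc[bad, "included"] = False
    return out


def excluded_fraction(table: pd.DataFrame) -> float:
    return float(1.0 - table["included"].mean())


def paired_t_test(x, y, tail: str = "two_sided") -> PairedTestResult:
    """Paired t-test on participant-aligned samples.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x - y; Cohen's d for paired data
    is mean(d)/sd(d). One-sided tests the alternative mean(d) > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 2:
        raise InvalidInputError("need at least 2 pairs")
    if tail not in ("one_sided", "two_sided"):
        raise InvalidInputError(f"unknown tail {tail!r}")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            # identical paired samples: t = 0 by convention
            p = 0.5 if tail == "one_sided" else 1.0
            return PairedTestResult(0.0, n - 1, p, 0.0, tail, n)
        raise DegenerateInputError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    if tail == "one_sided":
        p = float(st.t.sf(t, df))
    else:
        p = float(2 * st.t.sf(abs(t), df))
    return PairedTestResult(float(t), df, p, float(d.mean() / sd), tail, n)


def paired_t_power(n: int, d: float, alpha: float, tail: str) -> float:
    """Power of an n-pair t-test at standardized effect d (noncentral t)."""
    df = n - 1
    ncp = d * np.sqrt(n)
    if tail == "two_sided":
        tc = st.t.ppf(1 - alpha / 2, df)
        return float(1 - st.nct.cdf(tc, df, ncp) + st.nct.cdf(-tc, df, ncp))
    tc = st.t.ppf(1 - alpha, df)
    return float(1 - st.nct.cdf(tc, df, ncp))


def required_sample_size(d: float, alpha: float = 0.05, power: float = 0.80,
                         tail: str = "two_sided", n_max: int = 10**6) -> int:
    """Smallest n whose paired t-test attains the requested power.

    The defaults (d = 1, alpha = .05, power = .80, two-sided) give n = 10.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise InvalidInputError("alpha and power must be in (0, 1)")
    if d <= 0:
        raise InvalidInputError("d must be positive")
    if tail not in ("one_sided", "two_sided"):
        raise InvalidInputError(f"unknown tail {tail!r}")
    n = 2
    while n <= n_max:
        if paired_t_power(n, d, alpha, tail) >= power:
            return n
        n += 1
    raise InvalidInputError(f"power {power} unattainable with n <= {n_max}")
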