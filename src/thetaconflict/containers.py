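"""In-memory containers shared by all pipeline stages.

Signal values are microvolts throughout. Events are a pandas DataFrame with
columns ``sample`` (int, 0-based), ``kind`` ("stimulus" or "response"),
``condition`` ("AP-AP" or "AV-AV"), and ``trial_id`` (int, unique per
recording). Containers round-trip through a single HDF5 file whose metadata
is stored as a JSON string attribute.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from thetaconflict.exceptions import InvalidInputError

EVENT_COLUMNS = ("sample", "kind", "condition", "trial_id")

CONDITIONS = ("AP-AP", "AV-AV")


def _events_frame(events: pd.DataFrame | None) -> pd.DataFrame:
    if events is None:
        return pd.DataFrame({c: [] for c in EVENT_COLUMNS})
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise InvalidInputError(f"events table missing columns: {sorted(missing)}")
    return events.reset_index(drop=True)


@dataclass
class ContinuousRecording:
    """A multichannel continuous EEG recording with event markers."""

    signal: np.ndarray  # channels x samples, microvolts
    rate_hz: float
    channel_names: list[str]
    events: pd.DataFrame = None  # type: ignore[assignment]
    participant_id: str = "P00"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise InvalidInputError("signal must be channels x samples")
        if len(self.channel_names) != self.signal.shape[0]:
            raise InvalidInputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise InvalidInputError("channel names must be unique")
        self.events = _events_frame(self.events)
        if len(self.events):
            s = self.events["sample"].to_numpy()
            if s.min() < 0 or s.max() >= self.n_samples:
                raise InvalidInputError("event sample index outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise InvalidInputError(
                f"channel {name!r} not in recording (have {self.channel_names})"
            ) from None

    def get_channel(self, name: str) -> np.ndarray:
        return self.signal[self.channel_index(name)]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            self.signal.copy(), self.rate_hz, list(self.channel_names),
            self.events.copy(), self.participant_id,
        )

    def save(self, path) -> None:
        _save_h5(path, "continuous", {"signal": self.signal},
                 {"rate_hz": self.rate_hz, "channel_names": self.channel_names,
                  "participant_id": self.participant_id},
                 events=self.events)

    @classmethod
    def load(cls, path) -> "ContinuousRecording":
        arrays, meta, events = _load_h5(path, "continuous")
        return cls(arrays["signal"], meta["rate_hz"], meta["channel_names"],
                   events, meta["participant_id"])


@dataclass
class EpochSet:
    """Fixed-length trials cut around a lock event.

    ``data`` is trials x channels x samples; the time axis starts at
    ``t0_offset_ms`` relative to the lock event (stimulus or response).
    ``rejected`` flags are only ever set by artifact-rejection operations.
    """

    data: np.ndarray
    t0_offset_ms: float
    rate_hz: float
    lock: str
    channel_names: list[str]
    conditions: np.ndarray  # str per trial
    trial_ids: np.ndarray  # int per trial
    rejected: np.ndarray = None  # type: ignore[assignment]
    participant_id: str = "P00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise InvalidInputError("epoch data must be trials x channels x samples")
        if self.lock not in ("stimulus", "response"):
            raise InvalidInputError(f"unknown lock {self.lock!r}")
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64)
        if self.rejected is None:
            self.rejected = np.zeros(self.n_trials, dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        for name, arr in (("conditions", self.conditions),
                          ("trial_ids", self.trial_ids),
                          ("rejected", self.rejected)):
            if len(arr) != self.n_trials:
                raise InvalidInputError(f"{name} length != number of trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time of each sample relative to the lock event, in ms."""
        return self.t0_offset_ms + np.arange(self.n_samples) * 1000.0 / self.rate_hz

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise InvalidInputError(
                f"channel {name!r} not in epochs (have {self.channel_names})"
            ) from None

    def sample_window(self, start_ms: float, end_ms: float) -> slice:
        """Half-open [start, end) window in ms -> slice into the sample axis."""
        t = self.times_ms
        if start_ms >= end_ms:
            raise InvalidInputError("window start must precede end")
        if start_ms < t[0] - 0.5 or end_ms > t[-1] + 1000.0 / self.rate_hz + 0.5:
            raise InvalidInputError(
                f"window [{start_ms}, {end_ms}) ms outside epoch span "
                f"[{t[0]}, {t[-1]}] ms"
            )
        idx = np.flatnonzero((t >= start_ms - 1e-9) & (t < end_ms - 1e-9))
        if idx.size == 0:
            raise InvalidInputError("window contains no samples")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def mask(self, condition: str | None = None, include_rejected: bool = False):
        m = np.ones(self.n_trials, dtype=bool)
        if condition is not None:
            m &= self.conditions == condition
        if not include_rejected:
            m &= ~self.rejected
        return m

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.t0_offset_ms, self.rate_hz, self.lock,
            list(self.channel_names), self.conditions.copy(),
            self.trial_ids.copy(), self.rejected.copy(), self.participant_id,
        )

    def save(self, path) -> None:
        _save_h5(path, "epochs",
                 {"data": self.data,
                  "trial_ids": self.trial_ids,
                  "rejected": self.rejected.astype(np.int8),
                  "conditions": np.array([c.encode() for c in self.conditions])},
                 {"t0_offset_ms": self.t0_offset_ms, "rate_hz": self.rate_hz,
                  "lock": self.lock, "channel_names": self.channel_names,
                  "participant_id": self.participant_id})

    @classmethod
    def load(cls, path) -> "EpochSet":
        arrays, meta, _ = _load_h5(path, "epochs")
        conditions = np.array([c.decode() for c in arrays["conditions"]], dtype=object)
        return cls(arrays["data"], meta["t0_offset_ms"], meta["rate_hz"],
                   meta["lock"], meta["channel_names"], conditions,
                   arrays["trial_ids"], arrays["rejected"].astype(bool),
                   meta["participant_id"])


@dataclass
class TFDecomposition:
    """Time-frequency power: trials (or conditions) x frequencies x timepoints.

    Raw wavelet power is non-negative; after :func:`db_normalize` the values
    are decibels relative to the pre-stimulus baseline and ``normalized`` is
    True. ``labels`` holds the condition of each trial (per-trial maps) or the
    condition name of each averaged map.
    """

    power: np.ndarray
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    labels: np.ndarray
    normalized: bool = False
    baseline_window_ms: tuple[float, float] | None = None
    channel: str = "FCz"
    participant_id: str = "P00"
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=np.float64)
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.power.ndim != 3:
            raise InvalidInputError("power must be maps x frequencies x timepoints")
        if self.power.shape[1] != self.freqs_hz.size:
            raise InvalidInputError("frequency axis mismatch")
        if self.power.shape[2] != self.times_ms.size:
            raise InvalidInputError("time axis mismatch")
        if not self.normalized and np.any(self.power < 0):
            raise InvalidInputError("raw power must be non-negative")

    @property
    def n_maps(self) -> int:
        return self.power.shape[0]

    def time_window(self, start_ms: float, end_ms: float) -> slice:
        if start_ms >= end_ms:
            raise InvalidInputError("window start must precede end")
        idx = np.flatnonzero((self.times_ms >= start_ms - 1e-9)
                             & (self.times_ms < end_ms - 1e-9))
        if idx.size == 0:
            raise InvalidInputError("window contains no timepoints")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def band_indices(self, low_hz: float, high_hz: float) -> np.ndarray:
        """Frequency bins whose center lies in [low, high], inclusive."""
        idx = np.flatnonzero((self.freqs_hz >= low_hz - 1e-12)
                             & (self.freqs_hz <= high_hz + 1e-12))
        if idx.size == 0:
            raise InvalidInputError(f"no frequency bins in [{low_hz}, {high_hz}] Hz")
        return idx

    def save(self, path) -> None:
        arrays = {"power": self.power, "freqs_hz": self.freqs_hz,
                  "times_ms": self.times_ms,
                  "labels": np.array([str(c).encode() for c in self.labels])}
        if self.trial_ids is not None:
            arrays["trial_ids"] = np.asarray(self.trial_ids, dtype=np.int64)
        _save_h5(path, "tfr", arrays,
                 {"normalized": self.normalized,
                  "baseline_window_ms": list(self.baseline_window_ms)
                  if self.baseline_window_ms else None,
                  "channel": self.channel,
                  "participant_id": self.participant_id})

    @classmethod
    def load(cls, path) -> "TFDecomposition":
        arrays, meta, _ = _load_h5(path, "tfr")
        bw = meta["baseline_window_ms"]
        return cls(arrays["power"], arrays["freqs_hz"], arrays["times_ms"],
                   np.array([c.decode() for c in arrays["labels"]], dtype=object),
                   meta["normalized"], tuple(bw) if bw else None,
                   meta["channel"], meta["participant_id"],
                   arrays.get("trial_ids"))


def _save_h5(path, container_kind: str, arrays: dict, meta: dict,
             events: pd.DataFrame | None = None) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["container"] = container_kind
        f.attrs["meta"] = json.dumps(meta)
        for name, arr in arrays.items():
            f.create_dataset(name, data=arr)
        if events is not None:
            g = f.create_group("events")
            g.create_dataset("sample", data=events["sample"].to_numpy(np.int64))
            g.create_dataset("trial_id", data=events["trial_id"].to_numpy(np.int64))
            for col in ("kind", "condition"):
                g.create_dataset(
                    col, data=np.array([s.encode() for s in events[col]]))


def _load_h5(path, expected_kind: str):
    import h5py

    with h5py.File(path, "r") as f:
        kind = f.attrs["container"]
        if kind != expected_kind:
            raise InvalidInputError(
                f"{path} holds a {kind!r} container, expected {expected_kind!r}")
        meta = json.loads(f.attrs["meta"])
        arrays = {k: f[k][()] for k in f.keys() if k != "events"}
        events = None
        if "events" in f:
            g = f["events"]
            events = pd.DataFrame({
                "sample": g["sample"][()],
                "kind": [s.decode() for s in g["kind"][()]],
                "condition": [s.decode() for s in g["condition"][()]],
                "trial_id": g["trial_id"][()],
            })
    return arrays, meta, events
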