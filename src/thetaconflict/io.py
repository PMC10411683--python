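"""File formats: BioSemi BDF, BIDS-style events TSV, and report JSON.

The internal container format (HDF5 + JSON metadata) lives on the container
classes themselves; this module adds BDF export/import for interoperability
with acquisition-side tooling. BDF is the 24-bit BioSemi variant of EDF:
a 256-byte fixed header, 256 header bytes per channel, then data records of
little-endian 3-byte two's-complement integers. Reading goes through MNE
when available; the writer is self-contained.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from thetaconflict.containers import ContinuousRecording
from thetaconflict.exceptions import InvalidInputError

_DIG_MIN, _DIG_MAX = -8388608, 8388607


def _field(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")
    if len(b) > width:
        raise InvalidInputError(f"header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_bdf(recording: ContinuousRecording, path) -> None:
    """Write the recording as a 24-bit BDF file (1-second data records).

    Per-channel physical ranges are fitted to the data; the last record is
    zero-padded. Event markers are not embedded (export them separately as
    an events TSV).
    """
    rate = recording.rate_hz
    if abs(rate - round(rate)) > 1e-9:
        raise InvalidInputError("BDF export needs an integer sampling rate")
    spr = int(round(rate))  # samples per 1 s record
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))

    phys_max = np.maximum(np.abs(recording.signal).max(axis=1) * 1.01, 1.0)
    # round to what the 8-char header field actually stores, then scale with
    # the stored value so reader-side gains match exactly
    phys_max = np.array([float(f"{p:.6g}") for p in phys_max])
    gains = phys_max / _DIG_MAX

    header = bytearray()
    header += b"\xffBIOSEMI"
    header += _field(recording.participant_id, 80)
    header += _field("synthetic recording", 80)
    header += _field("01.01.00", 8)
    header += _field("00.00.00", 8)
    header += _field(str(256 * (1 + n_ch)), 8)
    header += _field("24BIT", 44)
    header += _field(str(n_records), 8)
    header += _field("1", 8)
    header += _field(str(n_ch), 4)
    for name in recording.channel_names:
        header += _field(name, 16)
    for _ in range(n_ch):
        header += _field("active electrode", 80)
    for _ in range(n_ch):
        header += _field("uV", 8)
    for p in phys_max:
        header += _field(f"{-p:.6g}"[:8], 8)
    for p in phys_max:
        header += _field(f"{p:.6g}"[:8], 8)
    for _ in range(n_ch):
        header += _field(str(_DIG_MIN), 8)
    for _ in range(n_ch):
        header += _field(str(_DIG_MAX), 8)
    for _ in range(n_ch):
        header += _field("", 80)
    for _ in range(n_ch):
        header += _field(str(spr), 8)
    for _ in range(n_ch):
        header += _field("", 32)

    padded = np.zeros((n_ch, n_records * spr))
    padded[:, : recording.n_samples] = recording.signal
    digital = np.round(padded / gains[:, None]).astype(np.int32)
    np.clip(digital, _DIG_MIN, _DIG_MAX, out=digital)

    with open(path, "wb") as f:
        f.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            # channels sequential within a record; 3-byte little-endian
            b = block.astype("<i4").tobytes()
            arr = np.frombuffer(b, dtype=np.uint8).reshape(-1, 4)[:, :3]
            f.write(arr.tobytes())


def read_bdf(path, events: pd.DataFrame | None = None,
             participant_id: str = "P00") -> ContinuousRecording:
    """Import a BDF file via MNE; attach an externally stored events table."""
    import mne

    raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # Volts -> microvolts
    return ContinuousRecording(signal, float(raw.info["sfreq"]),
                               list(raw.ch_names), events, participant_id)


def read_events_tsv(path) -> pd.DataFrame:
    """Read a BIDS-style events TSV (onset/duration in seconds)."""
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def events_to_marker_table(events_tsv: pd.DataFrame, rate_hz: float) -> pd.DataFrame:
    """Convert a BIDS events table to the internal marker format."""
    rows = []
    for tid, row in enumerate(events_tsv.itertuples(index=False)):
        onset_sample = int(round(row.onset * rate_hz))
        rows.append({"sample": onset_sample, "kind": "stimulus",
                     "condition": row.trial_type, "trial_id": tid})
        if not pd.isna(row.response_time):
            rows.append({"sample": onset_sample + int(round(row.response_time * rate_hz)),
                         "kind": "response", "condition": row.trial_type,
                         "trial_id": tid})
    return pd.DataFrame(rows)


def write_report(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=2, sort_keys=True)
        f.write("\n")
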