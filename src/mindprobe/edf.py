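"""European Data Format (EDF) I/O for 32-channel recordings.

Writing produces plain 16-bit EDF with one-second data records,
physical units in microvolts, and a fixed header date so identical
data yield byte-identical files. Plain EDF has no annotation track, so
probe times travel in the reports CSV / ground-truth sidecar, not in
the signal file. Reading goes through MNE's EDF reader.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from .containers import Recording
from .layout import ChannelLayout, make_layout


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} (> {width})")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path) -> Path:
    """Write a recording as plain 16-bit EDF (physical units uV).

    The last data record is zero-padded to a whole second. Requires an
    integer sample rate.
    """
    fs = recording.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sample rate")
    fs = int(round(fs))
    data = recording.data
    n_ch, n_samp = data.shape
    n_rec = math.ceil(n_samp / fs)
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = data

    # symmetric physical range per channel, one digital step >= resolution
    phys_max = np.maximum(1.0, np.ceil(np.abs(padded).max(axis=1) * 1.05))
    dig_min, dig_max = -32767, 32767

    header = b"".join([
        _field("0", 8),
        _field(f"participant_{recording.participant_id}", 80),
        _field(f"session_{recording.session_id}_{recording.condition}"
               f"_block_{recording.block}", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (n_ch + 1), 8),
        _field("", 44),
        _field(n_rec, 8),
        _field("1", 8),
        _field(n_ch, 4),
    ])
    labels = b"".join(_field(lab, 16) for lab in recording.layout.labels)
    transducer = b"".join(_field("AgAgCl electrode", 80) for _ in range(n_ch))
    dim = b"".join(_field("uV", 8) for _ in range(n_ch))
    pmin = b"".join(_field(f"{-m:.1f}", 8) for m in phys_max)
    pmax = b"".join(_field(f"{m:.1f}", 8) for m in phys_max)
    dmin = b"".join(_field(dig_min, 8) for _ in range(n_ch))
    dmax = b"".join(_field(dig_max, 8) for _ in range(n_ch))
    prefilter = b"".join(_field("", 80) for _ in range(n_ch))
    n_per_rec = b"".join(_field(fs, 8) for _ in range(n_ch))
    reserved = b"".join(_field("", 32) for _ in range(n_ch))

    gain = dig_max / phys_max  # digital units per uV
    digital = np.rint(padded * gain[:, None]).astype("<i2")
    records = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)

    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(labels + transducer + dim + pmin + pmax + dmin + dmax
                 + prefilter + n_per_rec + reserved)
        fh.write(records.tobytes())
    return path


def read_edf(path, probe_times=None, condition: str = "task",
             participant_id: int = 0, session_id: int = 0, block: int = 0,
             layout: ChannelLayout | None = None) -> Recording:
    """Read an EDF file into a Recording (data in uV).

    Channel labels must match the packaged 32-channel layout order.
    Probe times are supplied by the caller (plain EDF carries no event
    track).
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on bad headers
        raise ValueError(f"malformed EDF file {path}: {exc}") from exc
    layout = layout or make_layout()
    got = tuple(raw.ch_names)
    if got != tuple(layout.labels):
        raise ValueError(
            f"channel labels do not match the packaged layout: {got[:4]}...")
    data_uv = raw.get_data() * 1e6
    # trim any zero-padded tail from whole-second records
    return Recording(
        data_uv, float(raw.info["sfreq"]), layout,
        np.asarray(probe_times if probe_times is not None else []),
        condition, participant_id, session_id, block)
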