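"""Deterministic signal conditioning and epoching.

Pipeline order: band-pass filter -> notch filter -> segmentation into
non-overlapping 2-s epochs (with 1-s reflected context on each side for
spectral estimation) -> common average reference. Human-in-the-loop
artifact steps (ICA, visual rejection, channel interpolation) are out of
scope: synthetic inputs are artifact-free, and this module is not
suitable on its own for artifact-laden real recordings.

Time convention: seconds from recording start; epoch cores are half-open
intervals [t_start, t_start + 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .containers import Recording

EPOCH_S = 2.0  # core epoch length, seconds
CONTEXT_S = 1.0  # context attached on each side


@dataclass
class Epoch:
    """One 2-s epoch with 1-s context on each side.

    data is electrode x time covering [t_start - 1, t_start + 3) s; the
    ``core`` property strips the context.
    """

    data: np.ndarray
    t_start: float
    sample_rate: float
    participant_id: int
    session_id: int
    condition: str
    block: int = 0

    @property
    def n_core(self) -> int:
        return int(round(EPOCH_S * self.sample_rate))

    @property
    def core(self) -> np.ndarray:
        ctx = int(round(CONTEXT_S * self.sample_rate))
        return self.data[:, ctx:ctx + self.n_core]


def bandpass_filter(recording: Recording, low_hz: float = 1.0,
                    high_hz: float = 55.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass, applied forward-backward.

    Raises ValueError if a cutoff reaches the Nyquist frequency.
    """
    nyq = recording.sample_rate / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < Nyquist ({nyq})")
    sos = signal.butter(4, (low_hz, high_hz), btype="bandpass",
                        fs=recording.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=filtered)


def notch_filter(recording: Recording, freqs=(60.0, 120.0),
                 quality: float = 30.0) -> Recording:
    """Narrow zero-phase band-stop at each listed frequency (line noise and
    harmonics). An empty frequency list is the identity."""
    nyq = recording.sample_rate / 2.0
    data = recording.data
    for f0 in freqs:
        if not (0 < f0 < nyq):
            raise ValueError(f"notch frequency {f0} must lie below Nyquist ({nyq})")
        b, a = signal.iirnotch(f0, quality, fs=recording.sample_rate)
        data = signal.filtfilt(b, a, data, axis=1)
    return replace(recording, data=data)


def segment_epochs(recording: Recording) -> list[Epoch]:
    """Tile the recording with non-overlapping 2-s epochs from t = 0.

    Each epoch carries 1 s of context on both sides; at the recording
    boundaries the context is obtained by time-reflection. Recordings
    shorter than 2 s yield an empty list.
    """
    fs = recording.sample_rate
    n_core = int(round(EPOCH_S * fs))
    n_ctx = int(round(CONTEXT_S * fs))
    n_epochs = recording.n_samples // n_core
    if n_epochs == 0:
        return []
    padded = np.pad(recording.data, ((0, 0), (n_ctx, n_ctx)), mode="reflect")
    epochs = []
    for k in range(n_epochs):
        start = k * n_core  # core start in original samples
        chunk = padded[:, start:start + n_core + 2 * n_ctx]
        epochs.append(Epoch(chunk.copy(), start / fs, fs,
                            recording.participant_id, recording.session_id,
                            recording.condition, recording.block))
    return epochs


def preprobe_window(epochs: list[Epoch], probe_time: float,
                    window_s: float = 12.0) -> list[Epoch]:
    """Epochs whose cores lie fully within [probe_time - window_s, probe_time).

    window_s is one of {8, 12, 16}. Probes too close to the recording
    start simply return the available subset.
    """
    if window_s not in (8.0, 12.0, 16.0, 8, 12, 16):
        raise ValueError("window_s must be 8, 12, or 16 seconds")
    lo = probe_time - window_s
    return [e for e in epochs
            if e.t_start >= lo - 1e-9 and e.t_start + EPOCH_S <= probe_time + 1e-9]


def common_average_reference(epoch: Epoch) -> Epoch:
    """Re-reference to the instantaneous mean across channels.

    Idempotent; invariant to adding a common constant to every channel.
    Requires at least 2 channels.
    """
    if epoch.data.shape[0] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return replace(epoch, data=data)


def preprocess_recording(recording: Recording, low_hz: float = 1.0,
                         high_hz: float = 55.0,
                         notch_freqs=(60.0, 120.0)) -> list[Epoch]:
    """Full conditioning chain: band-pass, notch, segment, re-reference."""
    rec = bandpass_filter(recording, low_hz, high_hz)
    rec = notch_filter(rec, notch_freqs)
    return [common_average_reference(e) for e in segment_epochs(rec)]
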