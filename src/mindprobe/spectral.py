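"""Periodic (oscillatory) power features via Welch estimation and
aperiodic fit-and-subtract.

Each 2-s epoch becomes a 32 electrode x 27 frequency matrix of
log10-power residuals: the Welch power spectral density on the 4-30 Hz
grid (1-Hz steps) minus a robust linear fit of log10-power against
log10-frequency. The linear fit stands for the aperiodic (1/f)
component; subtracting it in log space leaves narrowband peaks, the
feature used by every downstream stage (864 features per trial).

The Welch dialect is 1-s Hamming-windowed segments stepped by 0.5 s
across the 2-s core (3 segments), which yields the 1-Hz grid natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import Epoch

#: Analysis grid: 4..30 Hz inclusive at 1-Hz steps (27 bins).
FREQS = np.arange(4.0, 31.0, 1.0)

#: Canonical band table; closed integer ranges tiling 4-30 Hz.
BANDS = {
    "low_theta": (4, 5),
    "high_theta": (6, 7),
    "low_alpha": (8, 9),
    "high_alpha": (10, 13),
    "low_beta": (14, 20),
    "high_beta": (21, 30),
}


def band_range(name: str) -> tuple[int, int]:
    """Closed Hz range of a named band (e.g. ``"high_alpha"`` -> (10, 13)).

    Accepts spaces or underscores; unknown names raise KeyError.
    """
    key = name.strip().lower().replace(" ", "_").replace("-", "_")
    if key not in BANDS:
        raise KeyError(f"unknown band {name!r}; known: {sorted(BANDS)}")
    return BANDS[key]


def band_mask(name: str) -> np.ndarray:
    lo, hi = band_range(name)
    return (FREQS >= lo) & (FREQS <= hi)


@dataclass
class RawSpectrum:
    """Welch PSD (uV^2/Hz), electrode x frequency on the 4-30 Hz grid."""

    power: np.ndarray
    freqs: np.ndarray = field(default_factory=lambda: FREQS.copy())


@dataclass
class AperiodicFit:
    """Per-electrode aperiodic parameters: log10-power intercept (offset)
    and 1/f slope magnitude (exponent)."""

    offset: np.ndarray
    exponent: np.ndarray


@dataclass
class SpectralMatrix:
    """Electrode x frequency periodic log10-power residuals.

    provenance records what the matrix summarizes (epoch vs session
    mean, dimension, class end, ids).
    """

    periodic: np.ndarray
    freqs: np.ndarray = field(default_factory=lambda: FREQS.copy())
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.periodic = np.asarray(self.periodic, dtype=float)
        if not np.all(np.isfinite(self.periodic)):
            raise ValueError("periodic matrix must be finite")


def welch_psd(epoch: Epoch) -> RawSpectrum:
    """Welch PSD of the 2-s epoch core on the 4-30 Hz grid.

    Mean of Hamming-windowed periodograms over 1-s segments stepped by
    0.5 s (3 segments), density scaling, no detrending.
    """
    fs = epoch.sample_rate
    nperseg = int(round(fs))
    if epoch.data.shape[1] != 4 * nperseg:
        raise ValueError("epoch must carry a 2-s core with 1-s context "
                         f"(expected {4 * nperseg} samples, "
                         f"got {epoch.data.shape[1]})")
    core = epoch.core
    freqs, pxx = signal.welch(core, fs=fs, window="hamming", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend=False,
                              scaling="density", axis=1)
    sel = np.searchsorted(freqs, FREQS)
    if not np.allclose(freqs[sel], FREQS):
        raise ValueError("sampling rate does not resolve the 1-Hz grid")
    return RawSpectrum(pxx[:, sel])


def fit_aperiodic(spectrum: RawSpectrum, n_refits: int = 2) -> AperiodicFit:
    """Robust per-electrode line fit of log10(power) vs log10(frequency).

    An ordinary least-squares line is fit first; points lying more than
    one residual standard deviation *above* the line (candidate
    oscillatory peaks) are excluded and the line refit, twice. The
    negated slope is the aperiodic exponent.
    """
    power = np.asarray(spectrum.power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive for the log-log fit")
    logf = np.log10(spectrum.freqs)
    logp = np.log10(power)
    n_el = logp.shape[0]
    offset = np.empty(n_el)
    exponent = np.empty(n_el)
    for el in range(n_el):
        keep = np.ones(logf.size, dtype=bool)
        slope, intercept = np.polyfit(logf, logp[el], 1)
        for _ in range(n_refits):
            resid = logp[el] - (intercept + slope * logf)
            sd = resid[keep].std()
            new_keep = resid <= sd
            if new_keep.sum() < 3:
                break
            keep = new_keep
            slope, intercept = np.polyfit(logf[keep], logp[el][keep], 1)
        offset[el] = intercept
        exponent[el] = -slope
    return AperiodicFit(offset, exponent)


def periodic_component(spectrum: RawSpectrum, fit: AperiodicFit,
                       provenance: dict | None = None) -> SpectralMatrix:
    """Subtract the fitted aperiodic line in log10 space.

    periodic[el, f] = log10(power[el, f]) - (offset[el] - exponent[el] * log10(f))
    """
    if fit.offset.shape[0] != spectrum.power.shape[0]:
        raise ValueError("fit and spectrum have different channel counts")
    logf = np.log10(spectrum.freqs)
    aperiodic = fit.offset[:, None] - fit.exponent[:, None] * logf[None, :]
    return SpectralMatrix(np.log10(spectrum.power) - aperiodic,
                          spectrum.freqs.copy(), provenance or {})


def epoch_spectral_matrix(epoch: Epoch) -> SpectralMatrix:
    """Welch PSD, aperiodic fit, and subtraction for one epoch."""
    spec = welch_psd(epoch)
    fit = fit_aperiodic(spec)
    return periodic_component(spec, fit, provenance={
        "kind": "epoch", "t_start": epoch.t_start,
        "participant": epoch.participant_id, "session": epoch.session_id,
        "condition": epoch.condition,
    })


def session_mean_matrix(matrices: list[SpectralMatrix],
                        provenance: dict | None = None) -> SpectralMatrix:
    """Element-wise mean across trials of one session.

    An empty list raises ValueError (callers treat that as an exclusion).
    """
    if not matrices:
        raise ValueError("cannot average an empty list of spectral matrices")
    ref = matrices[0].freqs
    for m in matrices[1:]:
        if not np.array_equal(m.freqs, ref):
            raise ValueError("all matrices must share one frequency grid")
    stacked = np.stack([m.periodic for m in matrices])
    return SpectralMatrix(stacked.mean(axis=0), ref.copy(), provenance or {})
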