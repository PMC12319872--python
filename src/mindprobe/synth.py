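"""Synthetic cohorts of task and rest EEG with planted thought-dimension effects.

The generator emulates the study design this package analyzes: each
participant contributes several ~80-minute task sessions with jittered
experience-sampling probes (~every 120 s, uniform 90-150 s) plus two
5-minute rest blocks per session, recorded from a 32-channel 10-20
montage at 256 Hz.

Signal model
------------
Each channel is the sum of

* a 1/f aperiodic background with per-participant offset and exponent,
  realized by spectrally shaping white noise in the Fourier domain;
* band-limited oscillatory components (narrowband-filtered independent
  noise sources) projected through fixed scalp topographies; and
* one narrowband source per planted effect, restricted to the effect's
  electrodes, whose amplitude during each pre-probe window is scaled by
  ``1 + gain * sign * latent`` for that window's latent thought state.

Latent thought states are piecewise-constant over pre-probe windows and
drawn from a correlated 7-dimensional standard normal; Likert reports
are a noisy affine quantization of the latents. The latent trajectory
and the planted electrode x frequency masks are returned as ground
truth so downstream recovery can be tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .containers import DIMENSIONS, REST_DIMENSIONS, GroundTruth, ProbeReport, Recording
from .layout import CHANNELS_32, ChannelLayout, make_layout

__all__ = [
    "EffectSpec",
    "Oscillator",
    "SynthConfig",
    "Cohort",
    "default_correlation",
    "default_effects",
    "default_oscillators",
    "simulate_latents",
    "latent_to_rating",
    "simulate_session",
    "simulate_rest",
    "simulate_cohort",
]

#: Self-selected activity categories with report frequencies matching the
#: naturalistic-task setting the generator emulates.
ACTIVITY_CATEGORIES = (
    ("reading", 0.32),
    ("writing/editing", 0.14),
    ("watching videos", 0.19),
    ("browsing the internet", 0.11),
    ("cognitively demanding task", 0.23),
    ("nothing", 0.01),
)


@dataclass(frozen=True)
class EffectSpec:
    """A planted coupling between one thought dimension and band power.

    gain is the multiplicative oscillatory-amplitude factor per unit
    latent (dimensionless, >= 0); sign +1 plants more power at the upper
    end of the dimension, -1 at the lower end. amplitude is the base
    standard deviation (microvolts) of the effect's narrowband source.
    """

    dimension: str
    electrodes: tuple[str, ...]
    band: tuple[float, float]
    gain: float
    sign: int = 1
    amplitude: float = 2.0

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if not self.electrodes:
            raise ValueError("effect needs at least one electrode")
        lo, hi = self.band
        if not (4.0 <= lo < hi <= 30.0):
            raise ValueError("effect band must lie within [4, 30] Hz")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


@dataclass(frozen=True)
class Oscillator:
    """A background oscillatory peak with a Gaussian scalp topography."""

    center_hz: float
    bandwidth_hz: float
    amplitude: float  # source standard deviation, microvolts
    topo_center: tuple[float, float]  # 2-D layout coordinates
    topo_width: float


def default_oscillators() -> tuple[Oscillator, ...]:
    """Posterior alpha, frontal theta, and central beta base peaks."""
    return (
        Oscillator(10.0, 2.0, 4.0, (0.0, -0.40), 0.35),
        Oscillator(6.0, 2.0, 2.0, (0.0, 0.35), 0.35),
        Oscillator(20.0, 6.0, 1.5, (0.0, -0.05), 0.50),
    )


_POSTERIOR = ("P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10")
_FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
_CENTRAL = ("FC1", "FC2", "C3", "Cz", "C4", "CP1", "CP2")
_WIDESPREAD = ("F3", "Fz", "F4", "FC1", "FC2", "C3", "Cz", "C4",
               "CP1", "CP2", "P3", "Pz", "P4")


def default_effects(gain: float = 0.3) -> tuple[EffectSpec, ...]:
    """Qualitative planted-effect map (direction and region per dimension).

    Directions follow the qualitative findings for naturalistic tasks:
    off-task and internally oriented thought raise posterior/central low
    alpha, freely moving and self-oriented thought raise frontal low
    alpha, sticky thought raises central high theta, goal-oriented
    thought lowers widespread high beta, and other-oriented thought
    raises widespread low beta. These are test fixtures, not estimates.
    """
    return (
        EffectSpec("off_task", _POSTERIOR, (8.0, 9.0), gain, +1),
        EffectSpec("internal", ("CP1", "CP2", "P3", "Pz", "P4", "O1", "Oz", "O2"),
                   (8.0, 9.0), gain, +1),
        EffectSpec("freely_moving", _FRONTAL, (8.0, 9.0), gain, +1),
        EffectSpec("sticky", _CENTRAL, (6.0, 7.0), gain, +1),
        EffectSpec("goal_oriented", _WIDESPREAD, (21.0, 30.0), gain, -1),
        EffectSpec("self_oriented", _FRONTAL, (8.0, 9.0), gain, +1),
        EffectSpec("other_oriented", _WIDESPREAD, (14.0, 20.0), gain, +1),
    )


def default_correlation() -> np.ndarray:
    """Mild, realistic inter-dimension latent correlation (positive definite)."""
    c = np.eye(7)
    idx = {d: i for i, d in enumerate(DIMENSIONS)}

    def set_(a, b, r):
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r

    set_("off_task", "internal", 0.40)
    set_("off_task", "freely_moving", 0.30)
    set_("off_task", "self_oriented", 0.20)
    set_("internal", "self_oriented", 0.30)
    set_("self_oriented", "other_oriented", 0.15)
    set_("freely_moving", "goal_oriented", -0.30)
    set_("sticky", "goal_oriented", -0.15)
    set_("sticky", "freely_moving", -0.10)
    return c


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults are the emulated study's conditions: 7 participants x 7
    sessions, 80-minute tasks with 35 probes at uniform 90-150 s gaps,
    two 5-minute rest blocks per session, 256 Hz sampling.
    """

    n_participants: int = 7
    n_sessions: int = 7
    task_duration: float = 4800.0
    n_probes: int = 35
    probe_gap: tuple[float, float] = (90.0, 150.0)
    rest_duration: float = 300.0
    n_rest_blocks: int = 2
    sample_rate: float = 256.0
    aperiodic_offset: tuple[float, float] = (0.5, 1.5)
    aperiodic_exponent: tuple[float, float] = (0.8, 1.4)
    oscillators: tuple[Oscillator, ...] = field(default_factory=default_oscillators)
    effects: tuple[EffectSpec, ...] = field(default_factory=default_effects)
    correlation: np.ndarray = field(default_factory=default_correlation)
    report_noise: float = 0.5
    window_s: float = 16.0  # modulated pre-probe interval
    seed: int = 0

    def __post_init__(self):
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (7, 7) or not np.allclose(corr, corr.T):
            raise ValueError("correlation must be a symmetric 7x7 matrix")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("correlation must have unit diagonal")
        if np.linalg.eigvalsh(corr)[0] <= 1e-10:
            raise ValueError("correlation must be positive definite")
        object.__setattr__(self, "correlation", corr)
        lo, hi = self.probe_gap
        if not (0 < lo <= hi):
            raise ValueError("probe_gap must satisfy 0 < min <= max")
        if lo < self.window_s:
            raise ValueError(
                "minimum probe gap must be at least the modulated window "
                f"length ({self.window_s} s) so pre-probe windows never overlap"
            )
        labels = set(CHANNELS_32)
        for eff in self.effects:
            unknown = set(eff.electrodes) - labels
            if unknown:
                raise ValueError(f"effect references unknown electrodes: {sorted(unknown)}")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# random streams

def _rng(config_seed: int, *key: int) -> np.random.Generator:
    """Named substream: independent generator for one (participant, session,
    stage) coordinate, fully determined by the root seed."""
    return np.random.default_rng(np.random.SeedSequence(config_seed, spawn_key=key))


def participant_aperiodic(config: SynthConfig, participant_id: int) -> tuple[float, float]:
    """Per-participant aperiodic (offset, exponent), drawn once and reused
    across that participant's sessions."""
    rng = _rng(config.seed, participant_id)
    offset = rng.uniform(*config.aperiodic_offset)
    exponent = rng.uniform(*config.aperiodic_exponent)
    return offset, exponent


# ---------------------------------------------------------------------------
# latents and reports

def simulate_latents(
    config: SynthConfig, n_windows: int, seed=None
) -> np.ndarray:
    """Draw piecewise-constant latent thought states, one 7-vector per window.

    Marginals are standard normal; the sample correlation converges to
    ``config.correlation``. Returns an (n_windows, 7) array in
    DIMENSIONS order.
    """
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(config.correlation)
    return rng.standard_normal((n_windows, 7)) @ chol.T


def latent_to_rating(latent_value: float, report_noise: float, seed=None) -> int:
    """Map a latent value to a 1..7 Likert rating.

    rating = round(4 + 1.5 * latent + noise), clipped to [1, 7], with
    noise ~ N(0, report_noise^2).
    """
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, report_noise) if report_noise > 0 else 0.0
    return int(np.clip(np.rint(4.0 + 1.5 * latent_value + noise), 1, 7))


def _ratings_from_latent(
    latent: np.ndarray, dims: tuple[str, ...], report_noise: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    out = {}
    for dim in dims:
        i = DIMENSIONS.index(dim)
        noise = rng.normal(0.0, report_noise) if report_noise > 0 else 0.0
        out[dim] = int(np.clip(np.rint(4.0 + 1.5 * latent[i] + noise), 1, 7))
    return out


# ---------------------------------------------------------------------------
# signal synthesis

def _aperiodic_background(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float,
    offset: float, exponent: float,
) -> np.ndarray:
    """1/f-shaped noise: one-sided PSD 10**offset * f**-exponent (uV^2/Hz),
    flattened below 1 Hz to keep the variance finite."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f_eff = np.maximum(freqs, 1.0)
    psd = 10.0 ** offset * f_eff ** (-exponent)
    gain = np.sqrt(psd * fs / 2.0)
    gain[0] = 0.0  # no DC
    out = np.empty((n_channels, n_samples))
    for ch in range(n_channels):  # per-channel FFT keeps peak memory low
        spec = np.fft.rfft(rng.standard_normal(n_samples))
        out[ch] = np.fft.irfft(spec * gain, n_samples)
    return out


def _narrowband_source(
    rng: np.random.Generator, n_samples: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance band-limited noise source."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / sd if sd > 0 else x


def _gaussian_topography(layout: ChannelLayout, center: tuple[float, float],
                         width: float) -> np.ndarray:
    d2 = np.sum((layout.positions - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width ** 2))


def _indicator_topography(layout: ChannelLayout, electrodes: tuple[str, ...]) -> np.ndarray:
    topo = np.zeros(layout.n_channels)
    for name in electrodes:
        topo[layout.index(name)] = 1.0
    return topo


def _effect_mask(layout: ChannelLayout, eff: EffectSpec,
                 freqs: np.ndarray) -> np.ndarray:
    """Planted region quantized to the 1-Hz analysis grid."""
    mask = np.zeros((layout.n_channels, len(freqs)), dtype=bool)
    fsel = (freqs >= eff.band[0]) & (freqs <= eff.band[1])
    for name in eff.electrodes:
        mask[layout.index(name), fsel] = True
    return mask


def _synthesize(
    config: SynthConfig,
    rng: np.random.Generator,
    n_samples: int,
    offset: float,
    exponent: float,
    layout: ChannelLayout,
    latents: np.ndarray,
    window_bounds: list[tuple[float, float]],
) -> np.ndarray:
    """Background + base oscillators + latent-modulated effect sources."""
    fs = config.sample_rate
    data = _aperiodic_background(rng, layout.n_channels, n_samples, fs,
                                 offset, exponent)
    for osc in config.oscillators:
        topo = _gaussian_topography(layout, osc.topo_center, osc.topo_width)
        band = (osc.center_hz - osc.bandwidth_hz / 2.0,
                osc.center_hz + osc.bandwidth_hz / 2.0)
        src = _narrowband_source(rng, n_samples, fs, band)
        data += np.outer(topo, osc.amplitude * src)
    dim_index = {d: i for i, d in enumerate(DIMENSIONS)}
    for eff in config.effects:
        src = _narrowband_source(rng, n_samples, fs, eff.band)
        env = np.ones(n_samples)
        for (t0, t1), lat in zip(window_bounds, latents):
            i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
            scale = max(0.0, 1.0 + eff.gain * eff.sign * lat[dim_index[eff.dimension]])
            env[max(i0, 0):min(i1, n_samples)] = scale
        topo = _indicator_topography(layout, eff.electrodes)
        data += np.outer(topo, eff.amplitude * env * src)
    return data


# ---------------------------------------------------------------------------
# sessions, rest blocks, cohorts

def simulate_session(
    config: SynthConfig, participant_id: int, session_id: int, seed=None
) -> tuple[Recording, list[ProbeReport], GroundTruth]:
    """Generate one task session: EEG, probe reports, and ground truth.

    Probe gaps are uniform on ``config.probe_gap``; the recording is
    extended past ``task_duration`` if needed so exactly ``n_probes``
    probes fit. The latent state is constant over each pre-probe window
    of ``config.window_s`` seconds, and every planted effect scales its
    narrowband source by ``1 + gain*sign*latent`` inside those windows.
    """
    layout = make_layout()
    fs = config.sample_rate
    if seed is None:
        rng = _rng(config.seed, participant_id, session_id, 0)
    else:
        rng = np.random.default_rng(seed)
    offset, exponent = participant_aperiodic(config, participant_id)

    gaps = rng.uniform(*config.probe_gap, size=config.n_probes)
    probe_times = np.cumsum(gaps)
    duration = max(config.task_duration, probe_times[-1] + 2.0)
    n_samples = int(round(duration * fs))

    latents = simulate_latents(config, config.n_probes, rng)
    window_bounds = [(t - config.window_s, t) for t in probe_times]

    data = _synthesize(config, rng, n_samples, offset, exponent, layout,
                       latents, window_bounds)

    recording = Recording(data, fs, layout, probe_times, "task",
                          participant_id, session_id)

    names = [c for c, _ in ACTIVITY_CATEGORIES]
    probs = np.array([p for _, p in ACTIVITY_CATEGORIES])
    probs = probs / probs.sum()
    reports = []
    for k, t in enumerate(probe_times):
        activity = names[rng.choice(len(names), p=probs)]
        ratings = _ratings_from_latent(latents[k], DIMENSIONS,
                                       config.report_noise, rng)
        reports.append(ProbeReport(float(t), activity, ratings, "momentary",
                                   participant_id, session_id, probe_id=k))

    grid = np.arange(4, 31, dtype=float)
    masks = {}
    for eff in config.effects:
        m = _effect_mask(layout, eff, grid)
        masks[eff.dimension] = masks.get(eff.dimension, np.zeros_like(m)) | m
    truth = GroundTruth(
        latents=latents,
        window_starts=np.array([b[0] for b in window_bounds]),
        window_ends=np.array([b[1] for b in window_bounds]),
        effect_masks=masks,
    )
    return recording, reports, truth


def simulate_rest(
    config: SynthConfig, participant_id: int, session_id: int,
    block: int = 0, seed=None,
) -> tuple[Recording, ProbeReport]:
    """Generate one 5-minute rest block and its retrospective report.

    A single latent state holds for the whole block; the report's
    ratings derive from it. Rest reports omit the task-relatedness
    dimension (not probed at rest).
    """
    layout = make_layout()
    fs = config.sample_rate
    if seed is None:
        rng = _rng(config.seed, participant_id, session_id, 1 + block)
    else:
        rng = np.random.default_rng(seed)
    offset, exponent = participant_aperiodic(config, participant_id)

    n_samples = int(round(config.rest_duration * fs))
    latent = simulate_latents(config, 1, rng)
    window_bounds = [(0.0, config.rest_duration)]

    data = _synthesize(config, rng, n_samples, offset, exponent, layout,
                       latent, window_bounds)
    recording = Recording(data, fs, layout, np.array([]), "rest",
                          participant_id, session_id, block=block)
    ratings = _ratings_from_latent(latent[0], REST_DIMENSIONS,
                                   config.report_noise, rng)
    report = ProbeReport(config.rest_duration, None, ratings, "retrospective",
                         participant_id, session_id, block=block)
    return recording, report


@dataclass
class Cohort:
    """Bundle of all synthetic recordings, reports, and ground truth."""

    config: SynthConfig
    task_recordings: list[Recording]
    task_reports: list[ProbeReport]
    rest_recordings: list[Recording]
    rest_reports: list[ProbeReport]
    ground_truth: dict[tuple[int, int], GroundTruth]

    def task_session(self, participant_id: int, session_id: int) -> Recording:
        for rec in self.task_recordings:
            if (rec.participant_id, rec.session_id) == (participant_id, session_id):
                return rec
        raise KeyError((participant_id, session_id))


def simulate_cohort(config: SynthConfig) -> Cohort:
    """Generate the full cohort: every participant x session task recording
    plus ``n_rest_blocks`` rest blocks per session.

    Per-participant aperiodic parameters are drawn once per participant
    and shared across that participant's sessions.
    """
    task_recs, task_reps, rest_recs, rest_reps = [], [], [], []
    truth = {}
    for p in range(config.n_participants):
        for s in range(config.n_sessions):
            rec, reps, gt = simulate_session(config, p, s)
            task_recs.append(rec)
            task_reps.extend(reps)
            truth[(p, s)] = gt
            for b in range(config.n_rest_blocks):
                rrec, rrep = simulate_rest(config, p, s, block=b)
                rest_recs.append(rrec)
                rest_reps.append(rrep)
    return Cohort(config, task_recs, task_reps, rest_recs, rest_reps, truth)
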