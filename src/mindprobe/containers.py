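"""Core data containers: recordings and experience-sampling reports."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import ChannelLayout

#: The seven probed thought dimensions, in questionnaire order:
#: task-relatedness, dynamics (free movement, stickiness, goal constraint),
#: attentional focus, and social content (self / other).
DIMENSIONS = (
    "off_task",
    "freely_moving",
    "sticky",
    "goal_oriented",
    "internal",
    "self_oriented",
    "other_oriented",
)

#: Dimensions sampled by the retrospective post-rest questionnaire
#: (task activity and task-relatedness are not asked at rest).
REST_DIMENSIONS = tuple(d for d in DIMENSIONS if d != "off_task")


@dataclass
class Recording:
    """Continuous multichannel EEG with probe/rest event metadata.

    data is electrode x time in microvolts; probe_times are seconds from
    recording start and must be strictly increasing and lie within the
    recording.
    """

    data: np.ndarray
    sample_rate: float
    layout: ChannelLayout
    probe_times: np.ndarray
    condition: str  # "task" | "rest"
    participant_id: int
    session_id: int
    block: int = 0  # rest block index within session (0 for task)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.probe_times = np.asarray(self.probe_times, dtype=float)
        if self.condition not in ("task", "rest"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.data.ndim != 2 or self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        if self.probe_times.size:
            if np.any(np.diff(self.probe_times) <= 0):
                raise ValueError("probe_times must be strictly increasing")
            if self.probe_times[0] < 0 or self.probe_times[-1] > self.duration:
                raise ValueError("probe_times must lie within the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate


@dataclass
class ProbeReport:
    """One experience-sampling response.

    ratings maps dimension name to an integer 1..7. Momentary reports
    (task condition) carry all seven dimensions plus a free-text
    activity; retrospective reports (rest) omit the task-relatedness
    dimension and the activity string.
    """

    probe_time: float
    activity: str | None
    ratings: dict[str, int]
    scope: str  # "momentary" | "retrospective"
    participant_id: int
    session_id: int
    block: int = 0
    probe_id: int = 0

    def __post_init__(self):
        if self.scope not in ("momentary", "retrospective"):
            raise ValueError(f"unknown scope {self.scope!r}")
        for dim, r in self.ratings.items():
            if dim not in DIMENSIONS:
                raise ValueError(f"unknown dimension {dim!r}")
            if not (1 <= int(r) <= 7):
                raise ValueError(f"rating for {dim!r} outside 1..7: {r}")
        if self.scope == "retrospective":
            if "off_task" in self.ratings or self.activity:
                raise ValueError(
                    "retrospective rest reports carry neither an activity "
                    "string nor a task-relatedness rating"
                )


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping for one synthetic session.

    latents: window x dimension matrix of the piecewise-constant latent
    thought state; window_starts gives the start (s) of each modulated
    pre-probe window. effect_masks maps dimension -> boolean
    electrode x frequency mask of the planted region on the 1-Hz
    analysis grid.
    """

    latents: np.ndarray
    window_starts: np.ndarray
    window_ends: np.ndarray
    effect_masks: dict[str, np.ndarray] = field(default_factory=dict)
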