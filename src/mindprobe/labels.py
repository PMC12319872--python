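"""Likert reports -> class labels, trial assembly, and inclusion rules.

Ratings on the 7-point scale are dichotomized into a lower end (1-3)
and an upper end (5-7); the midpoint (4) is discarded. Every epoch in a
probe's pre-probe window inherits that probe's labels, one per
dimension. Session-level analyses exclude sessions lacking trials on
either end of a dimension, and rest analyses exclude a dimension
cohort-wide if any participant never reported one of its ends at rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DIMENSIONS, REST_DIMENSIONS, ProbeReport
from .preprocess import Epoch, preprobe_window
from .spectral import SpectralMatrix

LOWER, UPPER, DISCARDED = "lower", "upper", "discarded"


def dichotomize(rating: int) -> str:
    """Map a 1..7 rating to ``"lower"`` (1-3), ``"upper"`` (5-7), or
    ``"discarded"`` (4). Ratings outside 1..7 raise ValueError."""
    r = int(rating)
    if r != rating or not (1 <= r <= 7):
        raise ValueError(f"rating must be an integer in 1..7, got {rating!r}")
    if r <= 3:
        return LOWER
    if r == 4:
        return DISCARDED
    return UPPER


@dataclass
class LabeledTrial:
    """One epoch-level trial: a spectral matrix plus per-dimension labels."""

    matrix: SpectralMatrix
    participant_id: int
    session_id: int
    condition: str
    probe_id: int
    labels: dict[str, str]
    trial_id: str = ""
    block: int = 0


@dataclass
class SessionCondition:
    """Session-level mean matrix for one (dimension, end) cell."""

    participant_id: int
    session_id: int
    dimension: str
    end: str  # "upper" | "lower"
    matrix: SpectralMatrix
    n_trials: int


def assemble_trials(
    epoch_features: list[tuple[Epoch, SpectralMatrix]],
    reports: list[ProbeReport],
    window_s: float = 12.0,
) -> list[LabeledTrial]:
    """Attach each probe's dichotomized ratings to the epochs in its
    pre-probe window (task condition).

    Probes whose window contains no featured epochs are skipped with a
    warning.
    """
    epochs = [e for e, _ in epoch_features]
    by_epoch = {id(e): m for e, m in epoch_features}
    trials = []
    for rep in reports:
        if rep.scope != "momentary":
            continue
        window = preprobe_window(epochs, rep.probe_time, window_s)
        if not window:
            warnings.warn(
                f"probe {rep.probe_id} of participant {rep.participant_id} "
                f"session {rep.session_id} has no featured epochs; skipped"
            )
            continue
        labels = {dim: dichotomize(r) for dim, r in rep.ratings.items()}
        for e in window:
            trials.append(LabeledTrial(
                by_epoch[id(e)], rep.participant_id, rep.session_id, "task",
                rep.probe_id, dict(labels),
                trial_id=f"p{rep.participant_id}s{rep.session_id}"
                         f"b{rep.block}q{rep.probe_id}t{e.t_start:.0f}",
                block=rep.block,
            ))
    return trials


def label_rest(
    rest_epoch_features: list[tuple[Epoch, SpectralMatrix]],
    report: ProbeReport,
) -> list[LabeledTrial]:
    """Broadcast the single retrospective report's labels to every rest
    epoch of its block."""
    labels = {dim: dichotomize(r) for dim, r in report.ratings.items()}
    return [
        LabeledTrial(
            m, report.participant_id, report.session_id, "rest",
            probe_id=-1, labels=dict(labels),
            trial_id=f"p{report.participant_id}s{report.session_id}"
                     f"rest{report.block}t{e.t_start:.0f}",
            block=report.block,
        )
        for e, m in rest_epoch_features
    ]


def session_condition_pairs(
    trials: list[LabeledTrial], dimension: str
) -> tuple[SessionCondition, SessionCondition] | None:
    """Session-mean matrices for the upper and lower end of one dimension.

    Returns None (exclusion) if either end has no trials in this
    session. All trials must come from one (participant, session).
    """
    from .spectral import session_mean_matrix

    keys = {(t.participant_id, t.session_id) for t in trials}
    if len(keys) != 1:
        raise ValueError("trials must come from a single session")
    participant_id, session_id = keys.pop()
    ends = {}
    for end in (UPPER, LOWER):
        members = [t for t in trials if t.labels.get(dimension) == end]
        if not members:
            return None
        mean = session_mean_matrix(
            [t.matrix for t in members],
            provenance={"kind": "session_mean", "dimension": dimension,
                        "end": end, "participant": participant_id,
                        "session": session_id},
        )
        ends[end] = SessionCondition(participant_id, session_id, dimension,
                                     end, mean, len(members))
    return ends[UPPER], ends[LOWER]


def cohort_rest_exclusions(rest_reports: list[ProbeReport]) -> set[str]:
    """Dimensions excluded cohort-wide from rest analyses.

    A dimension is excluded for everyone if any participant lacks one
    end (upper or lower) across all of their rest reports.
    """
    excluded = set()
    participants = sorted({r.participant_id for r in rest_reports})
    for dim in REST_DIMENSIONS:
        for p in participants:
            ends = set()
            for rep in rest_reports:
                if rep.participant_id != p or dim not in rep.ratings:
                    continue
                cls = dichotomize(rep.ratings[dim])
                if cls != DISCARDED:
                    ends.add(cls)
            if not {LOWER, UPPER} <= ends:
                excluded.add(dim)
                break
    return excluded


def _session_correlations(df: pd.DataFrame, target: str,
                          dims: list[str]) -> np.ndarray:
    """Pearson r of the target dimension's ratings against every other
    dimension within one session; zero-variance vectors give r = 0."""
    out = np.zeros(len(dims))
    x = df[target].to_numpy(dtype=float)
    for j, dim in enumerate(dims):
        y = df[dim].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"zero-variance ratings for {target if np.std(x) == 0 else dim}; "
                "correlation undefined, treated as 0"
            )
            out[j] = 0.0
        else:
            out[j] = np.corrcoef(x, y)[0, 1]
    return out


def dimension_correlations(
    reports: list[ProbeReport], target_dimension: str
) -> dict[int, pd.Series]:
    """Per participant, the Fisher-z-averaged within-session Pearson
    correlation of every other dimension's ratings with the target's."""
    if target_dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {target_dimension!r}")
    rows = [
        {"participant": r.participant_id, "session": r.session_id,
         **{d: r.ratings[d] for d in DIMENSIONS if d in r.ratings}}
        for r in reports if r.scope == "momentary"
    ]
    df = pd.DataFrame(rows)
    others = [d for d in DIMENSIONS if d != target_dimension]
    result = {}
    for p, pdf in df.groupby("participant"):
        zs = []
        for _, sdf in pdf.groupby("session"):
            if len(sdf) < 2:
                continue
            r = _session_correlations(sdf, target_dimension, others)
            zs.append(np.arctanh(np.clip(r, -0.999999, 0.999999)))
        if not zs:
            raise ValueError(f"participant {p} has no session with >= 2 probes")
        result[int(p)] = pd.Series(np.tanh(np.mean(zs, axis=0)), index=others)
    return result


def top_correlated_dimensions(
    reports: list[ProbeReport], target_dimension: str, n_top: int = 3
) -> dict[int, list[str]]:
    """Per participant, the dimensions most correlated with the target.

    Pearson correlations of the Likert ratings are computed within each
    session, averaged across sessions via Fisher z, and ranked by
    absolute mean correlation; the top ``n_top`` are returned.
    """
    corr = dimension_correlations(reports, target_dimension)
    result = {}
    for p, series in corr.items():
        order = np.argsort(-np.abs(series.to_numpy()), kind="stable")
        result[p] = [series.index[i] for i in order[:n_top]]
    return result
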