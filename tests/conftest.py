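import numpy as np
import pytest

from mindprobe import (SynthConfig, assemble_trials, epoch_spectral_matrix,
                       make_layout, preprocess_recording, simulate_cohort)
from mindprobe.decode import trial_tensor
from mindprobe.synth import default_effects


@pytest.fixture(scope="session")
def layout():
    return make_layout()


def featured_trials(cohort, window_s=12.0):
    """Preprocess and label every task session of a cohort."""
    trials = []
    for rec in cohort.task_recordings:
        epochs = preprocess_recording(rec)
        feats = [(e, epoch_spectral_matrix(e)) for e in epochs]
        reps = [r for r in cohort.task_reports
                if (r.participant_id, r.session_id)
                == (rec.participant_id, rec.session_id)]
        trials.extend(assemble_trials(feats, reps, window_s))
    return trials


@pytest.fixture(scope="session")
def small_planted_cohort():
    """2 participants x 1 session with a strong planted off-task effect."""
    cfg = SynthConfig(
        n_participants=2, n_sessions=1, task_duration=380.0, n_probes=12,
        probe_gap=(25.0, 35.0), window_s=12.0, rest_duration=60.0,
        effects=default_effects(gain=0.5), seed=21)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_planted_tensor(small_planted_cohort):
    return trial_tensor(featured_trials(small_planted_cohort), "off_task")
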