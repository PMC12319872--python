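import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mindprobe import (ProbeReport, assemble_trials, cohort_rest_exclusions,
                       dichotomize, dimension_correlations, label_rest,
                       session_condition_pairs, top_correlated_dimensions)
from mindprobe.containers import DIMENSIONS, REST_DIMENSIONS
from mindprobe.labels import DISCARDED, LOWER, UPPER, LabeledTrial
from mindprobe.preprocess import Epoch
from mindprobe.spectral import SpectralMatrix


class TestDichotomize:
    @given(st.integers(1, 7))
    @settings(deadline=None)
    def test_class_fully_determined_by_rating(self, r):
        cls = dichotomize(r)
        assert cls == (LOWER if r <= 3 else DISCARDED if r == 4 else UPPER)

    @pytest.mark.parametrize("bad", [0, 8, -1, 3.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            dichotomize(bad)


def make_report(probe_time, ratings, participant=0, session=0, probe_id=0):
    full = {d: 4 for d in DIMENSIONS}
    full.update(ratings)
    return ProbeReport(probe_time, "reading", full, "momentary",
                       participant, session, probe_id=probe_id)


def make_pairs(t_starts, participant=0, session=0, condition="task"):
    rng = np.random.default_rng(0)
    out = []
    for t in t_starts:
        ep = Epoch(np.zeros((1, 1)), float(t), 256.0, participant, session,
                   condition)
        out.append((ep, SpectralMatrix(rng.standard_normal((32, 27)))))
    return out


class TestAssembleTrials:
    def test_each_probe_contributes_its_window(self):
        pairs = make_pairs(np.arange(0, 120, 2))
        reports = [make_report(40.0, {"off_task": 6}, probe_id=0),
                   make_report(80.0, {"off_task": 2}, probe_id=1)]
        trials = assemble_trials(pairs, reports, 12.0)
        assert len(trials) == 12  # 6 epochs per probe
        by_probe = {0: UPPER, 1: LOWER}
        for t in trials:
            assert t.labels["off_task"] == by_probe[t.probe_id]

    def test_midpoint_rating_discards_only_that_dimension(self):
        pairs = make_pairs(np.arange(0, 40, 2))
        trials = assemble_trials(
            pairs, [make_report(24.0, {"off_task": 4, "sticky": 7})], 12.0)
        assert all(t.labels["off_task"] == DISCARDED for t in trials)
        assert all(t.labels["sticky"] == UPPER for t in trials)

    def test_empty_reports_empty_output(self):
        assert assemble_trials(make_pairs([0, 2, 4]), [], 12.0) == []

    def test_probe_without_epochs_warned_and_skipped(self):
        pairs = make_pairs([100.0])
        with pytest.warns(UserWarning, match="no featured epochs"):
            trials = assemble_trials(pairs, [make_report(50.0, {})], 12.0)
        assert trials == []


class TestSessionConditionPairs:
    def _trials(self, labels_seq):
        rng = np.random.default_rng(1)
        return [LabeledTrial(SpectralMatrix(rng.standard_normal((32, 27))),
                             0, 0, "task", i, {"off_task": lab})
                for i, lab in enumerate(labels_seq)]

    def test_one_sided_session_excluded(self):
        trials = self._trials([UPPER] * 30)
        assert session_condition_pairs(trials, "off_task") is None

    def test_balanced_session_means_match_oracle(self):
        trials = self._trials([UPPER] * 10 + [LOWER] * 10)
        up, lo = session_condition_pairs(trials, "off_task")
        assert up.n_trials == lo.n_trials == 10
        oracle_up = np.mean([t.matrix.periodic for t in trials[:10]], axis=0)
        np.testing.assert_allclose(up.matrix.periodic, oracle_up, atol=1e-12)

    def test_discarded_trials_ignored(self):
        trials = self._trials([UPPER, DISCARDED, LOWER, DISCARDED])
        up, lo = session_condition_pairs(trials, "off_task")
        assert up.n_trials == 1 and lo.n_trials == 1


class TestLabelRest:
    def test_broadcast_to_all_epochs(self):
        pairs = make_pairs(np.arange(0, 300, 2), condition="rest")
        report = ProbeReport(300.0, None, {d: 6 for d in REST_DIMENSIONS},
                             "retrospective", 0, 0)
        trials = label_rest(pairs, report)
        assert len(trials) == 150
        assert all(t.labels["sticky"] == UPPER for t in trials)

    def test_midpoint_discards_dimension_everywhere(self):
        pairs = make_pairs([0, 2, 4], condition="rest")
        report = ProbeReport(300.0, None, {"sticky": 4}, "retrospective", 0, 0)
        assert all(t.labels["sticky"] == DISCARDED
                   for t in label_rest(pairs, report))

    def test_blocks_keep_their_own_labels(self):
        r0 = ProbeReport(300.0, None, {"sticky": 6}, "retrospective", 0, 0,
                         block=0)
        r1 = ProbeReport(300.0, None, {"sticky": 2}, "retrospective", 0, 0,
                         block=1)
        t0 = label_rest(make_pairs([0, 2], condition="rest"), r0)
        t1 = label_rest(make_pairs([0, 2], condition="rest"), r1)
        assert {t.labels["sticky"] for t in t0} == {UPPER}
        assert {t.labels["sticky"] for t in t1} == {LOWER}


def rest_report(participant, ratings, session=0, block=0):
    full = {d: 4 for d in REST_DIMENSIONS}
    full.update(ratings)
    return ProbeReport(300.0, None, full, "retrospective", participant,
                       session, block=block)


class TestCohortRestExclusions:
    def test_participant_missing_one_end_excludes_dimension_for_all(self):
        reports = [rest_report(0, {"sticky": r}) for r in (1, 2, 3)] \
            + [rest_report(1, {"sticky": r}) for r in (2, 6)]
        assert "sticky" in cohort_rest_exclusions(reports)

    def test_no_exclusions_when_everyone_has_both_ends(self):
        reports = []
        for p in (0, 1):
            reports.append(rest_report(p, {d: 2 for d in REST_DIMENSIONS}))
            reports.append(rest_report(p, {d: 6 for d in REST_DIMENSIONS},
                                       session=1))
        assert cohort_rest_exclusions(reports) == set()

    def test_reproduces_two_dimension_exclusion_pattern(self):
        """A fixture where one participant never leaves the upper end of
        freely-moving thought and another never leaves the lower end of
        internally oriented thought excludes exactly those two."""
        both_ends = [rest_report(p, {d: 2 for d in REST_DIMENSIONS},
                                 session=0)
                     for p in range(3)] + \
                    [rest_report(p, {d: 6 for d in REST_DIMENSIONS},
                                 session=1)
                     for p in range(3)]
        skew = [rest_report(0, {"freely_moving": 6}, session=2),
                rest_report(1, {"internal": 2}, session=2)]
        # participant 0's sessions never rate freely_moving below 4;
        # participant 1's never rate internal above 4
        reports = []
        for r in both_ends:
            ratings = dict(r.ratings)
            if r.participant_id == 0:
                ratings["freely_moving"] = 6
            if r.participant_id == 1:
                ratings["internal"] = 2
            reports.append(ProbeReport(r.probe_time, None, ratings,
                                       "retrospective", r.participant_id,
                                       r.session_id, block=r.block))
        reports += skew
        assert cohort_rest_exclusions(reports) == {"freely_moving", "internal"}


class TestTopCorrelatedDimensions:
    def _reports(self, n_probes, rng, transform=None):
        out = []
        for s in range(3):
            for k in range(n_probes):
                base = rng.integers(1, 8, size=7)
                ratings = dict(zip(DIMENSIONS, (int(v) for v in base)))
                if transform:
                    ratings = transform(ratings)
                out.append(ProbeReport(float(k), "reading", ratings,
                                       "momentary", 0, s, probe_id=k))
        return out

    def test_duplicate_dimension_ranks_first(self):
        rng = np.random.default_rng(6)
        reports = self._reports(
            20, rng, lambda r: {**r, "sticky": r["off_task"]})
        top = top_correlated_dimensions(reports, "off_task")
        assert top[0][0] == "sticky"

    def test_independent_ratings_have_small_correlations(self):
        rng = np.random.default_rng(7)
        reports = self._reports(300, rng)
        corr = dimension_correlations(reports, "off_task")[0]
        assert np.abs(corr.to_numpy()).max() < 0.15

    def test_constant_dimension_treated_as_zero(self):
        rng = np.random.default_rng(8)
        reports = self._reports(20, rng, lambda r: {**r, "internal": 5})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = dimension_correlations(reports, "off_task")[0]
        assert corr["internal"] == 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            top = top_correlated_dimensions(reports, "off_task")
        assert "internal" not in top[0]
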