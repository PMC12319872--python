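"""Decoding protocol: within-participant CV, leave-one-participant-out
transfer learning, and permutation significance.

Trials are epoch-level spectral matrices labeled by their probe's
dichotomized rating on one dimension. For each eligible participant
(at least 50 trials per class by default) the within-participant route
runs stratified five-fold cross-validation: 10% of each training fold
is held out for validation, the remainder is z-scored (statistics from
that partition only), SMOTE-balanced, and used to train the 1D-SCNN;
metrics (MCC, AUC, balanced accuracy) are computed on the untouched
test fold, averaged over folds, then over participants. The whole
procedure is repeated ``n_iterations`` times and summarized as mean and
SD across iterations.

The across-participant route holds one participant out, trains on the
others (90/10 train/validation, SMOTE on training), then adapts by
re-training on a SMOTE-balanced 25% split of the held-out participant
and testing on the remaining 75%, which never touches any training
stage.

Statistical significance uses label shuffling within participant: the
same pipeline is repeated on shuffled labels, the observed mean is
ranked against the permuted means (add-one rank p), and a two-sample
Wilcoxon rank-sum test compares the observed and permuted iteration
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .labels import LOWER, UPPER, LabeledTrial
from .metrics import auc, balanced_accuracy, confusion_counts, mcc
from .nn import ScnnConfig, ShallowCNN
from .smote import smote_balance

METRICS = ("mcc", "auc", "ba")


@dataclass
class TrialTensor:
    """Trials x channels x frequencies plus labels for one dimension."""

    X: np.ndarray  # (n, n_channels, n_freqs)
    y: np.ndarray  # (n,) 0 = lower, 1 = upper
    participants: np.ndarray
    groups: np.ndarray  # probe id per trial (for group-aware folds)
    trial_ids: list[str] = field(default_factory=list)
    dimension: str = ""

    def __len__(self):
        return len(self.y)

    def subset(self, idx) -> "TrialTensor":
        idx = np.asarray(idx)
        return TrialTensor(self.X[idx], self.y[idx], self.participants[idx],
                           self.groups[idx],
                           [self.trial_ids[i] for i in idx], self.dimension)


def trial_tensor(trials: list[LabeledTrial], dimension: str) -> TrialTensor:
    """Stack the trials labeled lower/upper on ``dimension`` (discarded
    trials are dropped)."""
    kept = [t for t in trials if t.labels.get(dimension) in (LOWER, UPPER)]
    if not kept:
        raise ValueError(f"no labeled trials for dimension {dimension!r}")
    X = np.stack([t.matrix.periodic for t in kept])
    y = np.array([1 if t.labels[dimension] == UPPER else 0 for t in kept])
    parts = np.array([t.participant_id for t in kept])
    groups = np.array([hash((t.participant_id, t.session_id, t.block, t.probe_id))
                       for t in kept])
    return TrialTensor(X, y, parts, groups, [t.trial_id for t in kept], dimension)


def zscore_fit_apply(train: np.ndarray, *others: np.ndarray):
    """Per-feature z-scoring with statistics from the training set only.

    Zero-variance features map to 0 everywhere. Returns the normalized
    training array followed by each other array transformed with the
    training statistics.
    """
    train = np.asarray(train, dtype=float)
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    nonconst = sd > 0
    safe_sd = np.where(nonconst, sd, 1.0)

    def transform(a):
        out = (np.asarray(a, dtype=float) - mean) / safe_sd
        out *= nonconst  # constant features -> 0
        return out

    results = [transform(train)] + [transform(a) for a in others]
    return results[0] if not others else tuple(results)


# ---------------------------------------------------------------------------
# summaries

@dataclass
class PerformanceSummary:
    """Per-iteration metric values plus cross-iteration mean/SD."""

    dimension: str
    approach: str  # "within_participant" | "loso_transfer"
    iteration_values: dict[str, np.ndarray]
    n_participants: int
    excluded_participants: list[int] = field(default_factory=list)
    audit: dict = field(default_factory=dict)

    def mean(self, metric: str = "mcc") -> float:
        return float(np.mean(self.iteration_values[metric]))

    def sd(self, metric: str = "mcc") -> float:
        return float(np.std(self.iteration_values[metric], ddof=1)) \
            if len(self.iteration_values[metric]) > 1 else 0.0

    def summary(self) -> pd.DataFrame:
        rows = [{"metric": m, "mean": self.mean(m), "sd": self.sd(m)}
                for m in self.iteration_values]
        return pd.DataFrame(rows).set_index("metric")


def _fold_indices(y, n_folds, rng, stratified=True, groups=None):
    """Test-index arrays per fold, stratified by class by default; with
    ``groups`` the split keeps all trials of a probe in one fold."""
    n = len(y)
    folds = [[] for _ in range(n_folds)]
    if groups is not None:
        uniq = np.unique(groups)
        order = rng.permutation(len(uniq))
        for j, g in enumerate(uniq[order]):
            folds[j % n_folds].extend(np.flatnonzero(groups == g))
    elif stratified:
        for cls in np.unique(y):
            idx = rng.permutation(np.flatnonzero(y == cls))
            for j, i in enumerate(idx):
                folds[j % n_folds].append(i)
    else:
        idx = rng.permutation(n)
        for j, i in enumerate(idx):
            folds[j % n_folds].append(i)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _evaluate(model: ShallowCNN, X, y) -> dict[str, float]:
    probs = model.predict_proba(X)
    pred = probs.argmax(axis=1)
    tp, tn, fp, fn = confusion_counts(y, pred)
    return {"mcc": mcc(tp, tn, fp, fn),
            "auc": auc(probs[:, 1], y),
            "ba": balanced_accuracy(tp, tn, fp, fn)}


def _train_eval_fold(X, y, train_idx, test_idx, config, rng, k_smote,
                     val_fraction):
    """One fold: carve validation, z-score, SMOTE, train, test."""
    train_idx = rng.permutation(train_idx)
    n_val = max(1, int(round(val_fraction * len(train_idx))))
    val_idx, fit_idx = train_idx[:n_val], train_idx[n_val:]
    Xf = X[fit_idx].reshape(len(fit_idx), -1)
    Xv = X[val_idx].reshape(len(val_idx), -1)
    Xt = X[test_idx].reshape(len(test_idx), -1)
    Xf, Xv, Xt = zscore_fit_apply(Xf, Xv, Xt)
    Xb, yb = smote_balance(Xf, y[fit_idx], k=k_smote,
                           seed=int(rng.integers(2 ** 31)))
    model = ShallowCNN(config, X.shape[1], X.shape[2],
                       seed=int(rng.integers(2 ** 31)))
    model.fit(Xb, yb, Xv, y[val_idx])
    return _evaluate(model, Xt, y[test_idx])


def eligible_participants(tensor: TrialTensor,
                          min_trials_per_class: int = 50) -> tuple[list[int], list[int]]:
    """Participants with at least ``min_trials_per_class`` trials in each
    class, and those excluded by the rule."""
    ok, excluded = [], []
    for p in np.unique(tensor.participants):
        yp = tensor.y[tensor.participants == p]
        if min((yp == 0).sum(), (yp == 1).sum()) >= min_trials_per_class:
            ok.append(int(p))
        else:
            excluded.append(int(p))
    return ok, excluded


def within_participant_cv(
    tensor: TrialTensor,
    config: ScnnConfig = ScnnConfig(),
    n_iterations: int = 25,
    n_folds: int = 5,
    val_fraction: float = 0.1,
    min_trials_per_class: int = 50,
    stratified: bool = True,
    group_folds: bool = False,
    k_smote: int = 5,
    seed=None,
) -> PerformanceSummary:
    """Five-fold within-participant cross-validation, repeated.

    Per iteration and participant: stratified folds, 10% of each
    training fold as validation, z-scoring and SMOTE on the training
    partition only, metrics on the untouched test fold. Fold metrics
    are averaged per participant, participants averaged to one value
    per iteration.
    """
    ok, excluded = eligible_participants(tensor, min_trials_per_class)
    if not ok:
        raise ValueError("no participant meets the per-class trial minimum")
    rng = np.random.default_rng(seed)
    iter_vals = {m: [] for m in METRICS}
    for _ in range(n_iterations):
        part_means = {m: [] for m in METRICS}
        for p in ok:
            mask = tensor.participants == p
            X, y = tensor.X[mask], tensor.y[mask]
            g = tensor.groups[mask] if group_folds else None
            folds = _fold_indices(y, n_folds, rng, stratified, g)
            fold_vals = {m: [] for m in METRICS}
            for f in range(n_folds):
                test_idx = folds[f]
                train_idx = np.concatenate([folds[j] for j in range(n_folds)
                                            if j != f])
                res = _train_eval_fold(X, y, train_idx, test_idx, config,
                                       rng, k_smote, val_fraction)
                for m in METRICS:
                    fold_vals[m].append(res[m])
            for m in METRICS:
                part_means[m].append(np.mean(fold_vals[m]))
        for m in METRICS:
            iter_vals[m].append(np.mean(part_means[m]))
    return PerformanceSummary(
        tensor.dimension, "within_participant",
        {m: np.array(v) for m, v in iter_vals.items()},
        n_participants=len(ok), excluded_participants=excluded)


def loso_transfer_cv(
    tensor: TrialTensor,
    config: ScnnConfig = ScnnConfig(),
    n_iterations: int = 25,
    adapt_fraction: float = 0.25,
    val_fraction: float = 0.1,
    min_trials_per_class: int = 50,
    k_smote: int = 5,
    seed=None,
) -> PerformanceSummary:
    """Leave-one-participant-out with transfer learning.

    For each held-out participant the model trains on all others
    (90/10 train/validation, SMOTE on training), is evaluated unadapted
    on the held-out 75% split, then re-trained on the SMOTE-balanced
    25% split and evaluated again (adapted). The 75% test split never
    enters any training stage. Adapted metrics are the headline values;
    unadapted counterparts are reported with an ``_unadapted`` suffix.
    """
    ok, excluded = eligible_participants(tensor, min_trials_per_class)
    if len(ok) < 2:
        raise ValueError("leave-one-participant-out needs >= 2 eligible participants")
    rng = np.random.default_rng(seed)
    keys = list(METRICS) + [f"{m}_unadapted" for m in METRICS]
    iter_vals = {m: [] for m in keys}
    audit = {}
    for it in range(n_iterations):
        part_vals = {m: [] for m in keys}
        for p in ok:
            test_mask = tensor.participants == p
            pool_mask = np.isin(tensor.participants, [q for q in ok if q != p])
            Xpool = tensor.X[pool_mask].reshape(pool_mask.sum(), -1)
            ypool = tensor.y[pool_mask]
            order = rng.permutation(len(ypool))
            n_val = max(1, int(round(val_fraction * len(ypool))))
            val_idx, fit_idx = order[:n_val], order[n_val:]
            Xf, Xv = Xpool[fit_idx], Xpool[val_idx]
            Xp = tensor.X[test_mask].reshape(test_mask.sum(), -1)
            yp = tensor.y[test_mask]
            Xf, Xv, Xp = zscore_fit_apply(Xf, Xv, Xp)
            Xb, yb = smote_balance(Xf, ypool[fit_idx], k=k_smote,
                                   seed=int(rng.integers(2 ** 31)))
            model = ShallowCNN(config, tensor.X.shape[1], tensor.X.shape[2],
                               seed=int(rng.integers(2 ** 31)))
            model.fit(Xb, yb, Xv, ypool[val_idx])

            # stratified 25/75 split of the held-out participant
            adapt_idx, eval_idx = [], []
            for cls in np.unique(yp):
                idx = rng.permutation(np.flatnonzero(yp == cls))
                n_adapt = max(1, int(round(adapt_fraction * len(idx))))
                adapt_idx.extend(idx[:n_adapt])
                eval_idx.extend(idx[n_adapt:])
            adapt_idx = np.sort(np.array(adapt_idx))
            eval_idx = np.sort(np.array(eval_idx))

            un = _evaluate(model, Xp[eval_idx], yp[eval_idx])
            Xa, ya = smote_balance(Xp[adapt_idx], yp[adapt_idx], k=k_smote,
                                   seed=int(rng.integers(2 ** 31)))
            tuned = model.copy()
            tuned.fit(Xa, ya)  # fine-tune; patience on training loss
            ad = _evaluate(tuned, Xp[eval_idx], yp[eval_idx])
            for m in METRICS:
                part_vals[m].append(ad[m])
                part_vals[f"{m}_unadapted"].append(un[m])
            if it == 0:
                ids = np.array(tensor.trial_ids, dtype=object)
                audit[int(p)] = {
                    "train_ids": set(ids[pool_mask])
                    | set(ids[test_mask][adapt_idx]),
                    "test_ids": set(ids[test_mask][eval_idx]),
                }
        for m in keys:
            iter_vals[m].append(np.mean(part_vals[m]))
    return PerformanceSummary(
        tensor.dimension, "loso_transfer",
        {m: np.array(v) for m, v in iter_vals.items()},
        n_participants=len(ok), excluded_participants=excluded, audit=audit)


# ---------------------------------------------------------------------------
# permutation significance

@dataclass
class PermutationResult:
    """Label-shuffle significance for one decoding pipeline."""

    observed: np.ndarray
    permuted: np.ndarray
    p_permutation: float
    p_wilcoxon: float

    def summary(self) -> str:
        return (f"observed mean = {np.mean(self.observed):.3f}, "
                f"permuted mean = {np.mean(self.permuted):.3f}, "
                f"rank p = {self.p_permutation:.4f}, "
                f"Wilcoxon rank-sum p = {self.p_wilcoxon:.4g}")


def shuffle_labels(tensor: TrialTensor, rng) -> TrialTensor:
    """Permute class labels within each participant (class counts per
    participant are preserved)."""
    y = tensor.y.copy()
    for p in np.unique(tensor.participants):
        idx = np.flatnonzero(tensor.participants == p)
        y[idx] = y[idx[rng.permutation(len(idx))]]
    return TrialTensor(tensor.X, y, tensor.participants, tensor.groups,
                       tensor.trial_ids, tensor.dimension)


def permutation_significance(
    cv_runner,
    tensor: TrialTensor,
    observed_values: np.ndarray,
    n_runs: int = 25,
    seed=None,
) -> PermutationResult:
    """Label-shuffled null for a decoding pipeline.

    ``cv_runner(tensor, seed) -> float`` runs the identical pipeline
    once and returns its mean metric. The rank p compares the observed
    mean against the ``n_runs`` shuffled means with the add-one
    convention; the Wilcoxon p is a two-sample rank-sum test between
    the observed and permuted value sets.
    """
    rng = np.random.default_rng(seed)
    observed_values = np.atleast_1d(np.asarray(observed_values, dtype=float))
    permuted = np.array([
        cv_runner(shuffle_labels(tensor, rng), int(rng.integers(2 ** 31)))
        for _ in range(n_runs)
    ])
    obs_mean = observed_values.mean()
    r = int(np.sum(permuted >= obs_mean))
    p_perm = (r + 1) / (n_runs + 1)
    if len(observed_values) > 1:
        p_wil = float(stats.mannwhitneyu(observed_values, permuted,
                                         alternative="two-sided").pvalue)
    else:
        p_wil = float("nan")
    return PermutationResult(observed_values, permuted, p_perm, p_wil)
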