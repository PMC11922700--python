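"""Shuffled-label randomization inference over repeated model searches.

Model selection optimistically biases cross-validated scores upward (the
best of many searched models is reported). The correction used here builds
an empirical chance distribution by re-running the *entire* search with
shuffled class labels: the full search is fit ``n_seeds`` times with the
true labels and ``n_seeds`` times with labels freshly permuted before each
search, and the two score samples are compared with a two-tailed Welch
t-test. The same machinery supports the cross-lag transfer analysis
(models trained at one post-impact lag, evaluated on the other lag's
post-impact sessions of held-out subjects) and subgroup analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import _derive_seed, grouped_cv, model_search
from .features import FeatureTable


# ---------------------------------------------------------------------------
# primitives


def sensitivity(labels, predictions) -> float:
    """True-positive rate TP / (TP + FN)."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if not (y == 1).any():
        raise ValueError("sensitivity needs at least one positive label")
    return float((p[y == 1] == 1).mean())


def shuffle_labels(table: FeatureTable, seed: int,
                   mode: str = "uniform") -> FeatureTable:
    """Permute class labels; features and subject grouping are untouched.

    ``mode="uniform"``: one uniform permutation over all rows (label counts
    conserved). ``mode="within_subject"``: each subject's baseline/post
    pair is swapped with probability 1/2 — a stricter exchangeability unit,
    provided for sensitivity analysis.
    """
    rng = np.random.default_rng(seed)
    if mode == "uniform":
        labels = rng.permutation(table.labels)
    elif mode == "within_subject":
        labels = table.labels.copy()
        for sid in table.subjects():
            if rng.random() < 0.5:
                rows = table.subject_ids == sid
                labels[rows] = 1 - labels[rows]
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return table.with_labels(labels)


@dataclass(frozen=True)
class WelchT:
    """Two-sample Welch t-test with Welch–Satterthwaite degrees of freedom."""

    t: float
    df: float
    p: float
    diagnostic: str | None = None

    def __str__(self) -> str:
        if self.diagnostic:
            return f"Welch t undefined ({self.diagnostic})"
        return f"t({self.df:.1f}) = {self.t:.2f}, p = {self.p:.3g}"


def welch_ttest(a, b) -> WelchT:
    """Two-tailed Welch t-test of independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchT(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        return WelchT(t=np.nan, df=np.nan, p=np.nan,
                      diagnostic="both samples degenerate with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return WelchT(t=float(res.statistic), df=float(df), p=float(res.pvalue))


# ---------------------------------------------------------------------------
# the randomization test


@dataclass
class RandomizationResult:
    true_scores: list[float]         # mean balanced accuracy per seed
    shuffled_scores: list[float]
    comparison: WelchT
    config: dict = field(default_factory=dict)

    @property
    def effect(self) -> float:
        """mean(true) - mean(shuffled): the selection-bias-corrected signal."""
        return float(np.mean(self.true_scores) - np.mean(self.shuffled_scores))


def randomization_test(table: FeatureTable, n_seeds: int = 100,
                       n_trials: int = 64, base_seed: int = 0,
                       strategy: str = "tpe", k: int = 5,
                       shuffle_mode: str = "uniform") -> RandomizationResult:
    """True-label vs shuffled-label model-search performance.

    Runs the full model-selection process ``n_seeds`` times with the true
    labels and ``n_seeds`` times with labels re-shuffled (fresh permutation
    and fresh search seed) before each search, then compares the two
    distributions of mean cross-validated balanced accuracy with a
    two-tailed Welch t-test.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    true_scores, shuffled_scores = [], []
    for i in range(n_seeds):
        res = model_search(table, seed=_derive_seed(base_seed, "true", i),
                           n_trials=n_trials, strategy=strategy, k=k)
        true_scores.append(res.best_score)
    for i in range(n_seeds):
        shuf = shuffle_labels(table, seed=_derive_seed(base_seed, "perm", i),
                              mode=shuffle_mode)
        res = model_search(shuf, seed=_derive_seed(base_seed, "shuffled", i),
                           n_trials=n_trials, strategy=strategy, k=k)
        shuffled_scores.append(res.best_score)
    return RandomizationResult(
        true_scores=true_scores, shuffled_scores=shuffled_scores,
        comparison=welch_ttest(true_scores, shuffled_scores),
        config={"n_seeds": n_seeds, "n_trials": n_trials,
                "base_seed": base_seed, "strategy": strategy, "k": k,
                "shuffle_mode": shuffle_mode, "n_obs": table.n_obs})


def subgroup_test(table: FeatureTable, group: str = "all", *,
                  n_seeds: int = 100, n_trials: int = 64, base_seed: int = 0,
                  strategy: str = "tpe", k: int = 5,
                  shuffle_mode: str = "uniform") -> RandomizationResult:
    """Randomization test restricted to one experimental group.

    ``group="all"`` reproduces :func:`randomization_test` exactly (same
    derived seeds). Raises if the group has fewer than ``k`` subjects.
    """
    sub = table if group == "all" else table.restrict_group(group)
    n_subj = len(sub.subjects())
    if n_subj < k:
        raise ValueError(
            f"group {group!r} has {n_subj} subjects; grouped {k}-fold CV "
            f"needs at least {k}")
    res = randomization_test(sub, n_seeds=n_seeds, n_trials=n_trials,
                             base_seed=base_seed, strategy=strategy, k=k,
                             shuffle_mode=shuffle_mode)
    res.config["group"] = group
    return res


# ---------------------------------------------------------------------------
# cross-lag transfer


@dataclass
class TransferResult:
    """Sensitivity of one train lag's models at both lags, per seed."""

    train_lag: str
    other_lag: str
    same_lag: list[float]
    cross_lag: list[float]
    shuffled_same: list[float]
    shuffled_cross: list[float]
    comparisons: dict = field(default_factory=dict)  # name -> WelchT


def _transfer_one_seed(train: FeatureTable, other: FeatureTable,
                       search_seed: int, cv_seed: int, n_trials: int,
                       strategy: str, k: int,
                       eval_labels: np.ndarray) -> tuple[float, float]:
    """Search on `train`, then per CV fold predict the held-out subjects'
    post-impact rows at both lags; pooled sensitivities (same, cross).

    ``eval_labels`` are the *true* labels of the train table, so shuffled-
    label models are still scored on genuinely post-impact sessions.
    """
    best = model_search(train, seed=search_seed, n_trials=n_trials,
                        strategy=strategy, k=k).best_params
    cv = grouped_cv(train, best, seed=cv_seed, k=k, keep_artifacts=True)

    same_true, same_pred, cross_true, cross_pred = [], [], [], []
    for fold in cv.folds:
        pos = eval_labels[fold.test_rows] == 1
        same_true.extend([1] * int(pos.sum()))
        same_pred.extend(fold.predictions[pos])
        held = np.isin(other.subject_ids, fold.test_subjects) & (other.labels == 1)
        if held.any():
            pred = fold.model.predict(other.X[held][:, fold.selected])
            cross_true.extend([1] * int(held.sum()))
            cross_pred.extend(pred)
    return (sensitivity(same_true, same_pred),
            sensitivity(cross_true, cross_pred))


def cross_lag_transfer(table_a: FeatureTable, table_b: FeatureTable,
                       n_seeds: int = 100, n_trials: int = 64,
                       base_seed: int = 0, strategy: str = "tpe", k: int = 5,
                       shuffle_mode: str = "uniform",
                       directions: tuple = ("a", "b")
                       ) -> tuple[TransferResult, ...]:
    """Do the EEG signatures at the two post-impact lags transfer?

    For each train lag and each seed, a full model search plus grouped CV
    yields the same-lag sensitivity on held-out post-impact sessions; each
    fold's model also classifies the *other* lag's post-impact sessions of
    that fold's held-out subjects (so a subject never informs a model that
    judges it). Shuffled-label baselines run the identical protocol.
    Because only post-impact (positive) rows are comparable across lags,
    performance is reported as sensitivity, not balanced accuracy.
    ``directions`` selects which train lags to evaluate ("a" trains on
    ``table_a``, "b" on ``table_b``); the default runs both.
    """
    shared = np.intersect1d(table_a.subjects(), table_b.subjects())
    if (len(shared) != len(table_a.subjects())
            or len(shared) != len(table_b.subjects())):
        warnings.warn("subject sets differ; intersecting")
        table_a = _restrict_subjects(table_a, shared)
        table_b = _restrict_subjects(table_b, shared)
    if table_a.feature_names != table_b.feature_names:
        raise ValueError("tables must share feature columns")

    results = []
    pairs = [p for p in (("a", table_a, table_b), ("b", table_b, table_a))
             if p[0] in directions]
    for tag, train, other in pairs:
        same, cross, sh_same, sh_cross = [], [], [], []
        for i in range(n_seeds):
            s, c = _transfer_one_seed(
                train, other,
                search_seed=_derive_seed(base_seed, f"{tag}-true", i),
                cv_seed=_derive_seed(base_seed, f"{tag}-cv", i),
                n_trials=n_trials, strategy=strategy, k=k,
                eval_labels=train.labels)
            same.append(s)
            cross.append(c)
        for i in range(n_seeds):
            shuf = shuffle_labels(
                train, seed=_derive_seed(base_seed, f"{tag}-perm", i),
                mode=shuffle_mode)
            s, c = _transfer_one_seed(
                shuf, other,
                search_seed=_derive_seed(base_seed, f"{tag}-shuf", i),
                cv_seed=_derive_seed(base_seed, f"{tag}-shufcv", i),
                n_trials=n_trials, strategy=strategy, k=k,
                eval_labels=train.labels)
            sh_same.append(s)
            sh_cross.append(c)
        train_lag = str(train.lags[train.labels == 1][0])
        other_lag = str(other.lags[other.labels == 1][0])
        results.append(TransferResult(
            train_lag=train_lag, other_lag=other_lag,
            same_lag=same, cross_lag=cross,
            shuffled_same=sh_same, shuffled_cross=sh_cross,
            comparisons={
                "same_vs_shuffled": welch_ttest(same, sh_same),
                "cross_vs_shuffled": welch_ttest(cross, sh_cross),
                "same_vs_cross": welch_ttest(same, cross),
            }))
    return tuple(results)


def _restrict_subjects(table: FeatureTable, subjects: np.ndarray) -> FeatureTable:
    keep = np.isin(table.subject_ids, subjects)
    return FeatureTable(table.X[keep], table.feature_names,
                        table.subject_ids[keep], table.labels[keep],
                        table.groups[keep], table.lags[keep])
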