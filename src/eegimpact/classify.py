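"""Baseline-vs-post-impact classification.

Gradient-boosted decision trees (histogram split finding, 100 estimators,
binary log-loss) preceded by ANOVA F-score feature selection, evaluated by
balanced accuracy under subject-grouped 5-fold cross-validation — both of a
subject's sessions always share a fold, so the score estimates performance
on a new participant. Hyperparameters are tuned by a Tree-Parzen-estimator
(TPE) sequential search over 64 trials; feature selection happens inside
every fold, on training rows only.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.feature_selection import f_classif

from .features import FeatureTable


def _derive_seed(*keys) -> int:
    """Stable 31-bit seed from arbitrary int/str keys (process-independent)."""
    ints = [zlib.crc32(k.encode()) if isinstance(k, str) else int(k)
            for k in keys]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# metrics


def balanced_accuracy(labels, predictions) -> float:
    """(sensitivity + specificity) / 2. Requires both classes in `labels`."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.min() == y.max():
        raise ValueError(
            "labels contain a single class; balanced accuracy is undefined — "
            "use inference.sensitivity for positive-only evaluation")
    sens = (p[y == 1] == 1).mean()
    spec = (p[y == 0] == 0).mean()
    return float((sens + spec) / 2.0)


def _fold_score(labels, predictions) -> float:
    """Balanced accuracy, degrading to the present class's recall when a
    held-out fold is single-class (possible once labels are shuffled)."""
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        return float((np.asarray(predictions, dtype=int) == y).mean())
    return balanced_accuracy(y, predictions)


# ---------------------------------------------------------------------------
# feature selection


def fscore_select(train_X: np.ndarray, train_y: np.ndarray, k: int) -> np.ndarray:
    """Indices of the top-k features by one-way ANOVA F between classes.

    Constant features get F = 0; ties break toward the lower feature index.
    Takes only the training split by construction, so selection can never
    see test-fold rows.
    """
    n_features = train_X.shape[1]
    if k > n_features:
        warnings.warn(f"k={k} > n_features={n_features}; clamping")
        k = n_features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(train_X, train_y)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-F, kind="stable")  # stable sort = index tie-break
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# hyperparameters


@dataclass(frozen=True)
class HyperParams:
    """The searched hyperparameters with their sampling bounds."""

    max_depth: int = 4
    reg_alpha: float = 1e-8
    reg_lambda: float = 1.0
    subsample_rows: float = 1.0
    subsample_cols: float = 1.0
    learning_rate: float = 0.1
    n_selected_features: int = 10

    def __post_init__(self) -> None:
        if not 2 <= self.max_depth <= 8:
            raise ValueError("max_depth must be in [2, 8]")
        if not 1e-15 <= self.reg_alpha <= 1:
            raise ValueError("reg_alpha out of [1e-15, 1]")
        if not 1e-15 <= self.reg_lambda <= 100:
            raise ValueError("reg_lambda out of [1e-15, 100]")
        if not 0.1 <= self.subsample_rows <= 1.0:
            raise ValueError("subsample_rows out of [0.1, 1.0]")
        if not 0.2 <= self.subsample_cols <= 1.0:
            raise ValueError("subsample_cols out of [0.2, 1.0]")
        if not 0.01 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate out of [0.01, 1.0]")
        if self.n_selected_features < 10:
            raise ValueError("n_selected_features must be >= 10")


@dataclass(frozen=True)
class FixedModelSettings:
    """Constants of every fitted model, recorded in provenance."""

    n_estimators: int = 100
    objective: str = "binary logistic (log-loss)"
    tree_method: str = "hist"
    min_split_loss: float = 1.0  # XGBoost gamma; no sklearn equivalent
    backend: str = "sklearn.HistGradientBoostingClassifier"
    unsupported: tuple = ("reg_alpha", "subsample_rows", "min_split_loss")
    # backend knobs chosen for subject-scale samples: leaves may be small
    # (XGBoost's min_child_weight=1 analogue) and 64 histogram bins are
    # lossless below 64 training rows
    min_samples_leaf: int = 2
    max_bins: int = 64


FIXED = FixedModelSettings()


def make_model(hp: HyperParams, seed: int) -> HistGradientBoostingClassifier:
    """Boosted-tree model with the fixed settings plus searched params.

    The sklearn histogram backend has no L1 penalty, row subsampling or
    min-split-loss; those sampled values are carried in provenance but not
    applied (see FixedModelSettings.unsupported).
    """
    return HistGradientBoostingClassifier(
        max_iter=FIXED.n_estimators,
        learning_rate=hp.learning_rate,
        max_depth=hp.max_depth,
        l2_regularization=hp.reg_lambda,
        max_features=hp.subsample_cols,
        min_samples_leaf=FIXED.min_samples_leaf,
        max_bins=FIXED.max_bins,
        early_stopping=False,
        random_state=seed,
    )


def search_space(n_features: int) -> dict:
    """The tuned distributions; log-uniform where the ranges span decades."""
    return {
        "max_depth": ("int", 2, 8),
        "reg_alpha": ("loguniform", 1e-15, 1.0),
        "reg_lambda": ("loguniform", 1e-15, 100.0),
        "subsample_rows": ("uniform", 0.1, 1.0),
        "subsample_cols": ("uniform", 0.2, 1.0),
        "learning_rate": ("loguniform", 0.01, 1.0),
        "n_selected_features": ("int", 10, max(10, n_features)),
    }


# ---------------------------------------------------------------------------
# grouped cross-validation


@dataclass
class FoldArtifacts:
    """What one CV fold trained and predicted (kept for transfer analyses
    and leakage instrumentation)."""

    test_subjects: list
    selected: np.ndarray
    model: HistGradientBoostingClassifier
    test_rows: np.ndarray
    predictions: np.ndarray


@dataclass
class CVResult:
    fold_scores: list[float]
    mean_score: float
    fold_subjects: list[list]
    seed: int
    folds: list[FoldArtifacts] | None = None


def assign_folds(subjects: np.ndarray, seed: int, k: int) -> list[np.ndarray]:
    """Deterministic subject partition: shuffle by seed, deal round-robin."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(np.asarray(subjects))
    return [perm[i::k] for i in range(k)]


def grouped_cv(table: FeatureTable, hp: HyperParams, seed: int, k: int = 5,
               keep_artifacts: bool = False) -> CVResult:
    """Subject-grouped k-fold CV scored by balanced accuracy.

    Within each fold: F-score selection of ``hp.n_selected_features`` on
    training rows, model fit on the selected training columns, balanced
    accuracy on the held-out subjects' rows. Fully reproducible from
    ``seed`` (fold assignment and every model's random state derive from it).
    """
    subjects = table.subjects()
    if len(subjects) < k:
        raise ValueError(f"grouped {k}-fold CV needs >= {k} subjects, "
                         f"got {len(subjects)}")
    folds = assign_folds(subjects, seed, k)

    scores, fold_subjects, artifacts = [], [], []
    for fi, test_subj in enumerate(folds):
        test = np.isin(table.subject_ids, test_subj)
        sel = fscore_select(table.X[~test], table.labels[~test],
                            hp.n_selected_features)
        model = make_model(hp, seed=_derive_seed(seed, fi))
        model.fit(table.X[~test][:, sel], table.labels[~test])
        pred = model.predict(table.X[test][:, sel])
        scores.append(_fold_score(table.labels[test], pred))
        fold_subjects.append(sorted(test_subj.tolist()))
        if keep_artifacts:
            artifacts.append(FoldArtifacts(
                test_subjects=sorted(test_subj.tolist()), selected=sel,
                model=model, test_rows=np.flatnonzero(test), predictions=pred))
    return CVResult(fold_scores=scores, mean_score=float(np.mean(scores)),
                    fold_subjects=fold_subjects, seed=seed,
                    folds=artifacts if keep_artifacts else None)


# ---------------------------------------------------------------------------
# Tree-Parzen-estimator search


def _to_unit(value: float, kind: str, lo: float, hi: float) -> float:
    if kind == "loguniform":
        return (math.log(value) - math.log(lo)) / (math.log(hi) - math.log(lo))
    return (value - lo) / (hi - lo)


def _from_unit(u: float, kind: str, lo: float, hi: float):
    u = min(max(u, 0.0), 1.0)
    if kind == "loguniform":
        v = math.exp(math.log(lo) + u * (math.log(hi) - math.log(lo)))
    else:
        v = lo + u * (hi - lo)
    if kind == "int":
        return min(max(int(round(v)), int(lo)), int(hi))
    return min(max(v, lo), hi)  # exp/log round-trip can overshoot the edge


def _sample_uniform(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, (kind, lo, hi) in space.items():
        if kind == "int":
            out[name] = int(rng.integers(int(lo), int(hi) + 1))
        elif kind == "loguniform":
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            out[name] = float(rng.uniform(lo, hi))
    return out


def _parzen_logpdf(u: float, centers: np.ndarray, sigma: float) -> float:
    """Mixture of Gaussians at the observed points plus one uniform prior
    component on [0,1], so no candidate ever has zero density."""
    k = centers.size
    comp = np.exp(-0.5 * ((u - centers) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    return math.log((comp.sum() + 1.0) / (k + 1))


class TPESampler:
    """Simplified one-dimensional-factored Tree-Parzen estimator.

    After ``n_startup`` uniform trials, observed configurations are split
    by score into a good set (top gamma fraction) and the rest; candidates
    are drawn from a Parzen mixture over the good set and ranked by the
    density ratio l(x)/g(x), per the TPE expected-improvement argument.
    """

    def __init__(self, space: dict, seed: int, n_startup: int = 10,
                 gamma: float = 0.25, n_candidates: int = 24):
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.history: list[tuple[dict, float]] = []

    def suggest(self) -> dict:
        if len(self.history) < self.n_startup:
            return _sample_uniform(self.space, self.rng)
        scores = np.array([s for _, s in self.history])
        order = np.argsort(-scores, kind="stable")
        n_good = max(1, int(math.ceil(self.gamma * len(order))))
        good, bad = order[:n_good], order[n_good:]

        unit = {name: np.array([_to_unit(p[name], *spec)
                                for p, _ in self.history])
                for name, spec in self.space.items()}
        best, best_score = None, -np.inf
        for _ in range(self.n_candidates):
            cand, logratio = {}, 0.0
            for name, spec in self.space.items():
                ug, ub = unit[name][good], unit[name][bad]
                sigma = max(1.0 / math.sqrt(ug.size + 1), 1e-3)
                u = float(np.clip(self.rng.choice(ug)
                                  + sigma * self.rng.standard_normal(), 0, 1))
                logratio += (_parzen_logpdf(u, ug, sigma)
                             - _parzen_logpdf(u, ub, sigma) if ub.size else 0.0)
                cand[name] = _from_unit(u, *spec)
            if logratio > best_score:
                best, best_score = cand, logratio
        return best

    def observe(self, params: dict, score: float) -> None:
        self.history.append((params, score))


@dataclass
class SearchResult:
    best_params: HyperParams
    best_score: float
    trials: list[dict]               # {params, mean_score, fold_scores}
    seed: int
    strategy: str
    settings: dict = field(default_factory=lambda: asdict(FIXED))

    @property
    def best_trial(self) -> int:
        return int(np.argmax([t["mean_score"] for t in self.trials]))


def model_search(table: FeatureTable, seed: int, n_trials: int = 64,
                 strategy: str = "tpe", k: int = 5) -> SearchResult:
    """Sequential hyperparameter search scored by grouped-CV balanced accuracy.

    ``strategy`` is ``"tpe"`` (default) or ``"random"`` (same distributions,
    no adaptation — cheaper for large randomization studies). Trial i's CV
    uses a seed derived from (seed, i), so trials are independent of
    execution order; the best trial is the arg-max of mean balanced accuracy
    with first-seen tie-break.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = search_space(table.n_features)
    rng = np.random.default_rng(_derive_seed(seed, "sampler"))
    sampler = TPESampler(space, seed=_derive_seed(seed, "tpe")) \
        if strategy == "tpe" else None
    if strategy not in ("tpe", "random"):
        raise ValueError(f"unknown strategy {strategy!r}")

    trials = []
    for i in range(n_trials):
        raw = sampler.suggest() if sampler else _sample_uniform(space, rng)
        raw["n_selected_features"] = min(raw["n_selected_features"],
                                         table.n_features)
        hp = HyperParams(**raw)
        cv = grouped_cv(table, hp, seed=_derive_seed(seed, "trial", i), k=k)
        if sampler:
            sampler.observe(raw, cv.mean_score)
        trials.append({"params": raw, "mean_score": cv.mean_score,
                       "fold_scores": cv.fold_scores})

    best = int(np.argmax([t["mean_score"] for t in trials]))
    return SearchResult(best_params=HyperParams(**trials[best]["params"]),
                        best_score=trials[best]["mean_score"],
                        trials=trials, seed=seed, strategy=strategy)
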