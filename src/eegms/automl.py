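"""Bayesian-optimized classifier selection and evaluation protocols.

The optimizer searches jointly over a pool of learner families and their
hyperparameters to minimize a cross-validated misclassification rate. One
random-forest surrogate is maintained per learner family ("multi-bagged-
trees" reading of the objective model); candidate configurations are drawn
uniformly from each family's domain and scored by expected improvement
against the incumbent (the lowest objective value observed so far). The
incumbent configuration is finally refit on the full training split.

Evaluation protocols:

* subject-dependent — stratified 80/20 epoch-level split with 5-fold CV
  inside the training split;
* leave-one-subject-out — one subject per group held out per fold, so no
  test subject's epochs ever appear in training;
* incremental ranked-feature models — top-k features for k = 1..k_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .learners import SearchSpace, default_search_space

__all__ = [
    "cv_objective",
    "expected_improvement",
    "OptimizationTrace",
    "bayes_optimize",
    "ClassificationReport",
    "classification_metrics",
    "evaluate_holdout",
    "leave_one_subject_out",
    "incremental_feature_curve",
]

_META_COLS = ("subject_id", "group", "epoch")


def _xy(
    table: pd.DataFrame, features: list[str] | None, positive: str
) -> tuple[np.ndarray, np.ndarray]:
    if features is None:
        features = [
            c for c in table.columns
            if c not in _META_COLS and pd.api.types.is_numeric_dtype(table[c])
        ]
    x = table[list(features)].to_numpy(dtype=float)
    y = (table["group"].to_numpy() == positive).astype(int)
    return x, y


def _decision_scores(model, x: np.ndarray) -> np.ndarray:
    """Continuous scores for the positive class (index 1 of classes_)."""
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(x)[:, -1]
        except AttributeError:
            pass
    return np.asarray(model.decision_function(x), dtype=float)


def cv_objective(
    estimator,
    x: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Stratified k-fold mean misclassification rate of one pipeline."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    errs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in skf.split(x, y):
            m = clone(estimator)
            m.fit(x[tr], y[tr])
            errs.append(float(np.mean(m.predict(x[te]) != y[te])))
    return float(np.mean(errs))


def expected_improvement(
    mean: np.ndarray, sd: np.ndarray, incumbent: float
) -> np.ndarray:
    """Closed-form expected improvement under Normal(mean, sd^2).

    ``EI = E[max(incumbent - Y, 0)] = imp * Phi(z) + sd * phi(z)`` with
    ``imp = incumbent - mean`` and ``z = imp / sd``; for ``sd = 0`` this
    degenerates to ``max(imp, 0)``.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd must be nonnegative")
    imp = incumbent - mean
    out = np.maximum(imp, 0.0)
    pos = sd > 0
    z = np.divide(imp, sd, out=np.zeros_like(imp + sd), where=pos)
    out = np.where(pos, imp * norm.cdf(z) + sd * norm.pdf(z), out)
    return out


@dataclass
class OptimizationTrace:
    """Evaluated configurations with their CV objective values."""

    configs: list[tuple[str, dict]] = field(default_factory=list)
    values: list[float] = field(default_factory=list)
    budget: int = 0
    seed: int | None = None

    def append(self, learner: str, params: dict, value: float) -> None:
        self.configs.append((learner, params))
        self.values.append(float(value))

    @property
    def incumbent_index(self) -> int:
        return int(np.argmin(self.values))

    @property
    def incumbent(self) -> tuple[str, dict]:
        return self.configs[self.incumbent_index]

    @property
    def incumbent_value(self) -> float:
        return float(np.min(self.values))

    def running_incumbent(self) -> np.ndarray:
        """Best objective seen so far, along the trace (non-increasing)."""
        return np.minimum.accumulate(np.asarray(self.values))


def bayes_optimize(
    space: SearchSpace | None = None,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    objective=None,
    budget: int = 50,
    n_init: int = 4,
    n_candidates: int = 256,
    cv_k: int = 5,
    seed: int = 0,
) -> tuple[OptimizationTrace, object | None]:
    """Minimize the CV misclassification rate over the learner pool.

    The initial design cycles through the learner families with random
    configurations (``n_init`` per family, truncated to ``budget``). Each
    subsequent step fits one regression-forest surrogate per family on
    that family's evaluated points (mean and spread taken across trees),
    draws ``n_candidates`` uniform candidates per family, and evaluates
    the candidate with the highest expected improvement over the
    incumbent. Families with fewer than two observations fall back to a
    random candidate.

    ``objective(learner, params) -> float`` may replace the built-in CV
    objective (used for testing the optimizer in isolation); with the
    built-in objective the incumbent is refit on all of ``x, y`` and
    returned as the second element.
    """
    if space is None:
        space = default_search_space()
    if objective is None:
        if x is None or y is None:
            raise ValueError("either (x, y) or an objective is required")
        cv_seed = int(np.random.default_rng(seed).integers(2**31))

        def objective(learner, params):
            return cv_objective(space.build(learner, params), x, y, cv_k, cv_seed)

        refit = True
    else:
        refit = False

    rng = np.random.default_rng(seed)
    pool = space.learners
    trace = OptimizationTrace(budget=budget, seed=seed)
    errors: list[str] = []

    def evaluate(learner: str, params: dict) -> None:
        try:
            value = float(objective(learner, params))
        except Exception as exc:  # noqa: BLE001 — a failed fit is a data point
            errors.append(f"{learner}: {exc}")
            return
        trace.append(learner, params, value)

    # initial round-robin random design
    init_plan = [pool[i % len(pool)] for i in range(min(budget, n_init * len(pool)))]
    for learner in init_plan:
        evaluate(learner, space.sample(learner, rng))

    while len(trace.values) < budget:
        if not trace.values:
            # nothing evaluated successfully yet — keep trying at random
            learner = pool[rng.integers(len(pool))]
            evaluate(learner, space.sample(learner, rng))
            if len(errors) > 5 * budget:
                raise RuntimeError(f"all evaluations failed: {errors[:3]}")
            continue
        incumbent = trace.incumbent_value
        # A bagged-tree surrogate never predicts below its lowest training
        # target, so pure EI starves exploitation on smooth objectives;
        # a quarter of the steps greedily evaluate the lowest predicted
        # mean instead.
        exploit = rng.random() < 0.25
        best_ei, best_cfg = -np.inf, None
        best_mean, best_mean_cfg = np.inf, None
        for learner in pool:
            pts = [
                (space.to_vector(l, p), v)
                for (l, p), v in zip(trace.configs, trace.values)
                if l == learner
            ]
            # candidate pool: uniform draws plus local refinements of the
            # learner's best configuration so far (the forest surrogate is
            # piecewise constant, so pure uniform sampling stalls early)
            n_local = n_candidates // 4
            cands = [space.sample(learner, rng) for _ in range(n_candidates - n_local)]
            if pts:
                j_best = int(np.argmin([v for _, v in pts]))
                best_params = [
                    p for (l, p) in trace.configs if l == learner
                ][j_best]
                for i in range(n_local):
                    scale = (0.1, 0.02, 0.005)[i % 3]
                    cands.append(
                        space.perturb(learner, best_params, rng, scale=scale)
                    )
            if len(pts) >= 2:
                xs = np.vstack([p[0] for p in pts])
                vs = np.array([p[1] for p in pts])
                forest = RandomForestRegressor(
                    n_estimators=50,
                    random_state=int(rng.integers(2**31)),
                )
                forest.fit(xs, vs)
                cx = np.vstack([space.to_vector(learner, c) for c in cands])
                preds = np.stack([t.predict(cx) for t in forest.estimators_])
                means = preds.mean(axis=0)
                ei = expected_improvement(means, preds.std(axis=0), incumbent)
                j = int(np.argmax(ei))
                cand_ei, cand = float(ei[j]), cands[j]
                jm = int(np.argmin(means))
                if means[jm] < best_mean:
                    best_mean, best_mean_cfg = float(means[jm]), (learner, cands[jm])
            else:
                cand_ei, cand = 0.0, cands[0]
            if cand_ei > best_ei:
                best_ei, best_cfg = cand_ei, (learner, cand)
        if exploit and best_mean_cfg is not None:
            best_cfg = best_mean_cfg
        evaluate(*best_cfg)
        if len(errors) > 5 * budget:
            raise RuntimeError(f"too many failed evaluations: {errors[:3]}")

    if not trace.values:
        raise RuntimeError(f"all evaluations failed: {errors[:3]}")

    model = None
    if refit:
        learner, params = trace.incumbent
        model = space.build(learner, params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, y)
    return trace, model


@dataclass
class ClassificationReport:
    """Test-set performance of the optimized classifier."""

    accuracy: float  # percent
    auc: float
    sensitivity: float  # percent, positive class = SZ-like group
    specificity: float  # percent
    confusion: dict[str, int]  # tp, fn, tn, fp
    best_model: str = ""
    features: list[str] = field(default_factory=list)
    protocol: str = ""
    seed: int | None = None
    trace: OptimizationTrace | None = None

    def to_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 4),
            "auc": round(self.auc, 4),
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
            "confusion": self.confusion,
            "best_model": self.best_model,
            "features": list(self.features),
            "protocol": self.protocol,
            "seed": self.seed,
        }


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> ClassificationReport:
    """Accuracy/sensitivity/specificity (percent) and rank-based AUC.

    The positive class is coded 1 (the SZ-like group throughout the
    package): sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    n = tp + fn + tn + fp
    acc = 100.0 * (tp + tn) / n if n else float("nan")
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    if scores is not None and np.unique(y_true).size == 2:
        auc = float(roc_auc_score(y_true, scores))
    else:
        auc = float("nan")
    return ClassificationReport(
        accuracy=acc, auc=auc, sensitivity=sens, specificity=spec,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    )


def evaluate_holdout(
    table: pd.DataFrame,
    features: list[str] | None = None,
    test_fraction: float = 0.2,
    budget: int = 50,
    space: SearchSpace | None = None,
    positive: str = "SZ",
    seed: int = 0,
) -> ClassificationReport:
    """Subject-dependent protocol: stratified 80/20 epoch-level split.

    The optimizer runs on the training split only; the refit incumbent is
    scored once on the held-out 20%.
    """
    x, y = _xy(table, features, positive)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    if np.unique(y_tr).size < 2 or np.unique(y_te).size < 2:
        raise ValueError("degenerate split: a side is single-class")
    trace, model = bayes_optimize(
        space=space, x=x_tr, y=y_tr, budget=budget, seed=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y_pred = model.predict(x_te)
        scores = _decision_scores(model, x_te)
    rep = classification_metrics(y_te, y_pred, scores)
    rep.best_model = f"{trace.incumbent[0]} {trace.incumbent[1]}"
    rep.features = list(features) if features is not None else []
    rep.protocol = "subject_dependent"
    rep.seed = seed
    rep.trace = trace
    return rep


def leave_one_subject_out(
    table: pd.DataFrame,
    features: list[str] | None = None,
    budget: int = 12,
    space: SearchSpace | None = None,
    positive: str = "SZ",
    groups: tuple[str, str] = ("HC", "SZ"),
    seed: int = 0,
) -> tuple[ClassificationReport, list[ClassificationReport]]:
    """Subject-independent protocol: hold out one subject per group.

    Subjects of each group are paired in sorted order; fold ``i`` tests on
    all epochs of pair ``i`` and trains (with its own optimizer run) on
    everyone else, so no test subject leaks into training. Metrics are
    averaged over folds; the pooled confusion matrix is also reported.
    """
    subj = {
        g: sorted(table.loc[table["group"] == g, "subject_id"].unique())
        for g in groups
    }
    n_folds = min(len(subj[g]) for g in groups)
    if n_folds < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    fold_reports: list[ClassificationReport] = []
    for i in range(n_folds):
        held = {subj[g][i] for g in groups}
        test_mask = table["subject_id"].isin(held).to_numpy()
        train_tab = table.loc[~test_mask]
        test_tab = table.loc[test_mask]
        x_tr, y_tr = _xy(train_tab, features, positive)
        x_te, y_te = _xy(test_tab, features, positive)
        fold_seed = int(rng.integers(2**31))
        trace, model = bayes_optimize(
            space=space, x=x_tr, y=y_tr, budget=budget, seed=fold_seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            y_pred = model.predict(x_te)
            scores = _decision_scores(model, x_te)
        rep = classification_metrics(y_te, y_pred, scores)
        rep.best_model = f"{trace.incumbent[0]} {trace.incumbent[1]}"
        rep.protocol = "loso"
        rep.seed = fold_seed
        fold_reports.append(rep)

    conf = {
        k: sum(r.confusion[k] for r in fold_reports) for k in ("tp", "fn", "tn", "fp")
    }
    aucs = [r.auc for r in fold_reports if np.isfinite(r.auc)]
    avg = ClassificationReport(
        accuracy=float(np.mean([r.accuracy for r in fold_reports])),
        auc=float(np.mean(aucs)) if aucs else float("nan"),
        sensitivity=float(np.mean([r.sensitivity for r in fold_reports])),
        specificity=float(np.mean([r.specificity for r in fold_reports])),
        confusion=conf,
        best_model="; ".join(sorted({r.best_model.split(" ")[0] for r in fold_reports})),
        features=list(features) if features is not None else [],
        protocol="loso",
        seed=seed,
    )
    return avg, fold_reports


def incremental_feature_curve(
    table: pd.DataFrame,
    ranking,
    k_max: int = 19,
    test_fraction: float = 0.2,
    budget: int = 50,
    space: SearchSpace | None = None,
    positive: str = "SZ",
    seed: int = 0,
) -> list[ClassificationReport]:
    """Evaluate models on the top-k ranked features for k = 1..k_max."""
    names = ranking.names if hasattr(ranking, "names") else list(ranking)
    if k_max > len(names):
        raise ValueError(f"k_max={k_max} exceeds {len(names)} ranked features")
    reports = []
    for k in range(1, k_max + 1):
        rep = evaluate_holdout(
            table, names[:k], test_fraction=test_fraction,
            budget=budget, space=space, positive=positive, seed=seed,
        )
        reports.append(rep)
    return reports
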