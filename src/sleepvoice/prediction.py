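"""Patient-level stratified cross-validated prediction of sleepiness.

Folds partition *participants*, never observations, so no patient
contributes to both the training and test side of a fold (leakage guard).
Stratification is on each patient's modal sleepiness level, assigned
greedily so fold-level sleepiness distributions stay similar.  Training
data are balanced per class with a floor/cap rule (classes under the floor
are skipped — removed from training only; classes over the cap are
downsampled without replacement).  Feature selection is per fold: a
feature is removed only when its node-purity importance falls below the
cutoff in every fold's training data.  A random forest classifies
sleepiness on the held-out rows; accuracy/precision/recall/F1 carry
bootstrap percentile 95% CIs over resampled (label, prediction) pairs.

The multiclass averaging scheme is explicit because four-level precision/
recall/F1 can be macro-averaged, weighted, or computed after collapsing to
a binary sleepy/not-sleepy split; all three are provided (macro default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .inference import _node_purity, _rf_design

DEFAULT_FEATURES = ("vrt_seconds", "cognition_scale", "mood", "age", "sex",
                    "caffeine", "bzra_use", "education", "difficulty")
AVERAGING_MODES = ("macro", "weighted", "binary-collapse")


class FoldError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fold planning


@dataclass(frozen=True)
class Fold:
    fold_id: int
    train_patient_ids: tuple[str, ...]
    test_patient_ids: tuple[str, ...]


@dataclass(frozen=True)
class FoldPlan:
    k: int
    folds: tuple[Fold, ...]
    stratify_on: str
    seed: int

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.folds:
            train, test = set(f.train_patient_ids), set(f.test_patient_ids)
            if train & test:
                raise FoldError(f"fold {f.fold_id} leaks patients "
                                f"{sorted(train & test)}")
            if seen & test:
                raise FoldError("a patient appears in more than one test fold")
            seen |= test

    def as_dict(self) -> dict:
        return dict(k=self.k, stratify_on=self.stratify_on, seed=self.seed,
                    folds=[dict(fold_id=f.fold_id,
                                train=list(f.train_patient_ids),
                                test=list(f.test_patient_ids))
                           for f in self.folds])


def _modal_level(values: pd.Series) -> int:
    m = values.mode()
    return int(m.min())  # ties break toward the lower level


def plan_folds(table: pd.DataFrame, k: int = 4, seed: int = 0,
               stratify_on: str = "sleepiness") -> FoldPlan:
    """Assign each patient to exactly one test fold, stratified by the
    patient's modal sleepiness.

    Patients are grouped by modal level, shuffled within group (seeded),
    and dealt round-robin to the currently smallest fold, which keeps
    fold-level sleepiness distributions as similar as the patient layout
    allows.  Deterministic given the seed.
    """
    patients = table["participant_id"].unique()
    if len(patients) < k:
        raise FoldError(f"need at least k={k} patients, have {len(patients)}")
    rng = np.random.default_rng(seed)
    modal = table.groupby("participant_id")[stratify_on].agg(_modal_level)

    assignment: dict[str, int] = {}
    fold_sizes = np.zeros(k, dtype=int)
    for level in sorted(modal.unique()):
        group = sorted(modal.index[modal == level])
        order = rng.permutation(len(group))
        for idx in order:
            target = int(np.argmin(fold_sizes))  # ties -> lowest fold id
            assignment[group[idx]] = target
            fold_sizes[target] += 1

    folds = []
    all_pids = sorted(patients)
    for fid in range(k):
        test = tuple(p for p in all_pids if assignment[p] == fid)
        train = tuple(p for p in all_pids if assignment[p] != fid)
        folds.append(Fold(fold_id=fid + 1, train_patient_ids=train,
                          test_patient_ids=test))
    return FoldPlan(k=k, folds=tuple(folds), stratify_on=stratify_on, seed=seed)


def plan_folds_unstratified(table: pd.DataFrame, k: int = 4, seed: int = 0
                            ) -> FoldPlan:
    """Random patient partition ignoring sleepiness — baseline for
    quantifying the benefit of stratification."""
    patients = sorted(table["participant_id"].unique())
    if len(patients) < k:
        raise FoldError(f"need at least k={k} patients, have {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    folds = []
    chunks = np.array_split(order, k)
    for fid, chunk in enumerate(chunks):
        test = tuple(patients[i] for i in sorted(chunk))
        train = tuple(p for p in patients if p not in set(test))
        folds.append(Fold(fold_id=fid + 1, train_patient_ids=train,
                          test_patient_ids=test))
    return FoldPlan(k=k, folds=tuple(folds), stratify_on="none", seed=seed)


# ---------------------------------------------------------------------------
# Class balancing


@dataclass(frozen=True)
class BalancingRule:
    floor: int = 180
    cap: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.floor > self.cap:
            raise ValueError(f"floor {self.floor} exceeds cap {self.cap}")


def balance_training(train: pd.DataFrame, rule: BalancingRule,
                     class_col: str = "sleepiness"
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the floor/cap balancing rule to training rows only.

    Classes with fewer than ``floor`` rows are skipped (dropped from
    training); classes with more than ``cap`` rows are downsampled without
    replacement to ``cap``.  The ledger records original/kept counts and
    the action per class; original = kept + removed always holds.
    """
    if class_col not in train.columns:
        raise KeyError(f"class column {class_col!r} missing")
    rng = np.random.default_rng(rule.seed)
    kept_parts, ledger = [], []
    for cls, sub in train.groupby(class_col, sort=True):
        n = len(sub)
        if n < rule.floor:
            ledger.append(dict(class_label=cls, original=n, kept=0,
                               removed=n, action="skipped"))
        elif n > rule.cap:
            idx = np.sort(rng.choice(n, size=rule.cap, replace=False))
            kept_parts.append(sub.iloc[idx])
            ledger.append(dict(class_label=cls, original=n, kept=rule.cap,
                               removed=n - rule.cap, action="downsampled"))
        else:
            kept_parts.append(sub)
            ledger.append(dict(class_label=cls, original=n, kept=n,
                               removed=0, action="kept"))
    if not kept_parts:
        raise FoldError("training set is empty after class balancing")
    balanced = pd.concat(kept_parts).sort_index()
    return balanced, pd.DataFrame(ledger)


# ---------------------------------------------------------------------------
# Per-fold feature selection


def apply_fold_rule(fold_importances: Mapping[str, Sequence[float]],
                    cutoff: float) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """All-folds rule: a feature is removed only if its importance is below
    the cutoff in EVERY fold; below-cutoff in some folds only -> retained."""
    retained, removed = [], []
    for f, vals in fold_importances.items():
        if all(v < cutoff for v in vals):
            removed.append(f)
        else:
            retained.append(f)
    return tuple(retained), tuple(removed)


def select_features_per_fold(train_sets: Sequence[pd.DataFrame],
                             outcome: str = "sleepiness",
                             candidates: Sequence[str] = DEFAULT_FEATURES,
                             cutoff: float = 20.0, n_trees: int = 500,
                             seed: int = 0
                             ) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Node-purity screening on each fold's training data with the
    all-folds removal rule.  Returns (retained features, per-fold
    importance table)."""
    if not train_sets:
        raise FoldError("need at least one fold")
    per_fold: dict[str, list[float]] = {f: [] for f in candidates}
    rows = []
    for i, ts in enumerate(train_sets):
        feats = [f for f in candidates if f in ts.columns]
        X, parents = _rf_design(ts, feats)
        forest = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=seed + i, n_jobs=1)
        forest.fit(X, ts[outcome].to_numpy())
        imp = _node_purity(forest, parents)
        for f in feats:
            per_fold[f].append(imp.get(f, 0.0))
            rows.append(dict(fold=i + 1, feature=f, importance=imp.get(f, 0.0)))
    retained, _removed = apply_fold_rule(
        {f: v for f, v in per_fold.items() if v}, cutoff)
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metrics


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray
               ) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    ti = np.array([index[v] for v in y_true])
    pi = np.array([index[v] for v in y_pred])
    c = len(classes)
    return np.bincount(ti * c + pi, minlength=c * c).reshape(c, c)


def metrics_from_confusion(cm: np.ndarray, mode: str = "macro") -> dict[str, float]:
    """accuracy/precision/recall/F1 from a (true x predicted) count matrix.

    ``macro`` averages per-class metrics over classes present in the truth;
    ``weighted`` weights them by class support; per-class precision with an
    empty predicted class counts as 0.
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    acc = float(np.trace(cm) / total) if total else 0.0
    support = cm.sum(axis=1)
    pred_tot = cm.sum(axis=0)
    present = support > 0
    tp = np.diag(cm)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_tot > 0, tp / np.maximum(pred_tot, 1), 0.0)
        rec = np.where(present, tp / np.maximum(support, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec,
                                                                  1e-300), 0.0)
    if mode == "macro":
        w = present / max(present.sum(), 1)
    elif mode == "weighted":
        w = support / max(total, 1)
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    return dict(accuracy=acc, precision=float(np.sum(prec * w)),
                recall=float(np.sum(rec * w)), f1=float(np.sum(f1 * w)))


def metrics_from_predictions(y_true: Sequence, y_pred: Sequence,
                             mode: str = "macro",
                             positive_threshold: int = 2) -> dict[str, float]:
    """Point metrics under the chosen averaging mode.

    ``binary-collapse`` maps levels >= positive_threshold to the positive
    class before computing ordinary binary precision/recall/F1.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if mode == "binary-collapse":
        t = (y_true >= positive_threshold).astype(int)
        p = (y_pred >= positive_threshold).astype(int)
        cm = _confusion(t, p, np.array([0, 1]))
        tp, fp = cm[1, 1], cm[0, 1]
        fn, tn = cm[1, 0], cm[0, 0]
        acc = (tp + tn) / cm.sum()
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return dict(accuracy=float(acc), precision=float(prec),
                    recall=float(rec), f1=float(f1))
    classes = np.unique(np.concatenate([y_true, y_pred]))
    return metrics_from_confusion(_confusion(y_true, y_pred, classes), mode)


def bootstrap_cis(y_true: np.ndarray, y_pred: np.ndarray, mode: str,
                  b: int = 1000, seed: int = 0, positive_threshold: int = 2
                  ) -> dict[str, tuple[float, float]]:
    """Percentile 95% CIs from ``b`` resamples of (label, prediction) pairs."""
    rng = np.random.default_rng(seed)
    n = len(y_true)
    names = ("accuracy", "precision", "recall", "f1")
    samples = {m: np.empty(b) for m in names}
    for i in range(b):
        idx = rng.integers(0, n, n)
        m = metrics_from_predictions(y_true[idx], y_pred[idx], mode,
                                     positive_threshold)
        for name in names:
            samples[name][i] = m[name]
    return {name: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for name, v in samples.items()}


# ---------------------------------------------------------------------------
# Cross-validated runs


@dataclass(frozen=True)
class FoldMetrics:
    fold_id: int
    n_test: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    cis: dict[str, tuple[float, float]]
    averaging_mode: str
    confusion: np.ndarray = field(repr=False, default=None)
    classes: tuple = ()
    balancing_ledger: pd.DataFrame = field(repr=False, default=None)

    def as_row(self) -> dict:
        row = dict(fold=self.fold_id, n_test=self.n_test)
        for m in ("accuracy", "precision", "recall", "f1"):
            row[m] = getattr(self, m)
            lo, hi = self.cis[m]
            row[f"{m}_ci_low"], row[f"{m}_ci_high"] = lo, hi
        return row


def run_skcv(table: pd.DataFrame, plan: FoldPlan,
             rule: BalancingRule | None = None,
             features: Sequence[str] = DEFAULT_FEATURES,
             rf_params: Mapping | None = None, bootstrap: int = 1000,
             averaging_mode: str = "macro", positive_threshold: int = 2,
             seed: int = 0, class_col: str = "sleepiness"
             ) -> list[FoldMetrics]:
    """Train/evaluate the forest per fold; returns one FoldMetrics per fold.

    Training rows are the plan's train patients' observations after class
    balancing; test rows are the held-out patients' observations,
    untouched — including rows of classes the floor rule skipped from
    training, which therefore count against recall.  Deterministic given
    the seed.
    """
    if averaging_mode not in AVERAGING_MODES:
        raise ValueError(f"averaging_mode must be one of {AVERAGING_MODES}")
    rule = rule or BalancingRule()
    rf_params = dict(rf_params or {})
    n_trees = rf_params.pop("n_estimators", 500)
    table_pids = set(table["participant_id"])
    plan_pids = set().union(*(f.test_patient_ids for f in plan.folds))
    if not table_pids <= plan_pids:
        raise FoldError(f"plan does not cover patients "
                        f"{sorted(table_pids - plan_pids)}")

    out = []
    for f in plan.folds:
        assert not set(f.train_patient_ids) & set(f.test_patient_ids)
        train = table[table["participant_id"].isin(f.train_patient_ids)]
        test = table[table["participant_id"].isin(f.test_patient_ids)]
        if len(test) == 0:
            raise FoldError(f"fold {f.fold_id} has an empty test set")
        balanced, ledger = balance_training(
            train, BalancingRule(rule.floor, rule.cap,
                                 seed=rule.seed + f.fold_id), class_col)
        # one design over the whole table so category levels (and hence
        # column counts) agree between train and test slices
        feats = [c for c in features if c in table.columns]
        X_all, parents = _rf_design(table, feats)
        pos = {idx: i for i, idx in enumerate(table.index)}
        X_tr = X_all[[pos[i] for i in balanced.index]]
        X_te = X_all[[pos[i] for i in test.index]]
        clf = RandomForestClassifier(n_estimators=n_trees,
                                     random_state=seed + f.fold_id,
                                     n_jobs=1, **rf_params)
        clf.fit(X_tr, balanced[class_col].to_numpy())
        y_pred = clf.predict(X_te)
        y_true = test[class_col].to_numpy()

        point = metrics_from_predictions(y_true, y_pred, averaging_mode,
                                         positive_threshold)
        cis = bootstrap_cis(y_true, y_pred, averaging_mode, b=bootstrap,
                            seed=seed + 1000 + f.fold_id,
                            positive_threshold=positive_threshold)
        classes = tuple(np.unique(np.concatenate([y_true, y_pred])))
        cm = _confusion(y_true, y_pred, np.array(classes))
        out.append(FoldMetrics(fold_id=f.fold_id, n_test=len(test),
                               accuracy=point["accuracy"],
                               precision=point["precision"],
                               recall=point["recall"], f1=point["f1"],
                               cis=cis, averaging_mode=averaging_mode,
                               confusion=cm, classes=classes,
                               balancing_ledger=ledger))
    return out


@dataclass(frozen=True)
class AggregateMetrics:
    stats: dict[str, tuple[float, float]]  # metric -> (mean, sd over folds)

    def as_dict(self) -> dict:
        return {m: dict(mean=v[0], sd=v[1]) for m, v in self.stats.items()}


def aggregate(fold_metrics: Sequence[FoldMetrics | Mapping]) -> AggregateMetrics:
    """Across-fold mean and sample SD (n-1 denominator) per metric."""
    if len(fold_metrics) < 2:
        raise ValueError("aggregation needs at least 2 folds")
    stats = {}
    for m in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([fm[m] if isinstance(fm, Mapping) else getattr(fm, m)
                         for fm in fold_metrics], dtype=float)
        stats[m] = (float(vals.mean()), float(vals.std(ddof=1)))
    return AggregateMetrics(stats)


def fold_metrics_frame(fold_metrics: Sequence[FoldMetrics]) -> pd.DataFrame:
    """Table-shaped view: fold, each metric with its CI bounds."""
    return pd.DataFrame([fm.as_row() for fm in fold_metrics])
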