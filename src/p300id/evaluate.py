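"""Nested cross-validation with balanced-accuracy metrics.

Protocol: the samples are partitioned into 12 outer folds; each outer
training set D_tra is further partitioned into 8 inner folds.  Inside
every outer fold, F_score selection and z-score standardisation are fit
on D_tra only; one classifier is trained per inner split and scored on
its validation subset by balanced validation accuracy (BVA = mean of
sensitivity and specificity, in percent); the inner model with the best
BVA is applied to the held-out outer test set, giving that fold's
balanced testing accuracy (BTA).  ABTA is the mean of the 12 BTAs.

Sensitivity = TP/(TP+FN) x 100 and specificity = TN/(TN+FP) x 100, with
the addiction (MA) class as positive.

Fold construction is stratified by class; a ``subject_aware`` flag
instead keeps all averaged samples of one subject in a single fold
(stricter: no subject appears in both training and test).  Everything is
deterministic given (data, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .classify import TrainConfig, predict_proba, train_bilstm, train_svm_baseline
from .erpfeatures import FeatureTable, N_FEATURES_PER_CHANNEL
from .fscore_select import fit_selection

__all__ = [
    "ConfusionCounts",
    "CVPlan",
    "CVReport",
    "EvalConfig",
    "confusion",
    "sen_spe",
    "balanced_accuracy",
    "build_cv_plan",
    "nested_cv",
    "channel_ablation",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "MA"  # addiction class


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Count TP/FN/TN/FP with class 1 (addiction) as positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def sen_spe(c: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity %, specificity %) of a confusion table."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("undefined rate: a class has no samples")
    return 100.0 * c.tp / (c.tp + c.fn), 100.0 * c.tn / (c.tn + c.fp)


def balanced_accuracy(c: ConfusionCounts) -> float:
    sen, spe = sen_spe(c)
    return (sen + spe) / 2.0


@dataclass
class CVPlan:
    """Outer folds (train/test index pairs) and nested inner folds."""

    outer: list  # [(train_idx, test_idx)] per outer fold
    inner: list  # per outer fold: [(inner_train_idx, inner_val_idx)]
    seed: int
    stratified: bool
    subject_aware: bool

    @property
    def n_outer(self) -> int:
        return len(self.outer)

    def validate(self, n_samples: int, labels: np.ndarray | None = None) -> None:
        """Assert the partition invariants; raises on any violation."""
        all_test = np.concatenate([te for _, te in self.outer])
        if len(all_test) != n_samples or len(np.unique(all_test)) != n_samples:
            raise AssertionError("outer test folds must partition all samples exactly once")
        for k, (tr, te) in enumerate(self.outer):
            if np.intersect1d(tr, te).size:
                raise AssertionError(f"outer fold {k}: train/test overlap")
            if len(tr) + len(te) != n_samples:
                raise AssertionError(f"outer fold {k}: not exhaustive")
            inner_val = np.concatenate([va for _, va in self.inner[k]])
            if sorted(inner_val.tolist()) != sorted(tr.tolist()):
                raise AssertionError(f"outer fold {k}: inner folds must partition the training set")
            for itr, iva in self.inner[k]:
                if np.intersect1d(itr, iva).size:
                    raise AssertionError(f"outer fold {k}: inner train/val overlap")
                union = np.union1d(itr, iva)
                if sorted(union.tolist()) != sorted(tr.tolist()):
                    raise AssertionError(f"outer fold {k}: inner split must cover the training set")


def _stratified_partition(idx_by_class: dict, n_folds: int, rng) -> list[np.ndarray]:
    """Split each class's indices into n_folds near-equal shuffled chunks."""
    folds = [[] for _ in range(n_folds)]
    for cls in sorted(idx_by_class):
        idx = rng.permutation(idx_by_class[cls])
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[f].append(chunk)
    return [np.sort(np.concatenate(parts)) for parts in folds]


def build_cv_plan(
    labels: np.ndarray,
    subject_ids: np.ndarray | None = None,
    outer: int = 12,
    inner: int = 8,
    seed: int = 0,
    stratified: bool = True,
    subject_aware: bool = False,
) -> CVPlan:
    """Seeded 12x8 (by default) nested fold assignment over the samples."""
    labels = np.asarray(labels)
    n = len(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if n < outer or (stratified and counts.min() < outer):
        raise ValueError(f"infeasible fold counts: {counts.min()} samples in the smallest class "
                         f"for {outer} outer folds")
    rng = np.random.default_rng(seed)

    if subject_aware:
        if subject_ids is None:
            raise ValueError("subject_aware folds need subject_ids")
        subject_ids = np.asarray(subject_ids)
        subj_class = {s: labels[subject_ids == s][0] for s in np.unique(subject_ids)}
        by_class = {}
        for s, cls in subj_class.items():
            by_class.setdefault(cls, []).append(s)
        subj_folds = _stratified_partition(
            {c: np.array(v) for c, v in by_class.items()}, outer, rng
        )
        test_folds = [
            np.flatnonzero(np.isin(subject_ids, fold_subjects)) for fold_subjects in subj_folds
        ]
    elif stratified:
        test_folds = _stratified_partition(
            {c: np.flatnonzero(labels == c) for c in classes}, outer, rng
        )
    else:
        test_folds = [np.sort(f) for f in np.array_split(rng.permutation(n), outer)]

    outer_folds, inner_folds = [], []
    for k, te in enumerate(test_folds):
        tr = np.setdiff1d(np.arange(n), te)
        outer_folds.append((tr, te))
        inner_rng = np.random.default_rng((seed, k))
        if stratified and not subject_aware:
            val_folds = _stratified_partition(
                {c: tr[labels[tr] == c] for c in classes}, inner, inner_rng
            )
        else:
            val_folds = [np.sort(f) for f in np.array_split(inner_rng.permutation(tr), inner)]
        inner_folds.append([(np.setdiff1d(tr, va), va) for va in val_folds])

    plan = CVPlan(outer=outer_folds, inner=inner_folds, seed=seed,
                  stratified=stratified, subject_aware=subject_aware)
    plan.validate(n, labels)
    return plan


@dataclass
class EvalConfig:
    classifier: str = "bilstm"  # "bilstm" | "svm"
    outer: int = 12
    inner: int = 8
    seed: int = 0
    stratified: bool = True
    subject_aware: bool = False
    global_selection: bool = False  # one-shot F_score on all data (leaky; off by default)
    train: TrainConfig = field(default_factory=TrainConfig)
    svm_C: float = 1.0


@dataclass
class CVReport:
    """Everything the nested CV measured, per fold and aggregated."""

    folds: list = field(default_factory=list)
    abta: float = np.nan
    abta_sd: float = np.nan
    best_fold: int = -1
    config: dict = field(default_factory=dict)

    @property
    def btas(self) -> np.ndarray:
        return np.array([f["bta"] for f in self.folds])

    def to_json(self, path) -> None:
        payload = {
            "abta": self.abta, "abta_sd": self.abta_sd, "best_fold": self.best_fold,
            "config": self.config, "folds": self.folds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(f"not serialisable: {type(o)}")


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "iufb":
        return labels.astype(int)
    return (labels == POSITIVE_LABEL).astype(int)


def _fit_fold(
    X: np.ndarray, y: np.ndarray, tr: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Selection mask and standardisation moments from the training rows only."""
    sel = fit_selection(X[tr], y[tr])
    mu = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return sel.mask, mu, sd


def _apply(X: np.ndarray, mask: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Standardise, then zero out dropped features (sequence shape preserved)."""
    Xs = (X - mu) / sd
    Xs[:, ~mask] = 0.0
    return Xs


def nested_cv(features: FeatureTable, cfg: EvalConfig | None = None) -> CVReport:
    """Run the full nested protocol on a feature table.

    Returns a report with, per outer fold: the 8 inner (sen, spe, BVA)
    triples, the index of the selected inner model, the outer-test
    confusion counts and BTA, and the kept-feature indices; plus ABTA
    (mean +- sd of the 12 BTAs) and the fold whose BTA is highest.
    """
    cfg = cfg or EvalConfig()
    X = features.matrix.astype(float)
    y = _encode_labels(features.labels)
    plan = build_cv_plan(
        y, features.subject_id, outer=cfg.outer, inner=cfg.inner,
        seed=cfg.seed, stratified=cfg.stratified, subject_aware=cfg.subject_aware,
    )
    n_ch = features.n_channels
    report = CVReport(config={
        "classifier": cfg.classifier, "outer": cfg.outer, "inner": cfg.inner,
        "seed": cfg.seed, "stratified": cfg.stratified,
        "subject_aware": cfg.subject_aware, "global_selection": cfg.global_selection,
        "n_samples": len(y), "n_features": X.shape[1],
    })
    failed = 0
    global_fit = _fit_fold(X, y, np.arange(len(y))) if cfg.global_selection else None

    for k, (tr, te) in enumerate(plan.outer):
        try:
            mask, mu, sd = global_fit if cfg.global_selection else _fit_fold(X, y, tr)
            Xs = _apply(X, mask, mu, sd)
            if cfg.classifier == "bilstm":
                Xin = Xs.reshape(len(y), n_ch, N_FEATURES_PER_CHANNEL)
            elif cfg.classifier == "svm":
                Xin = Xs
            else:
                raise ValueError(f"unknown classifier {cfg.classifier!r}")

            inner_runs = []
            models = []
            for j, (itr, iva) in enumerate(plan.inner[k]):
                if cfg.classifier == "bilstm":
                    tcfg = TrainConfig(**{**asdict(cfg.train), "seed": cfg.train.seed + j})
                    model = train_bilstm(Xin[itr], y[itr], Xin[iva], y[iva], tcfg)
                    val_pred = (predict_proba(model, Xin[iva]) >= 0.5).astype(int)
                else:
                    model = train_svm_baseline(Xin[itr], y[itr], C=cfg.svm_C)
                    val_pred = model.predict(Xin[iva])
                c = confusion(y[iva], val_pred)
                sen, spe = sen_spe(c)
                inner_runs.append({"sen": sen, "spe": spe, "bva": (sen + spe) / 2.0})
                models.append(model)

            bvas = [r["bva"] for r in inner_runs]
            best_inner = int(np.argmax(bvas))  # ties -> lowest fold index
            best_model = models[best_inner]
            if cfg.classifier == "bilstm":
                te_pred = (predict_proba(best_model, Xin[te]) >= 0.5).astype(int)
            else:
                te_pred = best_model.predict(Xin[te])
            c_te = confusion(y[te], te_pred)
            sen_te, spe_te = sen_spe(c_te)
            report.folds.append({
                "fold": k,
                "inner": inner_runs,
                "bva": float(np.mean(bvas)),
                "best_inner": best_inner,
                "counts": {"tp": c_te.tp, "fn": c_te.fn, "tn": c_te.tn, "fp": c_te.fp},
                "sen": sen_te, "spe": spe_te,
                "bta": (sen_te + spe_te) / 2.0,
                "kept_features": np.flatnonzero(mask),
                "n_kept": int(mask.sum()),
            })
            logger.info("outer fold %d: BVA %.2f, BTA %.2f (kept %d features)",
                        k, report.folds[-1]["bva"], report.folds[-1]["bta"], int(mask.sum()))
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover - defensive
            failed += 1
            logger.error("outer fold %d failed: %s", k, exc)
            report.folds.append({"fold": k, "failed": str(exc)})
            if failed * 3 >= plan.n_outer:
                raise RuntimeError(f"{failed} of {plan.n_outer} outer folds failed") from exc

    ok = [f for f in report.folds if "bta" in f]
    report.abta = float(np.mean([f["bta"] for f in ok]))
    report.abta_sd = float(np.std([f["bta"] for f in ok], ddof=1)) if len(ok) > 1 else 0.0
    report.best_fold = int(max(ok, key=lambda f: f["bta"])["fold"])
    return report


def channel_ablation(features: FeatureTable, cfg: EvalConfig | None = None,
                     channels=None):
    """Per-electrode nested CV: classify from each channel's 31 features alone.

    Returns a pandas DataFrame ranked by ABTA (descending), analogous to a
    per-electrode accuracy table.
    """
    import pandas as pd

    cfg = cfg or EvalConfig()
    channels = list(channels) if channels is not None else list(features.channel_names)
    rows = []
    for ch in channels:
        sub = features.restrict([ch])
        rep = nested_cv(sub, cfg)
        rows.append({"channel": ch, "abta": rep.abta, "abta_sd": rep.abta_sd})
        logger.info("ablation %s: ABTA %.2f +- %.2f", ch, rep.abta, rep.abta_sd)
    df = pd.DataFrame(rows).sort_values("abta", ascending=False).reset_index(drop=True)
    df.index += 1
    return df
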