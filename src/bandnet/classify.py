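"""Nested cross-validated RBF-SVM classification.

The outer loop is leave-one-out: every subject is held out once while
feature selection and hyperparameter tuning run on the remaining subjects
only, which is what makes the accuracy estimate unbiased.  The inner loop
is a stratified 10-fold grid search over (C, sigma) maximizing inner
accuracy, ties resolved toward the smaller C then smaller sigma.  The
kernel is K(x1, x2) = exp(-||x1 - x2||^2 / sigma^2) (no factor 2); the
maximal-margin problem itself is solved by scikit-learn's SVC on the
precomputed Gram matrix.

Metrics: ACC/SEN/SPE from the pooled leave-one-out confusion counts, and
AUC from the pooled decision scores (trapezoidal ROC, identical to the
tie-aware normalized Mann-Whitney statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .featselect import FeatureTable, fisher_score, mrmr_rank, sslr_rank

__all__ = [
    "SvmConfig",
    "ConfusionCounts",
    "MetricRates",
    "CvResult",
    "rbf_kernel",
    "rbf_gram",
    "make_selector",
    "nested_cv",
    "metrics",
    "roc_auc",
]


@dataclass(frozen=True)
class SvmConfig:
    """Hyperparameter search space and inner-CV layout."""

    c_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-5, 16, 2))
    sigma_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-4, 7))
    inner_folds: int = 10
    seed: int = 0
    positive_label: int = 1

    def __post_init__(self) -> None:
        if not self.c_grid or not self.sigma_grid:
            raise ValueError("hyperparameter grids must be nonempty")
        if any(c <= 0 for c in self.c_grid) or any(s <= 0 for s in self.sigma_grid):
            raise ValueError("C and sigma must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricRates:
    """ACC/SEN/SPE as percentages; an undefined (0/0) metric is NaN and its
    name is listed in ``undefined`` rather than silently reported as 0."""

    acc: float
    sen: float
    spe: float
    undefined: tuple[str, ...] = ()

    def rounded(self) -> dict[str, float]:
        return {k: round(getattr(self, k), 2) for k in ("acc", "sen", "spe")}


@dataclass(frozen=True)
class CvResult:
    records: pd.DataFrame  # one row per held-out subject
    confusion: ConfusionCounts
    acc: float
    sen: float
    spe: float
    auc: float
    selector: str
    k_features: int


# ---------------------------------------------------------------------------
# kernel


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """exp(-||x1 - x2||^2 / sigma^2)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("vectors must have equal dimension")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return float(np.exp(-np.sum((x1 - x2) ** 2) / sigma**2))


def rbf_gram(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d2 = cdist(a, b, metric="sqeuclidean")
    return np.exp(-d2 / sigma**2)


# ---------------------------------------------------------------------------
# selectors

Selector = Callable[[np.ndarray, np.ndarray, int, int], np.ndarray]


def make_selector(name: str, **kwargs) -> Selector:
    """Wrap a ranking method as ``f(X, y, k, seed) -> top-k indices``."""

    def _mrmr(X, y, k, seed):
        return mrmr_rank(FeatureTable(X, y), k).top(k)

    def _fisher(X, y, k, seed):
        return fisher_score(FeatureTable(X, y)).top(k)

    def _sslr(X, y, k, seed):
        return sslr_rank(FeatureTable(X, y), seed=seed, **kwargs).top(k)

    table = {"mrmr": _mrmr, "fisher": _fisher, "sslr": _sslr}
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"unknown selector {name!r}; known: {sorted(table)}") from None


# ---------------------------------------------------------------------------
# metrics


def metrics(confusion: ConfusionCounts) -> MetricRates:
    """Pooled ACC/SEN/SPE percentages; 0/0 denominators are flagged NaN."""
    und: list[str] = []

    def _pct(num: int, den: int, name: str) -> float:
        if den == 0:
            und.append(name)
            return float("nan")
        return 100.0 * num / den

    acc = _pct(confusion.tp + confusion.tn, confusion.total, "acc")
    sen = _pct(confusion.tp, confusion.tp + confusion.fn, "sen")
    spe = _pct(confusion.tn, confusion.tn + confusion.fp, "spe")
    if und:
        warnings.warn(f"undefined metric(s) {und}: zero denominator", stacklevel=2)
    return MetricRates(acc=acc, sen=sen, spe=spe, undefined=tuple(und))


def roc_auc(scores: Sequence[float], labels: Sequence[int], positive_label: int = 1) -> float:
    """Tie-aware AUC: probability a random positive outranks a random
    negative, with half credit for ties (equals the trapezoidal ROC area)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)  # average ranks give the half-credit tie handling
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# nested CV


def _grid_search(
    X: np.ndarray, y: np.ndarray, cfg: SvmConfig, rng_seed: int
) -> tuple[float, float]:
    """Inner stratified k-fold accuracy over the (C, sigma) grid.

    Best = highest mean accuracy; ties toward smaller C, then smaller
    sigma.  Iterating the grids in ascending order makes the tie rule a
    strict-improvement comparison.
    """
    skf = StratifiedKFold(n_splits=cfg.inner_folds, shuffle=True, random_state=rng_seed % (2**31))
    splits = list(skf.split(X, y))
    d2 = cdist(X, X, metric="sqeuclidean")
    best = (-1.0, None, None)
    for sigma in sorted(cfg.sigma_grid):
        K = np.exp(-d2 / sigma**2)
        for c in sorted(cfg.c_grid):
            hits = 0
            total = 0
            for tr, va in splits:
                svc = SVC(C=c, kernel="precomputed")
                svc.fit(K[np.ix_(tr, tr)], y[tr])
                pred = svc.predict(K[np.ix_(va, tr)])
                hits += int((pred == y[va]).sum())
                total += len(va)
            acc = hits / total
            if acc > best[0] or (
                acc == best[0] and (c, sigma) < (best[1], best[2])
            ):
                best = (acc, c, sigma)
    return best[1], best[2]


def nested_cv(
    table: FeatureTable,
    selector: str | Selector,
    k_features: int,
    cfg: SvmConfig | None = None,
) -> CvResult:
    """Leave-one-out outer loop with in-fold feature selection and inner
    grid search; returns pooled confusion counts, ACC/SEN/SPE and AUC.

    The held-out subject is never seen by the selector, the scaler or the
    grid search.
    """
    cfg = SvmConfig() if cfg is None else cfg
    n = table.n_subjects
    if n < cfg.inner_folds + 1:
        raise ValueError(f"need at least inner_folds+1={cfg.inner_folds + 1} subjects, got {n}")
    selector_name = selector if isinstance(selector, str) else getattr(selector, "__name__", "custom")
    select = make_selector(selector) if isinstance(selector, str) else selector

    ss = np.random.SeedSequence(cfg.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]

    rows = []
    for i in range(n):
        tr = np.setdiff1d(np.arange(n), [i])
        Xtr, ytr = table.X[tr], table.y[tr]
        if len(np.unique(ytr)) < 2:
            raise ValueError(f"training fold {i} contains a single class")
        feat = np.asarray(select(Xtr, ytr, k_features, fold_seeds[i]))[:k_features]
        mu = Xtr[:, feat].mean(axis=0)
        sd = Xtr[:, feat].std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Ztr = (Xtr[:, feat] - mu) / sd
        Zte = (table.X[[i]][:, feat] - mu) / sd

        c, sigma = _grid_search(Ztr, ytr, cfg, fold_seeds[i])
        svc = SVC(C=c, kernel="precomputed")
        Ktr = rbf_gram(Ztr, Ztr, sigma)
        svc.fit(Ktr, ytr)
        Kte = rbf_gram(Zte, Ztr, sigma)
        pred = int(svc.predict(Kte)[0])
        score = float(svc.decision_function(Kte)[0])
        # decision_function sign follows sklearn's class ordering; orient it
        # toward the configured positive label so pooled scores are comparable
        if svc.classes_[1] != cfg.positive_label:
            score = -score
        rows.append(
            {
                "subject": i,
                "true": int(table.y[i]),
                "pred": pred,
                "score": score,
                "C": c,
                "sigma": sigma,
                "selected": tuple(int(f) for f in feat),
            }
        )

    rec = pd.DataFrame(rows)
    pos = cfg.positive_label
    tp = int(((rec["true"] == pos) & (rec["pred"] == pos)).sum())
    tn = int(((rec["true"] != pos) & (rec["pred"] != pos)).sum())
    fp = int(((rec["true"] != pos) & (rec["pred"] == pos)).sum())
    fn = int(((rec["true"] == pos) & (rec["pred"] != pos)).sum())
    confusion = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    rates = metrics(confusion)
    auc = roc_auc(rec["score"].to_numpy(), rec["true"].to_numpy(), positive_label=pos)
    return CvResult(
        records=rec,
        confusion=confusion,
        acc=rates.acc,
        sen=rates.sen,
        spe=rates.spe,
        auc=auc,
        selector=selector_name,
        k_features=int(k_features),
    )
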