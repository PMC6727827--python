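"""Feature ranking: mRMR, stability-selection sparse regression, Fisher Score.

Three selectors rank nodal network features by their ability to separate
two groups:

* **mRMR** — greedy minimal-redundancy-maximal-relevance.  Mutual
  information is estimated by the canonical plug-in estimator on features
  discretized to three levels at mean +/- sd.  The first feature maximizes
  I(x; c); each subsequent one maximizes relevance minus mean redundancy
  against the already-selected set (the incremental first-order search).
* **SS-LR** — stability selection over an L1-penalized linear regression on
  +/-1 labels: many half-sized subsamples, a grid of penalties
  (0.055..0.295 step 0.005), and a per-feature score equal to the maximum
  over the grid of its selection frequency.
* **Fisher Score** — the univariate between-class over within-class scatter
  ratio, with population (class-size) variance convention.

Ties are always broken by lower feature index, so every ranking is
bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "FeatureRanking",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "lasso_fit",
    "lambda_max",
    "sslr_rank",
    "fisher_score",
    "DEFAULT_LAMBDA_GRID",
]

#: Penalty grid: open interval (0.05, 0.3) at step 0.005.
DEFAULT_LAMBDA_GRID = tuple(np.round(0.05 + 0.005 * np.arange(1, 50), 3))


@dataclass(frozen=True)
class FeatureTable:
    """Subjects x features matrix with +/-1 class labels and per-column
    provenance (band, metric, roi)."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame | None = None  # columns: band, metric, roi (1-based)

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        if y.shape != (X.shape[0],):
            raise ValueError("y must have one label per row of X")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing/non-finite values")
        if not np.isin(y, (-1, 1)).all():
            raise ValueError("labels must be coded +1 / -1")
        if self.meta is not None and len(self.meta) != X.shape[1]:
            raise ValueError("meta must describe every feature column")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[rows], self.y[rows], self.meta)


@dataclass(frozen=True)
class FeatureRanking:
    """Feature indices best-first with per-feature scores."""

    order: np.ndarray
    scores: np.ndarray  # aligned with `order`
    method: str

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def to_frame(self, meta: pd.DataFrame | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.order) + 1),
                "feature_id": self.order,
                "score": self.scores,
                "method": self.method,
            }
        )
        if meta is not None:
            df = df.join(meta.reset_index(drop=True), on="feature_id")
        return df


def _rank_desc(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by score descending, ties by lower index."""
    idx = np.arange(len(scores))
    return np.lexsort((idx, -scores))


# ---------------------------------------------------------------------------
# mutual information / mRMR


def discretize(x: np.ndarray) -> np.ndarray:
    """Three-level coding of a feature column: below mean-sd, within, above
    mean+sd.  A constant column collapses to a single level (its MI with
    anything is then 0)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature column has non-finite values")
    mu, sd = x.mean(), x.std(ddof=0)
    levels = np.ones(x.shape, dtype=np.int64)
    levels[x < mu - sd] = 0
    levels[x > mu + sd] = 2
    return levels


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in MI (nats) from the joint contingency table of two
    categorical vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    na, nb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * nb + bi, minlength=na * nb).reshape(na, nb).astype(float)
    n = joint.sum()
    pj = joint / n
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    mask = pj > 0
    return float(np.sum(pj[mask] * np.log(pj[mask] / (pa @ pb)[mask])))


def mrmr_rank(table: FeatureTable, k: int | None = None) -> FeatureRanking:
    """Greedy incremental mRMR ranking of the top ``k`` features.

    Selection score of a candidate is its MI with the class minus the mean
    of its MI with every already-selected feature; the first pick is pure
    max-relevance.  Ties go to the lower feature index.
    """
    m = table.n_features
    k = m if k is None else min(k, m)
    disc = [discretize(table.X[:, j]) for j in range(m)]
    y = (table.y > 0).astype(np.int64)
    relevance = np.array([mutual_information(d, y) for d in disc])

    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(m)
    available = np.ones(m, dtype=bool)
    for step in range(k):
        if step == 0:
            obj = relevance.copy()
        else:
            obj = relevance - redundancy_sum / len(selected)
        obj[~available] = -np.inf
        j = int(np.lexsort((np.arange(m), -obj))[0])
        selected.append(j)
        scores.append(float(obj[j]))
        available[j] = False
        if step < k - 1:
            mi_j = np.array(
                [mutual_information(disc[i], disc[j]) if available[i] else 0.0 for i in range(m)]
            )
            redundancy_sum += mi_j
    return FeatureRanking(order=np.array(selected), scores=np.array(scores), method="mrmr")


# ---------------------------------------------------------------------------
# lasso / stability selection


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient of the standardized
    problem: 2 * max_j |x_j^T y| / n."""
    Xs = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    return float(2.0 * np.max(np.abs(Xs.T @ y)) / len(y))


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8, max_iter: int = 100_000) -> np.ndarray:
    """Minimize (1/n)||Xw - y||^2 + lam*||w||_1 by cyclic coordinate descent.

    Columns are standardized internally (zero mean, unit population
    variance); the returned coefficients are on that standardized scale, in
    original column order.  Non-convergence raises with diagnostics.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    Xs = _standardize(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    # sklearn's objective is 1/(2n)||y - Xw||^2 + alpha*||w||_1 -> alpha = lam/2
    model = Lasso(alpha=lam / 2.0, fit_intercept=False, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model.fit(Xs, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        raise RuntimeError(
            f"coordinate descent did not converge: lam={lam}, n_iter={model.n_iter_}, "
            f"max_iter={max_iter}, tol={tol}"
        )
    return np.asarray(model.coef_, dtype=float)


def sslr_rank(
    table: FeatureTable,
    lambda_grid: tuple[float, ...] | None = None,
    n_subsamples: int = 100,
    seed: int = 0,
) -> FeatureRanking:
    """Stability selection over the lasso path.

    For each of ``n_subsamples`` half-sized subsamples (without
    replacement; one-class draws are redrawn and logged) the lasso is fit
    at every grid penalty; a feature's stability score is the maximum over
    the grid of its selection (nonzero-coefficient) frequency.
    """
    grid = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float)
    grid = np.sort(grid)[::-1]  # descending for warm-started path
    rng = np.random.default_rng(seed)
    n, m = table.n_subjects, table.n_features
    half = int(np.ceil(n / 2))
    counts = np.zeros((len(grid), m))
    y_full = table.y.astype(float)
    done = 0
    while done < n_subsamples:
        rows = rng.choice(n, size=half, replace=False)
        if len(np.unique(y_full[rows])) < 2:
            logger.info("subsample with a single class redrawn")
            continue
        Xs = _standardize(table.X[rows])
        ys = y_full[rows]
        _, coefs, _ = lasso_path(Xs, ys, alphas=grid / 2.0, tol=1e-6, max_iter=100_000)
        counts += (np.abs(coefs.T) > 1e-12)
        done += 1
    freq = counts / n_subsamples
    scores = freq.max(axis=0)
    order = _rank_desc(scores)
    return FeatureRanking(order=order, scores=scores[order], method="sslr")


# ---------------------------------------------------------------------------
# Fisher Score


def fisher_score(table: FeatureTable) -> FeatureRanking:
    """Univariate between-class over within-class scatter per feature:

    FS(i) = [n1(m1i - mi)^2 + n2(m2i - mi)^2] / [n1*var1i + n2*var2i]

    with population (divide-by-class-size) variances.  A feature with zero
    pooled variance scores 0 when the class means agree and +inf (ranked
    first) when they differ.
    """
    y = table.y
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = table.X
    g1, g2 = X[y > 0], X[y < 0]
    n1, n2 = len(g1), len(g2)
    m_all = X.mean(axis=0)
    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    v1, v2 = g1.var(axis=0, ddof=0), g2.var(axis=0, ddof=0)
    num = n1 * (m1 - m_all) ** 2 + n2 * (m2 - m_all) ** 2
    den = n1 * v1 + n2 * v2
    scores = np.zeros(table.n_features)
    ok = den > 0
    scores[ok] = num[ok] / den[ok]
    scores[(~ok) & (num > 0)] = np.inf
    order = _rank_desc(scores)
    return FeatureRanking(order=order, scores=scores[order], method="fisher")
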