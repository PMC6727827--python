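"""Fisher-z Pearson connectivity matrices and cost-thresholded binary networks.

Edges of the functional network are Pearson correlations between every pair
of ROI time series, variance-stabilized by Fisher's r-to-z (atanh).  A
binary network at *cost* c keeps the round(c * n(n-1)/2) strongest edges,
so every subject's network has the same connection density regardless of
the overall correlation level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConnectivityMatrix",
    "BinaryNetwork",
    "correlation_matrix",
    "binarize_at_cost",
    "n_edges_at_cost",
]

#: Clip bound on |r| before atanh so z stays finite.
R_CLIP = 0.999999


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Fisher-z edge-weight matrix with zero diagonal."""

    z: np.ndarray
    band: str = "full"
    subject_id: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if not np.all(np.isfinite(z)):
            raise ValueError("z must be finite everywhere")
        if not np.allclose(z, z.T):
            raise ValueError("z must be symmetric")
        if np.any(np.diag(z) != 0):
            raise ValueError("z must have a zero diagonal")

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Square TSV-friendly frame with 1-based ROI labels."""
        labels = [str(i + 1) for i in range(self.n_rois)]
        return pd.DataFrame(self.z, index=labels, columns=labels)


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected unweighted network retained at a given connection cost."""

    adjacency: np.ndarray
    cost: float = float("nan")

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.dtype != np.int8:
            a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("no self-loops allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def correlation_matrix(series) -> ConnectivityMatrix:
    """Pearson correlations between all ROI pairs, Fisher r-to-z transformed.

    r is clipped to [-0.999999, 0.999999] before atanh so that perfectly
    (anti)correlated pairs stay finite; the diagonal is set to zero.
    """
    data = np.asarray(series.data, dtype=float)
    sd = data.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance ROI(s) {(dead + 1).tolist()} (1-based) in subject "
            f"{getattr(series, 'subject_id', '?')}: correlation undefined"
        )
    r = np.corrcoef(data)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # exact symmetry against float round-off
    return ConnectivityMatrix(z=z, band=getattr(series, "band", "full"),
                              subject_id=getattr(series, "subject_id", ""))


def n_edges_at_cost(n_nodes: int, cost: float) -> int:
    """round-half-up(cost * n(n-1)/2); deterministic across platforms."""
    return int(np.floor(cost * n_nodes * (n_nodes - 1) / 2.0 + 0.5))


def _ranked_edges(z: np.ndarray, rank_by: str) -> tuple[np.ndarray, np.ndarray]:
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju]
    if rank_by == "absolute":
        w = np.abs(w)
    elif rank_by != "signed":
        raise ValueError(f"rank_by must be 'signed' or 'absolute', got {rank_by!r}")
    # strongest first; ties broken by lexicographic (i, j)
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def binarize_at_cost(cm: ConnectivityMatrix, cost: float, rank_by: str = "signed") -> BinaryNetwork:
    """Keep the m = round(cost * n(n-1)/2) strongest edges.

    ``rank_by='signed'`` keeps the largest signed z (strongest positive
    correlations); ``'absolute'`` ranks by |z|.  Ties are broken by
    lexicographic (i, j) order, which also makes the retained edge set
    monotone in cost.
    """
    if not (0.0 < cost <= 1.0):
        raise ValueError(f"cost must be in (0, 1], got {cost}")
    n = cm.n_rois
    m = n_edges_at_cost(n, cost)
    if m == 0:
        raise ValueError(f"cost {cost} retains zero edges on {n} nodes")
    iu, ju = _ranked_edges(cm.z, rank_by)
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[:m], ju[:m]] = 1
    a = a | a.T
    return BinaryNetwork(adjacency=a, cost=cost)
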