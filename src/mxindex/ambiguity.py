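"""Resolution of indexing ambiguities across many partial datasets.

For lattices whose point symmetry is lower than that of the Bravais
lattice (e.g. space group I23 on a cubic I lattice), two geometrically
indistinguishable index assignments exist.  Before merging, every
partial dataset must be brought to a consistent mode.  Following the
pair-correlation embedding approach of Brehm & Diederichs, each dataset
is embedded as a low-dimensional point x_i by minimizing

    E(X) = sum_{i<j} w_ij (x_i . x_j - cc_ij)^2

over the pairwise Pearson correlations cc_ij of intensities on shared
Miller indices; datasets indexed in the same mode form one cluster of
directions, the alternative mode the other.  Labels are meaningful only
up to a global swap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "PartialDataset",
    "ambiguity_operators",
    "point_group_rotations",
    "laue_group_ops",
    "canonical_index",
    "pairwise_cc",
    "resolve_modes",
    "ModeResolution",
]

_IDENTITY = np.eye(3, dtype=int)
# two-fold along [110]: (h, k, l) -> (k, h, -l); the coset representative
# exchanging the two indexing modes of a cubic I/P lattice with point
# group 23
_SWAP_HK = np.array([[0, 1, 0], [1, 0, 0], [0, 0, -1]], dtype=int)

_TWO_MODE_GROUPS = {"I23", "P23", "I213", "P213", "F23"}


def _normalize_symbol(symbol: str) -> str:
    return symbol.replace(" ", "").replace("_", "").upper()


def ambiguity_operators(space_group_symbol: str) -> list[np.ndarray]:
    """Identity plus the alternative-indexing operators for a space group.

    Supported: P1 (no ambiguity) and the cubic point-group-23 groups
    (exactly two indexing modes).  Anything else raises
    NotImplementedError.
    """
    sym = _normalize_symbol(space_group_symbol)
    if sym == "P1":
        return [_IDENTITY.copy()]
    if sym in _TWO_MODE_GROUPS:
        return [_IDENTITY.copy(), _SWAP_HK.copy()]
    raise NotImplementedError(f"ambiguity operators for {space_group_symbol!r} not implemented")


def point_group_rotations(point_group: str = "23") -> list[np.ndarray]:
    """Rotation matrices (acting on hkl) of a supported point group."""
    if point_group != "23":
        raise NotImplementedError(f"point group {point_group!r} not implemented")
    # 23: identity, 3 two-folds along axes, 8 three-folds along body diagonals
    ops = []
    perms = [
        np.eye(3),
        np.array([[0, 0, 1], [1, 0, 0], [0, 1, 0]]),  # cyclic h->k->l->h
        np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]]),
    ]
    signs = [
        np.diag(s)
        for s in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1])
    ]
    for P in perms:
        for S in signs:
            ops.append((P @ S).astype(int))
    return ops


def laue_group_ops(point_group: str = "23") -> list[np.ndarray]:
    """Point-group rotations plus Friedel inversion (Laue group m-3)."""
    rots = point_group_rotations(point_group)
    return rots + [-M for M in rots]


def canonical_index(h: np.ndarray, ops: list[np.ndarray]) -> tuple:
    """Lexicographically largest symmetry equivalent of a Miller index."""
    h = np.asarray(h, dtype=int)
    return max(tuple(int(v) for v in (M @ h)) for M in ops)


def laue_ops_for_space_group(symbol: str) -> list[np.ndarray]:
    """Laue-group operators used to merge symmetry-equivalent indices."""
    sym = _normalize_symbol(symbol)
    if sym == "P1":
        return [_IDENTITY.copy(), -_IDENTITY]
    if sym in _TWO_MODE_GROUPS:
        return laue_group_ops("23")
    raise NotImplementedError(f"Laue operators for {symbol!r} not implemented")


@dataclass
class PartialDataset:
    """Very incomplete reflection set from one narrow wedge.

    ``observations`` has columns h, k, l, I, sigma; indices are merged
    (mean intensity) within the dataset before any correlation.
    """

    id: str
    observations: pd.DataFrame
    space_group: str = "I23"

    def merged(self) -> dict[tuple, float]:
        """Mean intensity per symmetry-unique (Laue-reduced) index."""
        ops = laue_ops_for_space_group(self.space_group)
        acc: dict[tuple, list[float]] = {}
        for row in self.observations.itertuples(index=False):
            key = canonical_index((row.h, row.k, row.l), ops)
            acc.setdefault(key, []).append(float(row.I))
        return {k: float(np.mean(v)) for k, v in acc.items()}


def pairwise_cc(
    datasets: list[PartialDataset],
    operators: list[np.ndarray] | None = None,
    min_common: int = 3,
) -> dict:
    """Pairwise intensity correlations under each relative reindexing.

    Returns a dict with 'cc' (correlation under identity), 'cc_best'
    (max over operators), 'best_op' (operator index achieving it) and
    'n_common'; entries are NaN/-1 for pairs sharing fewer than
    ``min_common`` reflections.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    if operators is None:
        operators = ambiguity_operators(datasets[0].space_group)
    n = len(datasets)
    laue = laue_ops_for_space_group(datasets[0].space_group)
    merged = [ds.merged() for ds in datasets]
    reindexed = []
    for m in merged:
        per_op = []
        for M in operators:
            # reindex, then re-reduce: the operator maps between symmetry
            # classes, not individual indices
            per_op.append({canonical_index(M @ np.array(k), laue): val for k, val in m.items()})
        reindexed.append(per_op)

    cc = np.full((n, n), np.nan)
    cc_best = np.full((n, n), np.nan)
    best_op = np.full((n, n), -1, dtype=int)
    n_common = np.zeros((n, n), dtype=int)
    np.fill_diagonal(cc, 1.0)
    np.fill_diagonal(cc_best, 1.0)
    np.fill_diagonal(best_op, 0)

    for i in range(n):
        for j in range(i + 1, n):
            vals = []
            for op_idx in range(len(operators)):
                mj = reindexed[j][op_idx]
                common = [k for k in merged[i] if k in mj]
                if len(common) < min_common:
                    vals.append((np.nan, len(common)))
                    continue
                a = np.array([merged[i][k] for k in common])
                b = np.array([mj[k] for k in common])
                if np.std(a) == 0 or np.std(b) == 0:
                    vals.append((np.nan, len(common)))
                    continue
                vals.append((pearsonr(a, b).statistic, len(common)))
            cc[i, j] = cc[j, i] = vals[0][0]
            n_common[i, j] = n_common[j, i] = max(v[1] for v in vals)
            finite = [(v, k) for k, (v, _) in enumerate(vals) if np.isfinite(v)]
            if finite:
                v, k = max(finite)
                cc_best[i, j] = cc_best[j, i] = v
                best_op[i, j] = best_op[j, i] = k
    return {"cc": cc, "cc_best": cc_best, "best_op": best_op, "n_common": n_common}


@dataclass
class ModeResolution:
    labels: np.ndarray  # 0 / 1 per dataset, up to a global swap
    coords: np.ndarray  # embedded points, shape (n, dim)
    objective: float
    history: list = field(default_factory=list)


def _objective_grad(X: np.ndarray, C: np.ndarray, W: np.ndarray):
    S = X @ X.T
    D = W * (S - C)
    np.fill_diagonal(D, 0.0)
    E = 0.5 * float(np.sum(D * (S - C)))  # each pair counted twice in the sum
    G = 2.0 * D @ X
    return E, G


def resolve_modes(
    cc_matrix: np.ndarray,
    seed: int = 0,
    dim: int = 2,
    n_restarts: int = 100,
    n_iterations: int = 300,
) -> ModeResolution:
    """Embed datasets from their correlation matrix and split into 2 modes.

    Gradient descent with backtracking line search minimizes the
    weighted discrepancy between pairwise dot products and observed
    correlations; the best of ``n_restarts`` random starts is kept and
    the embedded directions are partitioned into two clusters.  Missing
    correlations get weight zero; if the resulting pair graph is
    disconnected, each component is labelled independently and a
    warning is issued.
    """
    C = np.array(cc_matrix, dtype=float)
    n = C.shape[0]
    W = np.isfinite(C).astype(float)
    np.fill_diagonal(W, 0.0)
    C = np.nan_to_num(C)

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(*np.where(W > 0)))
    components = list(nx.connected_components(g))
    if len(components) > 1:
        warnings.warn(
            f"correlation graph has {len(components)} components; "
            "modes are labelled per component",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        X = rng.normal(scale=0.5, size=(n, dim))
        E, G = _objective_grad(X, C, W)
        history = [E]
        step = 0.05
        for _ in range(n_iterations):
            # backtracking line search keeps the objective non-increasing
            while step > 1e-12:
                X_new = X - step * G
                E_new, G_new = _objective_grad(X_new, C, W)
                if E_new <= E:
                    break
                step *= 0.5
            if step <= 1e-12 or E - E_new < 1e-12 * max(E, 1.0):
                X, E, G = X_new, E_new, G_new
                history.append(E)
                break
            X, E, G = X_new, E_new, G_new
            history.append(E)
            step *= 1.3
        if best is None or E < best[0]:
            best = (E, X, history)
    E, X, history = best

    labels = np.zeros(n, dtype=int)
    for comp in components:
        idx = sorted(comp)
        if len(idx) == 1:
            continue
        norms = np.linalg.norm(X[idx], axis=1)
        dirs = X[idx] / np.maximum(norms, 1e-12)[:, None]
        km = KMeans(n_clusters=2, n_init=10, random_state=int(seed) % (2**31)).fit(dirs)
        labels[idx] = km.labels_
    return ModeResolution(labels=labels, coords=X, objective=E, history=history)
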