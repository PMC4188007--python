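"""Known-cell hemisphere search for real-space basis-vector directions.

Given the set of reciprocal-lattice vectors {r_j} mapped from observed
centroids, the real-space functional

    F(x) = sum_j cos(2 pi r_j . x)

is maximal where every r_j . x is close to an integer, i.e. where x is a
real-space basis vector of a lattice present in the data (or an integer
combination of basis vectors).  Because the target unit cell is known,
|x| can be fixed to each cell-edge length in turn, reducing the search
to a two-dimensional scan over directions sampled quasi-uniformly on a
hemisphere.  Surviving high-scoring directions are combined into
candidate setting matrices consistent with the known cell, and the
candidate indexing the most centroids wins.

Multiple lattices simply contribute separate families of maxima to
F(x), which is what makes the iterative peel-off strategy of the
indexing driver possible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .geometry import Crystal, UnitCell

logger = logging.getLogger(__name__)

__all__ = [
    "DirectionCandidate",
    "SearchConfig",
    "IndexingFailure",
    "sample_hemisphere",
    "functional_F",
    "find_candidate_vectors",
    "candidate_bases",
    "select_best_basis",
]


class IndexingFailure(RuntimeError):
    """Raised when no lattice can be determined from the input."""


@dataclass(frozen=True)
class DirectionCandidate:
    """A scored basis-vector candidate from the hemisphere search."""

    x: np.ndarray  # real-space vector, Angstrom
    score: float  # F(x)
    psi: float  # spherical azimuth, radians
    theta: float  # spherical polar angle from the pole, radians

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.x))

    @property
    def direction(self) -> np.ndarray:
        return self.x / self.length


@dataclass(frozen=True)
class SearchConfig:
    """Tunable parameters of the basis search.

    angular_spacing : radians between sampled hemisphere directions.
        The default 0.015 rad keeps the worst-case direction error
        (~0.43 degrees) inside the refinement basin.
    collinearity_angle : degrees; candidates within this angle (parallel
        or antiparallel) of a higher-scoring candidate are dropped.
    max_candidates : size of the reduced candidate list fed to basis
        assembly (default 30).
    rel_length_tol / abs_angle_tol : tolerances for matching candidate
        triples against the known cell.
    hkl_tolerance : max |h' - round(h')| for a centroid to count as
        indexed (default 0.3).
    """

    angular_spacing: float = 0.015
    collinearity_angle: float = 5.0
    max_candidates: int = 30
    rel_length_tol: float = 0.10
    abs_angle_tol: float = 5.0
    hkl_tolerance: float = 0.3

    def __post_init__(self):
        if not (
            self.angular_spacing > 0
            and self.collinearity_angle > 0
            and self.rel_length_tol > 0
            and self.abs_angle_tol > 0
            and self.hkl_tolerance > 0
        ):
            raise ValueError("search parameters must be positive")
        if self.max_candidates < 3:
            raise ValueError("max_candidates must be at least 3")


def sample_hemisphere(angular_spacing: float) -> np.ndarray:
    """Quasi-uniform unit directions covering one hemisphere (v_z >= 0).

    Rings of constant polar angle theta spaced by ``angular_spacing``;
    within each ring the azimuthal step scales as 1/sin(theta) so the
    surface density is approximately constant.  The equatorial ring is
    restricted to half a turn so no two returned vectors are
    antiparallel.
    """
    if not 0 < angular_spacing < math.pi / 2:
        raise ValueError("angular_spacing must lie in (0, pi/2)")
    n_rings = int(round(math.pi / 2 / angular_spacing))
    dirs = [np.array([0.0, 0.0, 1.0])]
    psis, thetas = [0.0], [0.0]
    for i in range(1, n_rings + 1):
        theta = i * (math.pi / 2) / n_rings
        at_equator = i == n_rings
        span = math.pi if at_equator else 2 * math.pi
        n_psi = max(1, int(round(span * math.sin(theta) / angular_spacing)))
        for j in range(n_psi):
            psi = j * span / n_psi
            dirs.append(
                np.array(
                    [
                        math.sin(theta) * math.cos(psi),
                        math.sin(theta) * math.sin(psi),
                        math.cos(theta),
                    ]
                )
            )
            psis.append(psi)
            thetas.append(theta)
    return np.array(dirs)


def _hemisphere_with_angles(angular_spacing: float):
    dirs = sample_hemisphere(angular_spacing)
    theta = np.arccos(np.clip(dirs[:, 2], -1, 1))
    psi = np.arctan2(dirs[:, 1], dirs[:, 0]) % (2 * math.pi)
    return dirs, psi, theta


def functional_F(r_set: np.ndarray, x: np.ndarray) -> float:
    """Direct-space periodicity score F(x) = sum_j cos(2 pi r_j . x)."""
    r_set = np.atleast_2d(np.asarray(r_set, dtype=float))
    if r_set.size == 0:
        return 0.0
    return float(np.sum(np.cos(2.0 * math.pi * (r_set @ np.asarray(x, dtype=float)))))


def _functional_F_many(r_set: np.ndarray, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """F evaluated for each row of X; chunked to bound memory."""
    scores = np.empty(len(X))
    for i in range(0, len(X), chunk):
        block = X[i : i + chunk] @ r_set.T
        scores[i : i + chunk] = np.cos(2.0 * math.pi * block).sum(axis=1)
    return scores


def find_candidate_vectors(
    r_set: np.ndarray, cell: UnitCell, config: SearchConfig | None = None
) -> list[DirectionCandidate]:
    """Top basis-vector candidates from the known-length hemisphere search.

    For each distinct cell-edge length the hemisphere of directions is
    scored with F; the merged list is sorted by decreasing score,
    near-collinear lower-scoring candidates are eliminated and the list
    truncated to ``config.max_candidates``.
    """
    config = config or SearchConfig()
    r_set = np.atleast_2d(np.asarray(r_set, dtype=float))
    if len(r_set) < 20:
        raise IndexingFailure(f"too few reflections for a basis search ({len(r_set)} < 20)")
    dirs, psi, theta = _hemisphere_with_angles(config.angular_spacing)

    lengths = []
    for L in cell.lengths:
        if not any(abs(L - L0) <= 1e-3 * L0 for L0 in lengths):
            lengths.append(L)

    cands: list[DirectionCandidate] = []
    for L in lengths:
        scores = _functional_F_many(r_set, dirs * L)
        for i in range(len(dirs)):
            cands.append(
                DirectionCandidate(x=dirs[i] * L, score=scores[i], psi=psi[i], theta=theta[i])
            )
    cands.sort(key=lambda c: -c.score)

    cos_tol = math.cos(math.radians(config.collinearity_angle))
    kept: list[DirectionCandidate] = []
    kept_dirs = np.empty((0, 3))
    for c in cands:
        if len(kept) and np.any(np.abs(kept_dirs @ c.direction) > cos_tol):
            continue
        kept.append(c)
        kept_dirs = np.vstack([kept_dirs, c.direction])
        if len(kept) >= config.max_candidates:
            break
    logger.info(
        "direction search: %d candidates kept, best score %.1f of %d reflections",
        len(kept),
        kept[0].score if kept else float("nan"),
        len(r_set),
    )
    return kept


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    return math.degrees(
        math.acos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
    )


def candidate_bases(
    candidates: list[DirectionCandidate],
    cell: UnitCell,
    config: SearchConfig | None = None,
) -> list[Crystal]:
    """Assemble candidate setting matrices from scored direction vectors.

    Enumerates ordered triples (with sign choices, since the hemisphere
    search only sees one of +-x) whose lengths match (a, b, c) within
    ``rel_length_tol`` and whose pairwise angles match (alpha, beta,
    gamma) within ``abs_angle_tol``; each consistent right-handed,
    non-degenerate triple yields a Crystal.
    """
    config = config or SearchConfig()
    if len(candidates) < 3:
        return []
    a, b, c = cell.lengths
    al, be, ga = cell.angles
    vol_min = 0.1 * cell.volume

    vecs = [cand.x for cand in candidates]
    lens = np.array([cand.length for cand in candidates])
    ok_a = np.where(np.abs(lens - a) <= config.rel_length_tol * a)[0]
    ok_b = np.where(np.abs(lens - b) <= config.rel_length_tol * b)[0]
    ok_c = np.where(np.abs(lens - c) <= config.rel_length_tol * c)[0]

    bases: list[Crystal] = []
    seen: set[tuple] = set()
    for i in ok_a:
        v1 = vecs[i]
        for j in ok_b:
            if j == i:
                continue
            for sj in (1.0, -1.0):
                v2 = sj * vecs[j]
                if abs(_angle_deg(v1, v2) - ga) > config.abs_angle_tol:
                    continue
                for k in ok_c:
                    if k == i or k == j:
                        continue
                    for sk in (1.0, -1.0):
                        v3 = sk * vecs[k]
                        if abs(_angle_deg(v1, v3) - be) > config.abs_angle_tol:
                            continue
                        if abs(_angle_deg(v2, v3) - al) > config.abs_angle_tol:
                            continue
                        real = np.array([v1, v2, v3])
                        det = np.linalg.det(real)
                        if abs(det) < vol_min:
                            continue  # (near-)coplanar triple
                        if det < 0:
                            # overall inversion preserves lengths/angles
                            real = -real
                        key = tuple(np.round(real.ravel(), 6))
                        if key in seen:
                            continue
                        seen.add(key)
                        bases.append(Crystal.from_A(np.linalg.inv(real)))
    return bases


def select_best_basis(
    bases: list[Crystal], r_set: np.ndarray, hkl_tolerance: float = 0.3
) -> Crystal:
    """Pick the basis indexing the most centroids.

    Ties are broken by the smaller mean |h' - h| over the reflections the
    basis indexes.
    """
    if not bases:
        raise IndexingFailure("no candidate bases to select from")
    r_set = np.atleast_2d(np.asarray(r_set, dtype=float))
    best = None
    best_key = None
    for crystal in bases:
        hf = r_set @ crystal.A_inv.T
        resid = np.linalg.norm(hf - np.round(hf), axis=1)
        n_indexed = int(np.sum(resid < hkl_tolerance))
        mean_resid = float(resid[resid < hkl_tolerance].mean()) if n_indexed else np.inf
        key = (-n_indexed, mean_resid)
        if best_key is None or key < best_key:
            best, best_key = crystal, key
    logger.info("selected basis indexes %d / %d reflections", -best_key[0], len(r_set))
    return best
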