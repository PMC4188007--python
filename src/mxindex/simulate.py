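"""Rotation-method spot-list simulator.

Generates synthetic spot-centroid tables with known ground truth for one
or more crystal lattices recorded over a wedge of rotation data — the
test bed for the multi-lattice indexing pipeline.  Works at the centroid
level: the reflecting condition is solved exactly for every
reciprocal-lattice point inside the resolution sphere, the detector
impact computed, and Gaussian centroid noise plus optional spurious
spots added.  Pixel-level image synthesis, intensity profiles and
radiation damage are out of scope.

The default fixture mirrors a narrow-wedge microcrystal experiment:
0.1 degree frames, wavelength 0.97949 A, 214 mm crystal-to-detector
distance and a PILATUS-6M-like pixel grid (2463 x 2527 pixels of
0.172 mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import (
    Beam,
    Crystal,
    Detector,
    Experiment,
    GeometryError,
    Goniometer,
    Scan,
    UnitCell,
    rotation_about_axis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationSpec",
    "default_experiment",
    "random_crystal",
    "solve_reflecting_angles",
    "impacts_on_detector",
    "predict_spots",
    "add_noise",
    "compose_lattices",
    "simulate_multi_lattice",
]

SPOT_COLUMNS = ["x_px", "y_px", "z", "var_x", "var_y", "var_z"]


def default_experiment(
    wavelength: float = 0.97949,
    distance: float = 214.0,
    delta_phi: float = 0.1,
    n_frames: int = 100,
    phi_start: float = 0.0,
    n_fast: int = 2463,
    n_slow: int = 2527,
    pixel_size: float = 0.172,
) -> Experiment:
    """Beam along +z, rotation axis along +x, detector normal to the beam.

    The detector origin is placed so the direct beam strikes the panel
    centre.
    """
    origin = np.array([-0.5 * n_fast * pixel_size, -0.5 * n_slow * pixel_size, distance])
    return Experiment(
        beam=Beam(wavelength=wavelength, direction=np.array([0.0, 0.0, 1.0])),
        detector=Detector(
            fast_axis=np.array([1.0, 0.0, 0.0]),
            slow_axis=np.array([0.0, 1.0, 0.0]),
            origin=origin,
            n_fast=n_fast,
            n_slow=n_slow,
            pixel_size=pixel_size,
        ),
        goniometer=Goniometer(axis=np.array([1.0, 0.0, 0.0])),
        scan=Scan(phi_start=phi_start, delta_phi=delta_phi, n_frames=n_frames),
    )


def random_crystal(cell: UnitCell, rng: np.random.Generator) -> Crystal:
    """Crystal with the given cell and a uniformly random orientation."""
    U = Rotation.random(random_state=rng).as_matrix()
    return Crystal(U=U, cell=cell)


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic multi-lattice experiment."""

    crystals: list
    geometry: Experiment
    d_min: float = 4.0
    noise_sd: tuple = (0.3, 0.3, 0.3)  # (px, px, frames)
    n_spurious: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")
        if min(self.noise_sd) < 0:
            raise ValueError("noise_sd must be non-negative")


def _miller_grid(crystal: Crystal, d_min: float) -> np.ndarray:
    """All integer triples whose reciprocal vector can reach 1/d_min."""
    real = crystal.real_space_vectors
    hmax = np.floor(np.linalg.norm(real, axis=1) / d_min).astype(int) + 1
    axes = [np.arange(-m, m + 1) for m in hmax]
    H = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return H[np.any(H != 0, axis=1)]


def solve_reflecting_angles(
    r0: np.ndarray, beam: Beam, goniometer: Goniometer
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation angles at which each vector crosses the Ewald sphere.

    For each reciprocal-lattice vector ``r0`` (rows, phi = 0 frame) the
    reflecting condition ``|R(phi) r0 + s0| = 1/lambda`` reduces to
    ``a cos(phi) + b sin(phi) = c``.  Returns (phi1, phi2, solvable):
    two solution branches in degrees (in [0, 360)) and a mask of rows
    with any solution; blind-region vectors have solvable = False.
    """
    r0 = np.atleast_2d(np.asarray(r0, dtype=float))
    m = goniometer.axis
    s0 = beam.s0
    proj = r0 @ m
    c0 = np.outer(proj, m)
    c1 = r0 - c0
    c2 = np.cross(np.broadcast_to(m, r0.shape), r0)
    a = 2.0 * (c1 @ s0)
    b = 2.0 * (c2 @ s0)
    c = -(np.sum(r0 * r0, axis=1) + 2.0 * (c0 @ s0))
    rho = np.hypot(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(rho > 0, c / np.where(rho > 0, rho, 1.0), np.inf)
    solvable = np.abs(ratio) <= 1.0
    base = np.arctan2(b, a)
    delta = np.arccos(np.clip(ratio, -1.0, 1.0))
    phi1 = np.degrees(base + delta) % 360.0
    phi2 = np.degrees(base - delta) % 360.0
    return phi1, phi2, solvable


def impacts_on_detector(
    s1: np.ndarray, detector: Detector
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Intersect scattered-beam rays with the detector plane.

    Solves ``t s1 = d_x x + d_y y + d_0`` per row; returns continuous
    pixel coordinates (x_px, y_px) and a mask of rays that hit the panel
    travelling forwards (t > 0) inside the pixel bounds.
    """
    s1 = np.atleast_2d(s1)
    n = s1.shape[0]
    M = np.empty((n, 3, 3))
    M[:, :, 0] = detector.fast_axis
    M[:, :, 1] = detector.slow_axis
    M[:, :, 2] = -s1
    rhs = np.broadcast_to(-detector.origin, (n, 3))
    ok = np.abs(np.linalg.det(M)) > 1e-12
    sol = np.full((n, 3), np.nan)
    if ok.any():
        sol[ok] = np.linalg.solve(M[ok], rhs[ok][..., None])[..., 0]
    x_mm, y_mm, t = sol[:, 0], sol[:, 1], sol[:, 2]
    x_px = x_mm / detector.pixel_size - 0.5
    y_px = y_mm / detector.pixel_size - 0.5
    with np.errstate(invalid="ignore"):
        hit = (
            ok
            & (t > 0)
            & (x_px >= 0)
            & (x_px < detector.n_fast)
            & (y_px >= 0)
            & (y_px < detector.n_slow)
        )
    return x_px, y_px, hit


def predict_spots(crystal: Crystal, geometry: Experiment, d_min: float) -> pd.DataFrame:
    """Predict all spot centroids for one crystal over the scan.

    Returns a DataFrame with columns h, k, l, phi, x_px, y_px, z: one
    row per Ewald-sphere crossing inside the scan whose scattered ray
    hits the detector.  Reflections in the blind region (never crossing
    the sphere) or missing the panel are omitted.
    """
    scan, beam, det, gonio = geometry.scan, geometry.beam, geometry.detector, geometry.goniometer
    if scan.total_range <= 0:
        return pd.DataFrame(columns=["h", "k", "l", "phi", "x_px", "y_px", "z"])
    H = _miller_grid(crystal, d_min)
    r0 = H @ crystal.A.T
    norms = np.linalg.norm(r0, axis=1)
    keep = (norms > 0) & (norms <= 1.0 / d_min) & (norms <= 2.0 / beam.wavelength)
    H, r0 = H[keep], r0[keep]
    if len(H) == 0:
        logger.warning("no reciprocal-lattice points inside the resolution sphere")
        return pd.DataFrame(columns=["h", "k", "l", "phi", "x_px", "y_px", "z"])
    phi1, phi2, solvable = solve_reflecting_angles(r0, beam, gonio)

    rows = []
    for phis in (phi1, phi2):
        # bring each branch solution into the scan interval (mod 360)
        shift = np.floor((phis - scan.phi_start) / 360.0)
        phi = phis - 360.0 * shift  # in [phi_start, phi_start + 360)
        in_scan = solvable & (phi >= scan.phi_start) & (phi <= scan.phi_end)
        if not in_scan.any():
            continue
        idx = np.where(in_scan)[0]
        R = rotation_about_axis(gonio.axis, phi[idx])
        r_phi = np.einsum("nij,nj->ni", R, r0[idx])
        s1 = r_phi + beam.s0
        x_px, y_px, hit = impacts_on_detector(s1, det)
        sub = np.where(hit)[0]
        for j in sub:
            i = idx[j]
            rows.append(
                (
                    H[i, 0],
                    H[i, 1],
                    H[i, 2],
                    phi[i],
                    x_px[j],
                    y_px[j],
                    (phi[i] - scan.phi_start) / scan.delta_phi,
                )
            )
    df = pd.DataFrame(rows, columns=["h", "k", "l", "phi", "x_px", "y_px", "z"])
    if len(df):
        df[["h", "k", "l"]] = df[["h", "k", "l"]].astype(int)
    return df.sort_values(["h", "k", "l", "phi"], ignore_index=True)


def add_noise(spots: pd.DataFrame, noise_sd, seed: int) -> pd.DataFrame:
    """Add independent Gaussian centroid noise; records variances used.

    ``noise_sd`` is (sd_x px, sd_y px, sd_z frames).  Deterministic for
    a given seed; zero sd leaves coordinates untouched.
    """
    sx, sy, sz = (float(s) for s in noise_sd)
    if min(sx, sy, sz) < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = spots.copy()
    n = len(out)
    out["x_px"] = out["x_px"] + rng.normal(0.0, sx, n) if sx > 0 else out["x_px"]
    out["y_px"] = out["y_px"] + rng.normal(0.0, sy, n) if sy > 0 else out["y_px"]
    out["z"] = out["z"] + rng.normal(0.0, sz, n) if sz > 0 else out["z"]
    out["var_x"] = sx * sx
    out["var_y"] = sy * sy
    out["var_z"] = sz * sz
    return out


def compose_lattices(
    spot_lists: list[pd.DataFrame],
    n_spurious: int,
    seed: int,
    geometry: Experiment,
) -> pd.DataFrame:
    """Union of per-lattice spot lists plus uniform spurious spots.

    Adds ground-truth columns ``true_lattice`` (index into spot_lists,
    -1 for spurious) and ``true_h/k/l`` for scoring; shuffles row order.
    Spurious spot variances copy the median of the real spots (or 0).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for i, df in enumerate(spot_lists):
        d = df.copy()
        d["true_lattice"] = i
        for col, src in (("true_h", "h"), ("true_k", "k"), ("true_l", "l")):
            d[col] = d[src] if src in d.columns else 0
        frames.append(d)
    combined = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    for col in SPOT_COLUMNS:
        if col not in combined.columns:
            combined[col] = 0.0
    det, scan = geometry.detector, geometry.scan
    if n_spurious > 0:
        med = combined[["var_x", "var_y", "var_z"]].median() if len(combined) else None
        spurious = pd.DataFrame(
            {
                "x_px": rng.uniform(0, det.n_fast, n_spurious),
                "y_px": rng.uniform(0, det.n_slow, n_spurious),
                "z": rng.uniform(0, scan.n_frames, n_spurious),
                "var_x": med["var_x"] if med is not None else 0.0,
                "var_y": med["var_y"] if med is not None else 0.0,
                "var_z": med["var_z"] if med is not None else 0.0,
                "true_lattice": -1,
                "true_h": 0,
                "true_k": 0,
                "true_l": 0,
            }
        )
        combined = pd.concat([combined, spurious], ignore_index=True)
    combined = combined.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(
        drop=True
    )
    keep = SPOT_COLUMNS + ["true_lattice", "true_h", "true_k", "true_l"]
    extra = [c for c in ("h", "k", "l", "phi") if c in combined.columns]
    return combined[keep + extra].drop(columns=extra)


def simulate_multi_lattice(spec: SimulationSpec) -> tuple[pd.DataFrame, list[Crystal]]:
    """Full pipeline: predict, perturb and merge spots for all crystals.

    Returns (spot table with hidden truth columns, ground-truth crystal
    list).  All randomness derives from ``spec.seed``.
    """
    lists = []
    for i, crystal in enumerate(spec.crystals):
        spots = predict_spots(crystal, spec.geometry, spec.d_min)
        if len(spots) == 0:
            logger.warning("crystal %d predicts no spots", i)
        spots = add_noise(spots, spec.noise_sd, seed=spec.seed + 1000 + i)
        # noise can push a centroid marginally outside the panel or scan;
        # real spotfinding could never report such a centroid, so clip
        det, scan = spec.geometry.detector, spec.geometry.scan
        eps = 1e-9
        spots["x_px"] = spots["x_px"].clip(0.0, det.n_fast - eps)
        spots["y_px"] = spots["y_px"].clip(0.0, det.n_slow - eps)
        spots["z"] = spots["z"].clip(0.0, float(scan.n_frames))
        lists.append(spots)
    table = compose_lattices(lists, spec.n_spurious, spec.seed, spec.geometry)
    return table, list(spec.crystals)


def simulate_partial_intensities(
    n_datasets: int,
    cell: UnitCell,
    mode_fraction: float,
    seed: int,
    space_group: str = "I23",
    d_min: float = 2.5,
    n_obs: int = 150,
    noise_frac: float = 0.1,
):
    """Partial-dataset fixture for indexing-ambiguity resolution.

    Draws one shared ground-truth intensity table for the unique
    reflections of the lattice (symmetry-reduced under the Laue group),
    then emits ``n_datasets`` partial observations: random subsets of
    ``n_obs`` unique reflections with multiplicative log-normal noise of
    relative width ``noise_frac``.  A fraction ``mode_fraction`` of the
    datasets is reindexed by the ambiguity operator before labelling,
    emulating wedges indexed in the alternative mode.

    Returns (datasets, true_mode_labels).
    """
    from .ambiguity import PartialDataset, ambiguity_operators, canonical_index, laue_group_ops

    ops_laue = laue_group_ops("23")
    amb = ambiguity_operators(space_group)
    if len(amb) != 2:
        raise ValueError("fixture requires a two-mode ambiguity (e.g. I23)")
    swap = amb[1]
    centred = space_group.replace(" ", "").upper().startswith("I")

    rng = np.random.default_rng(seed)
    hmax = int(np.floor(max(cell.lengths) / d_min))
    uniques = set()
    for h in range(-hmax, hmax + 1):
        for k in range(-hmax, hmax + 1):
            for l in range(-hmax, hmax + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                if centred and (h + k + l) % 2 != 0:
                    continue
                g = cell.reciprocal_metric_tensor()
                q2 = np.array([h, k, l]) @ g @ np.array([h, k, l])
                if q2 > 1.0 / d_min**2:
                    continue
                uniques.add(canonical_index((h, k, l), ops_laue))
    uniques = sorted(uniques)
    truth = {hkl: float(rng.exponential(1.0)) for hkl in uniques}

    n_swapped = int(round(mode_fraction * n_datasets))
    modes = np.array([1] * n_swapped + [0] * (n_datasets - n_swapped))
    rng.shuffle(modes)

    datasets = []
    for i in range(n_datasets):
        chosen = rng.choice(len(uniques), size=min(n_obs, len(uniques)), replace=False)
        rows = []
        for c in chosen:
            hkl = uniques[c]
            intensity = truth[hkl] * float(np.exp(rng.normal(0.0, noise_frac))) if noise_frac > 0 else truth[hkl]
            label = hkl
            if modes[i] == 1:
                # the wedge was indexed in the alternative mode: its
                # Miller labels are the swapped, re-reduced equivalents
                label = canonical_index(swap @ np.array(hkl), ops_laue)
            rows.append((*label, intensity, noise_frac * max(intensity, 1e-6)))
        datasets.append(
            PartialDataset(
                id=f"ds{i:03d}",
                observations=pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma"]),
                space_group=space_group,
            )
        )
    return datasets, modes
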