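"""Crystal refinement and the iterative multi-lattice indexing driver.

Refinement minimizes, via weighted least squares, the discrepancy
between observed spot centroids and the central impacts predicted from
the current crystal model(s).  Residuals live in (x_px, y_px, phi_deg)
with weights from the inverse centroid variances.  Each crystal
contributes three orientation parameters (an axis-angle update applied
to U) plus the free cell lengths/angles of the target cell's crystal
system; beam and detector are held fixed by default, since narrow
wedges under-determine them — refined geometry is better imported via
the geometry file.

The driver alternates: map unindexed centroids to reciprocal space,
search for a basis, assign indices across all lattices found so far,
refine jointly, reject outliers — until an insignificant number of
unindexed reflections remain or no further lattice can be found.  A
lattice whose refinement fails to converge is discarded and the loop
stops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .assign import UNASSIGNED, assign_multilattice, reject_outliers
from .geometry import Crystal, Experiment, UnitCell, build_B, frame_to_phi, spots_to_rlp
from .search import IndexingFailure, SearchConfig, candidate_bases, find_candidate_vectors, select_best_basis
from .simulate import impacts_on_detector, solve_reflecting_angles
from .symmetry import crystal_system

logger = logging.getLogger(__name__)

__all__ = [
    "RefineOptions",
    "RefinementResult",
    "IndexingConfig",
    "IndexingResult",
    "predict_centroids",
    "refine_single",
    "refine_joint",
    "index_multi_lattice",
]

_VAR_FLOOR = 1e-6  # px^2 / frame^2 floor so noise-free data keeps finite weights


@dataclass(frozen=True)
class RefineOptions:
    """Settings for least-squares refinement."""

    constrain_cell: bool = True  # restrict cell to the target's crystal system
    fix_cell: bool = False
    target_cell: UnitCell | None = None  # defines the system when constraining
    max_iterations: int = 100
    ftol: float = 1e-6
    xtol: float = 1e-8
    min_assignments: int = 10
    # soft-L1 keeps mis-assigned reflections (common while peeling off the
    # first of several equally strong lattices) from dragging the fit;
    # weighted residuals of correctly assigned spots stay in the quadratic
    # regime, so the solution is unchanged on clean data
    loss: str = "soft_l1"
    f_scale: float = 3.0


@dataclass
class RefinementResult:
    crystals: list
    rmsd: tuple  # (px, px, degrees)
    n_used: int
    converged: bool
    history: list = field(default_factory=list)
    per_lattice_rmsd: dict = field(default_factory=dict)
    per_lattice_converged: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_centroids(
    crystal: Crystal,
    geometry: Experiment,
    assignments: pd.DataFrame,
    phi_obs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted central impacts for the assigned reflections of one lattice.

    For each assigned (h, k, l) the reflecting condition nearest the
    observed rotation angle is solved; returns columns ``spot_id, x_px,
    y_px, z, phi``.  Reflections with no reflecting condition (blind
    region) or missing the detector are omitted — callers treat them as
    unpredictable and may flag them.
    """
    scan = geometry.scan
    sel = assignments["lattice_id"] != UNASSIGNED
    sub = assignments[sel]
    if len(sub) == 0:
        return pd.DataFrame(columns=["spot_id", "x_px", "y_px", "z", "phi"])
    H = sub[["h", "k", "l"]].to_numpy(dtype=float)
    r0 = H @ crystal.A.T
    phi1, phi2, solvable = solve_reflecting_angles(r0, geometry.beam, geometry.goniometer)
    if phi_obs is None:
        raise ValueError("phi_obs (observed rotation angles, degrees) is required")
    phi_obs = np.asarray(phi_obs, dtype=float)[sel.to_numpy()]

    def nearest(phi_sol):
        # closest representative of phi_sol (mod 360) to the observation
        d = (phi_sol - phi_obs + 180.0) % 360.0 - 180.0
        return phi_obs + d

    cand1, cand2 = nearest(phi1), nearest(phi2)
    use1 = np.abs(cand1 - phi_obs) <= np.abs(cand2 - phi_obs)
    phi = np.where(use1, cand1, cand2)

    from .geometry import rotation_about_axis  # local to avoid clutter above

    R = rotation_about_axis(geometry.goniometer.axis, phi)
    r_phi = np.einsum("nij,nj->ni", R, r0)
    s1 = r_phi + geometry.beam.s0
    x_px, y_px, hit = impacts_on_detector(s1, geometry.detector)
    ok = solvable & hit
    return pd.DataFrame(
        {
            "spot_id": sub["spot_id"].to_numpy()[ok],
            "x_px": x_px[ok],
            "y_px": y_px[ok],
            "z": (phi[ok] - scan.phi_start) / scan.delta_phi,
            "phi": phi[ok],
        }
    )


# ---------------------------------------------------------------------------
# parametrization
# ---------------------------------------------------------------------------

_SYSTEM_PARAMS = {
    "cubic": ("a",),
    "tetragonal": ("a", "c"),
    "hexagonal": ("a", "c"),
    "rhombohedral": ("a", "alpha"),
    "orthorhombic": ("a", "b", "c"),
    "monoclinic": ("a", "b", "c", "beta"),
    "triclinic": ("a", "b", "c", "alpha", "beta", "gamma"),
}


def _cell_param_names(options: RefineOptions, cell: UnitCell) -> tuple[str, ...]:
    if options.fix_cell:
        return ()
    system = crystal_system(options.target_cell or cell)
    return _SYSTEM_PARAMS[system]


def _project_cell(cell: UnitCell, system: str) -> UnitCell:
    """Snap a nearly-symmetric cell onto its system's constraints."""
    a, b, c = cell.lengths
    al, be, ga = cell.angles
    if system == "cubic":
        m = (a + b + c) / 3
        return UnitCell(m, m, m)
    if system == "tetragonal":
        m = (a + b) / 2
        return UnitCell(m, m, c)
    if system == "hexagonal":
        m = (a + b) / 2
        return UnitCell(m, m, c, 90, 90, 120)
    if system == "rhombohedral":
        m = (a + b + c) / 3
        ang = (al + be + ga) / 3
        return UnitCell(m, m, m, ang, ang, ang)
    if system == "orthorhombic":
        return UnitCell(a, b, c)
    if system == "monoclinic":
        return UnitCell(a, b, c, 90, be, 90)
    return cell


def _cell_from_params(base: UnitCell, system: str, values: dict) -> UnitCell:
    a = values.get("a", base.a)
    if system == "cubic":
        return UnitCell(a, a, a)
    if system == "tetragonal":
        return UnitCell(a, a, values.get("c", base.c))
    if system == "hexagonal":
        return UnitCell(a, a, values.get("c", base.c), 90, 90, 120)
    if system == "rhombohedral":
        ang = values.get("alpha", base.alpha)
        return UnitCell(a, a, a, ang, ang, ang)
    b = values.get("b", base.b)
    c = values.get("c", base.c)
    if system == "orthorhombic":
        return UnitCell(a, b, c)
    if system == "monoclinic":
        return UnitCell(a, b, c, 90, values.get("beta", base.beta), 90)
    return UnitCell(
        a,
        b,
        c,
        values.get("alpha", base.alpha),
        values.get("beta", base.beta),
        values.get("gamma", base.gamma),
    )


class _CrystalParametrization:
    """Maps a flat parameter vector to a Crystal and back."""

    def __init__(self, crystal: Crystal, options: RefineOptions):
        self.options = options
        self.system = crystal_system(options.target_cell or crystal.cell)
        cell0 = _project_cell(crystal.cell, self.system) if options.constrain_cell else crystal.cell
        if not options.constrain_cell:
            self.system = "triclinic"
        # re-orthonormalized U consistent with the projected cell
        A = crystal.A
        from .geometry import _nearest_rotation

        self.U0 = _nearest_rotation(A @ np.linalg.inv(build_B(cell0)))
        self.cell0 = cell0
        self.cell_names = _cell_param_names(options, cell0)

    @property
    def n_params(self) -> int:
        return 3 + len(self.cell_names)

    def initial(self) -> np.ndarray:
        x = np.zeros(self.n_params)
        for i, name in enumerate(self.cell_names):
            x[3 + i] = getattr(self.cell0, name)
        return x

    def build(self, x: np.ndarray) -> Crystal:
        dU = Rotation.from_rotvec(x[:3]).as_matrix()
        values = {name: x[3 + i] for i, name in enumerate(self.cell_names)}
        cell = _cell_from_params(self.cell0, self.system, values) if values else self.cell0
        return Crystal(U=dU @ self.U0, cell=cell)


# ---------------------------------------------------------------------------
# least squares
# ---------------------------------------------------------------------------

def _residual_blocks(
    crystals: list[Crystal],
    assignments: pd.DataFrame,
    observations: pd.DataFrame,
    geometry: Experiment,
):
    """Pre-extract per-lattice observation arrays used by the residual fn."""
    scan = geometry.scan
    obs = observations.reset_index(drop=True)
    phi_obs_all = frame_to_phi(obs["z"].to_numpy(), scan)
    blocks = []
    usable = (assignments["lattice_id"] != UNASSIGNED) & (~assignments["outlier"])
    for lid in range(len(crystals)):
        sel = usable & (assignments["lattice_id"] == lid)
        sub = assignments[sel]
        sid = sub["spot_id"].to_numpy().astype(int)
        H = sub[["h", "k", "l"]].to_numpy(dtype=float)
        wx = 1.0 / np.sqrt(np.maximum(obs["var_x"].to_numpy()[sid], _VAR_FLOOR))
        wy = 1.0 / np.sqrt(np.maximum(obs["var_y"].to_numpy()[sid], _VAR_FLOOR))
        var_phi = np.maximum(obs["var_z"].to_numpy()[sid], _VAR_FLOOR) * scan.delta_phi**2
        wphi = 1.0 / np.sqrt(var_phi)
        blocks.append(
            {
                "H": H,
                "x_obs": obs["x_px"].to_numpy()[sid],
                "y_obs": obs["y_px"].to_numpy()[sid],
                "phi_obs": phi_obs_all[sid],
                "w": (wx, wy, wphi),
                "n": len(sid),
            }
        )
    return blocks


def _block_residuals(crystal: Crystal, block: dict, geometry: Experiment) -> np.ndarray:
    """Weighted (dx, dy, dphi) residuals for one lattice; zeros where the
    reflecting condition is unreachable (those spots carry no signal)."""
    H = block["H"]
    if len(H) == 0:
        return np.zeros(0)
    r0 = H @ crystal.A.T
    phi1, phi2, solvable = solve_reflecting_angles(r0, geometry.beam, geometry.goniometer)
    phi_obs = block["phi_obs"]
    d1 = (phi1 - phi_obs + 180.0) % 360.0 - 180.0
    d2 = (phi2 - phi_obs + 180.0) % 360.0 - 180.0
    use1 = np.abs(d1) <= np.abs(d2)
    phi = phi_obs + np.where(use1, d1, d2)

    from .geometry import rotation_about_axis

    R = rotation_about_axis(geometry.goniometer.axis, phi)
    r_phi = np.einsum("nij,nj->ni", R, r0)
    s1 = r_phi + geometry.beam.s0
    x_px, y_px, hit = impacts_on_detector(s1, geometry.detector)
    ok = solvable & hit
    wx, wy, wphi = block["w"]
    res = np.zeros((len(H), 3))
    res[ok, 0] = (block["x_obs"][ok] - x_px[ok]) * wx[ok]
    res[ok, 1] = (block["y_obs"][ok] - y_px[ok]) * wy[ok]
    res[ok, 2] = (phi_obs[ok] - phi[ok]) * wphi[ok]
    return res.ravel()


def _unweighted_rmsd(crystal: Crystal, block: dict, geometry: Experiment):
    H = block["H"]
    if len(H) == 0:
        return (np.nan, np.nan, np.nan)
    r0 = H @ crystal.A.T
    phi1, phi2, solvable = solve_reflecting_angles(r0, geometry.beam, geometry.goniometer)
    phi_obs = block["phi_obs"]
    d1 = (phi1 - phi_obs + 180.0) % 360.0 - 180.0
    d2 = (phi2 - phi_obs + 180.0) % 360.0 - 180.0
    phi = phi_obs + np.where(np.abs(d1) <= np.abs(d2), d1, d2)
    from .geometry import rotation_about_axis

    R = rotation_about_axis(geometry.goniometer.axis, phi)
    s1 = np.einsum("nij,nj->ni", R, r0) + geometry.beam.s0
    x_px, y_px, hit = impacts_on_detector(s1, geometry.detector)
    ok = solvable & hit
    if not ok.any():
        return (np.nan, np.nan, np.nan)
    return (
        float(np.sqrt(np.mean((block["x_obs"][ok] - x_px[ok]) ** 2))),
        float(np.sqrt(np.mean((block["y_obs"][ok] - y_px[ok]) ** 2))),
        float(np.sqrt(np.mean((phi_obs[ok] - phi[ok]) ** 2))),
    )


def refine_joint(
    crystals: list[Crystal],
    assignments: pd.DataFrame,
    observations: pd.DataFrame,
    geometry: Experiment,
    options: RefineOptions | None = None,
) -> RefinementResult:
    """Simultaneously refine all crystals against their assigned spots.

    Shared beam/detector geometry is held fixed; with it fixed the
    per-lattice problems are separable, but they are solved in one
    damped least-squares system as the driver interleaves them.
    """
    options = options or RefineOptions()
    blocks = _residual_blocks(crystals, assignments, observations, geometry)
    n_used = sum(b["n"] for b in blocks)
    params = [_CrystalParametrization(c, options) for c in crystals]
    for lid, b in enumerate(blocks):
        if b["n"] < options.min_assignments:
            logger.warning("lattice %d has only %d usable assignments", lid, b["n"])

    offsets = np.cumsum([0] + [p.n_params for p in params])
    x0 = np.concatenate([p.initial() for p in params]) if params else np.zeros(0)
    history: list[float] = []

    def build_all(x):
        return [p.build(x[offsets[i] : offsets[i + 1]]) for i, p in enumerate(params)]

    def fun(x):
        try:
            cs = build_all(x)
        except Exception:
            return np.full(3 * max(n_used, 1), 1e6)
        res = [_block_residuals(c, b, geometry) for c, b in zip(cs, blocks)]
        r = np.concatenate(res) if res else np.zeros(0)
        history.append(float(r @ r))
        return r

    converged = True
    if n_used >= options.min_assignments and params:
        try:
            fit = least_squares(
                fun,
                x0,
                method="trf",
                loss=options.loss,
                f_scale=options.f_scale,
                ftol=options.ftol,
                xtol=options.xtol,
                max_nfev=options.max_iterations * (len(x0) + 1),
            )
            converged = fit.status > 0 and np.all(np.isfinite(fit.x))
            x_final = fit.x
        except Exception as exc:  # singular normal matrix, etc.
            logger.warning("refinement failed: %s", exc)
            converged = False
            x_final = x0
    else:
        converged = False
        x_final = x0

    refined = build_all(x_final) if params else []
    per_rmsd, per_conv = {}, {}
    comps = []
    for lid, (c, b) in enumerate(zip(refined, blocks)):
        r = _unweighted_rmsd(c, b, geometry)
        per_rmsd[lid] = r
        per_conv[lid] = converged and b["n"] >= options.min_assignments
        if b["n"]:
            comps.append((r, b["n"]))
    if comps:
        tot = sum(n for _, n in comps)
        rmsd = tuple(
            float(np.sqrt(sum((r[i] ** 2) * n for r, n in comps) / tot)) for i in range(3)
        )
    else:
        rmsd = (np.nan, np.nan, np.nan)

    return RefinementResult(
        crystals=refined,
        rmsd=rmsd,
        n_used=n_used,
        converged=converged,
        history=history,
        per_lattice_rmsd=per_rmsd,
        per_lattice_converged=per_conv,
    )


def refine_single(
    crystal: Crystal,
    assignments: pd.DataFrame,
    observations: pd.DataFrame,
    geometry: Experiment,
    options: RefineOptions | None = None,
) -> RefinementResult:
    """Refine one crystal (the single-lattice reduction of refine_joint)."""
    return refine_joint([crystal], assignments, observations, geometry, options)


# ---------------------------------------------------------------------------
# multi-lattice driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexingConfig:
    """Configuration of the iterative multi-lattice indexing loop."""

    search: SearchConfig = field(default_factory=SearchConfig)
    max_lattices: int = 10
    min_spots_per_lattice: int = 20
    unindexed_fraction_stop: float = 0.05
    macro_cycles: int = 3
    max_dx: float = 3.0  # px, outlier limits
    max_dy: float = 3.0
    max_dphi: float = 2.0
    # a genuine lattice explains its retained spots to well within the
    # outlier limits; chance-indexed spurious "lattices" sit near them
    max_rmsd_fraction: float = 0.5
    refine: RefineOptions = field(default_factory=RefineOptions)


@dataclass
class IndexingResult:
    crystals: list
    assignments: pd.DataFrame
    report: dict

    @property
    def n_lattices(self) -> int:
        return len(self.crystals)


def _predictions_all(crystals, geometry, assignments, phi_obs):
    preds = []
    for lid, crystal in enumerate(crystals):
        mask = assignments["lattice_id"] == lid
        sub = assignments.copy()
        sub.loc[~mask, "lattice_id"] = UNASSIGNED
        preds.append(predict_centroids(crystal, geometry, sub, phi_obs))
    return (
        pd.concat(preds, ignore_index=True)
        if preds
        else pd.DataFrame(columns=["spot_id", "x_px", "y_px", "z", "phi"])
    )


def index_multi_lattice(
    spots: pd.DataFrame,
    geometry: Experiment,
    cell: UnitCell,
    config: IndexingConfig | None = None,
) -> IndexingResult:
    """Iteratively find, index and refine every lattice in a spot table.

    Raises :class:`IndexingFailure` if no lattice at all can be found;
    otherwise returns the refined crystals, the final assignment table
    and a diagnostic report.
    """
    config = config or IndexingConfig()
    options = replace(config.refine, target_cell=config.refine.target_cell or cell)
    spots = spots.reset_index(drop=True)
    n_total = len(spots)
    r_all = spots_to_rlp(spots, geometry)
    phi_obs = frame_to_phi(spots["z"].to_numpy(), geometry.scan)
    obs = spots.copy()
    obs["phi"] = phi_obs

    crystals: list[Crystal] = []
    assignments = assign_multilattice(r_all, crystals, config.search.hkl_tolerance)
    stop_threshold = max(config.min_spots_per_lattice, config.unindexed_fraction_stop * n_total)
    report: dict = {"n_spots": n_total, "cycles": [], "stop_reason": None}

    while len(crystals) < config.max_lattices:
        unindexed = (assignments["lattice_id"] == UNASSIGNED) & (~assignments["outlier"])
        n_unindexed = int(unindexed.sum())
        if n_unindexed < stop_threshold:
            report["stop_reason"] = "insignificant number of unindexed reflections"
            break
        r_sub = r_all[unindexed.to_numpy()]
        try:
            cands = find_candidate_vectors(r_sub, cell, config.search)
            bases = candidate_bases(cands, cell, config.search)
            if not bases:
                report["stop_reason"] = "no candidate basis consistent with the cell"
                break
            trial = select_best_basis(bases, r_sub, config.search.hkl_tolerance)
        except IndexingFailure as exc:
            report["stop_reason"] = str(exc)
            break

        # quick viability check on the unindexed subset
        hf = r_sub @ trial.A_inv.T
        n_new = int(np.sum(np.linalg.norm(hf - np.round(hf), axis=1) < config.search.hkl_tolerance))
        if n_new < config.min_spots_per_lattice:
            report["stop_reason"] = (
                f"best candidate indexes only {n_new} unindexed reflections"
            )
            break

        trial_crystals = crystals + [trial]
        cycle_info = {"lattice": len(trial_crystals) - 1, "search_score": cands[0].score}
        ok = True
        trial_assign = assignments
        for cycle in range(config.macro_cycles):
            trial_assign = assign_multilattice(
                r_all, trial_crystals, config.search.hkl_tolerance
            )
            result = refine_joint(trial_crystals, trial_assign, spots, geometry, options)
            new_id = len(trial_crystals) - 1
            if not result.per_lattice_converged.get(new_id, False):
                ok = False
                break
            trial_crystals = result.crystals
            preds = _predictions_all(trial_crystals, geometry, trial_assign, phi_obs)
            trial_assign = reject_outliers(
                trial_assign, obs, preds, config.max_dx, config.max_dy, config.max_dphi
            )
            cycle_info[f"rmsd_cycle_{cycle}"] = result.rmsd
        if not ok:
            report["stop_reason"] = "refinement of the newest lattice did not converge"
            break
        new_id = len(trial_crystals) - 1
        keep_mask = (trial_assign["lattice_id"] == new_id) & ~trial_assign["outlier"]
        n_kept = int(keep_mask.sum())
        if n_kept < config.min_spots_per_lattice:
            report["stop_reason"] = "newest lattice retained too few reflections"
            break
        # model-quality gate on the newest lattice's clean assignments
        blocks = _residual_blocks(trial_crystals, trial_assign, spots, geometry)
        rmsd_new = _unweighted_rmsd(trial_crystals[new_id], blocks[new_id], geometry)
        f = config.max_rmsd_fraction
        if not (
            rmsd_new[0] <= f * config.max_dx
            and rmsd_new[1] <= f * config.max_dy
            and rmsd_new[2] <= f * config.max_dphi
        ):
            report["stop_reason"] = (
                f"newest lattice rejected: rmsd {tuple(round(v, 3) for v in rmsd_new)} "
                "is not well within the outlier limits"
            )
            break
        crystals = trial_crystals
        assignments = trial_assign
        cycle_info["n_assigned"] = n_kept
        report["cycles"].append(cycle_info)
        logger.info(
            "lattice %d accepted: %d reflections assigned", len(crystals) - 1, n_kept
        )

    if not crystals:
        raise IndexingFailure(
            f"no lattice found: {report['stop_reason']} "
            f"(n_spots={n_total})"
        )

    per_lattice = {}
    for lid in range(len(crystals)):
        sel = (assignments["lattice_id"] == lid) & ~assignments["outlier"]
        per_lattice[lid] = {
            "n_assigned": int(sel.sum()),
            "cell": crystals[lid].cell.parameters,
        }
    report["per_lattice"] = per_lattice
    report["n_unindexed"] = int(
        ((assignments["lattice_id"] == UNASSIGNED) & ~assignments["outlier"]).sum()
    )
    report["n_outliers"] = int(assignments["outlier"].sum())
    report["n_lattices"] = len(crystals)
    if report["stop_reason"] is None:
        report["stop_reason"] = "max_lattices reached"
    return IndexingResult(crystals=crystals, assignments=assignments, report=report)
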