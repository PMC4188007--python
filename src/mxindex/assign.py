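"""Miller-index assignment and outlier rejection.

Each reciprocal-lattice vector r gets a fractional index h' = A^-1 r
per candidate lattice; it is assigned to the lattice minimizing the
rounding residual |h' - round(h')|, provided that residual is below a
tolerance (0.3 by default).  Two reflections may not claim the same
(lattice, h): only the smallest-residual claimant keeps it, the rest
are flagged as outliers.  A further positional filter flags
assignments whose predicted centroid deviates from the observation by
more than configurable x / y / phi limits (defaults 3 px, 3 px, 2 deg).

Unassigned is not the same as outlier: unassigned reflections feed the
search for further lattices, outliers do not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import Crystal

__all__ = [
    "UNASSIGNED",
    "assign_indices",
    "assign_multilattice",
    "reject_outliers",
]

UNASSIGNED = -1

ASSIGNMENT_COLUMNS = [
    "spot_id",
    "lattice_id",
    "h",
    "k",
    "l",
    "h_frac",
    "k_frac",
    "l_frac",
    "residual",
    "outlier",
]


def _empty_assignments(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spot_id": np.arange(n),
            "lattice_id": np.full(n, UNASSIGNED),
            "h": 0,
            "k": 0,
            "l": 0,
            "h_frac": 0.0,
            "k_frac": 0.0,
            "l_frac": 0.0,
            "residual": np.nan,
            "outlier": False,
        }
    )


def assign_multilattice(
    r_set: np.ndarray, crystals: list[Crystal], hkl_tolerance: float = 0.3
) -> pd.DataFrame:
    """Assign each reciprocal-lattice vector to its best-fitting lattice.

    Returns an assignment table indexed by ``spot_id`` (the row order of
    ``r_set``).  Duplicate (lattice, h) claims keep the smallest
    residual (ties broken by spot_id) and flag the rest as outliers.
    """
    r_set = np.atleast_2d(np.asarray(r_set, dtype=float))
    n = len(r_set)
    out = _empty_assignments(n)
    if n == 0 or not crystals:
        return out

    resid = np.full((n, len(crystals)), np.inf)
    hfrac = np.empty((n, len(crystals), 3))
    for j, crystal in enumerate(crystals):
        hf = r_set @ crystal.A_inv.T
        hfrac[:, j] = hf
        resid[:, j] = np.linalg.norm(hf - np.round(hf), axis=1)

    best = np.argmin(resid, axis=1)
    best_resid = resid[np.arange(n), best]
    assigned = best_resid < hkl_tolerance

    hf_best = hfrac[np.arange(n), best]
    h_int = np.round(hf_best).astype(int)
    out.loc[assigned, "lattice_id"] = best[assigned]
    out.loc[assigned, ["h", "k", "l"]] = h_int[assigned]
    out[["h_frac", "k_frac", "l_frac"]] = hf_best
    out.loc[assigned, "residual"] = best_resid[assigned]

    # enforce (lattice, h) uniqueness among assigned spots
    sub = out[assigned].sort_values(["residual", "spot_id"], kind="stable")
    dup = sub.duplicated(subset=["lattice_id", "h", "k", "l"], keep="first")
    losers = sub.loc[dup, "spot_id"].to_numpy()
    out.loc[out["spot_id"].isin(losers), "outlier"] = True
    return out


def assign_indices(r_set: np.ndarray, crystal: Crystal, hkl_tolerance: float = 0.3) -> pd.DataFrame:
    """Single-lattice index assignment (lattice_id 0 or unassigned)."""
    return assign_multilattice(r_set, [crystal], hkl_tolerance)


def reject_outliers(
    assignments: pd.DataFrame,
    observed: pd.DataFrame,
    predicted: pd.DataFrame,
    max_dx: float = 3.0,
    max_dy: float = 3.0,
    max_dphi: float = 2.0,
) -> pd.DataFrame:
    """Flag assignments whose observed centroid is far from prediction.

    ``predicted`` must carry columns ``spot_id, x_px, y_px, phi`` for
    (at least) the assigned spots; ``observed`` carries the spot table
    with ``x_px, y_px`` and observed ``phi`` (degrees).  Limits are the
    maximum acceptable |dx| (px), |dy| (px) and |dphi| (deg).  Flags are
    only ever added, never removed; assigned spots with no available
    prediction (blind region) are also flagged.
    """
    out = assignments.copy().reset_index(drop=True)
    assigned = (out["lattice_id"] != UNASSIGNED) & ~out["outlier"]
    if not assigned.any():
        return out

    obs = observed.reset_index(drop=True)
    merged = out.loc[assigned, ["spot_id"]].merge(
        predicted[["spot_id", "x_px", "y_px", "phi"]], on="spot_id", how="left"
    )
    sid = merged["spot_id"].to_numpy().astype(int)
    ox = obs["x_px"].to_numpy()[sid]
    oy = obs["y_px"].to_numpy()[sid]
    ophi = obs["phi"].to_numpy()[sid]
    px = merged["x_px"].to_numpy()
    py = merged["y_px"].to_numpy()
    pphi = merged["phi"].to_numpy()
    dphi = np.abs(ophi - pphi)
    dphi = np.minimum(dphi, 360.0 - dphi)
    bad = (
        np.isnan(px)  # no prediction available (e.g. blind region)
        | (np.abs(ox - px) > max_dx)
        | (np.abs(oy - py) > max_dy)
        | (dphi > max_dphi)
    )
    flag_ids = sid[bad]
    out.loc[out["spot_id"].isin(flag_ids), "outlier"] = True
    return out
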