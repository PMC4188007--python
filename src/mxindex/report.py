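"""Diagnostics for multi-lattice sweeps.

The tell-tale signature of multiple lattices in a wedge is an excess of
found spots over the number a single crystal of the known cell would
predict.  The expected count is estimated by Monte Carlo over random
orientations; the ratio of observed to expected spots approximates the
number of lattices illuminated.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .geometry import Experiment, Scan, UnitCell
from .simulate import predict_spots, random_crystal

__all__ = [
    "ExpectedCountSummary",
    "expected_spot_count",
    "multi_lattice_flag",
    "validate_report",
]


@dataclass
class ExpectedCountSummary:
    mean: float
    sd: float
    counts: list
    histogram: dict = field(default_factory=dict)


def expected_spot_count(
    cell: UnitCell,
    geometry: Experiment,
    wedge: float,
    d_min: float,
    n_orientations: int,
    seed: int = 0,
) -> ExpectedCountSummary:
    """Monte-Carlo distribution of predicted spot counts per wedge.

    ``wedge`` is the total rotation range in degrees; the frame width of
    the supplied geometry is kept.
    """
    if wedge < 0:
        raise ValueError("wedge must be non-negative")
    rng = np.random.default_rng(seed)
    if wedge == 0:
        counts = [0] * n_orientations
    else:
        scan = geometry.scan
        n_frames = max(1, int(round(wedge / scan.delta_phi)))
        geom = Experiment(
            beam=geometry.beam,
            detector=geometry.detector,
            goniometer=geometry.goniometer,
            scan=Scan(phi_start=scan.phi_start, delta_phi=wedge / n_frames, n_frames=n_frames),
        )
        counts = [
            len(predict_spots(random_crystal(cell, rng), geom, d_min))
            for _ in range(n_orientations)
        ]
    counts_arr = np.asarray(counts)
    edges = np.histogram_bin_edges(counts_arr, bins=min(20, max(1, len(set(counts)))))
    hist, _ = np.histogram(counts_arr, bins=edges)
    return ExpectedCountSummary(
        mean=float(counts_arr.mean()),
        sd=float(counts_arr.std(ddof=1)) if len(counts_arr) > 1 else 0.0,
        counts=[int(c) for c in counts],
        histogram={"edges": [float(e) for e in edges], "counts": [int(c) for c in hist]},
    )


def multi_lattice_flag(
    n_found: int, expected: ExpectedCountSummary, threshold: float = 1.5
) -> tuple[bool, float]:
    """Flag a sweep whose spot count exceeds the single-lattice expectation.

    Returns (flag, excess ratio = n_found / expected mean).
    """
    if expected.mean <= 0:
        raise ValueError("expected distribution must have positive mean")
    ratio = n_found / expected.mean
    return ratio > threshold, float(ratio)


_REPORT_SCHEMA = {
    "n_spots": int,
    "n_lattices": int,
    "n_unindexed": int,
    "n_outliers": int,
    "per_lattice": dict,
    "seed": int,
    "config": dict,
}


def validate_report(report: dict) -> None:
    """Check a run report against the published key/type schema."""
    for key, typ in _REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    for lid, entry in report["per_lattice"].items():
        if "n_assigned" not in entry or entry["n_assigned"] < 0:
            raise ValueError(f"per_lattice[{lid}] must carry non-negative n_assigned")


def build_run_report(index_report: dict, seed: int, config: dict) -> dict:
    """Assemble the serializable run report from an indexing report."""
    out = dict(index_report)
    out["per_lattice"] = {str(k): v for k, v in index_report.get("per_lattice", {}).items()}
    out["seed"] = int(seed)
    out["config"] = config
    return out
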