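"""Detection of overlapping reflections between lattices.

Each predicted reflection gets a shoebox: an integer bounding box in
pixel x pixel x frame space enclosing its peak region under a Gaussian
profile model, plus a voxel mask labelling peak versus background.  The
profile model assumes a Gaussian in a local reflection frame spanned by
two directions tangent to the Ewald sphere at s1 and the rotation
direction: standard deviations sigma_b (effective beam divergence, on
the detector) and sigma_m (mosaic rocking width, along phi), truncated
at n_sigma standard deviations.

Overlaps are found in two stages: a space-partitioning query (k-d tree
on box centres) yields candidate pairs whose bounding boxes intersect,
and each candidate pair is confirmed only if at least one voxel is
labelled peak in both masks.  Box ranges are half-open, so boxes
sharing only a face do not intersect.  A voxel's membership is decided
at its centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Experiment, GeometryError, mm_to_s1, pixel_to_mm

__all__ = [
    "ProfileModel",
    "ReflectionShoebox",
    "compute_shoebox",
    "shoeboxes_for_predictions",
    "find_bbox_overlaps",
    "confirm_overlaps",
    "overlap_stats",
]

_SIGMA_FLOOR = 1e-12  # degrees; degenerate profiles collapse to the centroid voxel


@dataclass(frozen=True)
class ProfileModel:
    """Gaussian reflection profile: sigma_b, sigma_m in degrees."""

    sigma_b: float
    sigma_m: float
    n_sigma: float = 3.0

    def __post_init__(self):
        if self.sigma_b < 0 or self.sigma_m < 0 or self.n_sigma <= 0:
            raise ValueError("profile parameters must be positive")


@dataclass
class ReflectionShoebox:
    """Bounding box plus peak mask of one predicted reflection.

    bbox = (x0, x1, y0, y1, z0, z1), half-open integer ranges in fast
    pixel, slow pixel and frame; mask has shape (z1-z0, y1-y0, x1-x0)
    with True = peak.
    """

    lattice_id: int
    h: tuple
    centroid: tuple  # (x_px, y_px, z)
    bbox: tuple
    mask: np.ndarray
    d_spacing: float

    @property
    def n_peak(self) -> int:
        return int(self.mask.sum())


def _local_frame(s1: np.ndarray, s0: np.ndarray):
    """Orthonormal (e1, e2) spanning the Ewald-sphere tangent plane at s1."""
    s1_hat = s1 / np.linalg.norm(s1)
    e1 = np.cross(s1, s0)
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        # forward scattering: any perpendicular pair will do
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, s1_hat)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(s1_hat, helper)
        e1 /= np.linalg.norm(e1)
    else:
        e1 /= n1
    e2 = np.cross(s1_hat, e1)
    return s1_hat, e1, e2


def _angular_offsets(px_idx, py_idx, s1_hat, e1, e2, experiment: Experiment):
    """Angular displacement components (degrees) of pixel centres from s1."""
    x_mm, y_mm = pixel_to_mm(np.asarray(px_idx, float), np.asarray(py_idx, float), experiment.detector)
    s_p = np.atleast_2d(mm_to_s1(x_mm, y_mm, experiment.detector, experiment.beam))
    s_hat = s_p / np.linalg.norm(s_p, axis=1)[:, None]
    d = s_hat - s1_hat
    return np.degrees(d @ e1), np.degrees(d @ e2)


def compute_shoebox(
    lattice_id: int,
    h: tuple,
    centroid: tuple,
    profile: ProfileModel,
    experiment: Experiment,
    d_spacing: float = np.nan,
) -> ReflectionShoebox:
    """Bounding box and peak mask for one predicted reflection.

    ``centroid`` is (x_px, y_px, z) of the predicted central impact.
    The bbox maps the +-n_sigma profile extent corners into pixel/frame
    space and clips to the detector/scan; a voxel is peak iff its
    centre's scaled displacement lies within the n_sigma ellipsoid.
    Reflections whose centroid falls outside the detector or scan are
    rejected.
    """
    det, scan = experiment.detector, experiment.scan
    xc, yc, zc = (float(v) for v in centroid)
    if not (0 <= xc < det.n_fast and 0 <= yc < det.n_slow and 0 <= zc <= scan.n_frames):
        raise GeometryError("predicted centroid outside detector/scan")
    x_mm, y_mm = pixel_to_mm(xc, yc, det)
    s1 = mm_to_s1(x_mm, y_mm, det, experiment.beam)
    s1_hat, e1, e2 = _local_frame(s1, experiment.beam.s0)

    sb = max(profile.sigma_b, _SIGMA_FLOOR)
    sm = max(profile.sigma_m, _SIGMA_FLOOR)
    delta = math.radians(profile.n_sigma * sb)

    # extremal corners of the +-delta square in the tangent plane
    corners = []
    for u in (-1.0, 1.0):
        for v in (-1.0, 1.0):
            d = s1_hat + math.tan(delta) * (u * e1 + v * e2)
            corners.append(d / np.linalg.norm(d))
    from .simulate import impacts_on_detector

    cx, cy, _ = impacts_on_detector(np.array(corners), det)
    xs = np.append(cx, xc)
    ys = np.append(cy, yc)
    x0 = int(np.clip(math.floor(np.nanmin(xs) + 0.5), 0, det.n_fast - 1))
    x1 = int(np.clip(math.ceil(np.nanmax(xs) + 0.5), x0 + 1, det.n_fast))
    y0 = int(np.clip(math.floor(np.nanmin(ys) + 0.5), 0, det.n_slow - 1))
    y1 = int(np.clip(math.ceil(np.nanmax(ys) + 0.5), y0 + 1, det.n_slow))

    wz = profile.n_sigma * sm / scan.delta_phi  # frames
    z0 = int(np.clip(math.floor(zc - wz), 0, scan.n_frames - 1))
    z1 = int(np.clip(math.floor(zc + wz) + 1, z0 + 1, scan.n_frames))

    # mask: evaluate the ellipsoid at every voxel centre
    gx = np.arange(x0, x1)
    gy = np.arange(y0, y1)
    PX, PY = np.meshgrid(gx.astype(float), gy.astype(float), indexing="xy")
    a1, a2 = _angular_offsets(PX.ravel(), PY.ravel(), s1_hat, e1, e2, experiment)
    radial2 = (a1 / sb) ** 2 + (a2 / sb) ** 2  # (ny*nx,)
    zs = np.arange(z0, z1) + 0.5
    dphi = (zs - zc) * scan.delta_phi
    mask = np.zeros((z1 - z0, y1 - y0, x1 - x0), dtype=bool)
    for iz, dp in enumerate(dphi):
        val = radial2 + (dp / sm) ** 2
        mask[iz] = (val <= profile.n_sigma**2).reshape(y1 - y0, x1 - x0)
    # the voxel containing the centroid is peak by definition (covers the
    # degenerate sigma -> 0 limit where no voxel centre satisfies the test)
    cxi = int(np.clip(round(xc), x0, x1 - 1)) - x0
    cyi = int(np.clip(round(yc), y0, y1 - 1)) - y0
    czi = int(np.clip(math.floor(zc), z0, z1 - 1)) - z0
    mask[czi, cyi, cxi] = True
    return ReflectionShoebox(
        lattice_id=lattice_id,
        h=tuple(int(v) for v in h),
        centroid=(xc, yc, zc),
        bbox=(x0, x1, y0, y1, z0, z1),
        mask=mask,
        d_spacing=float(d_spacing),
    )


def shoeboxes_for_predictions(
    predictions: pd.DataFrame, profile: ProfileModel, experiment: Experiment
) -> list[ReflectionShoebox]:
    """Shoeboxes for a prediction table (lattice_id, h, k, l, x_px, y_px, z, d)."""
    boxes = []
    for row in predictions.itertuples(index=False):
        try:
            boxes.append(
                compute_shoebox(
                    int(getattr(row, "lattice_id", 0)),
                    (row.h, row.k, row.l),
                    (row.x_px, row.y_px, row.z),
                    profile,
                    experiment,
                    d_spacing=getattr(row, "d", np.nan),
                )
            )
        except GeometryError:
            continue
    return boxes


def _boxes_intersect(b1: tuple, b2: tuple) -> bool:
    x0a, x1a, y0a, y1a, z0a, z1a = b1
    x0b, x1b, y0b, y1b, z0b, z1b = b2
    return (
        max(x0a, x0b) < min(x1a, x1b)
        and max(y0a, y0b) < min(y1a, y1b)
        and max(z0a, z0b) < min(z1a, z1b)
    )


def find_bbox_overlaps(shoeboxes: list[ReflectionShoebox]) -> list[tuple[int, int]]:
    """Unordered index pairs whose bounding boxes intersect.

    Candidate pairs come from a single k-d-tree query on box centres
    with a radius bounding any possible intersection; each candidate is
    then checked exactly against the half-open interval semantics.
    """
    n = len(shoeboxes)
    if n < 2:
        return []
    boxes = np.array([s.bbox for s in shoeboxes], dtype=float)
    centres = np.column_stack(
        [
            (boxes[:, 0] + boxes[:, 1]) / 2,
            (boxes[:, 2] + boxes[:, 3]) / 2,
            (boxes[:, 4] + boxes[:, 5]) / 2,
        ]
    )
    half = np.column_stack(
        [
            (boxes[:, 1] - boxes[:, 0]) / 2,
            (boxes[:, 3] - boxes[:, 2]) / 2,
            (boxes[:, 5] - boxes[:, 4]) / 2,
        ]
    )
    radius = 2.0 * float(np.linalg.norm(half, axis=1).max())
    tree = cKDTree(centres)
    pairs = []
    for i, j in tree.query_pairs(r=radius):
        a, b = (i, j) if i < j else (j, i)
        if _boxes_intersect(shoeboxes[a].bbox, shoeboxes[b].bbox):
            pairs.append((a, b))
    return sorted(pairs)


def confirm_overlaps(
    pairs: list[tuple[int, int]], shoeboxes: list[ReflectionShoebox]
) -> list[tuple[int, int, int]]:
    """Keep pairs whose peak regions share at least one voxel.

    Returns (i, j, n_shared_voxels) triples.
    """
    confirmed = []
    for i, j in pairs:
        a, b = shoeboxes[i], shoeboxes[j]
        x0 = max(a.bbox[0], b.bbox[0])
        x1 = min(a.bbox[1], b.bbox[1])
        y0 = max(a.bbox[2], b.bbox[2])
        y1 = min(a.bbox[3], b.bbox[3])
        z0 = max(a.bbox[4], b.bbox[4])
        z1 = min(a.bbox[5], b.bbox[5])
        if x0 >= x1 or y0 >= y1 or z0 >= z1:
            continue
        ma = a.mask[z0 - a.bbox[4] : z1 - a.bbox[4], y0 - a.bbox[2] : y1 - a.bbox[2], x0 - a.bbox[0] : x1 - a.bbox[0]]
        mb = b.mask[z0 - b.bbox[4] : z1 - b.bbox[4], y0 - b.bbox[2] : y1 - b.bbox[2], x0 - b.bbox[0] : x1 - b.bbox[0]]
        shared = int(np.logical_and(ma, mb).sum())
        if shared > 0:
            confirmed.append((i, j, shared))
    return confirmed


def overlap_stats(
    shoeboxes: list[ReflectionShoebox],
    overlaps: list[tuple],
    resolution_bins: np.ndarray,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-resolution-bin overlap fractions and per-reflection pixel fractions.

    ``resolution_bins`` are d-spacing bin edges in Angstrom (ascending).
    Returns (DataFrame with bin midpoints, totals, overlap counts and
    fractions for occupied bins only; array of shared-peak-voxel
    fractions, one entry per reflection involved in any overlap).
    """
    edges = np.asarray(resolution_bins, dtype=float)
    d = np.array([s.d_spacing for s in shoeboxes])
    overlapping = set()
    shared_voxels: dict[int, int] = {}
    for pair in overlaps:
        i, j = pair[0], pair[1]
        nshared = pair[2] if len(pair) > 2 else 1
        overlapping.update((i, j))
        shared_voxels[i] = shared_voxels.get(i, 0) + nshared
        shared_voxels[j] = shared_voxels.get(j, 0) + nshared

    rows = []
    which = np.digitize(d, edges) - 1
    for b in range(len(edges) - 1):
        sel = which == b
        total = int(sel.sum())
        if total == 0:
            continue  # empty bins are absent, not zero
        n_over = int(sum(1 for i in np.where(sel)[0] if i in overlapping))
        rows.append(
            {
                "d_mid": 0.5 * (edges[b] + edges[b + 1]),
                "n_total": total,
                "n_overlapping": n_over,
                "fraction": n_over / total,
            }
        )
    fractions = np.array(
        [min(1.0, shared_voxels[i] / max(shoeboxes[i].n_peak, 1)) for i in sorted(overlapping)]
    )
    return pd.DataFrame(rows), fractions
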