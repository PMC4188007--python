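"""Experimental geometry models and detector/reciprocal-space transforms.

The rotation-method experiment is described by four components: an
incident :class:`Beam`, a flat-panel :class:`Detector`, a single-axis
:class:`Goniometer` and a :class:`Scan` of contiguous equal-width frames.
A crystal is an orientation matrix ``U`` plus a :class:`UnitCell`, giving
the setting matrix ``A = U B`` that maps integer Miller indices ``h`` to
lab-frame reciprocal-lattice vectors ``r = A h`` (units 1/Angstrom).

An observed spot centroid ``(x_px, y_px, z)`` is mapped to its
reciprocal-lattice vector in four steps: pixel -> millimetre position in
the virtual detector plane; millimetre position -> scattered beam vector
``s1`` on the Ewald sphere (``|s1| = 1/lambda``); ``r_phi = s1 - s0``;
and rotation by ``-phi`` about the goniometer axis back to the zero-angle
lab frame, ``r = R(-phi) r_phi``.

Conventions: right-handed lab frame; 0-based pixel indices with the
continuous coordinate ``p`` mapping to ``(p + 0.5) * pixel_size`` mm
(pixel-centre convention); frame coordinate ``z`` measured continuously
from the scan start so ``phi(z) = phi_start + z * delta_phi``; angles in
degrees at every interface, radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Beam",
    "Detector",
    "Goniometer",
    "Scan",
    "UnitCell",
    "Crystal",
    "Experiment",
    "GeometryError",
    "pixel_to_mm",
    "mm_to_s1",
    "s1_to_rphi",
    "rphi_to_r",
    "frame_to_phi",
    "phi_to_frame",
    "build_B",
    "rotation_about_axis",
    "spots_to_rlp",
]


class GeometryError(ValueError):
    """Raised for invalid or degenerate experimental geometry."""


def _as_unit(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise GeometryError(f"{name} must be a non-zero 3-vector")
    return v / n


@dataclass(frozen=True)
class Beam:
    """Monochromatic incident beam.

    ``direction`` points from the source toward the crystal; the wave
    vector is ``s0 = direction / wavelength`` with ``|s0| = 1/lambda``.
    """

    wavelength: float
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if self.wavelength <= 0:
            raise GeometryError("wavelength must be positive")
        object.__setattr__(self, "direction", _as_unit(self.direction, "beam direction"))

    @property
    def s0(self) -> np.ndarray:
        return self.direction / self.wavelength


@dataclass(frozen=True)
class Detector:
    """Flat detector panel.

    ``fast_axis`` and ``slow_axis`` are unit lab-frame vectors along the
    fast (x) and slow (y) pixel directions; ``origin`` is the lab-frame
    vector (mm) to the outer corner of pixel (0, 0).  The projection
    matrix ``D = (d_x d_y d_0)^-1`` maps a lab point in the detector
    plane to homogeneous plane coordinates ``(x_mm, y_mm, 1)``.
    """

    fast_axis: np.ndarray
    slow_axis: np.ndarray
    origin: np.ndarray
    n_fast: int
    n_slow: int
    pixel_size: float

    def __post_init__(self):
        object.__setattr__(self, "fast_axis", _as_unit(self.fast_axis, "fast_axis"))
        object.__setattr__(self, "slow_axis", _as_unit(self.slow_axis, "slow_axis"))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        if abs(np.dot(self.fast_axis, self.slow_axis)) > 1 - 1e-9:
            raise GeometryError("fast and slow axes must be linearly independent")
        if abs(np.linalg.det(self.d_matrix)) < 1e-12:
            raise GeometryError("detector basis (d_x, d_y, d_0) is singular")

    @property
    def d_matrix(self) -> np.ndarray:
        """Columns (d_x, d_y, d_0)."""
        return np.column_stack([self.fast_axis, self.slow_axis, self.origin])

    @property
    def D(self) -> np.ndarray:
        """Projection matrix, inverse of (d_x d_y d_0)."""
        return np.linalg.inv(self.d_matrix)

    @property
    def size_mm(self) -> tuple[float, float]:
        return self.n_fast * self.pixel_size, self.n_slow * self.pixel_size


@dataclass(frozen=True)
class Goniometer:
    """Single rotation axis, a unit vector in the lab frame."""

    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    def __post_init__(self):
        object.__setattr__(self, "axis", _as_unit(self.axis, "goniometer axis"))


@dataclass(frozen=True)
class Scan:
    """Contiguous sequence of rotation frames."""

    phi_start: float
    delta_phi: float
    n_frames: int

    def __post_init__(self):
        if self.delta_phi <= 0:
            raise GeometryError("delta_phi must be positive")
        if self.n_frames < 1:
            raise GeometryError("n_frames must be >= 1")

    @property
    def phi_end(self) -> float:
        return self.phi_start + self.delta_phi * self.n_frames

    @property
    def total_range(self) -> float:
        return self.delta_phi * self.n_frames


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise GeometryError("cell angles must lie in (0, 180)")
        # metric tensor positive definite <=> the volume argument positive
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        arg = (
            1
            - math.cos(al) ** 2
            - math.cos(be) ** 2
            - math.cos(ga) ** 2
            + 2 * math.cos(al) * math.cos(be) * math.cos(ga)
        )
        if arg <= 0:
            raise GeometryError("degenerate cell: metric tensor not positive definite")

    @property
    def parameters(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.parameters)

    @property
    def volume(self) -> float:
        return self.to_gemmi().volume

    def reciprocal(self) -> tuple[float, ...]:
        """Reciprocal-cell parameters (1/A lengths, degree angles)."""
        rc = self.to_gemmi().reciprocal()
        return (rc.a, rc.b, rc.c, rc.alpha, rc.beta, rc.gamma)

    def metric_tensor(self) -> np.ndarray:
        a, b, c = self.lengths
        al, be, ga = (math.radians(x) for x in self.angles)
        return np.array(
            [
                [a * a, a * b * math.cos(ga), a * c * math.cos(be)],
                [a * b * math.cos(ga), b * b, b * c * math.cos(al)],
                [a * c * math.cos(be), b * c * math.cos(al), c * c],
            ]
        )

    def reciprocal_metric_tensor(self) -> np.ndarray:
        return np.linalg.inv(self.metric_tensor())


def build_B(cell: UnitCell) -> np.ndarray:
    """Reciprocal-space orthogonalization matrix (Busing-Levy convention).

    Columns are the reciprocal cell vectors a*, b*, c* in a fixed
    reference orientation with a* along lab x and b* in the x-y plane, so
    ``B^T B`` equals the reciprocal metric tensor and ``det B = 1/V``.
    """
    ra, rb, rc, ral, rbe, rga = cell.reciprocal()
    ral, rbe, rga = (math.radians(x) for x in (ral, rbe, rga))
    alpha = math.radians(cell.alpha)
    return np.array(
        [
            [ra, rb * math.cos(rga), rc * math.cos(rbe)],
            [0.0, rb * math.sin(rga), -rc * math.sin(rbe) * math.cos(alpha)],
            [0.0, 0.0, 1.0 / cell.c],
        ]
    )


def _nearest_rotation(M: np.ndarray) -> np.ndarray:
    """Closest proper rotation to M in the Frobenius norm (via SVD)."""
    Uq, _, Vt = np.linalg.svd(M)
    R = Uq @ Vt
    if np.linalg.det(R) < 0:
        Uq[:, -1] *= -1
        R = Uq @ Vt
    return R


@dataclass(frozen=True)
class Crystal:
    """Crystal model: orientation matrix U and unit cell.

    ``A = U B`` is the setting matrix; the rows of ``A^-1`` are the
    real-space cell vectors in the lab frame.
    """

    U: np.ndarray
    cell: UnitCell

    def __post_init__(self):
        U = np.asarray(self.U, dtype=float)
        if U.shape != (3, 3):
            raise GeometryError("U must be 3x3")
        if not np.allclose(U @ U.T, np.eye(3), atol=1e-8) or np.linalg.det(U) < 0:
            raise GeometryError("U must be orthonormal with det +1")
        object.__setattr__(self, "U", U)

    @property
    def B(self) -> np.ndarray:
        return build_B(self.cell)

    @property
    def A(self) -> np.ndarray:
        return self.U @ self.B

    @property
    def A_inv(self) -> np.ndarray:
        return np.linalg.inv(self.A)

    @property
    def real_space_vectors(self) -> np.ndarray:
        """Rows are the real-space cell vectors a, b, c (Angstrom)."""
        return self.A_inv

    @classmethod
    def from_A(cls, A: np.ndarray) -> "Crystal":
        """Build a crystal from a setting matrix, deriving cell and U."""
        A = np.asarray(A, dtype=float)
        if abs(np.linalg.det(A)) < 1e-30:
            raise GeometryError("setting matrix is singular")
        real = np.linalg.inv(A)  # rows: a, b, c
        a, b, c = (np.linalg.norm(real[i]) for i in range(3))

        def ang(u, v):
            return math.degrees(
                math.acos(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
            )

        cell = UnitCell(a, b, c, ang(real[1], real[2]), ang(real[0], real[2]), ang(real[0], real[1]))
        U = _nearest_rotation(A @ np.linalg.inv(build_B(cell)))
        return cls(U=U, cell=cell)


@dataclass(frozen=True)
class Experiment:
    """Bundle of beam, detector, goniometer and scan models."""

    beam: Beam
    detector: Detector
    goniometer: Goniometer
    scan: Scan


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def pixel_to_mm(x_px, y_px, detector: Detector):
    """Map pixel coordinates to millimetres in the virtual detector plane.

    Accepts scalars or arrays; raises for out-of-bounds coordinates.
    """
    x_px = np.asarray(x_px, dtype=float)
    y_px = np.asarray(y_px, dtype=float)
    if np.any(x_px < 0) or np.any(x_px >= detector.n_fast) or np.any(y_px < 0) or np.any(
        y_px >= detector.n_slow
    ):
        raise GeometryError("pixel coordinates outside detector bounds")
    return (x_px + 0.5) * detector.pixel_size, (y_px + 0.5) * detector.pixel_size


def mm_to_s1(x_mm, y_mm, detector: Detector, beam: Beam) -> np.ndarray:
    """Map detector-plane mm coordinates to the scattered beam vector s1.

    s1 points from the crystal toward the detector position and is
    normalized to the Ewald-sphere radius 1/lambda.  Returns shape (3,)
    for scalar input, (N, 3) for array input.
    """
    scalar = np.asarray(x_mm).ndim == 0
    x_mm = np.atleast_1d(np.asarray(x_mm, dtype=float))
    y_mm = np.atleast_1d(np.asarray(y_mm, dtype=float))
    p = (
        np.outer(x_mm, detector.fast_axis)
        + np.outer(y_mm, detector.slow_axis)
        + detector.origin
    )
    norms = np.linalg.norm(p, axis=1)
    if np.any(norms == 0):
        raise GeometryError("detector position coincides with the crystal")
    s1 = p / norms[:, None] / beam.wavelength
    return s1[0] if scalar else s1


def s1_to_rphi(s1: np.ndarray, beam: Beam) -> np.ndarray:
    """Reciprocal-lattice vector in diffracting condition: r_phi = s1 - s0."""
    return np.asarray(s1, dtype=float) - beam.s0


def rotation_about_axis(axis: np.ndarray, phi_deg) -> np.ndarray:
    """Right-handed rotation matrix (or stack) about a unit axis."""
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    return Rotation.from_rotvec(np.multiply.outer(phi, axis)).as_matrix()


def rphi_to_r(r_phi: np.ndarray, goniometer: Goniometer, phi_deg) -> np.ndarray:
    """Rotate r_phi by -phi about the goniometer axis into the phi=0 frame."""
    r_phi = np.asarray(r_phi, dtype=float)
    r2 = np.atleast_2d(r_phi)
    phi = np.broadcast_to(np.atleast_1d(np.asarray(phi_deg, dtype=float)), (r2.shape[0],))
    R = rotation_about_axis(goniometer.axis, -phi)  # (N, 3, 3)
    r = np.einsum("nij,nj->ni", R, r2)
    return r[0] if r_phi.ndim == 1 else r


def frame_to_phi(z, scan: Scan):
    """Continuous frame coordinate to rotation angle in degrees."""
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > scan.n_frames):
        raise GeometryError("frame coordinate outside scan")
    return scan.phi_start + z * scan.delta_phi


def phi_to_frame(phi_deg, scan: Scan):
    """Inverse of :func:`frame_to_phi` (no bounds check)."""
    return (np.asarray(phi_deg, dtype=float) - scan.phi_start) / scan.delta_phi


def spots_to_rlp(spots, experiment: Experiment) -> np.ndarray:
    """Map a spot-centroid table to reciprocal-lattice vectors.

    Parameters
    ----------
    spots : pandas.DataFrame
        Columns ``x_px, y_px, z`` (pixel, pixel, fractional frame).
    experiment : Experiment

    Returns
    -------
    (N, 3) array of r vectors (1/Angstrom) in the phi=0 lab frame.
    """
    x_mm, y_mm = pixel_to_mm(spots["x_px"].to_numpy(), spots["y_px"].to_numpy(), experiment.detector)
    s1 = np.atleast_2d(mm_to_s1(x_mm, y_mm, experiment.detector, experiment.beam))
    r_phi = s1_to_rphi(s1, experiment.beam)
    phi = frame_to_phi(spots["z"].to_numpy(), experiment.scan)
    return rphi_to_r(r_phi, experiment.goniometer, phi)
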