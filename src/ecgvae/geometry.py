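"""Heart localization and coordinate-frame geometry from cardiac MRI plane metadata.

A standard cardiac MRI study provides three imaging planes: a short-axis (SAX)
stack and the 2-chamber and 4-chamber long-axis views.  Each plane is known from
DICOM-style metadata as a normal vector and a point, ``n . (X - P) = 0``.  The
heart center is the intersection of the three planes; a heart-local right-handed
orthonormal frame (eX, eY, eZ) is built from the SAX and 4-chamber normals:

    eX = (nSAX x n4CH) / |nSAX x n4CH|        (the SAX/4CH intersection line)
    eZ = n4CH - (n4CH . eX) eX, normalized
    eY = eZ x eX                              (completes a right-handed set)

Heart orientation is summarized by three projection angles onto the anatomical
axes (reported in degrees):

    alpha = arccos(eX . x),  beta = -arccos(eZ . z),  gamma = -arccos(eX . N)

with N = z, the normal of the anatomical XOY plane.  These are three independent
projection angles, not a rotation decomposition, and are implemented verbatim.

Electrode coordinates measured in the anatomical (scanner) frame are mapped into
the heart frame by translating to the heart center and projecting onto the basis,
so that conditioning features are comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .errors import DegenerateGeometry, FrameMismatch

__all__ = [
    "ELECTRODE_NAMES",
    "Plane3D",
    "HeartPose",
    "ElectrodeLayout",
    "heart_position",
    "heart_frame",
    "euler_angles",
    "build_pose",
    "to_heart_frame",
    "from_heart_frame",
]

#: Canonical electrode order used whenever a layout is flattened to a 30-vector.
ELECTRODE_NAMES: Tuple[str, ...] = (
    "RA", "LA", "RL", "LL", "V1", "V2", "V3", "V4", "V5", "V6",
)

_ANATOMICAL_AXES = np.eye(3)


def _as_vec3(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    return a


@dataclass(frozen=True)
class Plane3D:
    """An MRI imaging plane: unit normal + a point on the plane (mm).

    The normal is re-normalized on construction; a zero normal is rejected.
    """

    normal: np.ndarray
    point: np.ndarray

    def __post_init__(self):
        n = _as_vec3(self.normal)
        norm = np.linalg.norm(n)
        if norm <= 0.0 or not np.isfinite(norm):
            raise DegenerateGeometry("plane normal must be nonzero and finite")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "point", _as_vec3(self.point))

    def signed_distance(self, x) -> float:
        """Residual n . (x - P); zero iff x lies on the plane."""
        return float(self.normal @ (_as_vec3(x) - self.point))


@dataclass(frozen=True)
class HeartPose:
    """Heart center (mm) plus the orthonormal heart frame and its angles (deg)."""

    position: np.ndarray
    eX: np.ndarray
    eY: np.ndarray
    eZ: np.ndarray
    euler: Tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "position", _as_vec3(self.position))
        for name in ("eX", "eY", "eZ"):
            object.__setattr__(self, name, _as_vec3(getattr(self, name)))
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise DegenerateGeometry("heart frame is not orthonormal")
        if np.linalg.det(R) < 0:
            raise DegenerateGeometry("heart frame is not right-handed")

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns (eX, eY, eZ): heart -> anatomical rotation."""
        return np.column_stack([self.eX, self.eY, self.eZ])

    def condition_values(self) -> np.ndarray:
        """Position (mm) followed by the three angles (deg), as a 6-vector."""
        return np.concatenate([self.position, np.asarray(self.euler, dtype=float)])


@dataclass
class ElectrodeLayout:
    """The ten standard 12-lead electrodes as named 3-D coordinates (mm).

    ``frame`` records whether coordinates live in the anatomical (scanner)
    coordinate system or in the heart-local frame.
    """

    coords: Dict[str, np.ndarray]
    frame: str = "anatomical"

    def __post_init__(self):
        if self.frame not in ("anatomical", "heart"):
            raise ValueError(f"unknown frame {self.frame!r}")
        missing = [n for n in ELECTRODE_NAMES if n not in self.coords]
        extra = [n for n in self.coords if n not in ELECTRODE_NAMES]
        if missing or extra:
            raise ValueError(
                f"layout must contain exactly {ELECTRODE_NAMES}; "
                f"missing={missing}, unexpected={extra}"
            )
        self.coords = {n: _as_vec3(self.coords[n]) for n in ELECTRODE_NAMES}

    def as_vector(self) -> np.ndarray:
        """Flatten to a 30-vector in the canonical RA,LA,RL,LL,V1..V6 order."""
        return np.concatenate([self.coords[n] for n in ELECTRODE_NAMES])

    def as_array(self) -> np.ndarray:
        """(10, 3) coordinate array in canonical order."""
        return np.stack([self.coords[n] for n in ELECTRODE_NAMES])

    @classmethod
    def from_array(cls, arr, frame: str = "anatomical") -> "ElectrodeLayout":
        arr = np.asarray(arr, dtype=float).reshape(10, 3)
        return cls({n: arr[i] for i, n in enumerate(ELECTRODE_NAMES)}, frame=frame)


def heart_position(
    sax: Plane3D,
    lax2ch: Plane3D,
    lax4ch: Plane3D,
    cond_threshold: float = 1e8,
) -> np.ndarray:
    """Heart center as the intersection point of the three MRI planes (mm).

    Solves the linear system n_i . X = n_i . P_i for the three planes.

    Raises
    ------
    DegenerateGeometry
        If the stacked-normal matrix has condition number above
        ``cond_threshold`` (near-parallel or duplicated planes).
    """
    N = np.stack([sax.normal, lax2ch.normal, lax4ch.normal])
    b = np.array([
        sax.normal @ sax.point,
        lax2ch.normal @ lax2ch.point,
        lax4ch.normal @ lax4ch.point,
    ])
    cond = np.linalg.cond(N)
    if not np.isfinite(cond) or cond > cond_threshold:
        raise DegenerateGeometry(
            f"plane normals are near-coplanar (condition number {cond:.3g})"
        )
    return np.linalg.solve(N, b)


def heart_frame(sax: Plane3D, lax4ch: Plane3D) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Heart-local orthonormal frame (eX, eY, eZ) from the SAX and 4CH normals.

    eX points along the SAX/4CH plane-intersection line; eZ is the 4CH normal
    orthogonalized against eX (redundant for unit normals, kept for robustness);
    eY = eZ x eX completes the set.  Note the cross-product order: taking
    eX x eZ instead would leave det[eX, eY, eZ] = -1, i.e. a reflection rather
    than a rotation, which would silently break every downstream use of the
    frame as an orientation (the trio ordered (eX, eZ, eY) is the right-handed
    one, so the two conventions differ only in the sign of eY).
    """
    cross = np.cross(sax.normal, lax4ch.normal)
    norm = np.linalg.norm(cross)
    if norm < 1e-10:
        raise DegenerateGeometry("SAX and 4CH normals are parallel")
    eX = cross / norm
    eZ = lax4ch.normal - (lax4ch.normal @ eX) * eX
    eZ = eZ / np.linalg.norm(eZ)
    eY = np.cross(eZ, eX)
    return eX, eY, eZ


def euler_angles(
    frame: Tuple[np.ndarray, np.ndarray, np.ndarray],
    anatomical_axes: np.ndarray = _ANATOMICAL_AXES,
) -> Tuple[float, float, float]:
    """Projection angles (alpha, beta, gamma) of the heart frame, in degrees.

    alpha = arccos(eX . x), beta = -arccos(eZ . z), gamma = -arccos(eX . N)
    with N the anatomical XOY-plane normal (= z).  Dot products are clamped to
    [-1, 1] to absorb rounding before the arccos.
    """
    eX, _, eZ = (np.asarray(v, dtype=float) for v in frame)
    axes = np.asarray(anatomical_axes, dtype=float)
    x_hat, z_hat = axes[:, 0] / np.linalg.norm(axes[:, 0]), axes[:, 2] / np.linalg.norm(axes[:, 2])
    n_xoy = z_hat

    def _ang(u, v):
        c = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    alpha = _ang(eX, x_hat)
    beta = -_ang(eZ, z_hat)
    gamma = -_ang(eX, n_xoy)
    return (alpha, beta, gamma)


def build_pose(sax: Plane3D, lax2ch: Plane3D, lax4ch: Plane3D, **kwargs) -> HeartPose:
    """Full pose (position + frame + angles) from the three imaging planes."""
    pos = heart_position(sax, lax2ch, lax4ch, **kwargs)
    eX, eY, eZ = heart_frame(sax, lax4ch)
    return HeartPose(pos, eX, eY, eZ, euler_angles((eX, eY, eZ)))


def to_heart_frame(layout: ElectrodeLayout, pose: HeartPose) -> ElectrodeLayout:
    """Express an anatomical-frame electrode layout in the heart-local frame.

    Each coordinate p maps to ((p - position) . eX, (p - position) . eY,
    (p - position) . eZ); the heart center becomes the origin.
    """
    if layout.frame != "anatomical":
        raise FrameMismatch("layout is already in the heart frame")
    R = pose.rotation
    arr = (layout.as_array() - pose.position) @ R
    return ElectrodeLayout.from_array(arr, frame="heart")


def from_heart_frame(layout: ElectrodeLayout, pose: HeartPose) -> ElectrodeLayout:
    """Inverse of :func:`to_heart_frame`."""
    if layout.frame != "heart":
        raise FrameMismatch("layout is not in the heart frame")
    R = pose.rotation
    arr = layout.as_array() @ R.T + pose.position
    return ElectrodeLayout.from_array(arr, frame="anatomical")
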