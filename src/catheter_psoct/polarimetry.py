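"""Polarization algebra on the Poincaré sphere.

Pure retarders act on normalized Stokes vectors as rotations in SO(3); a linear
retarder with physical fast-axis orientation theta (degrees, mod 180) rotates
about the equatorial axis (cos 2*theta, sin 2*theta, 0).  Every array-valued
routine here broadcasts over leading dimensions, so a whole tomogram of
rotations is one (..., 3, 3) ndarray.

Sign conventions (fixed once, used by every downstream module):

* Stokes components from the two detection channels (h, v):
  q = (|h|^2 - |v|^2)/I,  u = 2 Re(h v*)/I,  v = -2 Im(h v*)/I.
* Rotations are right-handed about their axis.
* The SU(2) lift pairs (q, u, v) with the Pauli matrices (sigma_3, sigma_1,
  sigma_2) and fixes the global phase to zero:
  U = cos(phi/2) I - i sin(phi/2) (a_q sigma_3 + a_u sigma_1 + a_v sigma_2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PolarizationState",
    "LinearRetarderParams",
    "stokes_from_fields",
    "linear_retarder",
    "rotation_to_retvec",
    "retvec_to_rotation",
    "d_transpose",
    "rotation_from_state_pairs",
    "su2_from_rotation",
    "is_rotation",
    "rotation_angle",
]

#: Reciprocity operator for round-trip measurements, D = diag(1, 1, -1).
D_MIRROR = np.diag([1.0, 1.0, -1.0])

_DT_SIGNS = np.outer(np.diag(D_MIRROR), np.diag(D_MIRROR))


@dataclass(frozen=True)
class PolarizationState:
    """A (possibly array-valued) normalized Stokes vector with its intensity."""

    q: np.ndarray
    u: np.ndarray
    v: np.ndarray
    intensity: np.ndarray

    @property
    def vec(self) -> np.ndarray:
        """Stacked (q, u, v) components, shape (..., 3)."""
        return np.stack([self.q, self.u, self.v], axis=-1)

    @property
    def valid(self) -> np.ndarray:
        return np.asarray(self.intensity) > 0

    def normalized(self, atol: float = 1e-12) -> "PolarizationState":
        vec = self.vec
        norm = np.linalg.norm(vec, axis=-1, keepdims=True)
        vec = np.where(norm > atol, vec / np.where(norm > atol, norm, 1.0), vec)
        return PolarizationState(vec[..., 0], vec[..., 1], vec[..., 2], np.asarray(self.intensity))


@dataclass(frozen=True)
class LinearRetarderParams:
    """Physical parameters of a linear retarder.

    orientation_deg: fast-axis orientation in degrees, interpreted mod 180;
    retardance_rad: rotation angle about the Poincaré axis, >= 0.
    """

    orientation_deg: float
    retardance_rad: float

    @property
    def poincare_axis(self) -> np.ndarray:
        two_theta = 2.0 * np.deg2rad(self.orientation_deg)
        return np.array([np.cos(two_theta), np.sin(two_theta), 0.0])


def stokes_from_fields(h, v) -> PolarizationState:
    """Stokes vector of the field pair from polarization-diverse detection.

    Broadcasts over array inputs.  Pixels with zero total intensity return a
    zero vector and intensity 0 (flagged invalid via ``.valid``).
    """
    h = np.asarray(h, dtype=complex)
    v = np.asarray(v, dtype=complex)
    intensity = np.abs(h) ** 2 + np.abs(v) ** 2
    hv = h * np.conj(v)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe = np.where(intensity > 0, intensity, 1.0)
        q = (np.abs(h) ** 2 - np.abs(v) ** 2) / safe
        u = 2.0 * hv.real / safe
        vv = -2.0 * hv.imag / safe
    zero = intensity == 0
    q = np.where(zero, 0.0, q)
    u = np.where(zero, 0.0, u)
    vv = np.where(zero, 0.0, vv)
    return PolarizationState(q=q, u=u, v=vv, intensity=intensity)


def linear_retarder(orientation_deg, retardance_rad) -> np.ndarray:
    """SO(3) rotation of a linear retarder; broadcasts to (..., 3, 3).

    Rotation by ``retardance_rad`` about the equatorial Poincaré axis
    (cos 2*theta, sin 2*theta, 0); zero retardance gives the identity.
    """
    theta2 = 2.0 * np.deg2rad(np.asarray(orientation_deg, dtype=float))
    delta = np.asarray(retardance_rad, dtype=float)
    theta2, delta = np.broadcast_arrays(theta2, delta)
    axis = np.stack([np.cos(theta2), np.sin(theta2), np.zeros_like(theta2)], axis=-1)
    return retvec_to_rotation(axis, delta)


def retvec_to_rotation(axis, angle) -> np.ndarray:
    """Rotation matrix from a unit axis (..., 3) and angle (...)."""
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    rotvec = axis * angle[..., None]
    flat = rotvec.reshape(-1, 3)
    mats = Rotation.from_rotvec(flat).as_matrix()
    return mats.reshape(rotvec.shape[:-1] + (3, 3))


def rotation_to_retvec(r, pi_tol: float = 1e-9):
    """Axis-angle logarithm of a rotation stack.

    Returns ``(axis, angle)`` with angle in [0, pi].  The zero rotation maps to
    axis (1, 0, 0) by convention.  At angle pi the axis sign is ambiguous
    (R(a, pi) == R(-a, pi)); the tie-break makes the first component with
    magnitude above ``pi_tol`` positive.
    """
    r = np.asarray(r, dtype=float)
    flat = r.reshape(-1, 3, 3)
    rotvec = Rotation.from_matrix(flat).as_rotvec()
    angle = np.linalg.norm(rotvec, axis=-1)
    axis = np.where(angle[:, None] > 1e-15, rotvec / np.where(angle[:, None] > 0, angle[:, None], 1.0), [1.0, 0.0, 0.0])
    near_pi = angle > np.pi - 1e-7
    if np.any(near_pi):
        ax = axis[near_pi]
        # first component of magnitude > pi_tol must be positive
        lead = np.where(
            np.abs(ax[:, 0]) > pi_tol,
            np.sign(ax[:, 0]),
            np.where(np.abs(ax[:, 1]) > pi_tol, np.sign(ax[:, 1]), np.sign(ax[:, 2])),
        )
        lead = np.where(lead == 0, 1.0, lead)
        axis[near_pi] = ax * lead[:, None]
    shape = r.shape[:-2]
    return axis.reshape(shape + (3,)), angle.reshape(shape)


def rotation_angle(r) -> np.ndarray:
    """Rotation angle in [0, pi] of a rotation stack (cheap, trace-based)."""
    r = np.asarray(r)
    tr = np.trace(r, axis1=-2, axis2=-1)
    return np.arccos(np.clip((tr - 1.0) / 2.0, -1.0, 1.0))


def d_transpose(r) -> np.ndarray:
    """Reciprocity conjugate D r^T D with D = diag(1, 1, -1).

    Involution; leaves every linear retarder fixed and reverses the sense of
    circular retarders.  Reverses products: dT(A B) = dT(B) dT(A).
    """
    r = np.asarray(r)
    return np.swapaxes(r, -1, -2) * _DT_SIGNS


def _orthonormal_triad(a, b, atol):
    """Gram-Schmidt triad (a, b', a x b') from approximately orthogonal units."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1, keepdims=True)
    a = a / np.where(na > atol, na, 1.0)
    b = b - np.sum(a * b, axis=-1, keepdims=True) * a
    nb = np.linalg.norm(b, axis=-1, keepdims=True)
    b = b / np.where(nb > atol, nb, 1.0)
    c = np.cross(a, b)
    ok = (na[..., 0] > atol) & (nb[..., 0] > atol)
    return np.stack([a, b, c], axis=-1), ok


def rotation_from_state_pairs(in1, in2, out1, out2, *, atol=1e-9, max_angle_dev_deg=None):
    """Rotation mapping the input state pair onto the measured output pair.

    The two probing states are orthogonal on the Poincaré sphere; together with
    their cross product they form a triad, and the rotation is the change of
    basis between the input and output triads.  The output pair is
    orthogonalized against ``out1`` (Gram-Schmidt) to absorb measurement noise.

    Returns ``(rotation, valid)``.  ``valid`` is False where either pair is
    degenerate or, when ``max_angle_dev_deg`` is given, where the measured pair
    deviates from orthogonality by more than that limit.
    """
    in1 = _as_vec(in1)
    in2 = _as_vec(in2)
    out1 = _as_vec(out1)
    out2 = _as_vec(out2)
    bin_, ok_in = _orthonormal_triad(in1, in2, atol)
    bout, ok_out = _orthonormal_triad(out1, out2, atol)
    rot = bout @ np.swapaxes(bin_, -1, -2)
    valid = ok_in & ok_out
    if max_angle_dev_deg is not None:
        n1 = np.linalg.norm(out1, axis=-1)
        n2 = np.linalg.norm(out2, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.sum(out1 * out2, axis=-1) / np.where((n1 > 0) & (n2 > 0), n1 * n2, 1.0)
        dev = np.abs(90.0 - np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0))))
        valid = valid & (dev <= max_angle_dev_deg)
    return rot, valid


def _as_vec(s):
    if isinstance(s, PolarizationState):
        return s.vec
    return np.asarray(s, dtype=float)


_SIGMA = np.array(
    [
        [[1, 0], [0, -1]],  # pairs with q
        [[0, 1], [1, 0]],  # pairs with u
        [[0, -1j], [1j, 0]],  # pairs with v
    ],
    dtype=complex,
)


def su2_from_rotation(r) -> np.ndarray:
    """Half-angle SU(2) lift of a rotation stack, global phase fixed to zero.

    Satisfies Stokes(U j) == R @ Stokes(j) for every Jones vector j under the
    module's Stokes convention.
    """
    axis, angle = rotation_to_retvec(np.asarray(r, dtype=float))
    ns = np.einsum("...k,kij->...ij", axis, _SIGMA)
    c = np.cos(angle / 2.0)[..., None, None]
    s = np.sin(angle / 2.0)[..., None, None]
    eye = np.eye(2, dtype=complex)
    return c * eye - 1j * s * ns


def is_rotation(r, tol: float = 1e-9) -> np.ndarray:
    """True where r has orthonormal columns and determinant +1 within tol."""
    r = np.asarray(r, dtype=float)
    eye = np.eye(3)
    ortho = np.max(np.abs(np.swapaxes(r, -1, -2) @ r - eye), axis=(-2, -1)) <= tol
    det = np.abs(np.linalg.det(r) - 1.0) <= tol
    return ortho & det
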