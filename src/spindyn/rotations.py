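"""Euler angles, Wigner matrices, Clebsch–Gordan coefficients, 3D geometry.

Conventions: zyz active rotations (the NMR-community standard), with
D^J_{mm′}(α,β,γ) = e^{−imα} d^J_{mm′}(β) e^{−im′γ} and matrix indices
ordered m = +J … −J. Clebsch–Gordan coefficients follow Condon–Shortley
phases and are real.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "EulerAngles",
    "wigner_d",
    "wigner_D",
    "wigner_D_element",
    "clebsch_gordan",
    "euler_rotation_matrix",
    "axes3d",
    "axes_to_euler",
    "rotate_euler",
    "distance",
    "subtended_angle",
    "bond_angle",
    "geometry",
]


@dataclass(frozen=True)
class EulerAngles:
    """zyz Euler angle triplet Ω = (α, β, γ) in radians."""

    alpha: float
    beta: float
    gamma: float

    def __iter__(self):
        return iter((self.alpha, self.beta, self.gamma))


def _check_J(J: float) -> None:
    if J < 0 or abs(2 * J - round(2 * J)) > 1e-12:
        raise ValueError(f"rank J must be a nonnegative half-integer, got {J}")


def _jy_matrix(J: float) -> np.ndarray:
    """Angular-momentum J_y for rank J, indices m = +J … −J."""
    d = int(round(2 * J + 1))
    m = np.arange(J, -J - 0.5, -1.0)
    plus = np.zeros((d, d))
    for k in range(1, d):
        plus[k - 1, k] = math.sqrt(J * (J + 1) - m[k] * (m[k] + 1))
    return (-0.5j * (plus - plus.T)).astype(complex)


def wigner_d(J: float, beta: float) -> np.ndarray:
    """Reduced Wigner matrix d^J(β) = exp(−iβ J_y); real to rounding."""
    _check_J(J)
    w, V = np.linalg.eigh(_jy_matrix(J))
    d = (V * np.exp(-1j * beta * w)) @ V.conj().T
    return d.real.copy() if np.allclose(d.imag, 0, atol=1e-12) else d


def wigner_D(J: float, omega) -> np.ndarray:
    """Wigner matrix D^J(Ω); a list of Ω's gives the ordered product D(Ω₁)D(Ω₂)…"""
    _check_J(J)
    omegas = _as_omega_list(omega)
    m = np.arange(J, -J - 0.5, -1.0)
    out = np.eye(int(round(2 * J + 1)), dtype=complex)
    for alpha, beta, gamma in omegas:
        D = np.exp(-1j * m[:, None] * alpha) * wigner_d(J, beta) * np.exp(-1j * m[None, :] * gamma)
        out = out @ D
    return out


def _as_omega_list(omega):
    if isinstance(omega, EulerAngles):
        return [tuple(omega)]
    omega = list(omega)
    if len(omega) == 3 and np.isscalar(omega[0]):
        return [tuple(map(float, omega))]
    return [tuple(o) if not isinstance(o, EulerAngles) else tuple(o) for o in omega]


def wigner_D_element(J: float, m: float, mp: float, omega) -> complex:
    """Single element D^J_{m m′}(Ω) (or of the product over a list of Ω's)."""
    if abs(m) > J or abs(mp) > J:
        raise ValueError("|m|, |m′| must not exceed J")
    mvals = np.arange(J, -J - 0.5, -1.0)
    i = int(np.argmin(np.abs(mvals - m)))
    k = int(np.argmin(np.abs(mvals - mp)))
    return complex(wigner_D(J, omega)[i, k])


@lru_cache(maxsize=None)
def _fact(n: int) -> float:
    return float(math.factorial(n))


def clebsch_gordan(j1: float, m1: float, j2: float, m2: float, J: float, M: float) -> float:
    """Clebsch–Gordan coefficient ⟨j1 m1; j2 m2 | J M⟩ (Condon–Shortley, real).

    Computed from the Racah closed form. Returns 0 when the selection rules
    (M = m1 + m2, triangle rule, |m| ≤ j) are not satisfied.
    """
    for x in (j1, m1, j2, m2, J, M):
        if abs(2 * x - round(2 * x)) > 1e-9:
            raise ValueError("arguments must be integers or half-integers")
    if abs(m1 + m2 - M) > 1e-9:
        return 0.0
    if J < abs(j1 - j2) - 1e-9 or J > j1 + j2 + 1e-9:
        return 0.0
    if abs(m1) > j1 + 1e-9 or abs(m2) > j2 + 1e-9 or abs(M) > J + 1e-9:
        return 0.0
    # all of these are nonnegative integers when the rules above hold
    def f(x: float) -> float:
        n = round(x)
        if abs(x - n) > 1e-9 or n < 0:
            raise ValueError("non-integer factorial argument in CG evaluation")
        return _fact(int(n))

    pref = math.sqrt(
        (2 * J + 1)
        * f(J + j1 - j2) * f(J - j1 + j2) * f(j1 + j2 - J)
        / f(j1 + j2 + J + 1)
    )
    pref *= math.sqrt(
        f(J + M) * f(J - M) * f(j1 - m1) * f(j1 + m1) * f(j2 - m2) * f(j2 + m2)
    )
    total = 0.0
    kmin = int(max(0, round(j2 - J - m1), round(j1 + m2 - J)))
    kmax = int(min(round(j1 + j2 - J), round(j1 - m1), round(j2 + m2)))
    for k in range(kmin, kmax + 1):
        total += (-1) ** k / (
            f(k) * f(j1 + j2 - J - k) * f(j1 - m1 - k) * f(j2 + m2 - k)
            * f(J - j2 + m1 + k) * f(J - j1 - m2 + k)
        )
    return pref * total


# -- 3D geometry ---------------------------------------------------------

def euler_rotation_matrix(omega) -> np.ndarray:
    """Cartesian 3×3 matrix of the active zyz rotation R(α,β,γ) = Rz(α)Ry(β)Rz(γ)."""
    alpha, beta, gamma = tuple(omega) if isinstance(omega, EulerAngles) else tuple(map(float, omega))

    def rz(t):
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])

    def ry(t):
        c, s = math.cos(t), math.sin(t)
        return np.array([[c, 0, s], [0, 1.0, 0], [-s, 0, c]])

    return rz(alpha) @ ry(beta) @ rz(gamma)


def axes3d(z_guide, x_plane_guide=None) -> np.ndarray:
    """Right-handed orthonormal axes (columns x, y, z) from guide vectors.

    ``z_guide`` fixes the z-axis; the optional second vector fixes the
    plane containing the x-axis.
    """
    z = np.asarray(z_guide, dtype=float)
    nz = np.linalg.norm(z)
    if nz == 0:
        raise ValueError("zero z guide vector")
    z = z / nz
    if x_plane_guide is None:
        trial = np.array([1.0, 0, 0]) if abs(z[0]) < 0.9 else np.array([0, 1.0, 0])
    else:
        trial = np.asarray(x_plane_guide, dtype=float)
    x = trial - (trial @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-12:
        raise ValueError("x-plane guide is parallel to the z guide")
    x = x / nx
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def axes_to_euler(axes_a, axes_b) -> EulerAngles:
    """zyz Euler angles of the active rotation carrying axes A onto axes B.

    Axes are 3×3 matrices with the unit axis vectors as columns. For β ≈ 0
    (gauge degeneracy of α+γ) the result is canonicalized with γ = 0.
    """
    A = np.asarray(axes_a, dtype=float)
    B = np.asarray(axes_b, dtype=float)
    R = B @ A.T
    beta = math.acos(min(1.0, max(-1.0, R[2, 2])))
    if abs(math.sin(beta)) > 1e-10:
        alpha = math.atan2(R[1, 2], R[0, 2])
        gamma = math.atan2(R[2, 1], -R[2, 0])
    else:
        gamma = 0.0
        if R[2, 2] > 0:
            alpha = math.atan2(R[1, 0], R[0, 0])
        else:
            alpha = math.atan2(-R[1, 0], -R[0, 0])
    return EulerAngles(alpha, beta, gamma)


def rotate_euler(obj, omega):
    """Rotate a 3-vector, or a 3×3 axes matrix (columns), by R(Ω)."""
    R = euler_rotation_matrix(omega)
    arr = np.asarray(obj, dtype=float)
    return R @ arr


def distance(p1, p2) -> float:
    """Euclidean distance between two points (Å in, Å out)."""
    return float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p2, float)))


def _angle_at(vertex, p1, p2) -> float:
    v1 = np.asarray(p1, float) - np.asarray(vertex, float)
    v2 = np.asarray(p2, float) - np.asarray(vertex, float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("coincident points: angle undefined")
    c = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return math.acos(c)


def subtended_angle(p1, p2, vertex) -> float:
    """Angle subtended at ``vertex`` by points p1 and p2, in radians."""
    return _angle_at(vertex, p1, p2)


def bond_angle(p1, p2, p3) -> float:
    """Bond angle at the central atom p2 of the triad p1–p2–p3, in radians."""
    return _angle_at(p2, p1, p3)


def geometry(kind: str, *coords) -> float:
    """Dispatch helper: kind in {distance, subtended_angle, bond_angle}."""
    fns = {"distance": distance, "subtended_angle": subtended_angle, "bond_angle": bond_angle}
    if kind not in fns:
        raise ValueError(f"unknown geometry kind {kind!r}")
    return fns[kind](*coords)
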