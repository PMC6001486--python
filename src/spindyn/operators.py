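"""Basis-independent spin-operator algebra on Hilbert space.

A :class:`SpinOperator` stores its matrix in the reference Zeeman ordering;
its representation in any other orthonormal basis B with ket matrix V is
V†MV, so the object itself is basis-independent. Single-spin operators for
arbitrary I are built exactly from the ladder-operator matrix elements
(I⁺)_{m′,m} = √(I(I+1) − m(m+1)) δ_{m′,m+1}.
"""

from __future__ import annotations

import math
import numpy as np
import scipy.linalg

from .spin_system import HilbertBasis, Ket, SpinSystem

__all__ = [
    "SpinOperator",
    "RotationSpec",
    "single_spin_matrices",
    "op_I",
    "scalar_coupling",
    "operator_product",
    "matrix_representation",
    "operator_from_matrix",
    "operator_exp",
    "rotation_operator",
    "operator_norm",
    "normalize_operator",
    "operator_amplitude",
    "coherence_order",
    "special_operator",
    "unity_operator",
    "null_operator",
    "operators_close",
]

EQUALITY_TOL = 1e-12
COHERENCE_TOL = 1e-10


def single_spin_matrices(I: float) -> dict:
    """Exact angular-momentum matrices for one spin-I (m ordered +I … −I)."""
    d = int(round(2 * I + 1))
    m = np.arange(I, -I - 0.5, -1.0)
    plus = np.zeros((d, d))
    for k in range(1, d):  # raises m[k] -> m[k-1]
        mm = m[k]
        plus[k - 1, k] = math.sqrt(I * (I + 1) - mm * (mm + 1))
    minus = plus.T.copy()
    z = np.diag(m)
    x = 0.5 * (plus + minus)
    y = -0.5j * (plus - minus)
    return {
        "x": x.astype(complex),
        "y": y.astype(complex),
        "z": z.astype(complex),
        "+": plus.astype(complex),
        "-": minus.astype(complex),
        "e": np.eye(d, dtype=complex),
    }


class SpinOperator:
    """A linear operator on the Hilbert space of a spin system."""

    __array_priority__ = 100  # ensure our __rmul__ beats numpy scalars

    def __init__(self, system: SpinSystem, matrix, label: str | None = None):
        self.system = system
        self.matrix = np.asarray(matrix, dtype=complex)
        n = system.dimension
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix must be {n}x{n} for this system")
        self.label = label

    # -- algebra ---------------------------------------------------------
    def _check(self, other: "SpinOperator") -> None:
        if self.system is not other.system and self.system != other.system:
            raise ValueError("operators belong to different spin systems")

    def __add__(self, other):
        if isinstance(other, SpinOperator):
            self._check(other)
            return SpinOperator(self.system, self.matrix + other.matrix)
        if np.isscalar(other):  # scalar means scalar * unity
            return SpinOperator(self.system, self.matrix + other * np.eye(self.system.dimension))
        return NotImplemented

    __radd__ = __add__

    def __sub__(self, other):
        return self + (-1) * other

    def __rsub__(self, other):
        return (-1) * self + other

    def __neg__(self):
        return (-1) * self

    def __mul__(self, other):
        if np.isscalar(other):
            return SpinOperator(self.system, self.matrix * other)
        if isinstance(other, SpinOperator):
            return self @ other
        if isinstance(other, Ket):
            return Ket(other.system, self.matrix @ other.coefficients)
        return NotImplemented

    def __rmul__(self, other):
        if np.isscalar(other):
            return SpinOperator(self.system, self.matrix * other)
        return NotImplemented

    def __truediv__(self, other):
        if np.isscalar(other):
            return SpinOperator(self.system, self.matrix / other)
        return NotImplemented

    def __matmul__(self, other):
        if isinstance(other, SpinOperator):
            self._check(other)
            return SpinOperator(self.system, self.matrix @ other.matrix)
        if isinstance(other, Ket):
            return Ket(other.system, self.matrix @ other.coefficients)
        return NotImplemented

    def adjoint(self) -> "SpinOperator":
        return SpinOperator(self.system, self.matrix.conj().T)

    @property
    def H(self) -> "SpinOperator":
        return self.adjoint()

    def commutator(self, other: "SpinOperator") -> "SpinOperator":
        self._check(other)
        return SpinOperator(self.system, self.matrix @ other.matrix - other.matrix @ self.matrix)

    # -- metrics ---------------------------------------------------------
    def norm(self) -> float:
        return float(np.linalg.norm(self.matrix))

    def trace(self) -> complex:
        return complex(np.trace(self.matrix))

    def is_hermitian(self, tol: float = EQUALITY_TOL) -> bool:
        return bool(np.allclose(self.matrix, self.matrix.conj().T, atol=tol))

    def __repr__(self) -> str:
        tag = self.label or "SpinOperator"
        return f"<{tag} on {self.system!r}>"


def operators_close(a: SpinOperator, b: SpinOperator, tol: float = EQUALITY_TOL) -> bool:
    """Elementwise equality of two operators to absolute tolerance."""
    return bool(np.allclose(a.matrix, b.matrix, atol=tol))


def _embed(system: SpinSystem, idx: int, mat: np.ndarray) -> np.ndarray:
    """Embed a single-spin matrix at position idx with identity Kronecker factors."""
    out = np.ones((1, 1), dtype=complex)
    for j, d in enumerate(system.dims):
        out = np.kron(out, mat if j == idx else np.eye(d))
    return out


class RotationSpec:
    """A rotation specification: targets, angle β, and an axis.

    The axis may be a Cartesian name ("x", "y", "z", "-x", …), a phase
    angle φ in the xy-plane, a polar pair (θ tilt, φ phase), or an
    explicit 3-vector. Resolves to a unit axis vector n.
    """

    def __init__(self, angle: float, axis="x", targets=None):
        self.angle = float(angle)
        self.axis_spec = axis
        self.targets = targets
        self.axis = self._resolve_axis(axis)

    @staticmethod
    def _resolve_axis(spec) -> np.ndarray:
        named = {
            "x": (1, 0, 0), "y": (0, 1, 0), "z": (0, 0, 1),
            "-x": (-1, 0, 0), "-y": (0, -1, 0), "-z": (0, 0, -1),
        }
        if isinstance(spec, str):
            if spec not in named:
                raise ValueError(f"unknown axis {spec!r}")
            return np.array(named[spec], dtype=float)
        if np.isscalar(spec):  # phase angle in the xy-plane
            phi = float(spec)
            return np.array([math.cos(phi), math.sin(phi), 0.0])
        if len(spec) == 2:  # polar pair (tilt θ, phase φ)
            theta, phi = map(float, spec)
            return np.array(
                [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi), math.cos(theta)]
            )
        n = np.asarray(spec, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("zero axis vector")
        return n / norm


def op_I(system: SpinSystem, *args) -> SpinOperator:
    """Angular-momentum (and polarization) operators.

    ``op_I(system, spec)`` sums over all spins; ``op_I(system, targets, spec)``
    restricts to the given label(s). ``spec`` is one of "x", "y", "z",
    "-x", "-y", "-z", "+", "-", "α"/"β" (spin-1/2 projection operators),
    a phase angle φ (operator in the xy-plane), or a polar pair (θ, φ).
    Omitting ``spec`` entirely is not allowed; use :func:`operator_product`
    of bare vectors for scalar couplings (or ``scalar_coupling``).
    """
    if len(args) == 1:
        targets, spec = None, args[0]
    elif len(args) == 2:
        targets, spec = args
    else:
        raise TypeError("op_I(system, [targets,] spec)")
    idxs = system.indices(targets)

    total = np.zeros((system.dimension, system.dimension), dtype=complex)
    for idx in idxs:
        I = system.quantum_numbers[idx]
        mats = single_spin_matrices(I)
        if isinstance(spec, str):
            key = {"alpha": "α", "beta": "β", "a": "α", "b": "β"}.get(spec, spec)
            if key in ("α", "β"):
                if I != 0.5:
                    raise ValueError("polarization operators α/β require spin-1/2")
                proj = np.zeros((2, 2), dtype=complex)
                proj[0 if key == "α" else 1, 0 if key == "α" else 1] = 1.0
                single = proj
            elif key in ("x", "y", "z", "+", "-"):
                single = mats[key]
            elif key in ("-x", "-y", "-z"):
                single = -mats[key[1]]
            else:
                raise ValueError(f"unknown operator spec {spec!r}")
        elif np.isscalar(spec):  # phase angle in xy-plane
            phi = float(spec)
            single = mats["x"] * math.cos(phi) + mats["y"] * math.sin(phi)
        elif len(spec) == 2:  # polar pair (tilt, phase)
            theta, phi = map(float, spec)
            single = (
                math.sin(theta) * math.cos(phi) * mats["x"]
                + math.sin(theta) * math.sin(phi) * mats["y"]
                + math.cos(theta) * mats["z"]
            )
        else:
            raise ValueError(f"unknown operator spec {spec!r}")
        total += _embed(system, idx, single)
    label = f"I[{targets if targets is not None else 'all'},{spec!r}]"
    return SpinOperator(system, total, label=label)


def scalar_coupling(system: SpinSystem, label1, label2) -> SpinOperator:
    """The scalar product I_j·I_k = I_jxI_kx + I_jyI_ky + I_jzI_kz."""
    out = None
    for mu in ("x", "y", "z"):
        term = op_I(system, [label1], mu) @ op_I(system, [label2], mu)
        out = term if out is None else out + term
    out.label = f"I{label1}.I{label2}"
    return out


def operator_product(*ops: SpinOperator) -> SpinOperator:
    """Matrix product of the operators in listed order."""
    if not ops:
        raise ValueError("need at least one operator")
    out = ops[0]
    for op in ops[1:]:
        out = out @ op
    return out


def matrix_representation(op: SpinOperator, basis: HilbertBasis | None = None) -> np.ndarray:
    """The N_H×N_H matrix of ``op`` in ``basis`` (default: the Zeeman basis)."""
    if basis is None:
        return op.matrix.copy()
    if basis.system != op.system:
        raise ValueError("basis belongs to a different system")
    V = basis.kets_matrix
    return V.conj().T @ op.matrix @ V


def operator_from_matrix(system: SpinSystem, matrix, basis: HilbertBasis | None = None) -> SpinOperator:
    """Basis-independent operator with the given matrix representation in ``basis``."""
    M = np.asarray(matrix, dtype=complex)
    n = system.dimension
    if M.shape != (n, n):
        raise ValueError(f"matrix must be {n}x{n}")
    if basis is None:
        return SpinOperator(system, M)
    if basis.system != system:
        raise ValueError("basis belongs to a different system")
    V = basis.kets_matrix
    return SpinOperator(system, V @ M @ V.conj().T)


def operator_exp(scalar: complex, op: SpinOperator) -> SpinOperator:
    """Matrix exponential exp(scalar·op)."""
    M = scalar * op.matrix
    if np.allclose(M, M.conj().T, atol=1e-13):
        w, V = np.linalg.eigh(M)
        E = (V * np.exp(w)) @ V.conj().T
    else:
        A = op.matrix
        # Hermitian generator with (anti-)imaginary scalar: use the exact
        # eigendecomposition path; otherwise scaling-and-squaring.
        if np.allclose(A, A.conj().T, atol=1e-13):
            w, V = np.linalg.eigh(A)
            E = (V * np.exp(scalar * w)) @ V.conj().T
        else:
            E = scipy.linalg.expm(M)
    return SpinOperator(op.system, E)


def rotation_operator(system: SpinSystem, spec: RotationSpec | tuple, targets=None) -> SpinOperator:
    """Rotation operator R = exp(−iβ I·n) acting on the target spins.

    ``spec`` may be a :class:`RotationSpec` or an (angle, axis) pair. Spins
    outside ``targets`` are untouched (identity factors).
    """
    if not isinstance(spec, RotationSpec):
        angle, axis = spec
        spec = RotationSpec(angle, axis, targets)
    elif targets is None:
        targets = spec.targets
    n = spec.axis
    gen = (
        n[0] * op_I(system, targets, "x")
        + n[1] * op_I(system, targets, "y")
        + n[2] * op_I(system, targets, "z")
    )
    R = operator_exp(-1j * spec.angle, gen)
    R.label = f"R({spec.angle:.4g},{spec.axis_spec!r})"
    return R


def operator_norm(op: SpinOperator) -> float:
    """Frobenius norm: √(Σ|Q_rs|²)."""
    return op.norm()


def normalize_operator(op: SpinOperator) -> SpinOperator:
    nrm = op.norm()
    if nrm == 0:
        raise ValueError("cannot normalize the zero operator")
    out = op / nrm
    out.label = op.label
    return out


def operator_amplitude(A: SpinOperator, B: SpinOperator) -> complex:
    """Operator amplitude b = (B|A)/(B|B): A = b·B + (operators ⟂ B)."""
    A._check(B)
    bb = np.vdot(B.matrix, B.matrix)
    if abs(bb) == 0:
        raise ValueError("amplitude with respect to the zero operator")
    return complex(np.vdot(B.matrix, A.matrix) / bb)


def _coherence_plane(system: SpinSystem, targets=None) -> np.ndarray:
    """Matrix P with P[r, s] = Σ_{j∈targets}(m_j(r) − m_j(s))."""
    m = system.m_values()[:, system.indices(targets)].sum(axis=1)
    return m[:, None] - m[None, :]


def coherence_order(op: SpinOperator, targets=None):
    """Sorted coherence orders present in an operator.

    The operator is decomposed by the eigenvalue of the commutation action
    of Σ_{j∈targets} I_jz (all spins when ``targets`` is None); orders whose
    component exceeds the 1e−10 Frobenius tolerance are returned.
    """
    system = op.system
    P = _coherence_plane(system, targets)
    orders = []
    for p in np.unique(P):
        comp = np.where(np.isclose(P, p), op.matrix, 0.0)
        if np.linalg.norm(comp) > COHERENCE_TOL:
            orders.append(int(round(p)) if abs(p - round(p)) < 1e-9 else float(p))
    return sorted(orders)


def unity_operator(system: SpinSystem) -> SpinOperator:
    return SpinOperator(system, np.eye(system.dimension), label="1")


def null_operator(system: SpinSystem) -> SpinOperator:
    return SpinOperator(system, np.zeros((system.dimension, system.dimension)), label="0")


def _single_spin_tensor(I: float, lam: int, mu: int) -> np.ndarray:
    """Normalized irreducible spherical tensor T_{λμ} of one spin-I.

    Matrix elements from Clebsch–Gordan coupling (Condon–Shortley):
    ⟨I m′|T_{λμ}|I m⟩ ∝ ⟨I m; λ μ|I m′⟩, Frobenius-normalized.
    """
    from .rotations import clebsch_gordan  # deferred: avoids an import cycle

    d = int(round(2 * I + 1))
    mvals = np.arange(I, -I - 0.5, -1.0)
    T = np.zeros((d, d), dtype=complex)
    for a, mp in enumerate(mvals):
        for b, mm in enumerate(mvals):
            T[a, b] = clebsch_gordan(I, mm, lam, mu, I, mp)
    nrm = np.linalg.norm(T)
    if nrm == 0:
        raise ValueError(f"invalid tensor rank/component ({lam},{mu}) for spin {I}")
    return T / nrm


def special_operator(system: SpinSystem, kind: str, *args, basis: HilbertBasis | None = None,
                     **kwargs) -> SpinOperator:
    """Named special operators.

    kinds: ``unity``, ``null``, ``single_transition(r, s)`` (in ``basis``),
    ``projection(r)`` = |r⟩⟨r|, ``shift(label, "+"|"-")``,
    ``spherical_tensor(labels, rank, component)`` — a single label gives the
    embedded single-spin T_{λμ}; a pair gives the rank-1×rank-1 CG-coupled
    two-spin tensor. All tensors are Frobenius-normalized.
    """
    n = system.dimension
    if kind == "unity":
        return unity_operator(system)
    if kind == "null":
        return null_operator(system)
    if kind == "single_transition":
        r, s = args
        V = basis.kets_matrix if basis is not None else np.eye(n, dtype=complex)
        return SpinOperator(system, np.outer(V[:, r], V[:, s].conj()), label=f"|{r}⟩⟨{s}|")
    if kind == "projection":
        (r,) = args
        V = basis.kets_matrix if basis is not None else np.eye(n, dtype=complex)
        return SpinOperator(system, np.outer(V[:, r], V[:, r].conj()), label=f"|{r}⟩⟨{r}|")
    if kind == "shift":
        label, pm = args
        return op_I(system, [label], pm)
    if kind == "spherical_tensor":
        labels, lam, mu = args
        if abs(mu) > lam:
            raise ValueError(f"invalid component |μ|={abs(mu)} > λ={lam}")
        if not isinstance(labels, (list, tuple)):
            labels = [labels]
        if len(labels) == 1:
            idx = system.index(labels[0])
            T = _single_spin_tensor(system.quantum_numbers[idx], lam, mu)
            return SpinOperator(system, _embed(system, idx, T), label=f"T{lam}{mu}[{labels[0]}]")
        if len(labels) == 2:
            from .rotations import clebsch_gordan

            out = np.zeros((n, n), dtype=complex)
            for mu1 in (-1, 0, 1):
                mu2 = mu - mu1
                if abs(mu2) > 1:
                    continue
                cg = clebsch_gordan(1, mu1, 1, mu2, lam, mu)
                if cg == 0:
                    continue
                t1 = special_operator(system, "spherical_tensor", [labels[0]], 1, mu1)
                t2 = special_operator(system, "spherical_tensor", [labels[1]], 1, mu2)
                out += cg * (t1 @ t2).matrix
            nrm = np.linalg.norm(out)
            if nrm == 0:
                raise ValueError(f"vanishing coupled tensor ({lam},{mu})")
            return SpinOperator(system, out / nrm, label=f"T{lam}{mu}{tuple(labels)}")
        raise ValueError("spherical_tensor supports one or two spin labels")
    raise ValueError(f"unknown special operator kind {kind!r}")
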