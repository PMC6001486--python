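"""Liouville space: operator bases, superoperators, brackets, decomposition.

Operators are vectorized by column-major stacking of their Zeeman-ordered
matrices, so vec(AXB) = (Bᵀ ⊗ A)·vec(X): left multiplication by A is
(1 ⊗ A) and right multiplication by B is (Bᵀ ⊗ 1). The Liouville bracket
(A|B) = Tr(A†B) then equals vec(A)†·vec(B).
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import scipy.linalg

from .operators import (
    COHERENCE_TOL,
    SpinOperator,
    RotationSpec,
    _coherence_plane,
    _embed,
    op_I,
    rotation_operator,
    single_spin_matrices,
    special_operator,
    unity_operator,
)
from .spin_system import SpinSystem, singlet_triplet_basis, zeeman_basis

__all__ = [
    "vec",
    "unvec",
    "Superoperator",
    "OperatorBasis",
    "liouville_bracket",
    "commutation_superoperator",
    "double_commutation_superoperator",
    "rotation_superoperator",
    "coherence_filter_superoperator",
    "unity_superoperator",
    "null_superoperator",
    "superoperator_from_matrix",
    "superoperator_matrix_representation",
    "make_operator_basis",
    "express_operator",
]

SUPPRESS_TOL = 1e-10


def vec(M: np.ndarray) -> np.ndarray:
    """Column-major (Fortran) stacking of an operator matrix."""
    return np.asarray(M, dtype=complex).reshape(-1, order="F")


def unvec(v: np.ndarray, n: int) -> np.ndarray:
    return np.asarray(v, dtype=complex).reshape((n, n), order="F")


class Superoperator:
    """A linear map on operators, stored as its N_L×N_L action on vec(X)."""

    def __init__(self, system: SpinSystem, matrix, label: str | None = None):
        self.system = system
        nl = system.dimension**2
        self.matrix = np.asarray(matrix, dtype=complex)
        if self.matrix.shape != (nl, nl):
            raise ValueError(f"superoperator matrix must be {nl}x{nl}")
        self.label = label

    def __call__(self, op: SpinOperator) -> SpinOperator:
        if op.system != self.system:
            raise ValueError("operator belongs to a different spin system")
        n = self.system.dimension
        return SpinOperator(self.system, unvec(self.matrix @ vec(op.matrix), n))

    apply = __call__

    def __add__(self, other):
        if isinstance(other, Superoperator):
            return Superoperator(self.system, self.matrix + other.matrix)
        return NotImplemented

    def __sub__(self, other):
        if isinstance(other, Superoperator):
            return Superoperator(self.system, self.matrix - other.matrix)
        return NotImplemented

    def __neg__(self):
        return Superoperator(self.system, -self.matrix)

    def __mul__(self, other):
        if np.isscalar(other):
            return Superoperator(self.system, self.matrix * other)
        return NotImplemented

    __rmul__ = __mul__

    def __matmul__(self, other):
        if isinstance(other, Superoperator):
            return Superoperator(self.system, self.matrix @ other.matrix)
        if isinstance(other, SpinOperator):
            return self(other)
        return NotImplemented

    def expm(self, scale: complex = 1.0) -> "Superoperator":
        return Superoperator(self.system, scipy.linalg.expm(scale * self.matrix))

    def __repr__(self) -> str:
        tag = self.label or "Superoperator"
        return f"<{tag}^ on {self.system!r}>"


def liouville_bracket(A: SpinOperator, B: SpinOperator) -> complex:
    """(A|B) = Tr(A†B)."""
    A._check(B)
    return complex(np.vdot(A.matrix, B.matrix))


def _left_mult(system: SpinSystem, M: np.ndarray) -> np.ndarray:
    n = system.dimension
    return np.kron(np.eye(n), M)


def _right_mult(system: SpinSystem, M: np.ndarray) -> np.ndarray:
    n = system.dimension
    return np.kron(M.T, np.eye(n))


def commutation_superoperator(Q: SpinOperator) -> Superoperator:
    """Q̂ with Q̂(X) = [Q, X] = QX − XQ."""
    sys_ = Q.system
    mat = _left_mult(sys_, Q.matrix) - _right_mult(sys_, Q.matrix)
    return Superoperator(sys_, mat, label=f"[{Q.label or 'Q'},·]")


def double_commutation_superoperator(QA: SpinOperator, QB: SpinOperator) -> Superoperator:
    """(Q̂A Q̂B)(X) = [QA, [QB, X]] — the second operator's commutator acts first."""
    QA._check(QB)
    sa = commutation_superoperator(QA)
    sb = commutation_superoperator(QB)
    out = sa @ sb
    out.label = f"[{QA.label or 'QA'},[{QB.label or 'QB'},·]]"
    return out


def rotation_superoperator(system: SpinSystem, spec, targets=None) -> Superoperator:
    """X ↦ R X R† with R the matching rotation operator."""
    R = rotation_operator(system, spec, targets).matrix
    return Superoperator(system, np.kron(R.conj(), R), label="R^")


def unity_superoperator(system: SpinSystem) -> Superoperator:
    return Superoperator(system, np.eye(system.dimension**2), label="1^")


def null_superoperator(system: SpinSystem) -> Superoperator:
    nl = system.dimension**2
    return Superoperator(system, np.zeros((nl, nl)), label="0^")


def coherence_filter_superoperator(system: SpinSystem, orders, targets=None) -> Superoperator:
    """Idempotent projector keeping components with coherence order in ``orders``.

    Orders are counted with respect to the target spins (all spins if None).
    """
    if np.isscalar(orders):
        orders = [orders]
    P = _coherence_plane(system, targets)
    keep = np.zeros_like(P, dtype=bool)
    for p in orders:
        keep |= np.isclose(P, p)
    diag = vec(keep.astype(complex))
    return Superoperator(system, np.diag(diag), label=f"filter{tuple(orders)}")


def superoperator_from_matrix(system: SpinSystem, matrix,
                              operator_basis: "OperatorBasis | None" = None) -> Superoperator:
    """Superoperator with the given matrix representation in an operator basis."""
    M = np.asarray(matrix, dtype=complex)
    nl = system.dimension**2
    if M.shape != (nl, nl):
        raise ValueError(f"matrix must be {nl}x{nl}")
    if operator_basis is None:
        return Superoperator(system, M)
    W = operator_basis.vec_matrix()  # columns are vec(Q_j)
    return Superoperator(system, W @ M @ W.conj().T)


def superoperator_matrix_representation(S: Superoperator,
                                        operator_basis: "OperatorBasis | None" = None) -> np.ndarray:
    """Matrix with elements S_jk = (Q_j|Ŝ|Q_k) in the given operator basis."""
    if operator_basis is None:
        return S.matrix.copy()
    if operator_basis.system != S.system:
        raise ValueError("operator basis belongs to a different system")
    W = operator_basis.vec_matrix()
    return W.conj().T @ S.matrix @ W


def superoperator_element(S: Superoperator, Qj: SpinOperator, Qk: SpinOperator) -> complex:
    """Single matrix element (Q_j|Ŝ|Q_k), computable standalone."""
    return liouville_bracket(Qj, S(Qk))


class OperatorBasis:
    """An ordered, Liouville-orthonormal basis of N_L = N_H² operators."""

    def __init__(self, system: SpinSystem, operators: Sequence[SpinOperator],
                 name: str = "custom", coherence_orders=None, ranks=None,
                 labels: Sequence[str] | None = None, factors=None):
        nl = system.dimension**2
        if len(operators) != nl:
            raise ValueError(f"operator basis must contain N_L = {nl} elements")
        self.system = system
        self.operators = list(operators)
        self.name = name
        self.coherence_orders = list(coherence_orders) if coherence_orders is not None else None
        self.ranks = list(ranks) if ranks is not None else None
        self.labels = list(labels) if labels is not None else None
        #: per element: tuple of per-spin factor tags (product bases only)
        self.factors = list(factors) if factors is not None else None
        W = self.vec_matrix()
        gram = W.conj().T @ W
        if not np.allclose(gram, np.eye(nl), atol=1e-10):
            raise ValueError("operator basis is not Liouville-orthonormal to 1e-10")

    def vec_matrix(self) -> np.ndarray:
        return np.column_stack([vec(Q.matrix) for Q in self.operators])

    def __len__(self) -> int:
        return len(self.operators)

    def __getitem__(self, j: int) -> SpinOperator:
        return self.operators[j]

    def __repr__(self) -> str:
        return f"OperatorBasis({self.name!r}, N_L={len(self)})"


def _product_basis(system: SpinSystem, factor_sets, kindname: str) -> OperatorBasis:
    """Orthonormal product basis from per-spin factor lists [(tag, mat, order, rank)]."""
    ops, orders, ranks, labels, factors = [], [], [], [], []
    for combo in itertools.product(*factor_sets):
        mat = np.ones((1, 1), dtype=complex)
        for (_, m, _, _) in combo:
            mat = np.kron(mat, m)
        order = sum(c[2] for c in combo)
        rank = sum(c[3] for c in combo)
        tags = tuple(c[0] for c in combo)
        name = "".join(t for t in tags if t != "E") or "E"
        ops.append(SpinOperator(system, mat, label=name))
        orders.append(order)
        ranks.append(rank)
        labels.append(name)
        factors.append(tags)
    # stable sort: primary key depends on kind, secondary by product rank,
    # then by construction order
    if kindname == "cartesian_product":
        key = np.lexsort((np.arange(len(ops)), orders, ranks))
    else:
        key = np.lexsort((np.arange(len(ops)), ranks, orders))
    ops = [ops[i] for i in key]
    orders = [orders[i] for i in key]
    ranks = [ranks[i] for i in key]
    labels = [labels[i] for i in key]
    factors = [factors[i] for i in key]
    return OperatorBasis(system, ops, name=kindname, coherence_orders=orders,
                         ranks=ranks, labels=labels, factors=factors)


def make_operator_basis(system: SpinSystem, kind: str = "zeeman_ketbra") -> OperatorBasis:
    """Packaged operator bases.

    kinds: ``shift_and_z`` (spin-1/2 products of {1, I⁺, I⁻, √2·I_z}, sorted
    by ascending coherence order); ``cartesian_product`` (spin-1/2 products
    of {1, √2·I_x, √2·I_y, √2·I_z}, sorted by ascending product rank);
    ``spherical_tensor`` (products of single-spin irreducible tensors,
    sharp coherence order, any spins); ``zeeman_ketbra`` (|r⟩⟨s|, any spins);
    ``singlet_triplet`` (ket-bra basis over the singlet–triplet states of a
    spin-1/2 pair). All elements are normalized.
    """
    half = 1 / math.sqrt(2)
    if kind in ("shift_and_z", "cartesian_product"):
        if any(I != 0.5 for I in system.quantum_numbers):
            raise ValueError(f"operator basis kind {kind!r} requires an all-spin-1/2 system")
        factor_sets = []
        for j, lab in enumerate(system.labels):
            mats = single_spin_matrices(0.5)
            if kind == "shift_and_z":
                factors = [
                    ("E", mats["e"] * half, 0, 0),
                    (f"I{lab}+", mats["+"], +1, 1),
                    (f"I{lab}z", mats["z"] * math.sqrt(2), 0, 1),
                    (f"I{lab}-", mats["-"], -1, 1),
                ]
            else:
                factors = [
                    ("E", mats["e"] * half, 0, 0),
                    (f"I{lab}x", mats["x"] * math.sqrt(2), 0, 1),
                    (f"I{lab}y", mats["y"] * math.sqrt(2), 0, 1),
                    (f"I{lab}z", mats["z"] * math.sqrt(2), 0, 1),
                ]
            factor_sets.append(factors)
        return _product_basis(system, factor_sets, kind)
    if kind == "spherical_tensor":
        factor_sets = []
        for j, lab in enumerate(system.labels):
            I = system.quantum_numbers[j]
            factors = []
            for lam in range(0, int(round(2 * I)) + 1):
                for mu in range(lam, -lam - 1, -1):
                    if lam == 0:
                        mat = np.eye(int(round(2 * I + 1)), dtype=complex)
                        mat /= np.linalg.norm(mat)
                    else:
                        from .operators import _single_spin_tensor

                        mat = _single_spin_tensor(I, lam, mu)
                    factors.append((f"T{lam}{mu:+d}[{lab}]" if lam else "E", mat, mu, lam))
            factor_sets.append(factors)
        return _product_basis(system, factor_sets, kind)
    if kind == "zeeman_ketbra":
        basis = zeeman_basis(system)
        return _ketbra_basis(system, basis, "zeeman_ketbra")
    if kind == "singlet_triplet":
        basis = singlet_triplet_basis(system)
        return _ketbra_basis(system, basis, "singlet_triplet")
    raise ValueError(f"unknown operator basis kind {kind!r}")


def _ketbra_basis(system: SpinSystem, hilbert_basis, name: str) -> OperatorBasis:
    n = system.dimension
    V = hilbert_basis.kets_matrix
    P = _coherence_plane(system)
    ops, orders, labels = [], [], []
    for r in range(n):
        for s in range(n):
            mat = np.outer(V[:, r], V[:, s].conj())
            ops.append(SpinOperator(system, mat, label=f"|{r}⟩⟨{s}|"))
            # coherence order of a ketbra element of the packaged bases:
            # expectation of the order plane over its support
            supp = np.abs(mat) > 1e-14
            vals = np.unique(P[supp])
            orders.append(int(round(vals[0])) if len(vals) == 1 else None)
            labels.append(f"|{r}⟩⟨{s}|")
    idx = np.lexsort((np.arange(len(ops)),
                      [np.inf if o is None else o for o in orders]))
    ops = [ops[i] for i in idx]
    orders = [orders[i] for i in idx]
    labels = [labels[i] for i in idx]
    return OperatorBasis(system, ops, name=name, coherence_orders=orders, labels=labels)


def express_operator(A: SpinOperator, operator_basis: OperatorBasis | None = None):
    """Decompose A = Σ c_j Q_j over an orthonormal operator basis.

    Returns a list of (coefficient, basis operator) pairs; coefficients with
    |c| < 1e−10 are suppressed.
    """
    if operator_basis is None:
        operator_basis = make_operator_basis(A.system, "zeeman_ketbra")
    if operator_basis.system != A.system:
        raise ValueError("operator basis belongs to a different system")
    W = operator_basis.vec_matrix()
    coeffs = W.conj().T @ vec(A.matrix)
    return [
        (complex(c), operator_basis[j])
        for j, c in enumerate(coeffs)
        if abs(c) >= SUPPRESS_TOL
    ]
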