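"""Relaxation superoperators: phenomenological, mechanistic, secularized, thermalized.

All packaged relaxation generators are negative-semidefinite on the
traceless operator space and annihilate the unity operator (trace is
conserved) before thermalization.
"""

from __future__ import annotations

import numpy as np

from .liouville import (
    Superoperator,
    double_commutation_superoperator,
    make_operator_basis,
    vec,
    unvec,
)
from .operators import SpinOperator, op_I
from .spin_system import SpinSystem

__all__ = [
    "PhenomenologicalRates",
    "RandomFieldModel",
    "phenomenological_relaxation_superoperator",
    "random_field_relaxation_superoperator",
    "mechanistic_relaxation_superoperator",
    "secularize",
    "thermalize_superoperator",
]

SECULAR_TOL = 1e-6  # rad s⁻¹: |Δω| below this is treated as degenerate


class PhenomenologicalRates:
    """Per-spin (T1, T2) relaxation times in seconds.

    Construct from a mapping {label: (T1, T2)}, a uniform pair (T1, T2),
    or a single time constant T (T1 = T2 = T for every spin).
    """

    def __init__(self, system: SpinSystem, rates):
        self.system = system
        table = {}
        if np.isscalar(rates):
            table = {lab: (float(rates), float(rates)) for lab in system.labels}
        elif isinstance(rates, (tuple, list)) and len(rates) == 2 and np.isscalar(rates[0]):
            t1, t2 = map(float, rates)
            table = {lab: (t1, t2) for lab in system.labels}
        else:
            items = rates.items() if isinstance(rates, dict) else [(r[0], (r[1], r[2])) for r in rates]
            for lab, (t1, t2) in items:
                system.index(lab)  # validates the label
                table[lab] = (float(t1), float(t2))
        for lab, (t1, t2) in table.items():
            if t1 <= 0 or t2 <= 0:
                raise ValueError(f"relaxation times must be positive (spin {lab!r})")
        self.table = table

    def t1(self, label) -> float:
        return self.table[label][0]

    def t2(self, label) -> float:
        return self.table[label][1]


class RandomFieldModel:
    """Fluctuating z-field model: γ (rad s⁻¹ T⁻¹), B_z rms (T), τ_c (s)."""

    def __init__(self, gamma: float, Bz_rms: float, tau_c: float):
        if tau_c <= 0:
            raise ValueError("correlation time must be positive")
        self.gamma = float(gamma)
        self.Bz_rms = float(Bz_rms)
        self.tau_c = float(tau_c)

    @property
    def rate(self) -> float:
        """T2⁻¹ = γ²B_z²τ_c."""
        return self.gamma**2 * self.Bz_rms**2 * self.tau_c


def phenomenological_relaxation_superoperator(
    system: SpinSystem, rates
) -> Superoperator:
    """Diagonal relaxation generator in the Cartesian product operator basis.

    Each product operator decays at the sum over its non-identity
    single-spin factors: transverse (x, y) factors contribute 1/T2 of that
    spin, longitudinal (z) factors contribute 1/T1. The identity component
    does not decay, so the trace is conserved. Returned as a
    negative-semidefinite generator (−rate on the diagonal).
    """
    if any(I != 0.5 for I in system.quantum_numbers):
        raise ValueError("phenomenological relaxation is defined for spin-1/2 systems")
    if not isinstance(rates, PhenomenologicalRates):
        rates = PhenomenologicalRates(system, rates)
    missing = set(system.labels) - set(rates.table)
    if missing:
        raise ValueError(f"missing relaxation rates for spins {sorted(map(str, missing))}")
    basis = make_operator_basis(system, "cartesian_product")
    W = basis.vec_matrix()
    diag = np.zeros(len(basis))
    for j, tags in enumerate(basis.factors):
        rate = 0.0
        for lab, tag in zip(system.labels, tags):
            if tag == "E":
                continue
            if tag.endswith("z"):
                rate += 1.0 / rates.t1(lab)
            else:  # transverse x or y factor
                rate += 1.0 / rates.t2(lab)
        diag[j] = -rate
    mat = (W * diag) @ W.conj().T
    return Superoperator(system, mat, label="Gamma_phen")


def random_field_relaxation_superoperator(
    system: SpinSystem, model: RandomFieldModel, target
) -> Superoperator:
    """Γ̂ = −γ²B_z²τ_c [Î_z, [Î_z, ·]] for fluctuating z-fields on one spin.

    Transverse components of the target spin decay at T2⁻¹ = γ²B_z²τ_c;
    its longitudinal component does not relax.
    """
    iz = op_I(system, [target], "z")
    out = -model.rate * double_commutation_superoperator(iz, iz)
    out.label = "Gamma_rf"
    return out


def mechanistic_relaxation_superoperator(system: SpinSystem, terms) -> Superoperator:
    """Σ_k w_k · (−1)·[Q̂A_k, [Q̂B_k, ·]] with positive weights damping.

    ``terms`` is a list of (weight s⁻¹, QA, QB). The sign convention
    matches the random-field model: a single term (γ²B²τ_c, I_z, I_z)
    reproduces it exactly.
    """
    nl = system.dimension**2
    mat = np.zeros((nl, nl), dtype=complex)
    for weight, QA, QB in terms:
        if QA.system != system or QB.system != system:
            raise ValueError("relaxation term operators belong to a different system")
        mat -= weight * double_commutation_superoperator(QA, QB).matrix
    return Superoperator(system, mat, label="Gamma_mech")


def _h0_eigen(H0: SpinOperator):
    if not H0.is_hermitian(1e-10):
        raise ValueError("H0 must be Hermitian")
    w, V = np.linalg.eigh(H0.matrix)
    return w, V


def secularize(target, H0: SpinOperator, tol: float = SECULAR_TOL):
    """Project onto the kernel of frequency differences under Ĥ0.

    In the eigenbasis of H0 each ket-bra element |r⟩⟨s| is an eigenoperator
    of the commutation superoperator Ĥ0 with frequency ω_rs = E_r − E_s.
    Secularizing an operator keeps elements with |ω_rs| < tol; secularizing
    a superoperator keeps blocks connecting eigenoperators of equal
    frequency (|ω_rs − ω_uv| < tol). Both maps are idempotent, and a
    secularized superoperator commutes with Ĥ0.
    """
    w, V = _h0_eigen(H0)
    n = len(w)
    omega = w[:, None] - w[None, :]  # ω_rs
    if isinstance(target, SpinOperator):
        tilde = V.conj().T @ target.matrix @ V
        tilde = np.where(np.abs(omega) < tol, tilde, 0.0)
        return SpinOperator(target.system, V @ tilde @ V.conj().T, label=target.label)
    if isinstance(target, Superoperator):
        omega_vec = vec(omega).real
        T = np.kron(V.T, V.conj().T)  # vec(V† X V) = T vec(X)
        Tinv = np.kron(V.conj(), V)
        tilde = T @ target.matrix @ Tinv
        mask = np.abs(omega_vec[:, None] - omega_vec[None, :]) < tol
        tilde = np.where(mask, tilde, 0.0)
        return Superoperator(target.system, Tinv @ tilde @ T, label=target.label)
    raise TypeError("secularize expects a SpinOperator or Superoperator")


def thermalize_superoperator(Gamma: Superoperator, rho_eq) -> Superoperator:
    """Thermalized generator Γ̂′ = Γ̂ ∘ (Id − |ρ_eq)(E|) with (E|X) = Tr X.

    For any unit-trace ρ this gives Γ̂′ρ = Γ̂(ρ − ρ_eq), so Γ̂′ρ_eq = 0
    exactly while the master equation stays homogeneous.
    """
    if abs(complex(np.trace(rho_eq.matrix)) - 1) > 1e-10:
        raise ValueError("rho_eq must have unit trace")
    system = Gamma.system
    n = system.dimension
    e = vec(np.eye(n))  # (E| functional: e @ vec(X) = Tr X
    proj = np.eye(n * n) - np.outer(vec(rho_eq.matrix), e)
    out = Superoperator(system, Gamma.matrix @ proj)
    out.label = "Gamma_thermal"
    return out
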