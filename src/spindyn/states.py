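"""Rigorous density-operator constructions and polarization-level readout.

Rigorous constructors return unit-trace, Hermitian (and, for physical
parameter ranges, positive-semidefinite) density operators. Any spin
operator remains legal as a "loose" initial state elsewhere in the
package; rigour is only asserted here.
"""

from __future__ import annotations

import numpy as np

from .constants import HBAR, K_B
from .operators import SpinOperator, op_I, operator_amplitude, scalar_coupling
from .spin_system import SpinSystem

__all__ = [
    "DensityOperator",
    "thermal_equilibrium_density_operator",
    "polarized_density_operator",
    "singlet_polarized_density_operator",
    "polarization_level_operator",
    "singlet_polarization_level_operator",
    "singlet_order_of_polarized_pair",
]


class DensityOperator(SpinOperator):
    """A spin density operator; ``rigorous`` asserts unit trace and Hermiticity."""

    def __init__(self, system: SpinSystem, matrix, rigorous: bool = False, label=None):
        super().__init__(system, matrix, label=label)
        self.rigorous = rigorous
        if rigorous:
            if abs(self.trace() - 1) > 1e-12:
                raise ValueError("rigorous density operator must have unit trace")
            if not self.is_hermitian(1e-12):
                raise ValueError("rigorous density operator must be Hermitian")


def _axis_vector(axis) -> np.ndarray:
    from .operators import RotationSpec

    return RotationSpec._resolve_axis(axis if axis is not None else "z")


def thermal_equilibrium_density_operator(
    H_lab: SpinOperator, temperature: float, high_temperature: bool = True
) -> DensityOperator:
    """Thermal equilibrium state for a laboratory-frame Hamiltonian (rad s⁻¹).

    Exact mode: exp(−ħH/k_BT)/Tr exp(−ħH/k_BT). High-temperature mode
    (the default): N_H⁻¹(1 − ħH/k_BT), valid to second order in ħ‖H‖/k_BT.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    beta = HBAR / (K_B * temperature)
    n = H_lab.system.dimension
    if high_temperature:
        rho = (np.eye(n) - beta * H_lab.matrix) / n
    else:
        w, V = np.linalg.eigh(H_lab.matrix)
        w = w - w.min()  # overflow guard; shifts cancel in the normalization
        pops = np.exp(-beta * w)
        rho = (V * (pops / pops.sum())) @ V.conj().T
    return DensityOperator(H_lab.system, rho, rigorous=True, label="rho_eq")


def _normalize_polarization_spec(system: SpinSystem, spec):
    """Expand the polarization spec into [(label, p, axis_vector)] entries."""
    if np.isscalar(spec):  # uniform p along z for every spin
        return [(lab, float(spec), _axis_vector("z")) for lab in system.labels]
    out = []
    for entry in spec:
        if len(entry) == 2:
            lab, p = entry
            axis = "z"
        else:
            lab, p, axis = entry
        out.append((lab, float(p), _axis_vector(axis)))
    return out


def polarized_density_operator(system: SpinSystem, spec) -> DensityOperator:
    """Product state ρ = N_H⁻¹ ∏_j (1 + 2 p_j I_j·n_j) of spin-1/2 species.

    ``spec`` is either a single p (uniform, along z) or a list of
    (label, p[, axis]) entries; axis may be a Cartesian name, a (θ, φ)
    polar pair, or a 3-vector. Spins not listed contribute a unit factor.
    """
    entries = _normalize_polarization_spec(system, spec)
    n = system.dimension
    rho = np.eye(n, dtype=complex)
    for lab, p, axis in entries:
        if abs(p) > 1:
            raise ValueError(f"|p| must not exceed 1 (spin {lab!r})")
        idx = system.index(lab)
        if system.quantum_numbers[idx] != 0.5:
            raise ValueError("polarized_density_operator applies to spins-1/2 only")
        In = (
            axis[0] * op_I(system, [lab], "x")
            + axis[1] * op_I(system, [lab], "y")
            + axis[2] * op_I(system, [lab], "z")
        )
        rho = rho @ (np.eye(n) + 2 * p * In.matrix)
    return DensityOperator(system, rho / n, rigorous=True, label="rho_pol")


def singlet_polarized_density_operator(system: SpinSystem, pairs) -> DensityOperator:
    """ρ = N_H⁻¹ ∏ (1 − 4 p^S_jk I_j·I_k) over disjoint spin-1/2 pairs.

    ``pairs`` is a list of ((label_j, label_k), p^S) items, or a single such
    item for the common one-pair case.
    """
    if pairs and not isinstance(pairs[0], (tuple, list)):
        raise ValueError("pairs must be ((label_j, label_k), pS) items")
    if len(pairs) == 2 and np.isscalar(pairs[1]):
        pairs = [pairs]
    seen: set = set()
    n = system.dimension
    rho = np.eye(n, dtype=complex)
    for (labj, labk), pS in pairs:
        if labj == labk:
            raise ValueError("a singlet pair requires two distinct spins")
        for lab in (labj, labk):
            if lab in seen:
                raise ValueError(f"spin {lab!r} appears in more than one pair")
            seen.add(lab)
            if system.quantum_numbers[system.index(lab)] != 0.5:
                raise ValueError("singlet polarization requires spin-1/2 pairs")
        if abs(pS) > 1:
            raise ValueError("|p^S| must not exceed 1")
        rho = rho @ (np.eye(n) - 4 * pS * scalar_coupling(system, labj, labk).matrix)
    return DensityOperator(system, rho / n, rigorous=True, label="rho_singlet")


def polarization_level_operator(system: SpinSystem, targets=None, axis="z") -> SpinOperator:
    """PLO = 3 N_H⁻¹ Σ_j (I_j + 1)⁻¹ I_j·n.

    The operator amplitude (ρ → PLO) of a rigorously polarized state
    recovers the polarization level p of the target spins along n.
    """
    nvec = _axis_vector(axis)
    n = system.dimension
    out = np.zeros((n, n), dtype=complex)
    for idx in system.indices(targets):
        lab = system.labels[idx]
        I = system.quantum_numbers[idx]
        In = (
            nvec[0] * op_I(system, [lab], "x")
            + nvec[1] * op_I(system, [lab], "y")
            + nvec[2] * op_I(system, [lab], "z")
        )
        out += In.matrix / (I + 1)
    return SpinOperator(system, 3 * out / n, label="PLO")


def singlet_polarization_level_operator(system: SpinSystem, pair) -> SpinOperator:
    """SPLO = −4 N_H⁻¹ I_j·I_k for a spin-1/2 pair."""
    labj, labk = pair
    for lab in (labj, labk):
        if system.quantum_numbers[system.index(lab)] != 0.5:
            raise ValueError("singlet polarization level requires a spin-1/2 pair")
    n = system.dimension
    return SpinOperator(
        system, -4 * scalar_coupling(system, labj, labk).matrix / n, label="SPLO"
    )


def singlet_order_of_polarized_pair(p: float) -> float:
    """Singlet order carried intrinsically by a z-polarized spin-1/2 pair.

    Highly polarized pairs deplete the singlet state relative to the
    low-energy triplet, so the value is negative for any p ≠ 0 (−p²/3).
    """
    from .spin_system import make_spin_system

    system = make_spin_system(2)
    rho = polarized_density_operator(system, p)
    splo = singlet_polarization_level_operator(system, (1, 2))
    return float(operator_amplitude(rho, splo).real)
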