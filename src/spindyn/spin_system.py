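"""Spin-system definitions, nuclide constants, Hilbert bases, kets and bras.

A :class:`SpinSystem` is an ordered list of spins, each with a label, a
spin quantum number I (half-integer), and optionally an isotope assignment.
The order is significant: it fixes the tensor-product order of the Hilbert
space. The reference basis is the Zeeman product basis, ordered with the
first listed spin most significant and, within each spin, m descending
from +I to −I (so a spin-1/2 pair lists |αα⟩, |αβ⟩, |βα⟩, |ββ⟩).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import ANGSTROM, HBAR, MU0_OVER_4PI

__all__ = [
    "Nuclide",
    "SpinSystem",
    "HilbertBasis",
    "Ket",
    "Bra",
    "nuclide",
    "nuclide_table",
    "make_spin_system",
    "basis_dimension",
    "zeeman_basis",
    "singlet_triplet_basis",
    "larmor_frequency",
    "direct_dipolar_coupling",
]


def _is_half_integer(x: float) -> bool:
    return abs(2 * x - round(2 * x)) < 1e-12


@dataclass(frozen=True)
class Nuclide:
    """Constants of one magnetic nuclide.

    Attributes
    ----------
    isotope : str
        Label such as ``"1H"`` or ``"23Na"``.
    spin : float
        Spin quantum number (half-integer, > 0).
    gamma : float
        Gyromagnetic ratio, signed, in rad s⁻¹ T⁻¹.
    abundance : float
        Natural abundance in percent.
    """

    isotope: str
    spin: float
    gamma: float
    abundance: float

    def __post_init__(self) -> None:
        if not _is_half_integer(self.spin) or self.spin <= 0:
            raise ValueError(f"spin must be a positive half-integer, got {self.spin}")
        if self.gamma == 0:
            raise ValueError("gamma must be nonzero")
        if not 0 <= self.abundance <= 100:
            raise ValueError("abundance must lie in [0, 100] percent")


@lru_cache(maxsize=1)
def nuclide_table() -> pd.DataFrame:
    """The packaged nuclide constants table (isotope, spin, gamma, abundance)."""
    with resources.files("spindyn.data").joinpath("nuclides.csv").open() as fh:
        return pd.read_csv(fh, comment="#").set_index("isotope")


def nuclide(isotope: str) -> Nuclide:
    """Look up one nuclide by its isotope label."""
    table = nuclide_table()
    if isotope not in table.index:
        raise KeyError(f"unknown isotope {isotope!r}")
    row = table.loc[isotope]
    return Nuclide(isotope, float(row["spin"]), float(row["gamma"]), float(row["abundance"]))


@dataclass(frozen=True)
class SpinSystem:
    """An ordered collection of spins.

    ``labels[j]`` may be an integer or text; ``quantum_numbers[j]`` is the
    spin quantum number I_j. ``isotopes[j]`` is an optional Nuclide.
    """

    labels: tuple
    quantum_numbers: tuple
    isotopes: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("spin labels must be unique")
        for I in self.quantum_numbers:
            if not _is_half_integer(I) or I < 0.5:
                raise ValueError(f"quantum number must be half-integer ≥ 1/2, got {I}")
        if self.isotopes is None:
            object.__setattr__(self, "isotopes", (None,) * len(self.labels))

    @property
    def n_spins(self) -> int:
        return len(self.labels)

    @property
    def dims(self) -> tuple:
        """Per-spin multiplicities 2I_j + 1."""
        return tuple(int(round(2 * I + 1)) for I in self.quantum_numbers)

    @property
    def dimension(self) -> int:
        """Hilbert-space dimension N_H = ∏(2I_j + 1)."""
        return int(np.prod(self.dims))

    def index(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown spin label {label!r}") from None

    def indices(self, labels=None) -> list:
        """Positions of the given labels (all spins when labels is None)."""
        if labels is None:
            return list(range(self.n_spins))
        if not isinstance(labels, (list, tuple, set)):
            labels = [labels]
        return [self.index(lab) for lab in labels]

    def m_values(self) -> np.ndarray:
        """(N_H, N) array of magnetic quantum numbers of the Zeeman product states.

        Row r gives the m_j of every spin in product state r, in the reference
        ordering (first spin most significant, m descending within each spin).
        """
        per_spin = [np.arange(I, -I - 0.5, -1.0) for I in self.quantum_numbers]
        grids = np.meshgrid(*per_spin, indexing="ij")
        return np.column_stack([g.ravel() for g in grids])

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{lab}:I={I}" for lab, I in zip(self.labels, self.quantum_numbers)
        )
        return f"SpinSystem({parts})"


def make_spin_system(spec, isotopes: Sequence[str] | None = None) -> SpinSystem:
    """Build a spin system.

    Parameters
    ----------
    spec : int or iterable
        An integer n builds n spins-1/2 labelled 1..n. Otherwise an iterable
        of (label, quantum_number) pairs, of bare quantum numbers (labelled
        1..n), or of isotope strings (quantum numbers from the nuclide table).
    isotopes : sequence of str, optional
        Isotope labels to attach, parallel to the spins.
    """
    if isinstance(spec, (int, np.integer)):
        if spec < 1:
            raise ValueError("integer shortcut requires n ≥ 1")
        labels = tuple(range(1, int(spec) + 1))
        qns = (0.5,) * int(spec)
    else:
        labels_l, qns_l = [], []
        iso_from_spec: list = []
        for j, item in enumerate(spec):
            if isinstance(item, str):
                nuc = nuclide(item)
                labels_l.append(j + 1)
                qns_l.append(nuc.spin)
                iso_from_spec.append(nuc)
            elif isinstance(item, (tuple, list)) and len(item) == 2:
                labels_l.append(item[0])
                qns_l.append(float(item[1]))
                iso_from_spec.append(None)
            else:
                labels_l.append(j + 1)
                qns_l.append(float(item))
                iso_from_spec.append(None)
        labels, qns = tuple(labels_l), tuple(qns_l)
        if isotopes is None and any(x is not None for x in iso_from_spec):
            return SpinSystem(labels, qns, tuple(iso_from_spec))
    nucs = None
    if isotopes is not None:
        nucs = tuple(nuclide(iso) if iso is not None else None for iso in isotopes)
    return SpinSystem(labels, qns, nucs)


def basis_dimension(system: SpinSystem) -> int:
    """Number of states in the Hilbert basis, N_H = ∏(2I_j + 1)."""
    return system.dimension


class Ket:
    """A Hilbert-space ket: complex coefficients over the reference Zeeman states."""

    dual = False

    def __init__(self, system: SpinSystem, coefficients):
        self.system = system
        self.coefficients = np.asarray(coefficients, dtype=complex)
        if self.coefficients.shape != (system.dimension,):
            raise ValueError("coefficient vector has wrong length")

    def bra(self) -> "Bra":
        return Bra(self.system, self.coefficients.conj())

    @property
    def H(self) -> "Bra":
        return self.bra()

    def __repr__(self) -> str:
        return f"Ket({np.array2string(self.coefficients, precision=4)})"


class Bra(Ket):
    """The dual of a ket: stored as the conjugate coefficient vector."""

    dual = True

    def ket(self) -> Ket:
        return Ket(self.system, self.coefficients.conj())

    def __mul__(self, other):
        if isinstance(other, Ket) and not other.dual:
            return complex(self.coefficients @ other.coefficients)
        return NotImplemented

    def __repr__(self) -> str:
        return f"Bra({np.array2string(self.coefficients, precision=4)})"


class HilbertBasis:
    """An orthonormal basis of the Hilbert space.

    ``kets_matrix`` holds the basis kets as columns, expressed over the
    reference Zeeman states. Orthonormality (Gram matrix = identity to
    1e−12) is enforced at construction.
    """

    def __init__(self, system: SpinSystem, kets_matrix, name: str = "custom",
                 state_labels: Sequence[str] | None = None):
        self.system = system
        V = np.asarray(kets_matrix, dtype=complex)
        n = system.dimension
        if V.shape != (n, n):
            raise ValueError(f"basis must contain {n} kets of length {n}")
        gram = V.conj().T @ V
        if not np.allclose(gram, np.eye(n), atol=1e-12):
            raise ValueError("basis kets are not orthonormal to 1e-12")
        self.kets_matrix = V
        self.name = name
        self.state_labels = list(state_labels) if state_labels else None

    def __len__(self) -> int:
        return self.kets_matrix.shape[1]

    def ket(self, j: int) -> Ket:
        return Ket(self.system, self.kets_matrix[:, j])

    def bra(self, j: int) -> Bra:
        return self.ket(j).bra()

    def kets(self) -> list:
        return [self.ket(j) for j in range(len(self))]

    def __repr__(self) -> str:
        return f"HilbertBasis({self.name!r}, N_H={len(self)})"


_SPIN_HALF_SYMBOL = {0.5: "α", -0.5: "β"}


def _state_label(ms: Iterable[float]) -> str:
    out = []
    for m in ms:
        out.append(_SPIN_HALF_SYMBOL.get(m, f"{m:+g}"))
    return "|" + ",".join(out).replace("α,", "α").replace("β,", "β") + "⟩"


def zeeman_basis(system: SpinSystem) -> HilbertBasis:
    """The reference Zeeman product basis |m₁ m₂ …⟩ in canonical ordering."""
    n = system.dimension
    labels = [_state_label(row) for row in system.m_values()]
    return HilbertBasis(system, np.eye(n), name="zeeman", state_labels=labels)


def singlet_triplet_basis(system: SpinSystem) -> HilbertBasis:
    """Singlet–triplet basis {|S₀⟩, |T₊₁⟩, |T₀⟩, |T₋₁⟩} of a spin-1/2 pair."""
    if system.n_spins != 2 or system.quantum_numbers != (0.5, 0.5):
        raise ValueError("singlet-triplet basis requires exactly two spins-1/2")
    s = 1 / math.sqrt(2)
    # Zeeman order: |αα⟩, |αβ⟩, |βα⟩, |ββ⟩
    V = np.array(
        [
            [0, 1, 0, 0],
            [s, 0, s, 0],
            [-s, 0, s, 0],
            [0, 0, 0, 1],
        ],
        dtype=complex,
    )
    return HilbertBasis(system, V, name="singlet_triplet",
                        state_labels=["|S0⟩", "|T+1⟩", "|T0⟩", "|T-1⟩"])


def larmor_frequency(isotope: str, B0: float) -> float:
    """Larmor frequency ω₀ = −γ·B0 in rad s⁻¹ (signed; the sign is physical)."""
    return -nuclide(isotope).gamma * B0


def direct_dipolar_coupling(coord1, coord2, isotope1: str, isotope2: str) -> float:
    """Direct (through-space) dipolar coupling constant b₁₂ in rad s⁻¹.

    b = −(μ₀/4π)·γ₁γ₂ħ / r³ with coordinates in Å. Negative for a pair of
    like spins with positive γ.
    """
    r = np.linalg.norm(np.asarray(coord1, float) - np.asarray(coord2, float)) * ANGSTROM
    if r == 0:
        raise ValueError("coincident nuclei: zero distance")
    g1 = nuclide(isotope1).gamma
    g2 = nuclide(isotope2).gamma
    return -MU0_OVER_4PI * g1 * g2 * HBAR / r**3
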