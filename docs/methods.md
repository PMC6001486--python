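# Methods

## Model

`spindyn` simulates the dynamics of small ensembles of coupled nuclear
spins exactly, at the level of the density operator. A spin system of N
spins with quantum numbers I_j lives in a Hilbert space of dimension
N_H = ∏(2I_j + 1); the state of the ensemble is a density operator ρ and
its equation of motion is the Liouville–von Neumann equation

    dρ/dt = L̂(t) ρ,      L̂(t) = −i Ĥ_coh(t) + Γ̂(t),

where Ĥ_coh is the commutation superoperator of the coherent Hamiltonian
(identical for all ensemble members) and Γ̂ is a relaxation superoperator
summarizing incoherent, fluctuating interactions. Hamiltonians,
Liouvillians and relaxation superoperators are handled uniformly as
*generators*; purely Hamiltonian stretches are propagated in Hilbert
space (U = exp(−iHT), ρ → UρU†), anything involving a superoperator in
Liouville space (vec(ρ) → exp(LT) vec(ρ)).

All interaction strengths are angular frequencies (rad s⁻¹, ħ = 1).
Physical constants (CODATA ħ, k_B, μ₀/4π) enter only in the thermal
density operator and the dipolar-coupling helper.

## Conventions

- **Zeeman ordering.** Product states are ordered with the first listed
  spin most significant; within each spin m descends from +I to −I, so a
  spin-1/2 pair lists |αα⟩, |αβ⟩, |βα⟩, |ββ⟩. Every operator stores its
  matrix in this reference ordering; representations in other bases are
  V†MV with V the basis-ket matrix, so operators are basis-independent
  objects.
- **Single-spin matrices** are built exactly from the ladder elements
  (I⁺)_{m′,m} = √(I(I+1) − m(m+1)) δ_{m′,m+1}.
- **Vectorization.** Operators are column-stacked (Fortran order), so
  vec(AXB) = (Bᵀ ⊗ A) vec(X); the Liouville bracket (A|B) = Tr(A†B)
  equals vec(A)†vec(B). Commutation superoperators are (1 ⊗ Q) − (Qᵀ ⊗ 1)
  and rotation superoperators X ↦ RXR† are (R̄ ⊗ R).
- **Rotations.** R = exp(−iβ I·n); phase/polar axis specifications
  resolve to a unit vector n. A 2π rotation is −1 on half-integer spins.
  Euler angles are zyz, active; Wigner matrices follow
  D^J_{mm′}(α,β,γ) = e^{−imα} d^J_{mm′}(β) e^{−im′γ} with indices
  m = +J … −J, and d^J by exponentiating −iβ J_y. This convention is
  pinned by the cross-check that R̂_z(α)R̂_y(β)R̂_z(γ) applied to an
  irreducible tensor T_{λμ} reproduces Σ_{μ′} D^λ_{μ′μ} T_{λμ′}.
- **Clebsch–Gordan** coefficients use the Racah closed form with
  Condon–Shortley phases (real); sympy's implementation serves as an
  independent oracle in the tests only.
- **Coherence order** of an operator component is the eigenvalue of the
  commutation action of Σ_{j∈targets} I_jz; components are classified by
  the m-difference plane m_r − m_s of the Zeeman ket-bra grid.
  Components below 1e−10 (Frobenius) are discarded; the filtration
  superoperator is the corresponding 0/1 diagonal projector in vec space.

## Operator bases

Five packaged bases span Liouville space (N_L = N_H² elements, all
normalized, pairwise orthonormality enforced to 1e−10 at construction):
ket-bra bases over the Zeeman or singlet–triplet states; for all-spin-1/2
systems, product bases over {1, I⁺, I⁻, √2 I_z} (sorted by ascending
coherence order) and {1, √2 I_x, √2 I_y, √2 I_z} (sorted by ascending
product rank); and for arbitrary spins a basis of normalized products of
single-spin irreducible tensors T_{λμ}, each element carrying a sharp
coherence order Σμ_j. The coupled two-spin tensors available through
`special_operator` are built by CG-coupling two rank-1 tensors and
renormalizing; the *basis* uses uncoupled products because orthonormality
and sharp coherence order are the properties the rest of the machinery
relies on. Secondary sort keys (product rank, then construction order)
were an open choice and are fixed as stated.

## Density operators

Thermal equilibrium: ρ_eq = exp(−ħH/k_BT)/Tr{·} with H in rad s⁻¹; the
high-temperature form N_H⁻¹(1 − ħH/k_BT) is the default and agrees with
the exact form to second order in ħ‖H‖/k_BT (≈1e−9 relative for protons
at 11.4 T, 300 K). Polarized spin-1/2 products
ρ = N_H⁻¹ ∏(1 + 2p_j I_j·n_j) and singlet-polarized pairs
ρ = N_H⁻¹ ∏(1 − 4p^S I_j·I_k) are restricted to spins-1/2, where the
2p I·n factor form is exact; general spins get thermal states instead.
Readout inverts construction: the operator amplitude of ρ onto the
polarization-level operator 3N_H⁻¹Σ(I_j+1)⁻¹I_j·n returns p exactly, and
onto −4N_H⁻¹I_j·I_k returns p^S. A z-polarized pair carries intrinsic
singlet order −p²/3 (the singlet state is depleted relative to the
lowest triplet).

## Relaxation

- *Phenomenological*: diagonal in the Cartesian product basis with the
  uncorrelated-rate rule — each transverse factor of a product operator
  adds 1/T2 of its spin, each longitudinal factor 1/T1; the identity
  component does not decay (trace conservation). The generator is
  negative-semidefinite by construction.
- *Mechanistic*: weighted sums of double commutators
  −Σ w_k [Q̂A_k,[Q̂B_k, ·]] (the second operator's commutator acts
  first); the fluctuating-z-field model Γ̂ = −γ²B_z²τ_c [Î_z,[Î_z,·]]
  is the one-term special case, giving T2⁻¹ = γ²B_z²τ_c and no
  longitudinal relaxation.
- *Secularization* projects onto the kernel of frequency differences
  under a dominant Hamiltonian H0: in the H0 eigenbasis every ket-bra is
  an eigenoperator of Ĥ0 with frequency E_r − E_s, and only components
  (blocks, for superoperators) with frequency mismatch below 1e−6 rad s⁻¹
  survive. The map is idempotent and the result commutes with Ĥ0. The
  frequency-kernel construction is this package's concrete definition of
  the truncation.
- *Thermalization* replaces Γ̂ by Γ̂′ = Γ̂ ∘ (Id − |ρ_eq)(E|) with
  (E|X) = Tr X, so Γ̂′ρ = Γ̂(ρ − ρ_eq) on unit-trace states: ρ_eq is an
  exact fixed point while the master equation stays homogeneous. The
  closed-form inversion-recovery law M_z(t)/M_eq = 1 − 2e^{−t/T1} is
  reproduced to 1e−8 and serves as the regression anchor.

## Events and timing

Event sequences are chronological lists of instantaneous events (a
superoperator applied between time points; trajectories are
right-continuous there) and finite events (generator, duration). Start
times follow recursively from one anchor — the initial or the final time
point of the sequence; anchoring at the end gives negative start times.
Time laws may reference the global time t (`GlobalFunction`,
`PeriodicFunction`) or the local time τ = t − (t₀ + x·T) of their event
(`LocalShape`, x ∈ [0,1] placing the origin); a global-law modulation is
phase-coherent across intervening delays, a local shape restarts its
waveform with each event — both behaviours are asserted in the tests by
sampling H(t) inside the events.

Rectangular pulses resolve flip = ω_nut·T among flip angle, duration and
nutation frequency; over-specified, inconsistent combinations raise by
default (a lenient flag downgrades to a warning, duration winning). The
amplitude factor scales rf amplitude only, never duration. Shaped pulses
use H(τ) = a(τ)[I_x cos Φ(τ) + I_y sin Φ(τ)] with accumulated phase
Φ(τ) = phase(τ) + ∫₀^τ freq(τ′)dτ′, evaluated from a dense interpolant
of the integrated frequency (solve_ivp at rtol 1e−12). Folding frequency
modulation into the phase keeps the event self-contained in the rotating
frame; the alternative time-dependent-offset picture differs only by a
frame transformation that leaves I_z trajectories unchanged, which is
how the adiabatic-inversion test is formulated.

## Propagation

Per finite event, local and background generators are combined (any
superoperator term promotes the sum to Liouville space with Hamiltonians
entering as −iĤ). Constant Hamiltonians exponentiate by Hermitian
eigendecomposition; constant Liouvillians by scipy's scaling-and-squaring
expm; time-dependent generators integrate dU/dt = −iH(t)U or
d vec(ρ)/dt = L(t) vec(ρ) with DOP853 at rtol 1e−8 / atol 1e−10
(halving the tolerances moves reported amplitudes by < 1e−6 in the
tests). Periodic generators may be propagated stroboscopically: the
one-period propagator and a dense within-period solution are computed
once and composed as P(s)·Fᵐ, matching brute force to 1e−8.

## Signal synthesis

`signal1d` prepares the initial state (default I_z of all spins through
an ideal (π/2)_x rotation, anchored to end at t_min), then samples
s(t_n) = (Q_obs|ρ(t_n)) at t_n = t_min + n·dt with the default
quadrature observable Q_obs = −(i/2)ΣI_j⁻. Method selection: constant
acquisition generators diagonalize the Liouvillian, yielding a table of
Lorentzian modes (a_k, μ_k = iω_k − λ_k) that reconstructs the samples
to 1e−8; common-period generators and `Repeat`ed event blocks use the
stroboscopic path; everything else samples a dense trajectory. Line
broadening multiplies the FID by exp(−λ(t−t_min)/2), λ being the
Lorentzian full width at half height in rad s⁻¹; "automatic" picks
λ = 2·ln(100)/(t_last − t_min) so the envelope decays to 0.01 at the
last point, t_last = t_min + (npoints−1)·dt. The discrete FT halves the
first point and reports a centered Hz axis on which a mode e^{+iωt}
appears at +ω/2π; the −(i/2)ΣI⁻ observable sign was fixed jointly with
this FT sign so positive offsets land at positive frequencies — the
choice affects overall spectral phase only. Peak/mode counting groups
mode frequencies within 1e−6 rad s⁻¹ and ignores amplitudes below
1e−8 of the maximum.

Ensemble averages are weighted means of repeated calculations over a
sampling scheme (values or value–weight pairs); signals average sample
by sample and drop their per-member mode tables. The parallel flag is
accepted for interface compatibility and runs serially — the contract is
that parallelism could never change the result beyond float summation
order. Orientational sampling offers seeded Haar-random Euler triplets
(uniform α, γ; uniform cos β) and a deterministic low-discrepancy
ZCW-type golden-spiral scheme; both reproduce the isotropic moments
⟨cos²β⟩ = 1/3 and ⟨P₂(cosβ)⟩ = 0.

## Problem sizes and numerical choices

The package targets the regime the exact approach is meant for: up to
about five coupled spins-1/2 (N_H = 32, N_L = 1024) with dense numpy
matrices throughout; sparse storage is an optimization deliberately left
out because dense linear algebra at these sizes is both faster and
simpler. Key tolerances: operator equality 1e−12 (absolute, element-
wise), coherence/expansion suppression 1e−10, basis orthonormality
1e−10–1e−12, secular degeneracy 1e−6 rad s⁻¹, ODE rtol/atol
1e−8/1e−10. The test suite's worked examples (AB quartet at 200/300 Hz
with J = 50 Hz, 15 Hz INEPT, 20 Hz three-spin TOCSY chain, quadrupolar
spin-5/2 ensemble of 200 members, 0.2 s chirp with ±500 Hz tanh sweep
under a 100 Hz Gaussian envelope) are desk-scale and run in seconds;
the chirp parameters are this package's own adiabatic choice (the
adiabaticity factor ω₁²/|dω/dt| ≈ 6 at resonance guarantees > 0.9
inversion, which the test asserts).

## Limitations

No chemical exchange, no multidimensional spectroscopy, no symbolic
(unevaluated) operator algebra, no operator-basis-restriction
approximations for large systems, no spectrometer-format import. The
phenomenological relaxation model is uncorrelated by construction;
cross-correlated or mechanistically detailed models must be assembled
from double-commutator terms by the user. The quadrupolar interaction
helper in the CLI implements only the first-order secular form
(2πw_Q/6)(3I_z² − I(I+1)).
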