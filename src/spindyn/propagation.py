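"""Event-based numerical propagation of the density operator.

For each finite event, the local generator is combined with the
background generator. Propagation space is auto-selected: Hilbert space
(a unitary U) when every term is a Hamiltonian, Liouville space
otherwise. Time-independent generators use exact matrix exponentials
(Hermitian eigendecomposition for H, scaling-and-squaring for L);
time-dependent ones use adaptive high-order Runge–Kutta integration of
dU/dt = −iH(t)U or d vec(ρ)/dt = L(t) vec(ρ) in global time. Periodic
generators may be handled stroboscopically: within-period propagators
are computed once and composed with powers of the one-period propagator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.integrate import solve_ivp

from .events import (
    EventSequence,
    Finite,
    Generator,
    Instantaneous,
    combine_generators,
    resolve_timing,
)
from .liouville import Superoperator, unvec, vec
from .operators import SpinOperator
from .states import DensityOperator

__all__ = [
    "PropagationOptions",
    "PropagationResult",
    "DensityTrajectory",
    "propagate",
    "propagator_for_event",
    "propagate_periodic",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass
class PropagationOptions:
    initial_time: float | None = None
    final_time: float | None = None
    background: object = None
    continuous: bool = False
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL


def _expm_hermitian(H: np.ndarray, T: float) -> np.ndarray:
    """U = exp(−iHT) for Hermitian H, by eigendecomposition."""
    w, V = np.linalg.eigh(H)
    return (V * np.exp(-1j * w * T)) @ V.conj().T


class _Segment:
    """One finite event's worth of evolution, with dense evaluation."""

    def __init__(self, t_start: float, duration: float, rho_start: np.ndarray, evaluator):
        self.t_start = t_start
        self.duration = duration
        self.rho_start = rho_start
        self._eval = evaluator  # s in [0, duration] -> rho matrix

    def rho_at(self, s: float) -> np.ndarray:
        return self._eval(s)


class DensityTrajectory:
    """Piecewise evaluation of ρ(t) across a resolved event sequence.

    Right-continuous at instantaneous events: the value at a junction is
    the post-event density operator.
    """

    def __init__(self, system, segments, t0: float, t_end: float, rho_end: np.ndarray):
        self.system = system
        self.segments = segments
        self.domain = (t0, t_end)
        self._rho_end = rho_end
        self.breakpoints = sorted({t0, t_end} | {s.t_start for s in segments})

    def __call__(self, t: float) -> np.ndarray:
        t0, t1 = self.domain
        if t < t0 - 1e-12 or t > t1 + 1e-12:
            raise ValueError(f"time {t} outside trajectory domain [{t0}, {t1}]")
        t = min(max(t, t0), t1)
        # latest segment starting at or before t wins (right continuity)
        chosen = None
        for seg in self.segments:
            if seg.t_start <= t + 1e-15:
                chosen = seg
        if chosen is None:
            return self.segments[0].rho_start if self.segments else self._rho_end
        s = min(t - chosen.t_start, chosen.duration)
        return chosen.rho_at(s)


@dataclass
class PropagationResult:
    final: DensityOperator
    trajectory: DensityTrajectory | None = None


def _constant_segment_evaluator(gen: Generator, rho0: np.ndarray):
    """Dense evaluator s ↦ ρ(s) for a constant generator."""
    n = int(round(math.sqrt(rho0.size)))
    if gen is None:
        return lambda s: rho0
    if gen.is_hamiltonian:
        H = gen.hamiltonian_matrix()
        w, V = np.linalg.eigh(H)
        rho_t = V.conj().T @ rho0 @ V

        def ev(s: float) -> np.ndarray:
            ph = np.exp(-1j * w * s)
            return V @ (ph[:, None] * rho_t * ph.conj()[None, :]) @ V.conj().T

        return ev
    L = gen.liouvillian_matrix()
    v0 = vec(rho0)
    w, V = np.linalg.eig(L)
    cond = np.linalg.cond(V)
    if np.isfinite(cond) and cond < 1e8:
        c = np.linalg.solve(V, v0)

        def ev(s: float) -> np.ndarray:
            return unvec(V @ (np.exp(w * s) * c), n)

        return ev

    def ev(s: float) -> np.ndarray:  # defective L: direct expm per query
        return unvec(scipy.linalg.expm(L * s) @ v0, n)

    return ev


def _ode_segment(gen: Generator, rho0: np.ndarray, t_start: float, duration: float,
                 rtol: float, atol: float, dense: bool):
    """Integrate one time-dependent finite event; returns (rho_final, evaluator)."""
    n = int(round(math.sqrt(rho0.size)))
    t1 = t_start + duration
    if gen.is_hamiltonian:
        def rhs(t, y):
            U = y.reshape(n, n)
            H = gen.hamiltonian_matrix(t, t0=t_start, duration=duration)
            return (-1j * H @ U).reshape(-1)

        y0 = np.eye(n, dtype=complex).reshape(-1)
        sol = solve_ivp(rhs, (t_start, t1), y0, method="DOP853", rtol=rtol, atol=atol,
                        dense_output=dense)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        if dense:
            def ev(s: float) -> np.ndarray:
                U = sol.sol(t_start + s).reshape(n, n)
                return U @ rho0 @ U.conj().T

            Uf = sol.y[:, -1].reshape(n, n)
            return Uf @ rho0 @ Uf.conj().T, ev
        Uf = sol.y[:, -1].reshape(n, n)
        return Uf @ rho0 @ Uf.conj().T, None

    def rhs(t, y):
        L = gen.liouvillian_matrix(t, t0=t_start, duration=duration)
        return L @ y

    sol = solve_ivp(rhs, (t_start, t1), vec(rho0), method="DOP853", rtol=rtol, atol=atol,
                    dense_output=dense)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    rho_f = unvec(sol.y[:, -1], n)
    if dense:
        def ev(s: float) -> np.ndarray:
            return unvec(sol.sol(t_start + s), n)

        return rho_f, ev
    return rho_f, None


def propagate(events, rho0, *, background=None, initial_time: float | None = None,
              final_time: float | None = None, continuous: bool = False,
              rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL) -> PropagationResult:
    """Evolve a density operator through an event sequence.

    ``rho0`` may be any operator ("loose" initial states are legal).
    ``background`` is a generator acting throughout. One of
    initial_time/final_time anchors the global time axis (default: starts
    at 0). With ``continuous=True`` the result carries a dense
    :class:`DensityTrajectory`.
    """
    seq = EventSequence(events)
    system = rho0.system
    t0, timed = resolve_timing(seq, initial_time, final_time)
    bg = background
    rho = rho0.matrix.copy()
    segments = []
    for ev, t_start in timed:
        if isinstance(ev, Instantaneous):
            if ev.superoperator.system != system:
                raise ValueError("event superoperator on a different spin system")
            n = system.dimension
            rho_new = unvec(ev.superoperator.matrix @ vec(rho), n)
            rho = rho_new
            continue
        gen = combine_generators(ev.generator, bg)
        if gen is not None and gen.system != system:
            raise ValueError("event generator on a different spin system")
        if ev.duration == 0.0:
            continue
        if gen is None or gen.is_constant:
            evaluator = _constant_segment_evaluator(gen, rho)
            if continuous:
                segments.append(_Segment(t_start, ev.duration, rho, evaluator))
            rho = evaluator(ev.duration)
        else:
            rho_f, evaluator = _ode_segment(gen, rho, t_start, ev.duration, rtol, atol,
                                            dense=continuous)
            if continuous:
                segments.append(_Segment(t_start, ev.duration, rho, evaluator))
            rho = rho_f
    final = DensityOperator(system, rho)
    traj = None
    if continuous:
        t_end = t0 + seq.total_duration
        if not segments:  # purely instantaneous sequence
            segments = [_Segment(t0, 0.0, rho, lambda s, m=rho: m)]
        traj = DensityTrajectory(system, segments, t0, t_end, rho)
    return PropagationResult(final=final, trajectory=traj)


def propagator_for_event(event, background=None, *, t_start: float = 0.0,
                         rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL):
    """The reusable propagator of a single event.

    Returns a :class:`Superoperator` (or a unitary :class:`SpinOperator`
    for purely Hamiltonian finite events). Sequential application of
    per-event propagators reproduces :func:`propagate`.
    """
    if isinstance(event, Instantaneous):
        return event.superoperator
    if not isinstance(event, Finite):
        raise TypeError("expected an event")
    gen = combine_generators(event.generator, background)
    if gen is None:
        sys_ = event.generator.system if event.generator else background.system
        n = sys_.dimension
        return SpinOperator(sys_, np.eye(n))
    system = gen.system
    n = system.dimension
    T = event.duration
    if gen.is_hamiltonian:
        if gen.is_constant:
            U = _expm_hermitian(gen.hamiltonian_matrix(), T)
        else:
            def rhs(t, y):
                H = gen.hamiltonian_matrix(t, t0=t_start, duration=T)
                return (-1j * H @ y.reshape(n, n)).reshape(-1)

            sol = solve_ivp(rhs, (t_start, t_start + T), np.eye(n, dtype=complex).reshape(-1),
                            method="DOP853", rtol=rtol, atol=atol)
            if not sol.success:
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            U = sol.y[:, -1].reshape(n, n)
        return SpinOperator(system, U)
    if gen.is_constant:
        return Superoperator(system, scipy.linalg.expm(gen.liouvillian_matrix() * T))

    def rhs(t, y):
        L = gen.liouvillian_matrix(t, t0=t_start, duration=T)
        return (L @ y.reshape(n * n, n * n)).reshape(-1)

    y0 = np.eye(n * n, dtype=complex).reshape(-1)
    sol = solve_ivp(rhs, (t_start, t_start + T), y0, method="DOP853", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return Superoperator(system, sol.y[:, -1].reshape(n * n, n * n))


def propagate_periodic(generator: Generator, t_start: float, times, *,
                       rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL):
    """Stroboscopic propagators for a periodic generator at given times.

    Computes the one-period propagator F and dense within-period
    propagators P(s) once, then returns the propagator from ``t_start``
    to each requested time as P(s)·Fᵐ (t − t_start = m·T_p + s). Matches
    brute-force propagation but reuses the single-period solution.
    """
    Tp = generator.period
    if Tp is None:
        raise ValueError("generator has no (single) period")
    system = generator.system
    n = system.dimension
    hilbert = generator.is_hamiltonian
    dim = n if hilbert else n * n

    def rhs(t, y):
        M = (
            -1j * generator.hamiltonian_matrix(t, t0=t_start, duration=Tp)
            if hilbert
            else generator.liouvillian_matrix(t, t0=t_start, duration=Tp)
        )
        return (M @ y.reshape(dim, dim)).reshape(-1)

    y0 = np.eye(dim, dtype=complex).reshape(-1)
    sol = solve_ivp(rhs, (t_start, t_start + Tp), y0, method="DOP853",
                    rtol=rtol, atol=atol, dense_output=True)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    F = sol.y[:, -1].reshape(dim, dim)

    times = np.asarray(times, dtype=float)
    out = []
    # cache powers of F as they are needed (times are typically ascending)
    powers = {0: np.eye(dim, dtype=complex)}

    def F_power(m: int) -> np.ndarray:
        if m not in powers:
            powers[m] = F @ F_power(m - 1)
        return powers[m]

    for t in times:
        dt_rel = t - t_start
        if dt_rel < -1e-12:
            raise ValueError("requested time precedes the start of the periodic stretch")
        m = int(math.floor(dt_rel / Tp + 1e-12))
        s = dt_rel - m * Tp
        Ps = sol.sol(t_start + s).reshape(dim, dim)
        M = Ps @ F_power(m)
        out.append(SpinOperator(system, M) if hilbert else Superoperator(system, M))
    return out
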