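"""Generators with time laws; events (pulses, delays, shaped pulses); timing.

A *generator* is a Hamiltonian, a Liouvillian/relaxation superoperator, or
a combination, each with a time law: constant, a function of the global
time t, periodic in t, or a *local shape* — a function of the local time
τ = t − (t₀ + x·T) of the event it belongs to, where x ∈ [0, 1] places the
local origin within the event.

Events are either instantaneous (a superoperator applied at a point in
time) or finite (a generator acting for a duration). An event sequence is
read left to right in chronological order; start times follow recursively
from the sequence origin, which may be anchored at either end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .liouville import Superoperator
from .operators import RotationSpec, SpinOperator, op_I
from .spin_system import SpinSystem

__all__ = [
    "Constant",
    "GlobalFunction",
    "PeriodicFunction",
    "LocalShape",
    "Generator",
    "hamiltonian_generator",
    "liouvillian_generator",
    "combine_generators",
    "Instantaneous",
    "Finite",
    "EventSequence",
    "make_pulse",
    "make_delay",
    "make_shaped_pulse",
    "resolve_timing",
    "Repeat",
]


# -- time laws -----------------------------------------------------------

@dataclass
class Constant:
    value: object  # SpinOperator or Superoperator


@dataclass
class GlobalFunction:
    fn: Callable  # t -> SpinOperator | Superoperator


@dataclass
class PeriodicFunction:
    fn: Callable  # t -> SpinOperator | Superoperator
    period: float

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")


@dataclass
class LocalShape:
    fn: Callable  # tau -> SpinOperator | Superoperator
    x: float = 0.0  # origin fraction within the event

    def __post_init__(self):
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("local-origin fraction x must lie in [0, 1]")


class Generator:
    """A tagged sum of Hamiltonian/Liouvillian terms with time laws.

    ``terms`` is a list of (kind, law) with kind in {"hamiltonian",
    "liouvillian"}. The generator is *Hamiltonian* if every term is; any
    Liouvillian term promotes the whole object to Liouville space, where
    Hamiltonians enter as −i·(commutation superoperator).
    """

    def __init__(self, system: SpinSystem, terms):
        self.system = system
        self.terms = list(terms)
        if not self.terms:
            raise ValueError("a generator needs at least one term (use None for null)")

    # -- classification --------------------------------------------------
    @property
    def is_hamiltonian(self) -> bool:
        return all(kind == "hamiltonian" for kind, _ in self.terms)

    @property
    def is_constant(self) -> bool:
        return all(isinstance(law, Constant) for _, law in self.terms)

    @property
    def period(self) -> float | None:
        """Common period when every time-dependent term is periodic with one
        period; None otherwise (or when constant)."""
        periods = {law.period for _, law in self.terms if isinstance(law, PeriodicFunction)}
        others = any(isinstance(law, (GlobalFunction, LocalShape)) for _, law in self.terms)
        if others or len(periods) != 1:
            return None
        return periods.pop()

    @property
    def has_local_shape(self) -> bool:
        return any(isinstance(law, LocalShape) for _, law in self.terms)

    # -- evaluation ------------------------------------------------------
    def _term_value(self, law, t: float, t0: float, duration: float):
        if isinstance(law, Constant):
            return law.value
        if isinstance(law, (GlobalFunction, PeriodicFunction)):
            return law.fn(t)
        if isinstance(law, LocalShape):
            tau = t - (t0 + law.x * duration)
            return law.fn(tau)
        raise TypeError(f"unknown time law {law!r}")

    def hamiltonian_matrix(self, t: float = 0.0, t0: float = 0.0, duration: float = 0.0) -> np.ndarray:
        """H(t) as a Hilbert-space matrix (rad s⁻¹); valid when is_hamiltonian."""
        if not self.is_hamiltonian:
            raise ValueError("generator contains Liouvillian terms")
        n = self.system.dimension
        out = np.zeros((n, n), dtype=complex)
        for _, law in self.terms:
            out += self._term_value(law, t, t0, duration).matrix
        return out

    def liouvillian_matrix(self, t: float = 0.0, t0: float = 0.0, duration: float = 0.0) -> np.ndarray:
        """L(t) as a Liouville-space matrix: −iĤ terms plus superoperator terms."""
        n = self.system.dimension
        out = np.zeros((n * n, n * n), dtype=complex)
        eye = np.eye(n)
        for kind, law in self.terms:
            val = self._term_value(law, t, t0, duration)
            if kind == "hamiltonian":
                H = val.matrix
                out += -1j * (np.kron(eye, H) - np.kron(H.T, eye))
            else:
                out += val.matrix
        return out

    def __repr__(self) -> str:
        kinds = "+".join(k for k, _ in self.terms)
        return f"<Generator {kinds}, constant={self.is_constant}>"


def hamiltonian_generator(op_or_law, period: float | None = None) -> Generator:
    """Wrap a SpinOperator (constant), a callable t→SpinOperator (global, or
    periodic when a period is given), or a time law, as a Hamiltonian generator."""
    if isinstance(op_or_law, SpinOperator):
        return Generator(op_or_law.system, [("hamiltonian", Constant(op_or_law))])
    if isinstance(op_or_law, (Constant, GlobalFunction, PeriodicFunction, LocalShape)):
        law = op_or_law
        probe = law.value if isinstance(law, Constant) else law.fn(0.0)
        return Generator(probe.system, [("hamiltonian", law)])
    if callable(op_or_law):
        law = PeriodicFunction(op_or_law, period) if period else GlobalFunction(op_or_law)
        return Generator(op_or_law(0.0).system, [("hamiltonian", law)])
    raise TypeError("expected a SpinOperator, callable, or time law")


def liouvillian_generator(sup_or_law, period: float | None = None) -> Generator:
    """Like :func:`hamiltonian_generator`, for superoperator-valued terms."""
    if isinstance(sup_or_law, Superoperator):
        return Generator(sup_or_law.system, [("liouvillian", Constant(sup_or_law))])
    if isinstance(sup_or_law, (Constant, GlobalFunction, PeriodicFunction, LocalShape)):
        law = sup_or_law
        probe = law.value if isinstance(law, Constant) else law.fn(0.0)
        return Generator(probe.system, [("liouvillian", law)])
    if callable(sup_or_law):
        law = PeriodicFunction(sup_or_law, period) if period else GlobalFunction(sup_or_law)
        return Generator(sup_or_law(0.0).system, [("liouvillian", law)])
    raise TypeError("expected a Superoperator, callable, or time law")


def as_generator(obj) -> Generator | None:
    """Coerce None, operators, superoperators or generators to a Generator."""
    if obj is None or isinstance(obj, Generator):
        return obj
    if isinstance(obj, SpinOperator):
        return hamiltonian_generator(obj)
    if isinstance(obj, Superoperator):
        return liouvillian_generator(obj)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a generator")


def combine_generators(*gens) -> Generator | None:
    """Combine generators; None is the identity element.

    Hamiltonians sum in Hilbert space; any superoperator term promotes the
    combination to Liouville space (Hamiltonians entering via −iĤ at
    evaluation time). Time laws are preserved term by term, so a periodic
    term combined with a constant stays periodic, while incommensurate
    periodic terms simply lose the common-period tag.
    """
    terms = []
    system = None
    for g in gens:
        g = as_generator(g)
        if g is None:
            continue
        if system is None:
            system = g.system
        elif g.system != system:
            raise ValueError("cannot combine generators on different spin systems")
        terms.extend(g.terms)
    if not terms:
        return None
    return Generator(system, terms)


# -- events --------------------------------------------------------------

@dataclass
class Instantaneous:
    """An instantaneous transformation of the density operator."""

    superoperator: Superoperator

    @property
    def duration(self) -> float:
        return 0.0


@dataclass
class Finite:
    """Evolution under a generator (None = background only) for a duration."""

    generator: Generator | None
    duration: float

    def __post_init__(self):
        if not math.isfinite(self.duration) or self.duration < 0:
            raise ValueError("event duration must be finite and ≥ 0")


class Repeat:
    """Marker: repeat an event sequence to fill an acquisition interval."""

    def __init__(self, events):
        self.events = EventSequence(events)


class EventSequence:
    """A chronological list of events (read left to right)."""

    def __init__(self, events=()):
        if isinstance(events, EventSequence):
            events = events.events
        elif isinstance(events, (Instantaneous, Finite)):
            events = [events]
        self.events = list(events)
        for ev in self.events:
            if not isinstance(ev, (Instantaneous, Finite)):
                raise TypeError(f"not an event: {ev!r}")

    @property
    def total_duration(self) -> float:
        return sum(ev.duration for ev in self.events)

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    def __add__(self, other):
        return EventSequence(self.events + EventSequence(other).events)

    def __repr__(self):
        return f"EventSequence({len(self.events)} events, T={self.total_duration:g} s)"


def resolve_timing(seq, initial_time: float | None = None, final_time: float | None = None):
    """Assign a global start time to every event.

    Exactly one anchor is used: with ``initial_time`` the sequence starts
    there; with ``final_time`` it ends there (t₀ = final − T_tot). Giving
    both is allowed only when they are consistent. Default t₀ = 0.
    Returns (t0, [(event, t_start), ...]).
    """
    seq = EventSequence(seq)
    T = seq.total_duration
    if initial_time is not None and final_time is not None:
        if abs((initial_time + T) - final_time) > 1e-12 * max(1.0, abs(T)):
            raise ValueError(
                f"timing conflict: initial {initial_time} + duration {T} != final {final_time}"
            )
        t0 = initial_time
    elif final_time is not None:
        t0 = final_time - T
    else:
        t0 = 0.0 if initial_time is None else initial_time
    out = []
    t = t0
    for ev in seq:
        out.append((ev, t))
        t += ev.duration
    return t0, out


# -- pulse-programming helpers ------------------------------------------

def _parse_angle(x) -> float:
    """Angles may be numbers (radians) or strings like 'pi/2', '90deg'."""
    if isinstance(x, str):
        s = x.strip().lower().replace(" ", "")
        if s.endswith("deg"):
            return math.radians(float(s[:-3]))
        s = s.replace("pi", repr(math.pi))
        try:
            return float(eval(s, {"__builtins__": {}}, {}))  # noqa: S307 — arithmetic only
        except Exception as exc:
            raise ValueError(f"cannot parse angle {x!r}") from exc
    return float(x)


def make_pulse(system: SpinSystem, flip, phase="x", targets=None, *, duration=None,
               nutation=None, amplitude_factor: float = 1.0, lenient: bool = False):
    """A rectangular rf pulse event in the rotating frame.

    With neither duration nor nutation frequency the pulse is ideal: an
    instantaneous rotation superoperator. Giving a duration implies the
    nutation frequency ω_nut = flip/duration (rad s⁻¹) and vice versa.
    Over-specified, inconsistent parameters raise (or warn in lenient
    mode, with the duration taking precedence). ``amplitude_factor``
    scales the rf amplitude only, never the duration.
    """
    flip = _parse_angle(flip)
    if amplitude_factor <= 0:
        raise ValueError("amplitude factor must be positive")
    if duration is None and nutation is None:
        spec = RotationSpec(flip * amplitude_factor, phase, targets)
        from .liouville import rotation_superoperator

        return Instantaneous(rotation_superoperator(system, spec, targets))
    if duration is not None and nutation is not None:
        implied = flip / duration
        if not math.isclose(implied, nutation, rel_tol=1e-9, abs_tol=1e-12):
            msg = (
                f"pulse over-specified: flip {flip:g} rad / duration {duration:g} s implies "
                f"nutation {implied:g} rad/s, but {nutation:g} rad/s was given"
            )
            if lenient:
                warnings.warn(msg, stacklevel=2)
            else:
                raise ValueError(msg)
        nutation = flip / duration  # duration takes precedence
    elif duration is not None:
        if duration <= 0:
            raise ValueError("pulse duration must be positive")
        nutation = flip / duration
    else:
        if nutation == 0:
            raise ValueError("nutation frequency must be nonzero")
        duration = flip / nutation
    axis_op = _phase_operator(system, phase, targets)
    H = (nutation * amplitude_factor) * axis_op
    H.label = f"pulse({flip:g} rad)"
    return Finite(hamiltonian_generator(H), duration)


def _phase_operator(system: SpinSystem, phase, targets) -> SpinOperator:
    """I_φ for a named axis or phase angle (xy-plane or polar spec)."""
    n = RotationSpec._resolve_axis(phase)
    return (
        n[0] * op_I(system, targets, "x")
        + n[1] * op_I(system, targets, "y")
        + n[2] * op_I(system, targets, "z")
    )


def make_delay(duration: float) -> Finite:
    """A delay: the background generator acts alone."""
    if duration < 0:
        raise ValueError("delay duration must be ≥ 0")
    return Finite(None, float(duration))


def _accumulated_phase(frequency, tau_min: float, tau_max: float):
    """ψ(τ) = ∫₀^τ frequency(τ′) dτ′ as a dense interpolant over [τ_min, τ_max]."""
    def rhs(tau, y):
        return [frequency(tau)]

    sols = []
    if tau_max > 0:
        sols.append(solve_ivp(rhs, (0.0, tau_max), [0.0], dense_output=True,
                              rtol=1e-12, atol=1e-14, max_step=(tau_max - tau_min) / 50))
    if tau_min < 0:
        sols.append(solve_ivp(rhs, (0.0, tau_min), [0.0], dense_output=True,
                              rtol=1e-12, atol=1e-14, max_step=(tau_max - tau_min) / 50))

    def psi(tau: float) -> float:
        if tau == 0.0:
            return 0.0
        for sol in sols:
            lo, hi = sorted((sol.t[0], sol.t[-1]))
            if lo - 1e-12 <= tau <= hi + 1e-12:
                return float(sol.sol(np.clip(tau, lo, hi))[0])
        # outside the event span: clamp to the nearest end
        sol = sols[0] if tau > 0 else sols[-1]
        return float(sol.sol(sol.t[-1])[0])

    return psi


def make_shaped_pulse(system: SpinSystem, duration: float, amplitude, phase=0.0,
                      frequency=None, targets=None, *, origin_fraction: float = 0.5,
                      amplitude_factor: float = 1.0) -> Finite:
    """An rf pulse of arbitrary waveform, as a local-shape finite event.

    The effective rotating-frame Hamiltonian is
    H(τ) = a(τ)·[I_x cos Φ(τ) + I_y sin Φ(τ)] with the accumulated phase
    Φ(τ) = phase(τ) + ∫₀^τ frequency(τ′) dτ′ (frequency modulation is
    folded into the phase, keeping the event self-contained in the
    rotating frame). τ is the local time; ``origin_fraction`` x places
    τ = 0 within the event (x = 1/2: the midpoint). ``amplitude``,
    ``phase`` and ``frequency`` may be constants or callables of τ, with
    amplitudes and frequencies in rad s⁻¹.
    """
    if duration <= 0:
        raise ValueError("shaped pulse duration must be positive")

    def as_fn(v):
        if v is None:
            return lambda tau: 0.0
        if callable(v):
            return v
        return lambda tau, _v=float(v): _v

    a_fn, p_fn, f_fn = as_fn(amplitude), as_fn(phase), as_fn(frequency)
    x = float(origin_fraction)
    tau_min, tau_max = -x * duration, (1 - x) * duration
    if frequency is None or (not callable(frequency) and float(frequency) == 0.0):
        psi = lambda tau: 0.0  # noqa: E731
    else:
        psi = _accumulated_phase(f_fn, tau_min, tau_max)

    ix = _phase_operator(system, "x", targets)
    iy = _phase_operator(system, "y", targets)

    def shape(tau: float) -> SpinOperator:
        amp = a_fn(tau) * amplitude_factor
        phi = p_fn(tau) + psi(tau)
        return amp * (math.cos(phi) * ix + math.sin(phi) * iy)

    gen = Generator(system, [("hamiltonian", LocalShape(shape, x))])
    return Finite(gen, duration)
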