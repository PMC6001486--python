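"""Top-level simulation routines.

- transformation amplitudes (final-state overlap with target operators),
  with parameter sweeps,
- continuous observable trajectories,
- 1D time-domain signal synthesis (FID) with automatic method selection
  (diagonalization / stroboscopic periodic / direct trajectory sampling),
  Lorentzian line broadening, and Fourier transformation,
- ensemble averaging and orientational (powder) sampling schemes.

Transformation amplitudes and trajectories report *operator amplitudes*
(ρ → Q) = (Q|ρ)/(Q|Q), which give unit amplitude for a complete transfer
between normalized states; the FID samples the raw Liouville bracket
(Q_obs|ρ), the conventional quadrature signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .events import (
    EventSequence,
    Finite,
    Generator,
    Instantaneous,
    Repeat,
    as_generator,
    combine_generators,
    make_delay,
    resolve_timing,
)
from .liouville import rotation_superoperator, vec
from .operators import SpinOperator, op_I
from .propagation import (
    DEFAULT_ATOL,
    DEFAULT_RTOL,
    DensityTrajectory,
    propagate,
    propagate_periodic,
)
from .spin_system import SpinSystem

__all__ = [
    "transformation_amplitude",
    "transformation_amplitude_table",
    "TrajectoryFunction",
    "trajectory",
    "SignalTiming",
    "make_timing",
    "Signal",
    "Spectrum",
    "signal1d",
    "apply_line_broadening",
    "fourier_transform",
    "count_modes",
    "ensemble_average",
    "orientational_sampling_scheme",
]

MODE_AMPLITUDE_FLOOR = 1e-8  # relative, for peak/mode counting
MODE_FREQ_GROUP_TOL = 1e-6  # rad s⁻¹, frequency grouping


def _amp(rho_matrix: np.ndarray, Q: SpinOperator, raw: bool) -> complex:
    num = complex(np.vdot(Q.matrix, rho_matrix))
    if raw:
        return num
    return num / complex(np.vdot(Q.matrix, Q.matrix))


def transformation_amplitude(rho0, targets, events, *, background=None,
                             normalization: complex = 1.0, raw_bracket: bool = False,
                             initial_time=None, final_time=None,
                             rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL):
    """Amplitude(s) of the target operator(s) in the propagated state.

    Returns a complex number for a single target, or a list for several.
    The default convention is the operator amplitude (Q|ρ)/(Q|Q);
    ``raw_bracket=True`` returns the bare Liouville bracket. Results are
    divided by ``normalization``.
    """
    single = isinstance(targets, SpinOperator)
    target_list = [targets] if single else list(targets)
    for Q in target_list:
        if Q.norm() == 0:
            raise ValueError("zero target operator")
    res = propagate(events, rho0, background=background, initial_time=initial_time,
                    final_time=final_time, rtol=rtol, atol=atol)
    amps = [_amp(res.final.matrix, Q, raw_bracket) / normalization for Q in target_list]
    return amps[0] if single else amps


def transformation_amplitude_table(rho0, targets, events, iterator, *,
                                   coordinates=None, background=None, **kwargs):
    """Sweep a free parameter: iterator = (imin, imax, di).

    ``events``, ``background`` and ``rho0`` may be callables of the
    iterator value. ``coordinates`` maps the iterator value to the
    reported x-coordinate (default: the value itself). Returns an ordered
    list of (x, amplitude) pairs.
    """
    imin, imax, di = iterator
    if di == 0:
        raise ValueError("iterator increment must be nonzero")
    values = np.arange(imin, imax + di * 0.5, di)
    out = []
    for i in values:
        ev = events(i) if callable(events) else events
        bg = background(i) if callable(background) else background
        r0 = rho0(i) if callable(rho0) else rho0
        amp = transformation_amplitude(r0, targets, ev, background=bg, **kwargs)
        x = coordinates(i) if callable(coordinates) else float(i)
        out.append((x, amp))
    return out


class TrajectoryFunction:
    """Observable amplitudes as a continuous function of global time."""

    def __init__(self, density_trajectory: DensityTrajectory, observables, raw: bool,
                 normalization: complex = 1.0):
        self._traj = density_trajectory
        self.observables = observables
        self.raw = raw
        self.normalization = normalization
        self.domain = density_trajectory.domain
        self.breakpoints = density_trajectory.breakpoints

    def __call__(self, t: float):
        rho = self._traj(t)
        amps = np.array([_amp(rho, Q, self.raw) for Q in self.observables])
        amps = amps / self.normalization
        return amps[0] if len(self.observables) == 1 else amps

    def sample(self, times) -> np.ndarray:
        return np.array([np.atleast_1d(self(t)) for t in times])

    def density_operator(self, t: float) -> SpinOperator:
        return SpinOperator(self._traj.system, self._traj(t))


def trajectory(rho0, observables, events, *, background=None, normalization=1.0,
               raw_bracket: bool = False, initial_time=None, final_time=None,
               rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL) -> TrajectoryFunction:
    """Continuous propagation returning observable amplitudes over time."""
    obs = [observables] if isinstance(observables, SpinOperator) else list(observables)
    res = propagate(events, rho0, background=background, initial_time=initial_time,
                    final_time=final_time, continuous=True, rtol=rtol, atol=atol)
    return TrajectoryFunction(res.trajectory, obs, raw_bracket, normalization)


# -- signal synthesis ----------------------------------------------------

_NPOINT_STRINGS = {"1k": 1024, "2k": 2048, "4k": 4096, "8k": 8192, "16k": 16384}


def _parse_npoints(n) -> int:
    if isinstance(n, str):
        key = n.strip().lower()
        if key not in _NPOINT_STRINGS:
            raise ValueError(f"unknown point-count string {n!r}")
        return _NPOINT_STRINGS[key]
    n = int(n)
    if n < 2:
        raise ValueError("need at least 2 sampling points")
    return n


@dataclass(frozen=True)
class SignalTiming:
    """Uniform FID sampling: t_n = tmin + n·dt, n = 0 … npoints−1."""

    tmin: float
    dt: float
    npoints: int

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dwell time must be positive")
        if self.npoints < 2:
            raise ValueError("need at least 2 sampling points")

    @property
    def times(self) -> np.ndarray:
        return self.tmin + self.dt * np.arange(self.npoints)

    @property
    def tmax(self) -> float:
        return self.tmin + self.dt * (self.npoints - 1)

    @property
    def spectral_width(self) -> float:
        """SW in rad s⁻¹ (2π/dt)."""
        return 2 * math.pi / self.dt


def make_timing(tmin: float = 0.0, tmax: float | None = None, dt: float | None = None,
                sw: float | None = None, npoints=None) -> SignalTiming:
    """Build a SignalTiming from {tmin, tmax, dt} or {tmin, SW (rad s⁻¹), npoints}."""
    if sw is not None:
        if npoints is None:
            raise ValueError("spectral-width timing requires npoints")
        dt = 2 * math.pi / sw
        return SignalTiming(tmin, dt, _parse_npoints(npoints))
    if dt is None or tmax is None:
        raise ValueError("timing requires either (tmax, dt) or (sw, npoints)")
    n = int(math.floor((tmax - tmin) / dt + 1.5))
    return SignalTiming(tmin, dt, n)


@dataclass
class Signal:
    """A sampled complex FID with optional Lorentzian mode table.

    When present, the mode table entries (a_k, μ_k) reconstruct the
    samples as s_n = Σ_k a_k·exp(μ_k·(t_n − tmin)).
    """

    timing: SignalTiming
    samples: np.ndarray
    modes: list | None = None  # [(amplitude, mu = iω − λ)]
    line_broadening: float = 0.0  # λ in rad s⁻¹ (FWHM in angular units)
    method: str = "direct"

    @property
    def fwhm_hz(self) -> float:
        return self.line_broadening / (2 * math.pi)

    def reconstruct_from_modes(self) -> np.ndarray:
        if self.modes is None:
            raise ValueError("signal has no mode table")
        t = self.timing.times - self.timing.tmin
        out = np.zeros(self.timing.npoints, dtype=complex)
        for a, mu in self.modes:
            out += a * np.exp(mu * t)
        return out

    # -- text I/O --------------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_s,re,im\n")
            for t, s in zip(self.timing.times, self.samples):
                fh.write(f"{t:.17g},{s.real:.17g},{s.imag:.17g}\n")

    def to_json(self, path) -> None:
        payload = {
            "timing": {"tmin": self.timing.tmin, "dt": self.timing.dt,
                       "npoints": self.timing.npoints},
            "line_broadening_rad_s": self.line_broadening,
            "method": self.method,
            "samples": [[s.real, s.imag] for s in self.samples],
        }
        if self.modes is not None:
            payload["modes"] = [
                {"amplitude": [a.real, a.imag], "mu": [mu.real, mu.imag]}
                for a, mu in self.modes
            ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "Signal":
        """Read back a CSV FID (timing inferred from the time column)."""
        rows = []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                t, re, im = line.strip().split(",")
                rows.append((float(t), complex(float(re), float(im))))
        times = np.array([r[0] for r in rows])
        samples = np.array([r[1] for r in rows])
        timing = SignalTiming(times[0], float(times[1] - times[0]), len(times))
        return cls(timing, samples)

    @classmethod
    def from_json(cls, path) -> "Signal":
        with open(path) as fh:
            payload = json.load(fh)
        timing = SignalTiming(**payload["timing"])
        samples = np.array([complex(re, im) for re, im in payload["samples"]])
        modes = None
        if "modes" in payload:
            modes = [
                (complex(*m["amplitude"]), complex(*m["mu"])) for m in payload["modes"]
            ]
        return cls(timing, samples, modes, payload.get("line_broadening_rad_s", 0.0),
                   payload.get("method", "direct"))


@dataclass
class Spectrum:
    """Complex spectrum on a uniform frequency axis in Hz."""

    frequencies_hz: np.ndarray
    values: np.ndarray

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("freq_Hz,re,im\n")
            for f, v in zip(self.frequencies_hz, self.values):
                fh.write(f"{f:.17g},{v.real:.17g},{v.imag:.17g}\n")


def default_observable(system: SpinSystem, labels=None) -> SpinOperator:
    """Quadrature-detection observable Q_obs = −(i/2)·Σ_j I_j⁻ of the observed spins."""
    idxs = system.indices(labels)
    out = None
    for idx in idxs:
        term = op_I(system, [system.labels[idx]], "-")
        out = term if out is None else out + term
    q = (-0.5j) * out
    q.label = "Qobs"
    return q


def _default_preparation(system: SpinSystem) -> Instantaneous:
    return Instantaneous(rotation_superoperator(system, (math.pi / 2, "x")))


def signal1d(system: SpinSystem, timing: SignalTiming, acq=None, *,
             initial=None, preparation="default", background=None,
             observable=None, line_broadening="automatic",
             normalization: complex = 1.0,
             rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL) -> Signal:
    """Synthesize a 1D time-domain NMR signal (FID).

    The initial density operator (default: I_z over all spins) is first
    propagated through the preparation sequence (default: an ideal
    (π/2)_x rotation) anchored so that the global time equals
    ``timing.tmin`` when acquisition starts. The signal
    s(t_n) = (Q_obs|ρ(t_n)) is then sampled under the combination of the
    ``acq`` argument (a generator, event sequence, or Repeat) and the
    background generator. Method selection: time-independent generators
    use Liouville-space diagonalization and produce a Lorentzian mode
    table; generators periodic in global time use stroboscopic
    propagation over one period; anything else falls back to direct
    trajectory sampling. Line broadening: a value λ (rad s⁻¹, the FWHM of
    the resulting Lorentzian in angular units), "automatic" (decay to
    0.01 at the last point), or None.
    """
    if initial is None:
        initial = op_I(system, "z")
    rho = initial.matrix.copy()
    # preparation, anchored to end at tmin
    if preparation == "default":
        preparation = _default_preparation(system)
    if preparation is not None:
        prep_res = propagate(preparation, SpinOperator(system, rho), background=background,
                             final_time=timing.tmin, rtol=rtol, atol=atol)
        rho = prep_res.final.matrix

    if observable is None or (not isinstance(observable, SpinOperator)):
        qobs = default_observable(system, observable)
    else:
        qobs = observable

    times = timing.times
    modes = None

    if isinstance(acq, Repeat):
        acq_gen = None
        rep_seq = acq.events
        method = "periodic"
    else:
        acq_gen = as_generator(acq) if not isinstance(acq, (EventSequence, list, tuple)) else None
        rep_seq = None
        method = None

    if method is None and (isinstance(acq, (EventSequence, list, tuple))):
        method = "direct-events"
    if method is None:
        combined = combine_generators(acq_gen, background)
        if combined is None:
            method = "static"
        elif combined.is_constant:
            method = "diagonalization"
        elif combined.period is not None:
            method = "periodic-generator"
        else:
            method = "direct"

    v_obs = vec(qobs.matrix).conj()
    n = system.dimension

    if method == "static":
        s0 = complex(v_obs @ vec(rho))
        samples = np.full(timing.npoints, s0, dtype=complex)
        modes = [(s0, 0.0 + 0.0j)]
    elif method == "diagonalization":
        L = combined.liouvillian_matrix()
        w, V = np.linalg.eig(L)
        c = np.linalg.solve(V, vec(rho))
        a = (v_obs @ V) * c
        tt = times - timing.tmin
        samples = (np.exp(np.outer(tt, w)) * a).sum(axis=1)
        keep = np.abs(a) > MODE_AMPLITUDE_FLOOR * max(np.abs(a).max(), 1e-300)
        modes = [(complex(a[k]), complex(w[k])) for k in np.nonzero(keep)[0]]
    elif method in ("periodic", "periodic-generator"):
        if method == "periodic":
            # repeated event sequence: its one-pass propagator defines the period
            if rep_seq.total_duration <= 0:
                raise ValueError("Repeat requires a sequence of positive duration")
            # propagate block by block, sampling inside each repetition
            samples = _sample_repeated(system, rho, rep_seq, background, timing, v_obs,
                                       rtol, atol)
        else:
            props = propagate_periodic(combined, timing.tmin, times, rtol=rtol, atol=atol)
            samples = np.empty(timing.npoints, dtype=complex)
            v0 = vec(rho)
            for k, P in enumerate(props):
                if isinstance(P, SpinOperator):
                    rr = P.matrix @ rho @ P.matrix.conj().T
                    samples[k] = complex(v_obs @ vec(rr))
                else:
                    samples[k] = complex(v_obs @ (P.matrix @ v0))
    else:  # direct trajectory sampling
        if method == "direct-events":
            seq = EventSequence(acq)
            pad = timing.tmax - timing.tmin - seq.total_duration
            if pad > 0:
                seq = seq + [make_delay(pad)]
        else:
            seq = EventSequence([Finite(acq_gen, timing.tmax - timing.tmin)])
        res = propagate(seq, SpinOperator(system, rho), background=background,
                        initial_time=timing.tmin, continuous=True, rtol=rtol, atol=atol)
        samples = np.array([
            complex(v_obs @ vec(res.trajectory(t))) for t in times
        ])

    sig = Signal(timing, samples / normalization, modes=modes, method=method)
    if line_broadening is not None:
        sig = apply_line_broadening(sig, line_broadening)
    return sig


def _sample_repeated(system, rho, rep_seq, background, timing, v_obs, rtol, atol):
    """Sample the FID under a repeated event sequence, block by block."""
    samples = np.empty(timing.npoints, dtype=complex)
    times = timing.times
    k = 0
    t_block = timing.tmin
    seq_T = rep_seq.total_duration
    while k < timing.npoints:
        res = propagate(rep_seq, SpinOperator(system, rho), background=background,
                        initial_time=t_block, continuous=True, rtol=rtol, atol=atol)
        while k < timing.npoints and times[k] < t_block + seq_T - 1e-15:
            samples[k] = complex(v_obs @ vec(res.trajectory(times[k])))
            k += 1
        rho = res.final.matrix
        t_block += seq_T
        if k < timing.npoints and math.isclose(times[k], t_block, abs_tol=1e-15):
            samples[k] = complex(v_obs @ vec(rho))
            k += 1
    return samples


def apply_line_broadening(signal: Signal, lb="automatic") -> Signal:
    """Multiply the FID by exp(−λ(t−tmin)/2).

    λ is the full-width-at-half-height of the resulting Lorentzian in
    angular frequency units (rad s⁻¹). "automatic" chooses λ so the decay
    envelope reaches 0.01 at the last sampling point:
    λ = 2·ln(100)/(t_last − tmin).
    """
    timing = signal.timing
    if lb == "automatic":
        T = timing.tmax - timing.tmin
        lam = 2 * math.log(100.0) / T
    elif lb is None:
        lam = 0.0
    else:
        lam = float(lb)
        if lam < 0:
            raise ValueError("line broadening must be nonnegative")
    if lam == 0.0:
        return signal
    t = timing.times - timing.tmin
    samples = signal.samples * np.exp(-lam * t / 2)
    modes = None
    if signal.modes is not None:
        modes = [(a, mu - lam / 2) for a, mu in signal.modes]
    return Signal(timing, samples, modes=modes,
                  line_broadening=signal.line_broadening + lam, method=signal.method)


def fourier_transform(signal: Signal) -> Spectrum:
    """Discrete FT with half-weighted first point and a centered Hz axis.

    Sign convention: a signal mode e^{+iωt} appears at +ω/2π Hz.
    """
    s = signal.samples.copy()
    s[0] *= 0.5
    n = signal.timing.npoints
    dt = signal.timing.dt
    values = np.fft.fftshift(np.fft.fft(s))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=dt))
    return Spectrum(freqs, values)


def count_modes(signal: Signal, freq_tol: float = MODE_FREQ_GROUP_TOL,
                amp_floor: float = MODE_AMPLITUDE_FLOOR) -> int:
    """Number of distinct Lorentzian mode frequencies in the signal.

    Modes are grouped when their frequencies agree within ``freq_tol``
    (rad s⁻¹); amplitudes below ``amp_floor``·max are ignored.
    """
    if signal.modes is None:
        raise ValueError("signal has no mode table (non-diagonalization method)")
    amps = np.array([abs(a) for a, _ in signal.modes])
    if amps.size == 0:
        return 0
    keep = amps > amp_floor * amps.max()
    freqs = sorted(mu.imag for (a, mu), k in zip(signal.modes, keep) if k)
    if not freqs:
        return 0
    groups = 1
    for f0, f1 in zip(freqs, freqs[1:]):
        if f1 - f0 > freq_tol:
            groups += 1
    return groups


# -- ensemble averaging --------------------------------------------------

def ensemble_average(task, samples, weights=None, parallel: bool = False):
    """Weighted mean of ``task(value)`` over the sampling scheme.

    ``samples`` is a list of values or of (value, weight) pairs. Results
    may be numbers, arrays, or :class:`Signal` objects (samples are
    averaged; the mode table does not combine across ensemble members and
    is dropped). The ``parallel`` flag is accepted for interface
    compatibility; evaluation order never affects the result beyond
    floating-point summation.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sampling scheme")
    if weights is None and isinstance(samples[0], (tuple, list)) and len(samples[0]) == 2:
        values = [s[0] for s in samples]
        weights = [s[1] for s in samples]
    else:
        values = samples
    if weights is None:
        weights = [1.0] * len(values)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    w = w / w.sum()
    results = [task(v) for v in values]
    first = results[0]
    if isinstance(first, Signal):
        acc = np.zeros_like(first.samples)
        for r, wk in zip(results, w):
            acc = acc + wk * r.samples
        return Signal(first.timing, acc, modes=None,
                      line_broadening=first.line_broadening, method="ensemble")
    if isinstance(first, (list, tuple)):
        arr = np.array(results, dtype=complex)
        return list(arr.T @ w.astype(complex))
    return sum(wk * np.asarray(r) for r, wk in zip(results, w))


def orientational_sampling_scheme(kind: str, n: int, seed=None):
    """Euler-angle triplets with weights for powder averaging.

    ``random``: Haar-uniform orientations (α, γ uniform on [0, 2π),
    cos β uniform on [−1, 1]), seedable. ``zcw``: a deterministic
    ZCW-type low-discrepancy sequence (golden-ratio spiral over α and
    cos β, γ = 0). Weights are uniform.
    """
    if n < 1:
        raise ValueError("need at least one orientation")
    if kind == "random":
        rng = np.random.default_rng(seed)
        alpha = rng.uniform(0, 2 * math.pi, n)
        gamma = rng.uniform(0, 2 * math.pi, n)
        beta = np.arccos(rng.uniform(-1, 1, n))
    elif kind == "zcw":
        j = np.arange(n)
        golden = (math.sqrt(5) - 1) / 2
        alpha = 2 * math.pi * np.mod(j * golden, 1.0)
        beta = np.arccos(1 - 2 * (j + 0.5) / n)
        gamma = np.zeros(n)
    else:
        raise ValueError(f"unknown sampling scheme {kind!r}")
    w = 1.0 / n
    return [((float(a), float(b), float(g)), w) for a, b, g in zip(alpha, beta, gamma)]
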