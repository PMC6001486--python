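"""Generators, time laws, pulses, delays, shaped pulses, timing resolution."""

import math
import warnings

import numpy as np
import pytest

from spindyn import (
    EventSequence,
    Finite,
    Instantaneous,
    combine_generators,
    hamiltonian_generator,
    liouvillian_generator,
    make_delay,
    make_pulse,
    make_shaped_pulse,
    make_spin_system,
    op_I,
    operator_amplitude,
    phenomenological_relaxation_superoperator,
    propagate,
    resolve_timing,
)
from spindyn.events import LocalShape, PeriodicFunction


class TestCombineGenerators:
    def test_null_is_identity_element(self, s1):
        g = hamiltonian_generator(3.0 * op_I(s1, "z"))
        assert combine_generators(None, g) is not None
        combined = combine_generators(None, g, None)
        assert np.allclose(combined.hamiltonian_matrix(), g.hamiltonian_matrix())
        assert combine_generators(None, None) is None

    def test_hamiltonians_sum(self, s2):
        h1 = hamiltonian_generator(2.0 * op_I(s2, [1], "z"))
        h2 = hamiltonian_generator(5.0 * op_I(s2, [2], "x"))
        combined = combine_generators(h1, h2)
        assert combined.is_hamiltonian and combined.is_constant
        want = 2.0 * op_I(s2, [1], "z") + 5.0 * op_I(s2, [2], "x")
        assert np.allclose(combined.hamiltonian_matrix(), want.matrix)

    def test_relaxation_promotes_to_liouville_space(self, s1):
        G = phenomenological_relaxation_superoperator(s1, 1.0)
        Om = 2 * math.pi * 10
        combined = combine_generators(liouvillian_generator(G),
                                      hamiltonian_generator(Om * op_I(s1, "z")))
        assert not combined.is_hamiltonian
        # L = −iΩÎ_z + Γ
        from spindyn import commutation_superoperator

        want = -1j * Om * commutation_superoperator(op_I(s1, "z")).matrix + G.matrix
        assert np.allclose(combined.liouvillian_matrix(), want, atol=1e-12)

    def test_combined_action_equals_sum_hamiltonian_evolution(self, s1):
        h1 = hamiltonian_generator(40.0 * op_I(s1, "z"))
        h2 = hamiltonian_generator(-15.0 * op_I(s1, "x"))
        ev_split = Finite(combine_generators(h1, h2), 0.03)
        ev_sum = Finite(hamiltonian_generator(40.0 * op_I(s1, "z") - 15.0 * op_I(s1, "x")), 0.03)
        r1 = propagate([ev_split], op_I(s1, "y"))
        r2 = propagate([ev_sum], op_I(s1, "y"))
        assert np.allclose(r1.final.matrix, r2.final.matrix, atol=1e-12)

    def test_associative_and_periodic_tag_preserved(self, s1):
        per = hamiltonian_generator(lambda t: math.cos(t) * op_I(s1, "x"), period=2 * math.pi)
        const = hamiltonian_generator(op_I(s1, "z"))
        c1 = combine_generators(combine_generators(per, const), const)
        c2 = combine_generators(per, combine_generators(const, const))
        assert c1.period == c2.period == 2 * math.pi
        t = 0.37
        assert np.allclose(c1.hamiltonian_matrix(t), c2.hamiltonian_matrix(t))

    def test_incommensurate_periods_lose_period_tag(self, s1):
        p1 = hamiltonian_generator(lambda t: math.cos(t) * op_I(s1, "x"), period=2 * math.pi)
        p2 = hamiltonian_generator(lambda t: math.cos(1.7 * t) * op_I(s1, "x"),
                                   period=2 * math.pi / 1.7)
        assert combine_generators(p1, p2).period is None

    def test_system_mismatch_rejected(self, s1, s2):
        with pytest.raises(ValueError):
            combine_generators(hamiltonian_generator(op_I(s1, "z")),
                               hamiltonian_generator(op_I(s2, "z")))


class TestPulse:
    def test_duration_implies_nutation_frequency(self, s1):
        p = make_pulse(s1, math.pi, "y", duration=10e-6)
        nut = operator_amplitude(
            type(op_I(s1, "y"))(s1, p.generator.hamiltonian_matrix()), op_I(s1, "y")
        ).real
        assert nut / (2 * math.pi) == pytest.approx(50e3)

    def test_nutation_implies_duration(self, s1):
        p = make_pulse(s1, math.pi, "y", nutation=2 * math.pi * 10e3)
        assert p.duration == pytest.approx(50e-6)

    def test_no_timing_gives_ideal_instantaneous_rotation(self, s1):
        p = make_pulse(s1, math.pi, "y")
        assert isinstance(p, Instantaneous)
        res = propagate([p], op_I(s1, "z"))
        assert operator_amplitude(res.final, op_I(s1, "z")).real == pytest.approx(-1.0)

    def test_inconsistent_overspecification_raises(self, s1):
        with pytest.raises(ValueError, match="over-specified"):
            make_pulse(s1, math.pi, "y", duration=1e-5, nutation=1.0)

    def test_lenient_mode_warns_and_keeps_duration(self, s1):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            p = make_pulse(s1, math.pi, "y", duration=1e-5, nutation=1.0, lenient=True)
        assert caught and "over-specified" in str(caught[0].message)
        assert p.duration == pytest.approx(1e-5)

    def test_flip_equals_nutation_times_duration(self, s1):
        for flip, kw in [(math.pi / 3, dict(duration=2e-4)),
                         (1.1, dict(nutation=2 * math.pi * 300))]:
            p = make_pulse(s1, flip, "x", **kw)
            nut = operator_amplitude(
                type(op_I(s1, "x"))(s1, p.generator.hamiltonian_matrix()), op_I(s1, "x")
            ).real
            assert nut * p.duration == pytest.approx(flip)

    def test_amplitude_factor_scales_amplitude_not_duration(self, s1):
        p = make_pulse(s1, math.pi, "x", duration=1e-3, amplitude_factor=0.9)
        assert p.duration == pytest.approx(1e-3)
        nut = operator_amplitude(
            type(op_I(s1, "x"))(s1, p.generator.hamiltonian_matrix()), op_I(s1, "x")
        ).real
        assert nut == pytest.approx(0.9 * math.pi / 1e-3)

    def test_string_flip_angles(self, s1):
        p = make_pulse(s1, "pi/2", "x", duration=1e-3)
        assert p.duration * math.pi / 2 / 1e-3 == pytest.approx(math.pi / 2)


class TestDelayAndTiming:
    def test_delay_duration(self):
        assert make_delay(0.5).duration == 0.5

    def test_zero_delay_is_noop(self, s1):
        res = propagate([make_delay(0.0)], op_I(s1, "x"),
                        background=hamiltonian_generator(100 * op_I(s1, "z")))
        assert np.allclose(res.final.matrix, op_I(s1, "x").matrix)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            make_delay(-0.1)

    def test_start_times_follow_recursion(self):
        seq = [make_delay(1.0), make_delay(1.0), make_delay(1.0)]
        t0, timed = resolve_timing(seq, initial_time=0.0)
        assert t0 == 0.0
        assert [t for _, t in timed] == [0.0, 1.0, 2.0]
        assert EventSequence(seq).total_duration == 3.0

    def test_final_anchor_gives_negative_start(self):
        seq = [make_delay(0.4), make_delay(0.6)]
        t0, timed = resolve_timing(seq, final_time=0.0)
        assert t0 == pytest.approx(-1.0)
        assert [t for _, t in timed] == pytest.approx([-1.0, -0.6])

    def test_conflicting_anchors_rejected(self):
        with pytest.raises(ValueError, match="conflict"):
            resolve_timing([make_delay(1.0)], initial_time=0.0, final_time=2.0)

    def test_instantaneous_events_add_no_duration(self, s1):
        seq = EventSequence([make_delay(0.5), make_pulse(s1, math.pi, "x"),
                             make_delay(0.5)])
        assert seq.total_duration == 1.0


class TestShapedPulse:
    def test_gaussian_maximum_at_midpoint(self, s1):
        sigma, T = 0.01, 0.1
        ev = make_shaped_pulse(
            s1, T, amplitude=lambda tau: math.exp(-tau**2 / (2 * sigma**2)),
            origin_fraction=0.5)
        t0 = 2.0  # arbitrary event start
        law = ev.generator.terms[0][1]
        assert isinstance(law, LocalShape)
        mid = ev.generator.hamiltonian_matrix(t0 + T / 2, t0=t0, duration=T)
        edge = ev.generator.hamiltonian_matrix(t0, t0=t0, duration=T)
        assert np.linalg.norm(mid) > 10 * np.linalg.norm(edge)

    def test_local_origin_at_event_end(self, s1):
        ev = make_shaped_pulse(s1, 0.2, amplitude=lambda tau: tau, origin_fraction=1.0)
        H_end = ev.generator.hamiltonian_matrix(5.2, t0=5.0, duration=0.2)
        assert np.linalg.norm(H_end) == pytest.approx(0.0, abs=1e-14)  # τ = 0 at end

    def test_constant_waveform_matches_rectangular_pulse(self, s1):
        w1 = 2 * math.pi * 100
        shaped = make_shaped_pulse(s1, 5e-3, amplitude=w1)
        rect = Finite(hamiltonian_generator(w1 * op_I(s1, "x")), 5e-3)
        r1 = propagate([shaped], op_I(s1, "z"))
        r2 = propagate([rect], op_I(s1, "z"))
        assert np.allclose(r1.final.matrix, r2.final.matrix, atol=1e-8)

    def test_chirp_sweep_inverts_z_magnetization(self, s1):
        ev = make_shaped_pulse(
            s1, 0.2,
            amplitude=lambda tau: 2 * math.pi * 100 * math.exp(-tau**2 / (2 * 0.05**2)),
            phase=0.0,
            frequency=lambda tau: 2 * math.pi * 500 * math.tanh(tau / 0.05),
            origin_fraction=0.5)
        res = propagate([ev], op_I(s1, "z"))
        amp = operator_amplitude(res.final, op_I(s1, "z")).real
        assert amp < -0.9

    def test_global_law_is_phase_coherent_across_delay_local_law_restarts(self, s1):
        """Cosine-modulated pulse pair: a global-time law keeps the carrier
        phase through the intervening delay, a local-shape law restarts it."""
        wmax, wmod = 2 * math.pi * 50, 2 * math.pi * 7
        TA, TB = 0.04, 0.033  # delay not commensurate with the modulation

        def global_H(t):
            return wmax * math.cos(wmod * t) * op_I(s1, "x")

        g_global = hamiltonian_generator(global_H)
        seq_global = [Finite(g_global, TA), make_delay(TB), Finite(g_global, TA)]
        shaped = lambda: make_shaped_pulse(  # noqa: E731
            s1, TA, amplitude=lambda tau: wmax * math.cos(wmod * tau),
            origin_fraction=0.0)
        seq_local = [shaped(), make_delay(TB), shaped()]
        _, timed_g = resolve_timing(seq_global)
        _, timed_l = resolve_timing(seq_local)
        # inside the SECOND pulse the two encodings disagree...
        (ev_g, t_g), (ev_l, t_l) = timed_g[2], timed_l[2]
        probe = t_g + 0.011
        Hg = ev_g.generator.hamiltonian_matrix(probe, t0=t_g, duration=TA)
        Hl = ev_l.generator.hamiltonian_matrix(probe, t0=t_l, duration=TA)
        assert not np.allclose(Hg, Hl, atol=1e-6)
        # ...global law continues cos(ω t); local law restarts cos(ω τ)
        assert np.allclose(Hg, wmax * math.cos(wmod * probe) * op_I(s1, "x").matrix)
        assert np.allclose(Hl, wmax * math.cos(wmod * (probe - t_l)) * op_I(s1, "x").matrix)
        # and both pulses of the local encoding have identical internal waveforms
        (ev_l0, t_l0) = timed_l[0]
        H0 = ev_l0.generator.hamiltonian_matrix(t_l0 + 0.011, t0=t_l0, duration=TA)
        assert np.allclose(H0, Hl, atol=1e-12)
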