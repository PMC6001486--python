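"""Top-level routines: amplitudes, trajectories, FIDs, spectra, ensembles."""

import math

import numpy as np
import pytest

from spindyn import (
    Finite,
    Signal,
    SignalTiming,
    apply_line_broadening,
    count_modes,
    ensemble_average,
    fourier_transform,
    hamiltonian_generator,
    make_delay,
    make_pulse,
    make_spin_system,
    make_timing,
    op_I,
    orientational_sampling_scheme,
    scalar_coupling,
    signal1d,
    trajectory,
    transformation_amplitude,
    transformation_amplitude_table,
    unity_operator,
)
from spindyn.simulate import default_observable


def _ab_hamiltonian(s2):
    return (
        2 * math.pi * 200 * op_I(s2, [1], "z")
        + 2 * math.pi * 300 * op_I(s2, [2], "z")
        + 2 * math.pi * 50 * scalar_coupling(s2, 1, 2)
    )


class TestTransformationAmplitude:
    def test_finite_half_pi_pulse_transfers_z_to_x(self, s1):
        seq = [make_pulse(s1, math.pi / 2, "y", duration=0.25e-3)]
        ax, ay, az = transformation_amplitude(
            op_I(s1, "z"), [op_I(s1, "x"), op_I(s1, "y"), op_I(s1, "z")], seq
        )
        assert ax == pytest.approx(1.0, abs=1e-10)
        assert ay == pytest.approx(0.0, abs=1e-10)
        assert az == pytest.approx(0.0, abs=1e-10)

    def test_empty_sequence_self_overlap_is_one(self, s2, rng):
        from conftest import random_operator

        rho = random_operator(s2, rng)
        assert transformation_amplitude(rho, rho, []) == pytest.approx(1.0)

    def test_antiphase_maximum_at_half_second_for_1hz_coupling(self, s2):
        HJ = 2 * math.pi * 1.0 * (op_I(s2, [1], "z") @ op_I(s2, [2], "z"))
        anti = 2 * (op_I(s2, [1], "y") @ op_I(s2, [2], "z"))
        bg = hamiltonian_generator(HJ)
        a_anti = transformation_amplitude(op_I(s2, [1], "x"), anti, [make_delay(0.5)],
                                          background=bg)
        a_in = transformation_amplitude(op_I(s2, [1], "x"), op_I(s2, [1], "x"),
                                        [make_delay(0.5)], background=bg)
        assert abs(a_anti) == pytest.approx(1.0, abs=1e-10)
        assert abs(a_in) == pytest.approx(0.0, abs=1e-10)
        # strictly smaller away from the maximum
        a_earlier = transformation_amplitude(op_I(s2, [1], "x"), anti,
                                             [make_delay(0.3)], background=bg)
        assert abs(a_earlier) < 1.0

    def test_zero_target_rejected(self, s1):
        with pytest.raises(ValueError):
            transformation_amplitude(op_I(s1, "z"), 0 * op_I(s1, "z"), [])

    def test_normalization_factor_divides(self, s1):
        a = transformation_amplitude(op_I(s1, "z"), op_I(s1, "z"), [],
                                     normalization=0.5)
        assert a == pytest.approx(2.0)


class TestAmplitudeTable:
    def test_offset_sweep_coordinates_in_hz(self, s1):
        def events(Om):
            return [make_pulse(s1, math.pi / 2, "x", duration=1e-3)]

        def bg(Om):
            return hamiltonian_generator(Om * op_I(s1, "z"))

        table = transformation_amplitude_table(
            op_I(s1, "z"), op_I(s1, "z"), events,
            (-2 * math.pi * 1000, 2 * math.pi * 1000, 2 * math.pi * 100),
            coordinates=lambda Om: Om / (2 * math.pi), background=bg,
        )
        xs = [x for x, _ in table]
        assert xs[0] == pytest.approx(-1000.0)
        assert xs[-1] == pytest.approx(1000.0)
        # residual z-magnetization after an x-phase pulse is even in the offset
        amps = np.array([a.real for _, a in table])
        assert np.allclose(amps, amps[::-1], atol=1e-8)

    def test_single_point_sweep_equals_plain_call(self, s1):
        seq = [make_pulse(s1, math.pi / 3, "y", duration=1e-4)]
        plain = transformation_amplitude(op_I(s1, "z"), op_I(s1, "x"), seq)
        table = transformation_amplitude_table(op_I(s1, "z"), op_I(s1, "x"), seq,
                                               (1.0, 1.0, 1.0))
        assert len(table) == 1
        assert table[0][1] == pytest.approx(plain)

    def test_zero_increment_rejected(self, s1):
        with pytest.raises(ValueError):
            transformation_amplitude_table(op_I(s1, "z"), op_I(s1, "x"), [],
                                           (0.0, 1.0, 0.0))


class TestTrajectory:
    def test_half_pi_pulse_endpoints(self, s1):
        seq = [make_pulse(s1, math.pi / 2, "y", duration=0.25e-3)]
        tf = trajectory(op_I(s1, "z"), [op_I(s1, "x"), op_I(s1, "z")], seq)
        assert tf.domain == (0.0, pytest.approx(0.25e-3))
        start, end = tf(0.0), tf(0.25e-3)
        assert start[1].real == pytest.approx(1.0)  # I_z
        assert start[0].real == pytest.approx(0.0)  # I_x
        assert end[0].real == pytest.approx(1.0)
        assert end[1].real == pytest.approx(0.0, abs=1e-10)

    def test_composite_pulse_inverts_z(self, s1):
        comp = [make_pulse(s1, math.pi / 2, "x", duration=1e-3),
                make_pulse(s1, math.pi, "y", duration=2e-3),
                make_pulse(s1, math.pi / 2, "x", duration=1e-3)]
        tf = trajectory(op_I(s1, "z"), op_I(s1, "z"), comp)
        assert len(tf.breakpoints) >= 4
        assert tf(tf.domain[1]).real == pytest.approx(-1.0, abs=1e-9)

    def test_maximally_mixed_state_shows_no_observables(self, s1):
        tf = trajectory(unity_operator(s1) / 2, op_I(s1, "x"), [make_delay(0.1)],
                        background=hamiltonian_generator(100 * op_I(s1, "z")))
        for t in np.linspace(0, 0.1, 7):
            assert abs(tf(float(t))) < 1e-12

    def test_evaluation_outside_domain_rejected(self, s1):
        tf = trajectory(op_I(s1, "z"), op_I(s1, "z"), [make_delay(0.1)])
        with pytest.raises(ValueError):
            tf(0.2)


class TestSignalTiming:
    def test_spectral_width_form(self):
        t = make_timing(sw=2 * math.pi * 1000, npoints="2k")
        assert t.npoints == 2048
        assert t.dt == pytest.approx(1e-3)
        assert t.tmax == pytest.approx(2.047)

    def test_tmax_dt_form(self):
        t = make_timing(tmin=0.0, tmax=1.0, dt=1 / 256)
        assert t.npoints == 257

    def test_invalid(self):
        with pytest.raises(ValueError):
            make_timing(sw=2 * math.pi * 100)
        with pytest.raises(ValueError):
            SignalTiming(0.0, -1e-3, 16)


class TestSignal1D:
    def test_ab_system_has_four_lorentzian_modes(self, s2):
        timing = make_timing(sw=2 * math.pi * 1000, npoints="2k")
        sig = signal1d(s2, timing, acq=hamiltonian_generator(_ab_hamiltonian(s2)))
        assert sig.method == "diagonalization"
        assert count_modes(sig) == 4

    def test_mode_table_reconstructs_samples(self, s2):
        timing = make_timing(sw=2 * math.pi * 1000, npoints=256)
        sig = signal1d(s2, timing, acq=hamiltonian_generator(_ab_hamiltonian(s2)))
        assert np.max(np.abs(sig.reconstruct_from_modes() - sig.samples)) < 1e-8

    def test_no_acquisition_generator_gives_constant_signal(self, s1):
        timing = make_timing(sw=2 * math.pi * 100, npoints=16)
        sig = signal1d(s1, timing, acq=None, line_broadening=None)
        assert np.allclose(sig.samples, sig.samples[0])
        # default preparation (π/2)_x on I_z gives −I_y; the raw bracket with
        # Q_obs = −(i/2)I⁻ is Tr{(i/2)I⁺·(−I_y)} = 1/4 for one spin-1/2
        q = default_observable(s1)
        oracle = np.trace(q.matrix.conj().T @ (-op_I(s1, "y").matrix))
        assert sig.samples[0] == pytest.approx(oracle)
        assert abs(sig.samples[0]) == pytest.approx(0.25)

    def test_diagonalization_matches_direct_sampling(self, s2):
        timing = make_timing(sw=2 * math.pi * 1000, npoints=128)
        H = _ab_hamiltonian(s2)
        sig_diag = signal1d(s2, timing, acq=hamiltonian_generator(H),
                            line_broadening=None)
        sig_direct = signal1d(
            s2, timing, acq=[Finite(hamiltonian_generator(H), 0.128)],
            line_broadening=None)
        assert sig_diag.method == "diagonalization"
        assert sig_direct.method == "direct-events"
        assert np.max(np.abs(sig_diag.samples - sig_direct.samples)) < 1e-8

    def test_uncoupled_spins_give_one_mode_per_offset(self, s2):
        H = 2 * math.pi * (150 * op_I(s2, [1], "z") + 350 * op_I(s2, [2], "z"))
        timing = make_timing(sw=2 * math.pi * 1000, npoints=256)
        sig = signal1d(s2, timing, acq=hamiltonian_generator(H))
        assert count_modes(sig) == 2

    def test_selective_observation(self, s2):
        H = 2 * math.pi * (150 * op_I(s2, [1], "z") + 350 * op_I(s2, [2], "z"))
        timing = make_timing(sw=2 * math.pi * 1000, npoints=256)
        sig = signal1d(s2, timing, acq=hamiltonian_generator(H), observable=[1])
        assert count_modes(sig) == 1


class TestLineBroadening:
    def test_automatic_width_for_two_second_fid(self):
        timing = SignalTiming(0.0, 1e-3, 2048)  # spans 0 … 2.047 s
        sig = Signal(timing, np.ones(2048, dtype=complex))
        out = apply_line_broadening(sig, "automatic")
        assert out.fwhm_hz == pytest.approx(0.71, abs=0.01)
        # decays to 0.01 at the last point
        assert abs(out.samples[-1]) == pytest.approx(0.01, rel=1e-10)

    def test_zero_broadening_unchanged(self):
        timing = SignalTiming(0.0, 1e-3, 64)
        sig = Signal(timing, np.exp(1j * np.arange(64)))
        out = apply_line_broadening(sig, 0.0)
        assert np.array_equal(out.samples, sig.samples)

    def test_explicit_width_recorded_in_hz(self):
        timing = SignalTiming(0.0, 1e-3, 64)
        sig = Signal(timing, np.ones(64, dtype=complex))
        out = apply_line_broadening(sig, 2 * math.pi * 10)
        assert out.fwhm_hz == pytest.approx(10.0)

    def test_negative_broadening_rejected(self):
        timing = SignalTiming(0.0, 1e-3, 64)
        with pytest.raises(ValueError):
            apply_line_broadening(Signal(timing, np.ones(64, dtype=complex)), -1.0)


class TestFourierTransform:
    def test_single_mode_appears_at_positive_frequency(self):
        timing = SignalTiming(0.0, 1e-3, 512)
        t = timing.times
        sig = Signal(timing, np.exp((2j * math.pi * 200 - 3.0) * t))
        spec = fourier_transform(sig)
        peak = spec.frequencies_hz[np.argmax(np.abs(spec.values))]
        assert abs(peak - 200.0) < 1.0 / (timing.npoints * timing.dt) + 1e-9

    def test_axis_spans_spectral_width(self):
        timing = SignalTiming(0.0, 1e-3, 256)
        spec = fourier_transform(Signal(timing, np.ones(256, dtype=complex)))
        assert spec.frequencies_hz[0] == pytest.approx(-500.0)
        assert spec.frequencies_hz[-1] == pytest.approx(500.0 - 1 / 0.256)

    def test_real_even_signal_gives_hermitian_spectrum(self):
        timing = SignalTiming(0.0, 1e-3, 128)
        t = np.arange(128)
        sig = Signal(timing, np.cos(2 * math.pi * t / 16) + 0j)
        spec = fourier_transform(sig)
        vals = spec.values
        # S(−ν) = S(ν)* for a real signal
        assert np.allclose(vals[1:], vals[1:][::-1].conj(), atol=1e-9)

    def test_parseval(self, s2):
        timing = make_timing(sw=2 * math.pi * 1000, npoints=256)
        sig = signal1d(s2, timing, acq=hamiltonian_generator(_ab_hamiltonian(s2)),
                       line_broadening=None)
        spec = fourier_transform(sig)
        s = sig.samples.copy()
        s[0] *= 0.5
        assert np.sum(np.abs(s) ** 2) == pytest.approx(
            np.sum(np.abs(spec.values) ** 2) / timing.npoints, rel=1e-10
        )

    def test_ab_spectrum_shows_four_maxima(self, s2):
        timing = make_timing(sw=2 * math.pi * 1000, npoints="2k")
        sig = signal1d(s2, timing, acq=hamiltonian_generator(_ab_hamiltonian(s2)))
        spec = fourier_transform(sig)
        mag = np.abs(spec.values)
        maxima = [
            k for k in range(1, len(mag) - 1)
            if mag[k] > mag[k - 1] and mag[k] > mag[k + 1] and mag[k] > 0.2 * mag.max()
        ]
        assert len(maxima) == 4


class TestEnsembleAverage:
    def test_rf_inhomogeneity_reduces_transfer(self, s1):
        rng = np.random.default_rng(7)
        nut = 2 * math.pi * rng.normal(1.0, 0.3, 100)

        def task(wn):
            seq = [Finite(hamiltonian_generator(wn * op_I(s1, "y")),
                          (math.pi / 2) / (2 * math.pi * 1.0))]
            return transformation_amplitude(op_I(s1, "z"), op_I(s1, "x"), seq)

        avg = ensemble_average(task, list(nut))
        assert 0.5 < avg.real < 1.0

    def test_single_sample_equals_plain_call(self, s1):
        def task(x):
            return transformation_amplitude(op_I(s1, "z"), op_I(s1, "z"), [])

        assert ensemble_average(task, [(2.0, 1.0)]) == pytest.approx(task(2.0))

    def test_weighted_mean(self):
        out = ensemble_average(lambda v: v, [(1.0, 1.0), (3.0, 3.0)])
        assert out == pytest.approx(2.5)

    def test_empty_scheme_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average(lambda v: v, [])

    def test_quadrupolar_ensemble_broadens_satellites_not_central_line(self):
        """Spin-5/2 with a distributed quadrupolar splitting: the central
        transition stays narrow while the satellites smear out."""
        sysq = make_spin_system([(1, 2.5)])
        iz = op_I(sysq, "z")
        quad_shape = 3 * (iz @ iz) - 2.5 * 3.5 * unity_operator(sysq)
        timing = make_timing(sw=2 * math.pi * 8000, npoints=256)
        rng = np.random.default_rng(11)
        wq_hz = rng.normal(1000.0, 30.0, 200)

        def task(wq):
            H = (2 * math.pi * wq / 6.0) * quad_shape
            return signal1d(sysq, timing, acq=hamiltonian_generator(H),
                            line_broadening=None)

        avg = ensemble_average(task, list(wq_hz))
        spec = fourier_transform(avg)
        mag = np.abs(spec.values)
        freqs = spec.frequencies_hz

        def width_at(f0):
            k0 = int(np.argmin(np.abs(freqs - f0)))
            k0 = k0 - 2 + int(np.argmax(mag[k0 - 2:k0 + 3]))
            half = mag[k0] / 2
            lo = k0
            while lo > 0 and mag[lo] > half:
                lo -= 1
            hi = k0
            while hi < len(mag) - 1 and mag[hi] > half:
                hi += 1
            return freqs[hi] - freqs[lo]

        assert width_at(0.0) * 2 < width_at(1000.0)  # central ≪ satellite


class TestOrientationalSampling:
    def test_random_scheme_has_haar_moments(self):
        sch = orientational_sampling_scheme("random", 100_000, seed=3)
        cb2 = np.mean([math.cos(o[1]) ** 2 for o, _ in sch])
        assert cb2 == pytest.approx(1 / 3, abs=0.01)
        p2 = np.mean([0.5 * (3 * math.cos(o[1]) ** 2 - 1) for o, _ in sch])
        sd = np.std([0.5 * (3 * math.cos(o[1]) ** 2 - 1) for o, _ in sch]) / math.sqrt(100_000)
        assert abs(p2) < 3 * sd

    def test_seed_reproducibility(self):
        a = orientational_sampling_scheme("random", 5, seed=42)
        b = orientational_sampling_scheme("random", 5, seed=42)
        assert a == b

    def test_zcw_scheme_moments(self):
        sch = orientational_sampling_scheme("zcw", 4000)
        cb2 = np.mean([math.cos(o[1]) ** 2 for o, _ in sch])
        assert cb2 == pytest.approx(1 / 3, abs=1e-3)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            orientational_sampling_scheme("lebedev", 10)


class TestSignalIO:
    def test_json_round_trip(self, s2, tmp_path):
        timing = make_timing(sw=2 * math.pi * 1000, npoints=64)
        sig = signal1d(s2, timing, acq=hamiltonian_generator(_ab_hamiltonian(s2)))
        path = tmp_path / "fid.json"
        sig.to_json(path)
        back = Signal.from_json(path)
        assert np.array_equal(back.samples, sig.samples)
        assert back.timing == sig.timing
        assert back.modes == sig.modes

    def test_csv_round_trip(self, s1, tmp_path):
        timing = make_timing(sw=2 * math.pi * 100, npoints=8)
        sig = signal1d(s1, timing, acq=None, line_broadening=None)
        path = tmp_path / "fid.csv"
        sig.to_csv(path)
        rows = path.read_text().strip().splitlines()
        assert rows[0] == "t_s,re,im"
        assert len(rows) == 9
        back = Signal.from_csv(path)
        assert np.array_equal(back.samples, sig.samples)
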