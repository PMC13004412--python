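import math

import numpy as np
import pytest
import scipy.linalg

from chronohelix._constants import EV_TO_J, HBAR, PROTON_MASS
from chronohelix.proton_tunneling import (
    GridSpec,
    PotentialSpec,
    TunnelDriveSpec,
    base_to_pair,
    external_potential,
    gaussian_packet,
    quartic_potential,
    region_tunneling_experiment,
    right_well_probability,
    simulate_base_pair,
    split_operator_step,
)

GRID = GridSpec(n_points=256)
POT = PotentialSpec(v0_ev=0.065)


class TestQuarticPotential:
    # grid chosen so 0, +-a and 2a fall exactly on grid points
    ALIGNED = GridSpec(n_points=256, x_min=-4e-10, x_max=4e-10)

    def test_minima_at_plus_minus_a_are_zero(self):
        v = quartic_potential(self.ALIGNED, POT)
        x = self.ALIGNED.x
        for sign in (-1, 1):
            idx = np.argmin(np.abs(x - sign * POT.a))
            assert v[idx] == pytest.approx(0.0, abs=1e-10 * POT.v0_ev * EV_TO_J)

    def test_barrier_height_at_origin(self):
        v = quartic_potential(self.ALIGNED, POT)
        idx = np.argmin(np.abs(self.ALIGNED.x))
        assert v[idx] == pytest.approx(POT.v0_ev * EV_TO_J, rel=1e-6)

    def test_value_at_twice_a(self):
        # (16 - 8 + 1) V0 by direct substitution
        v = quartic_potential(self.ALIGNED, POT)
        idx = np.argmin(np.abs(self.ALIGNED.x - 2 * POT.a))
        assert v[idx] == pytest.approx(9 * POT.v0_ev * EV_TO_J, rel=1e-6)


class TestGaussianPacket:
    def test_normalized_on_grid(self):
        psi = gaussian_packet(GRID, x0=-1e-10, sigma=5e-11)
        assert psi.norm() == pytest.approx(1.0, abs=1e-9)

    def test_peak_at_nearest_grid_point(self):
        psi = gaussian_packet(GRID, x0=-1e-10, sigma=5e-11)
        peak_x = GRID.x[np.argmax(np.abs(psi.values))]
        assert abs(peak_x - (-1e-10)) <= GRID.dx

    def test_left_well_packet_has_small_right_tail(self):
        # |psi|^2 ~ exp(-(x-x0)^2/sigma^2): tail beyond 0 is erfc(a/sigma)/2
        psi = gaussian_packet(GRID, x0=-1e-10, sigma=5e-11)
        p_r = right_well_probability(psi)
        assert p_r < 0.01
        assert p_r == pytest.approx(math.erfc(1e-10 / 5e-11) / 2, rel=1e-2)

    def test_under_resolved_sigma_rejected(self):
        with pytest.raises(ValueError, match="under-resolved"):
            gaussian_packet(GRID, x0=0.0, sigma=GRID.dx)


class TestExternalPotential:
    def test_zero_amplitude_zero_field(self):
        drive = TunnelDriveSpec(e0=0.0, noise_amplitude=0.0)
        v = external_potential(1e-12, GRID, drive, a=1e-10)
        assert np.all(v == 0)

    def test_tilt_at_time_zero(self):
        drive = TunnelDriveSpec(e0=1e-6, gain_dBi=0.0, noise_amplitude=0.0)
        v = external_potential(0.0, GRID, drive, a=1e-10)
        idx = np.argmin(np.abs(GRID.x - 1e-10))
        lam = drive.lambda_pert(1e-10)
        assert v[idx] == pytest.approx(lam * GRID.x[idx] / 1e-10, rel=1e-12)

    def test_antenna_gain_linear_factor(self):
        flat = TunnelDriveSpec(gain_dBi=0.0)
        gained = TunnelDriveSpec(gain_dBi=1.7)
        ratio = gained.lambda_pert(1e-10) / flat.lambda_pert(1e-10)
        assert ratio == pytest.approx(10 ** 0.17, rel=1e-12)
        assert ratio == pytest.approx(1.479, abs=5e-4)


class TestSplitOperator:
    def test_free_gaussian_spreading_matches_closed_form(self):
        grid = GridSpec(n_points=512)
        sigma0 = 5e-11
        psi = gaussian_packet(grid, x0=0.0, sigma=sigma0)
        dt, steps = 5e-17, 1000
        v = np.zeros(grid.n_points)
        for _ in range(steps):
            psi = split_operator_step(psi, v, dt)
        t = dt * steps
        density = np.abs(psi.values) ** 2 * grid.dx
        mean = np.sum(grid.x * density)
        var = np.sum((grid.x - mean) ** 2 * density)
        # position std of |psi|^2 is sigma(t)/sqrt(2)
        sigma_t = sigma0 * math.sqrt(1 + (HBAR * t / (PROTON_MASS * sigma0**2)) ** 2)
        assert math.sqrt(2 * var) == pytest.approx(sigma_t, rel=5e-3)

    def test_harmonic_coherent_state_oscillates_at_ehrenfest_frequency(self):
        grid = GridSpec(n_points=512)
        omega = 5e13
        sigma = math.sqrt(HBAR / (PROTON_MASS * omega))  # ground-state width
        x0 = 5e-11
        psi = gaussian_packet(grid, x0=x0, sigma=sigma)
        v = 0.5 * PROTON_MASS * omega**2 * grid.x**2
        period = 2 * math.pi / omega
        steps = 400
        dt = period / steps
        means = []
        for step in range(steps + 1):
            density = np.abs(psi.values) ** 2 * grid.dx
            means.append(np.sum(grid.x * density))
            psi = split_operator_step(psi, v, dt)
        times = np.arange(steps + 1) * dt
        predicted = x0 * np.cos(omega * times)
        assert np.abs(np.array(means) - predicted).max() < 0.01 * x0

    def test_norm_preserved_over_1e5_steps(self):
        grid = GridSpec(n_points=128)
        psi = gaussian_packet(grid, x0=-1e-10, sigma=5e-11)
        v = quartic_potential(grid, POT)
        for _ in range(100_000):
            psi = split_operator_step(psi, v, 1e-15)
        assert psi.norm() == pytest.approx(1.0, abs=1e-7)

    def test_agrees_with_crank_nicolson_oracle(self):
        """Independent dense implicit propagator on a 64-point grid must
        agree with the split-operator result to 1e-4 in P_R."""
        grid = GridSpec(n_points=64)
        pot = PotentialSpec(v0_ev=0.065)
        v = quartic_potential(grid, pot)
        dt, steps = 2.5e-17, 200
        psi_split = gaussian_packet(grid, x0=-1e-10, sigma=8e-11)

        # Crank-Nicolson with a finite-difference kinetic matrix
        n, dx = grid.n_points, grid.dx
        lap = (
            np.diag(np.full(n, -2.0))
            + np.diag(np.ones(n - 1), 1)
            + np.diag(np.ones(n - 1), -1)
        ) / dx**2
        h = -(HBAR**2) / (2 * PROTON_MASS) * lap + np.diag(v)
        a_mat = np.eye(n) + 0.5j * dt / HBAR * h
        b_mat = np.eye(n) - 0.5j * dt / HBAR * h
        lu = scipy.linalg.lu_factor(a_mat)
        psi_cn = psi_split.values.copy()
        for _ in range(steps):
            psi_split = split_operator_step(psi_split, v, dt)
            psi_cn = scipy.linalg.lu_solve(lu, b_mat @ psi_cn)
        from chronohelix.proton_tunneling import Wavefunction

        p_split = right_well_probability(psi_split)
        psi_cn /= math.sqrt(np.sum(np.abs(psi_cn) ** 2) * dx)
        p_cn = right_well_probability(Wavefunction(psi_cn, grid))
        assert p_split == pytest.approx(p_cn, abs=1e-4)

    def test_dt_halving_shows_second_order_convergence(self):
        grid = GridSpec(n_points=128)
        v = quartic_potential(grid, POT)

        def final_pr(dt, steps):
            psi = gaussian_packet(grid, x0=-1e-10, sigma=5e-11)
            for _ in range(steps):
                psi = split_operator_step(psi, v, dt)
            return right_well_probability(psi)

        # E(dt) = C dt^2 against a quarter-dt reference gives the error
        # ratio (4 - 1/4) / (1 - 1/4) = 5
        ref = final_pr(5e-18, 4000)
        err_coarse = abs(final_pr(2e-17, 1000) - ref)
        err_fine = abs(final_pr(1e-17, 2000) - ref)
        assert err_coarse / err_fine == pytest.approx(5.0, rel=0.3)


class TestRightWellProbability:
    def test_packet_in_right_well(self):
        psi = gaussian_packet(GRID, x0=1e-10, sigma=5e-11)
        assert right_well_probability(psi) > 0.99

    def test_symmetric_packet_splits_evenly(self):
        psi = gaussian_packet(GRID, x0=0.0, sigma=5e-11)
        assert right_well_probability(psi) == pytest.approx(0.5, abs=1e-6)

    def test_left_and_right_sum_to_one(self):
        psi = gaussian_packet(GRID, x0=-3e-11, sigma=5e-11)
        p_r = right_well_probability(psi)
        mirrored = gaussian_packet(GRID, x0=3e-11, sigma=5e-11)
        # mirror symmetry of the grid makes P_L(x0) = P_R(-x0)
        assert p_r + right_well_probability(mirrored) == pytest.approx(1.0, abs=1e-6)

    def test_unnormalized_input_rejected(self):
        psi = gaussian_packet(GRID, x0=0.0, sigma=5e-11)
        psi.values = psi.values * 2.0
        with pytest.raises(ValueError, match="norm"):
            right_well_probability(psi)


class TestSymmetry:
    def test_undriven_symmetric_packet_keeps_half_probability(self):
        grid = GridSpec(n_points=256)
        v = quartic_potential(grid, POT)
        psi = gaussian_packet(grid, x0=0.0, sigma=5e-11)
        for step in range(500):
            psi = split_operator_step(psi, v, 1e-15)
            if step % 100 == 99:
                assert right_well_probability(psi) == pytest.approx(0.5, abs=1e-6)


class TestSimulateBasePair:
    def test_deeper_barrier_transfers_less(self):
        at = simulate_base_pair("AT", None, GRID, 1e-15, 2000, record_every=20)
        gc = simulate_base_pair("GC", None, GRID, 1e-15, 2000, record_every=20)
        assert at.p_right.max() > gc.p_right.max()

    def test_same_seed_bit_identical(self):
        drive = TunnelDriveSpec(seed=13)
        a = simulate_base_pair("AT", drive, GRID, 1e-15, 500)
        b = simulate_base_pair("AT", drive, GRID, 1e-15, 500)
        assert np.array_equal(a.p_right, b.p_right)

    def test_drive_changes_the_trace(self):
        off = simulate_base_pair("AT", None, GRID, 1e-15, 500)
        drive = TunnelDriveSpec(e0=1e6, noise_amplitude=0.0, seed=0)
        on = simulate_base_pair("AT", drive, GRID, 1e-15, 500)
        assert np.abs(on.p_right - off.p_right).max() > 0

    def test_probabilities_stay_in_unit_interval(self):
        tr = simulate_base_pair("GC", None, GRID, 1e-15, 1000, record_every=10)
        assert np.all(tr.p_right >= 0)
        assert np.all(tr.p_right <= 1)

    def test_unknown_pair_rejected(self):
        with pytest.raises(ValueError):
            simulate_base_pair("AA", None, GRID, 1e-15, 10)


class TestRegionExperiment:
    def test_base_pairing_by_complement(self):
        assert base_to_pair("A") == "AT"
        assert base_to_pair("C") == "CG"
        with pytest.raises(ValueError):
            base_to_pair("N")

    def test_duplicated_control_gives_exactly_zero_paired_t(self):
        seq = "ATGCATGC"
        drive = TunnelDriveSpec(seed=3)  # noise on: seeds are label-blind
        out = region_tunneling_experiment(
            (seq, seq), (seq, seq), drive=drive, dt=1e-15, steps=200, seed=5
        )
        for condition in ("real", "control"):
            assert out[condition].paired_t == 0.0

    def test_composition_difference_separates_regions(self):
        # AT-only vs GC-only segments maximize the barrier-mix contrast
        out = region_tunneling_experiment(
            ("ATATAT", "GCGCGC"), ("ATATAT", "ATATAT"),
            drive=None, dt=1e-15, steps=400, seed=1,
        )
        real = out["real"]
        assert real.per_base["nc"].mean() != pytest.approx(
            real.per_base["c"].mean(), abs=1e-6
        )
        assert out["control"].paired_t == 0.0
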