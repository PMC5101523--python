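"""Excitation protocols, velocity-Verlet integration, energy bookkeeping."""

import math

import numpy as np
import pytest

import nnmfmo as nm
from nnmfmo.units import OMEGA_UNIT_CM1, TIME_UNIT_FS


@pytest.fixture(scope="module")
def spring_modes(two_node_network):
    return nm.normal_modes(two_node_network)


class TestExcite:
    def test_velocity_kick_puts_all_energy_in_kinetic(self, two_node_network,
                                                      spring_modes):
        spec = nm.ExcitationSpec(mode_from_top=0, e0=40.0)
        x, v = nm.excite(two_node_network, spring_modes, spec)
        ke = 0.5 * np.sum(two_node_network.masses[:, None] * v**2)
        assert ke == pytest.approx(40.0, rel=1e-12)
        assert nm.potential_energy(two_node_network, x) == 0.0

    def test_displacement_protocol_total_energy(self, two_node_network,
                                                spring_modes):
        spec = nm.ExcitationSpec(mode_from_top=0, e0=7.5, protocol="displacement")
        x, v = nm.excite(two_node_network, spring_modes, spec)
        assert np.all(v == 0.0)
        assert nm.potential_energy(two_node_network, x) == pytest.approx(
            7.5, rel=1e-8
        )

    def test_perturbed_kick_keeps_total_energy(self, trimer_network, trimer_modes):
        spec = nm.ExcitationSpec(mode_from_top=0, e0=40.0, seed=3,
                                 perturbation=1e-2)
        x, v = nm.excite(trimer_network, trimer_modes, spec)
        ke = 0.5 * np.sum(trimer_network.masses[:, None] * v**2)
        assert ke == pytest.approx(40.0, rel=1e-10)

    def test_sign_mirror_in_harmonic_limit(self):
        """With k4 = 0 the two excitation signs give mirrored trajectories."""
        net = nm.build_network(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), 10.0, 10.0, 0.0
        )
        modes = nm.normal_modes(net)
        runs = {}
        for sign in (1, -1):
            spec = nm.ExcitationSpec(mode_from_top=0, e0=5.0, sign=sign)
            state = nm.excite(net, modes, spec)
            runs[sign] = nm.integrate(state, net, n_steps=500, stride=10)
        delta_p = runs[1].positions - net.positions0
        delta_m = runs[-1].positions - net.positions0
        assert np.abs(delta_p + delta_m).max() < 1e-10

    def test_invalid_energy_rejected(self):
        with pytest.raises(ValueError):
            nm.ExcitationSpec(e0=0.0)


class TestIntegrate:
    def test_harmonic_spring_matches_cosine(self):
        """Displacement protocol on a harmonic spring: x(t) = A cos(ωt)."""
        net = nm.build_network(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), 10.0, 10.0, 0.0
        )
        modes = nm.normal_modes(net)
        omega = modes.band_edge_cm1 / OMEGA_UNIT_CM1  # rad per internal time
        period_fs = 2 * math.pi / omega * TIME_UNIT_FS
        spec = nm.ExcitationSpec(mode_from_top=0, e0=2.0, protocol="displacement")
        state = nm.excite(net, modes, spec)
        amp0 = state[0][1, 0] - 5.0
        dt_fs = 0.05  # the O(dt²) Verlet phase shift must stay below 1e-6
        n_steps = int(10 * period_fs / dt_fs)
        traj = nm.integrate(state, net, n_steps=n_steps, dt_fs=dt_fs,
                            stride=n_steps, probes=[(1, 0)])
        t_int = traj.probe_times_fs / TIME_UNIT_FS
        expected = 5.0 + amp0 * np.cos(omega * t_int)
        err = np.abs(traj.probe_traces[:, 0] - expected).max() / abs(amp0)
        assert err < 1e-6

    def test_energy_conservation(self, periodic_chain):
        modes = nm.normal_modes(periodic_chain)
        spec = nm.ExcitationSpec(mode_from_top=0, e0=20.0)
        state = nm.excite(periodic_chain, modes, spec)
        traj = nm.integrate(state, periodic_chain, n_steps=50_000, stride=500)
        drift = np.abs(traj.total_energy - traj.total_energy[0]).max()
        assert drift / traj.total_energy[0] < 1e-3

    def test_time_reversibility(self, periodic_chain):
        modes = nm.normal_modes(periodic_chain)
        spec = nm.ExcitationSpec(mode_from_top=3, e0=10.0)
        x0, v0 = nm.excite(periodic_chain, modes, spec)
        fwd = nm.integrate((x0, v0), periodic_chain, n_steps=10_000, stride=10_000)
        back = nm.integrate(
            (fwd.positions[-1], -fwd.velocities[-1]),
            periodic_chain, n_steps=10_000, stride=10_000,
        )
        assert np.abs(back.positions[-1] - x0).max() < 1e-6

    def test_momentum_conservation(self, trimer_network, trimer_modes):
        spec = nm.ExcitationSpec(mode_from_top=0, e0=40.0)
        state = nm.excite(trimer_network, trimer_modes, spec)
        traj = nm.integrate(state, trimer_network, n_steps=2000, stride=500)
        p = np.einsum(
            "n,snd->sd", trimer_network.masses, traj.velocities
        )
        v_scale = np.abs(traj.velocities).max()
        assert np.abs(p).max() < 1e-8 * trimer_network.masses.sum() * v_scale

    def test_harmonic_mode_purity(self, trimer):
        """k4 = 0: >99.9% of the energy stays in the excited mode for 10 ps."""
        net = nm.build_network(trimer, 10.0, 10.0, 0.0)
        modes = nm.normal_modes(net)
        spec = nm.ExcitationSpec(mode_from_top=0, e0=40.0)
        state = nm.excite(net, modes, spec)
        traj = nm.integrate(state, net, n_steps=10_000, stride=1000)
        k = modes.from_top(0)
        for s in range(traj.n_samples):
            em = nm.project_mode_energies(
                modes, net, traj.positions[s], traj.velocities[s]
            )
            assert em[k] / em.sum() > 0.999

    def test_blowup_aborts_with_diagnostic(self, two_node_network):
        modes = nm.normal_modes(two_node_network)
        spec = nm.ExcitationSpec(mode_from_top=0, e0=500.0)
        state = nm.excite(two_node_network, modes, spec)
        with pytest.raises(RuntimeError, match="energy blow-up"):
            nm.integrate(state, two_node_network, n_steps=5000, dt_fs=25.0,
                         stride=10)

    def test_bad_timestep_rejected(self, two_node_network, spring_modes):
        state = nm.excite(two_node_network, spring_modes,
                          nm.ExcitationSpec(e0=1.0))
        with pytest.raises(ValueError):
            nm.integrate(state, two_node_network, n_steps=10, dt_fs=0.0)


class TestNodeEnergies:
    def test_partition_sums_to_total(self, periodic_chain):
        modes = nm.normal_modes(periodic_chain)
        spec = nm.ExcitationSpec(mode_from_top=0, e0=15.0)
        state = nm.excite(periodic_chain, modes, spec)
        traj = nm.integrate(state, periodic_chain, n_steps=2000, stride=100)
        en = nm.node_energies(traj, periodic_chain)
        assert np.allclose(en.totals, traj.total_energy, rtol=1e-10)

    def test_static_state_has_zero_kinetic(self, two_node_network):
        traj = nm.Trajectory(
            times_fs=np.array([0.0]),
            positions=two_node_network.positions0[None],
            velocities=np.zeros((1, 2, 3)),
            dt_fs=1.0,
            stride=1,
        )
        en = nm.node_energies(traj, two_node_network)
        assert np.all(en.node_energy == 0.0)

    def test_two_node_symmetry(self, two_node_network, spring_modes):
        spec = nm.ExcitationSpec(mode_from_top=0, e0=5.0)
        state = nm.excite(two_node_network, spring_modes, spec)
        traj = nm.integrate(state, two_node_network, n_steps=1000, stride=50)
        en = nm.node_energies(traj, two_node_network)
        assert np.allclose(en.node_energy[:, 0], en.node_energy[:, 1], atol=1e-12)

    def test_group_totals_partition(self, trimer, trimer_network, trimer_modes):
        spec = nm.ExcitationSpec(mode_from_top=0, e0=40.0)
        state = nm.excite(trimer_network, trimer_modes, spec)
        traj = nm.integrate(state, trimer_network, n_steps=1000, stride=200)
        en = nm.node_energies(traj, trimer_network)
        g = en.group_totals(trimer.monomer_index())
        assert np.allclose(g.sum(axis=1), en.totals, rtol=1e-12)
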