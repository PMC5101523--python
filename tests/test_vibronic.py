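"""Vibronic Hamiltonian, stick spectra, broadening and disorder."""

import math
from dataclasses import replace

import numpy as np
import pytest

import nnmfmo as nm
from nnmfmo.vibronic import build_vibronic_hamiltonian, first_moment


def poisson_weights(s, n):
    return np.array([math.exp(-s) * s**k / math.factorial(k) for k in range(n)])


class TestHamiltonian:
    def test_hermitian(self, monomer_system):
        H, _ = build_vibronic_hamiltonian(monomer_system)
        assert np.abs(H - H.T).max() == 0.0

    def test_dimension_and_labels(self, monomer_system):
        H, labels = build_vibronic_hamiltonian(monomer_system)
        assert H.shape == (15, 15)
        assert labels[0] == (0, 0)
        assert labels[-1] == (0, 14)

    def test_uncoupled_mode_block_structure(self):
        """S = 0: eigenvalues are exciton energies plus nω exactly."""
        fx = nm.make_vibronic_fixture("dimer", e1=12300.0, e2=12460.0,
                                      coupling=70.0, huang_rhys=0.0, n_levels=4)
        H, _ = build_vibronic_hamiltonian(fx)
        evals = np.sort(np.linalg.eigvalsh(H))
        h_el = np.array([[12300.0, 70.0], [70.0, 12460.0]])
        exciton = np.linalg.eigvalsh(h_el)
        expected = np.sort(
            np.concatenate([exciton + n * 100.0 for n in range(4)])
        )
        assert np.allclose(evals, expected, atol=1e-9)

    def test_single_site_polaron_ladder(self, monomer_system):
        """Displaced oscillator: eigenvalues ε − Sω + nω."""
        H, _ = build_vibronic_hamiltonian(monomer_system)
        evals = np.sort(np.linalg.eigvalsh(H))
        expected = 12300.0 - 0.3 * 100.0 + 100.0 * np.arange(8)
        # the top of a truncated oscillator basis is distorted; check low end
        assert np.allclose(evals[:8], expected, atol=1e-6)

    def test_symmetric_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nm.ExcitonSystem(
                site_energies=[1.0, 2.0],
                couplings=np.array([[0.0, 1.0], [2.0, 0.0]]),
                dipole_vectors=[[1, 0, 0], [1, 0, 0]],
            )
        with pytest.raises(ValueError):
            nm.ExcitonSystem(
                site_energies=[1.0],
                couplings=np.zeros((1, 1)),
                dipole_vectors=[[1, 0, 0]],
                huang_rhys=-0.1,
            )


class TestSticks:
    def test_franck_condon_progression(self, monomer_system):
        """Intensities follow the Poisson progression e^{-S} Sⁿ/n!."""
        sticks = nm.stick_transitions(monomer_system)
        order = np.argsort(sticks.energies)
        rel = sticks.intensities[order] / sticks.intensities.sum()
        expected = poisson_weights(0.3, 15)
        assert np.allclose(rel[:4], expected[:4], atol=1e-4)
        assert rel[0] == pytest.approx(0.7408, abs=5e-4)
        assert rel[1] == pytest.approx(0.2222, abs=5e-4)
        assert rel[2] == pytest.approx(0.0333, abs=5e-4)

    def test_oscillator_strength_sum_rule(self):
        """Σ sticks = Σ|μ_i|² independent of S, J and disorder draw."""
        rng = np.random.default_rng(5)
        fx = nm.make_vibronic_fixture("heptamer", seed=5, huang_rhys=0.3)
        total_mu2 = np.sum(fx.dipole_vectors**2)
        for _ in range(3):
            shifted = replace(
                fx, site_energies=fx.site_energies + rng.normal(0, 40, 7)
            )
            sticks = nm.stick_transitions(shifted)
            assert sticks.intensities.sum() == pytest.approx(
                total_mu2, rel=1e-3
            )

    def test_symmetric_dimer_dark_state(self):
        """Two identical parallel dipoles: one bright stick, one dark."""
        fx = nm.make_vibronic_fixture("dimer", coupling=50.0, huang_rhys=0.0,
                                      n_levels=1)
        sticks = nm.stick_transitions(fx)
        inten = np.sort(sticks.intensities)
        assert inten[0] == pytest.approx(0.0, abs=1e-12)
        assert inten[1] == pytest.approx(2.0, rel=1e-10)

    def test_coplanar_dipoles_through_one_point_give_zero_cd(self):
        """In-plane dipoles along their separation axis have R = 0."""
        fx = nm.make_vibronic_fixture(
            "dimer", coupling=40.0, huang_rhys=0.0, n_levels=1,
            dipoles=[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
            positions=[[0.0, 0.0, 0.0], [5.0, 5.0, 0.0]],
        )
        sticks = nm.stick_transitions(fx)
        # (r_i − r_j) lies in the xy-plane, μ_i × μ_j along z ⇒ R = 0
        assert np.abs(sticks.rotational_strengths).max() < 1e-12

    def test_chiral_dimer_cd_couplet(self):
        fx = nm.make_vibronic_fixture(
            "dimer", coupling=40.0, huang_rhys=0.0, n_levels=1,
            dipoles=[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
            positions=[[0.0, 0.0, 0.0], [0.0, 0.0, 8.0]],
        )
        sticks = nm.stick_transitions(fx)
        r = sticks.rotational_strengths
        assert r.sum() == pytest.approx(0.0, abs=1e-10)  # conservative couplet
        assert np.abs(r).max() > 0.1


class TestBroadening:
    def test_no_disorder_single_realisation_is_clean(self, monomer_system):
        grid = np.linspace(11800, 12800, 500)
        line = nm.LineshapeSpec(hwhm=25.0)
        clean = nm.broaden_and_average(
            monomer_system, grid, line, nm.DisorderSpec(1, 0.0, seed=0)
        )
        sticks = nm.stick_transitions(monomer_system)
        direct = np.zeros_like(grid)
        for e, w in zip(sticks.energies, sticks.intensities):
            direct += w * (25.0 / math.pi) / ((grid - e) ** 2 + 25.0**2)
        assert np.allclose(clean.la, direct, rtol=1e-10)

    def test_seed_reproducibility(self, monomer_system):
        grid = np.linspace(11800, 12800, 300)
        kw = dict(
            lineshape=nm.LineshapeSpec(20.0),
            disorder=nm.DisorderSpec(50, 100.0, seed=42),
        )
        a = nm.broaden_and_average(monomer_system, grid, **kw)
        b = nm.broaden_and_average(monomer_system, grid, **kw)
        assert np.array_equal(a.la, b.la)
        c = nm.broaden_and_average(
            monomer_system, grid, nm.LineshapeSpec(20.0),
            nm.DisorderSpec(50, 100.0, seed=43),
        )
        assert not np.array_equal(a.la, c.la)

    def test_disorder_broadens_spectrum(self, monomer_system):
        """Doubling the disorder FWHM increases the LA spectral variance."""
        grid = np.linspace(11300, 13300, 800)
        line = nm.LineshapeSpec(20.0)

        def spread(fwhm):
            ss = nm.broaden_and_average(
                monomer_system, grid, line, nm.DisorderSpec(200, fwhm, seed=7)
            )
            mu = first_moment(grid, ss.la)
            return np.sum((grid - mu) ** 2 * ss.la) / np.sum(ss.la)

        assert spread(200.0) > spread(100.0)

    def test_disorder_averaged_stick_moment_matches_clean(self, monomer_system):
        """Gaussian disorder is symmetric: the mean stick energy is the
        clean value ε (the FC mean; the 0-0 line sits Sω below it)."""
        rng_spec = nm.DisorderSpec(400, 100.0, seed=11)
        rng = np.random.default_rng(rng_spec.seed)
        moments = []
        for _ in range(rng_spec.n_realisations):
            eps = monomer_system.site_energies + rng.normal(0, rng_spec.sigma, 1)
            sticks = nm.stick_transitions(
                replace(monomer_system, site_energies=eps)
            )
            moments.append(first_moment(sticks.energies, sticks.intensities))
        mc_sigma = rng_spec.sigma / math.sqrt(rng_spec.n_realisations)
        assert np.mean(moments) == pytest.approx(12300.0, abs=3 * mc_sigma)

    def test_peak_sits_at_zero_zero_line(self, monomer_system):
        grid = np.linspace(12000, 12600, 3001)
        ss = nm.broaden_and_average(monomer_system, grid, nm.LineshapeSpec(10.0))
        assert grid[np.argmax(ss.la)] == pytest.approx(12270.0, abs=2.0)

    def test_convergence_in_oscillator_levels(self, monomer_system):
        grid = np.linspace(11300, 13300, 1000)
        line = nm.LineshapeSpec(20.0)
        la15 = nm.broaden_and_average(monomer_system, grid, line).la
        la25 = nm.broaden_and_average(
            replace(monomer_system, n_levels=25), grid, line
        ).la
        rel = np.trapezoid(np.abs(la15 - la25), grid) / np.trapezoid(la25, grid)
        assert rel < 1e-3


class TestModePlacement:
    def test_s_zero_variants_identical(self):
        fx = nm.make_vibronic_fixture("heptamer", seed=3, huang_rhys=0.0)
        grid = np.linspace(11800, 12800, 400)
        out = nm.compare_mode_placement(
            fx, grid, coupled_subset=[2, 3, 6],
            disorder=nm.DisorderSpec(20, 80.0, seed=1),
        )
        assert np.allclose(out["no_mode"].la, out["subset"].la, rtol=1e-10)
        assert np.allclose(out["subset"].la, out["all"].la, rtol=1e-10)

    def test_mode_on_subset_redshifts_lowest_exciton(self):
        """Coupling the mode to a pigment subset lowers the lowest state."""
        fx = nm.make_vibronic_fixture("heptamer", seed=3, huang_rhys=0.3)
        no_mode = replace(fx, huang_rhys=0.0, n_levels=1)
        e_with = np.min(nm.stick_transitions(fx).energies)
        e_without = np.min(nm.stick_transitions(no_mode).energies)
        assert e_with < e_without

    def test_identical_decoupled_sites_replicate_single_site(self):
        """Uniform ε, J = 0, mode on all sites: spectrum is N × monomer."""
        n = 3
        fx = nm.ExcitonSystem(
            site_energies=np.full(n, 12300.0),
            couplings=np.zeros((n, n)),
            dipole_vectors=np.tile([1.0, 0.0, 0.0], (n, 1)),
            mode_frequency=100.0, huang_rhys=0.3, n_levels=10,
        )
        mono = nm.make_vibronic_fixture("monomer", n_levels=10)
        grid = np.linspace(11900, 12700, 400)
        line = nm.LineshapeSpec(20.0)
        multi = nm.broaden_and_average(fx, grid, line)
        single = nm.broaden_and_average(mono, grid, line)
        assert np.allclose(multi.la, n * single.la, rtol=1e-6)
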