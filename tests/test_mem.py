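"""Maximum-entropy inversion: entropy algebra, recovery, populations."""

import numpy as np
import pytest

from oligofib.fcs import FocalVolume, diffusion_coefficient
from oligofib.mem import (
    MemGrid,
    mem_fit,
    detect_modes,
    shannon_jaynes_entropy,
    split_populations,
)
from oligofib.synthetic import FcsPreset, generate_fcs_curve


class TestEntropy:
    def test_uniform_delta_and_coin(self):
        assert shannon_jaynes_entropy(np.full(100, 0.01)) == pytest.approx(np.log(100), rel=1e-12)
        assert shannon_jaynes_entropy([1.0, 0.0, 0.0]) == 0.0
        assert shannon_jaynes_entropy([0.5, 0.5]) == pytest.approx(np.log(2), rel=1e-12)

    def test_invalid_distributions_rejected(self):
        with pytest.raises(ValueError):
            shannon_jaynes_entropy([0.6, 0.6])
        with pytest.raises(ValueError):
            shannon_jaynes_entropy([1.5, -0.5])


class TestMemFit:
    def test_noiseless_on_grid_component_concentrates(self):
        # A noiseless single species whose diffusion time sits on the grid
        # must collect essentially all probability mass at that grid point
        # when the fit is pushed to the (noise-free) chi-squared floor.
        grid = MemGrid.default()
        j = 30
        d_true = 0.3**2 / (4 * grid.tau_grid[j])
        curve = generate_fcs_curve(FcsPreset("ongrid", ((1.0, d_true),), noise_level=0.0))
        sol = mem_fit(curve, grid, chi2_target=1.0)
        assert sol.converged
        assert sol.rho[j - 1 : j + 2].sum() > 0.95

    def test_two_well_separated_components_give_bimodal_distribution(self):
        preset = FcsPreset("2c", ((0.5, 200.0), (0.5, 20.0)), noise_level=0.02)
        sol = mem_fit(generate_fcs_curve(preset, seed=2))
        modes = detect_modes(sol)
        assert len(modes) >= 2
        # the two largest modes sit within one grid step of the true taus
        tau_fast, tau_slow = 0.09 / (4 * 200.0), 0.09 / (4 * 20.0)
        step = np.log(sol.grid.tau_grid[1] / sol.grid.tau_grid[0])
        assert min(abs(np.log(m / tau_fast)) for m in modes) < 1.5 * step
        assert min(abs(np.log(m / tau_slow)) for m in modes) < 1.5 * step

    def test_zero_information_limit_is_uniform(self):
        curve = generate_fcs_curve("slp1_like", seed=1)
        sol = mem_fit(curve, chi2_target=float("inf"))
        n = len(sol.grid)
        assert sol.entropy == pytest.approx(np.log(n), rel=1e-9)
        np.testing.assert_allclose(sol.rho, 1.0 / n, rtol=1e-9)

    def test_solution_invariants(self):
        sol = mem_fit(generate_fcs_curve("slp3_like", seed=5))
        # rho identity and normalization
        mass = sol.amplitudes * sol.grid.tau_grid
        np.testing.assert_allclose(sol.rho, mass / mass.sum(), atol=1e-12)
        assert sol.rho.sum() == pytest.approx(1.0, abs=1e-8)
        assert 0.0 <= sol.entropy <= np.log(len(sol.grid)) + 1e-9

    def test_entropy_monotone_in_chi2_target(self):
        curve = generate_fcs_curve("slp1_like", seed=1)
        entropies = [
            mem_fit(curve, chi2_target=t).entropy for t in (80.0, 160.0, 640.0, 1e4)
        ]
        for lo, hi in zip(entropies, entropies[1:]):
            assert lo <= hi + 1e-6

    def test_deterministic_for_identical_inputs(self):
        curve = generate_fcs_curve("slp1_like", seed=9)
        a = mem_fit(curve)
        b = mem_fit(curve)
        np.testing.assert_array_equal(a.rho, b.rho)
        assert a.chi_squared == b.chi_squared


class TestPopulations:
    def test_all_fast_mass_is_monomeric(self, focal):
        from oligofib.mem import MemSolution

        grid = MemGrid.default()
        # all probability mass on grid points faster than the cutoff
        fast = diffusion_coefficient(grid.tau_grid, focal) > 150.0
        rho = np.where(fast, 1.0, 0.0)
        rho /= rho.sum()
        alpha = rho / grid.tau_grid
        sol = MemSolution(
            grid=grid,
            amplitudes=alpha / alpha.sum(),
            rho=rho,
            entropy=shannon_jaynes_entropy(rho),
            chi_squared=0.0,
            converged=True,
            chi2_target=1.0,
        )
        pop = split_populations(sol, focal)
        assert pop.monomer_fraction == pytest.approx(1.0, abs=1e-12)
        assert pop.oligomer_fraction == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(pop.modal_d_oligomer)

    def test_fraction_sum_and_cutoff_default(self, focal):
        sol = mem_fit(generate_fcs_curve("slp1_like", seed=4))
        pop = split_populations(sol, focal, force=True)
        assert pop.monomer_fraction + pop.oligomer_fraction == pytest.approx(1.0, abs=1e-8)
        assert pop.cutoff_d == 150.0

    def test_slp1_preset_recovers_slow_component_diffusivity(self, focal):
        # generator's slow component is 2 um^2/s; modal oligomer D must
        # land within one log-grid step
        sol = mem_fit(generate_fcs_curve("slp1_like", seed=11))
        pop = split_populations(sol, focal, force=True)
        grid_step = np.log(sol.grid.tau_grid[1] / sol.grid.tau_grid[0])
        assert abs(np.log(pop.modal_d_oligomer / 2.0)) < 1.5 * grid_step

    def test_median_modal_d_error_under_25_percent_over_replicates(self, focal):
        errors_fast, errors_slow = [], []
        for seed in range(20):
            sol = mem_fit(generate_fcs_curve("slp3_like", seed=seed))
            pop = split_populations(sol, focal, force=True)
            errors_fast.append(abs(pop.modal_d_monomer - 200.0) / 200.0)
            errors_slow.append(abs(pop.modal_d_oligomer - 20.0) / 20.0)
        assert np.median(errors_fast) < 0.25
        assert np.median(errors_slow) < 0.25

    def test_grid_requires_enough_points(self):
        with pytest.raises(ValueError):
            MemGrid(np.geomspace(1e-6, 1.0, 10))
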