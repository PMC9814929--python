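"""Work accumulation and Jarzynski free-energy estimation."""

import numpy as np
import pytest

from oligofib.pmf import (
    KB,
    PullTrace,
    WorkProfile,
    accumulate_work,
    dissociation_energy,
    jarzynski_pmf,
    stability_ratio,
)
from oligofib.synthetic import LANDSCAPE_PRESETS, generate_pull_traces


def _trace_from_grid(r, f, rate=0.01):
    t = r / rate
    return PullTrace(time=t, position=r, force=f, pull_rate=rate)


class TestAccumulateWork:
    def test_constant_force_gives_linear_work(self):
        r = np.linspace(0, 2, 200)
        trace = _trace_from_grid(r, np.full_like(r, 7.0))
        w = accumulate_work(trace, r)
        np.testing.assert_allclose(w.work, 7.0 * r, atol=1e-9)

    def test_zero_force_gives_zero_work(self):
        r = np.linspace(0, 2, 50)
        w = accumulate_work(_trace_from_grid(r, np.zeros_like(r)), r)
        np.testing.assert_allclose(w.work, 0.0)

    def test_linear_ramp_force_integrates_to_half_k_r_squared(self):
        k = 12.5
        r = np.linspace(0, 2, 2000)
        w = accumulate_work(_trace_from_grid(r, k * r), r)
        np.testing.assert_allclose(w.work, 0.5 * k * r**2, rtol=1e-5, atol=1e-6)

    def test_particle_coordinate_with_backsteps_warns_and_resamples(self):
        t = np.linspace(0, 10, 101)
        x = np.linspace(0, 1, 101)
        x[50] -= 0.2  # a large thermal back-step
        trace = PullTrace(time=t, position=x, force=np.ones_like(x), pull_rate=0.0)
        with pytest.warns(UserWarning):
            w = accumulate_work(trace, np.linspace(0, 0.99, 20), coordinate="particle")
        assert np.all(np.isfinite(w.work))

    def test_grid_outside_trace_span_rejected(self):
        r = np.linspace(0, 1, 50)
        trace = _trace_from_grid(r, np.ones_like(r))
        with pytest.raises(ValueError):
            accumulate_work(trace, np.linspace(0, 2, 10))


class TestJarzynski:
    def test_single_trajectory_identity(self):
        r = np.linspace(0, 2, 300)
        w = accumulate_work(_trace_from_grid(r, 3.0 * r), r)
        pmf = jarzynski_pmf([w], temperature=300.0)
        np.testing.assert_allclose(pmf.delta_g, w.work, atol=1e-10)

    def test_gaussian_work_ensemble_converges_to_analytic_limit(self, rng):
        # For W ~ N(mu, sigma^2): -kT ln<e^(-W/kT)> -> mu - sigma^2/(2 kT)
        mu, sigma, temp, m = 25.0, 2.0, 300.0, 10_000
        kbt = KB * temp
        r = np.array([0.0, 1.0])
        samples = rng.normal(mu, sigma, size=m)
        works = [WorkProfile(r_grid=r, work=np.array([0.0, wi])) for wi in samples]
        est = jarzynski_pmf(works, temperature=temp).delta_g[1]
        expected = mu - sigma**2 / (2 * kbt)
        assert est == pytest.approx(expected, rel=0.02)

    def test_jensen_bound_holds_at_every_grid_point(self, rng):
        r = np.linspace(0, 2, 40)
        works = [
            WorkProfile(r_grid=r, work=np.concatenate([[0.0], np.cumsum(rng.uniform(0, 1, 39))]))
            for _ in range(25)
        ]
        pmf = jarzynski_pmf(works)
        mean_w = np.mean([w.work for w in works], axis=0)
        assert np.all(pmf.delta_g <= mean_w + 1e-9)

    def test_estimate_invariant_under_reordering_and_balanced_duplication(self):
        r = np.linspace(0, 1, 20)
        base = [
            WorkProfile(r_grid=r, work=np.linspace(0, wf, 20)) for wf in (5.0, 9.0, 14.0)
        ]
        a = jarzynski_pmf(base).delta_g
        b = jarzynski_pmf(base[::-1]).delta_g
        c = jarzynski_pmf(base * 3).delta_g
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(a, c, atol=1e-12)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            jarzynski_pmf([])

    def test_prescribed_landscape_depth_recovered_within_15_percent(self):
        spec = LANDSCAPE_PRESETS["fibril_like"]
        traces = generate_pull_traces(spec, n=50, rate=0.002, dt=0.02, seed=17)
        r_grid = np.linspace(0.0, 1.98, 150)
        works = [accumulate_work(t, r_grid) for t in traces]
        pmf = jarzynski_pmf(works, temperature=spec.temperature)
        dgd = dissociation_energy(pmf)
        assert abs(dgd - spec.depth) / spec.depth < 0.15


class TestDissociationEnergy:
    def _pmf(self, g, r=None):
        r = np.linspace(0, 2, len(g)) if r is None else r
        return jarzynski_pmf(
            [WorkProfile(r_grid=r, work=np.asarray(g, dtype=float))], temperature=300.0
        )

    def test_plateau_height_above_minimum(self):
        g = np.concatenate([np.linspace(0, 20, 80), np.full(20, 20.0)])
        assert dissociation_energy(self._pmf(g)) == pytest.approx(20.0)

    def test_flat_profile_gives_zero(self):
        assert dissociation_energy(self._pmf(np.zeros(50))) == pytest.approx(0.0)

    def test_unplateaued_profile_warns(self):
        g = np.linspace(0, 60, 100)  # still rising at the end
        with pytest.warns(UserWarning):
            dissociation_energy(self._pmf(g))

    def test_three_to_one_landscape_contrast_recovered(self):
        energies = {}
        for name in ("fibril_like", "oligomer_like"):
            spec = LANDSCAPE_PRESETS[name]
            traces = generate_pull_traces(spec, n=25, rate=0.002, dt=0.02, seed=23)
            r_grid = np.linspace(0.0, 1.98, 120)
            works = [accumulate_work(t, r_grid) for t in traces]
            energies[name] = dissociation_energy(jarzynski_pmf(works))
        ratio = stability_ratio(energies["fibril_like"], energies["oligomer_like"])
        assert ratio == pytest.approx(3.0, rel=0.25)

    def test_ratio_arithmetic_and_validation(self):
        assert stability_ratio(30.0, 10.0) == pytest.approx(3.0)
        assert stability_ratio(8.0, 8.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            stability_ratio(30.0, 0.0)
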