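"""Seeded generators emulating the statistical structure of pipeline inputs.

Three families of synthetic data stand in for the raw measurements the
analysis stages consume:

* **FCS curves** — multi-component 3D-diffusion autocorrelations with a
  fast monomer population (D > 150 um^2/s) and a slow oligomer population,
  plus multiplicative Gaussian noise whose standard deviation shrinks with
  lag index (short lags are averaged over more correlator samples).  Named
  presets encode the qualitative contrasts of interest: peptides with two
  glutamates in the headgroup form ~10-fold slower (larger) oligomers than
  those with three, and the weakly assembling variant shows one broad
  population.  The absolute preset diffusivities are generator choices.
* **Pulling traces** — overdamped Langevin dynamics of a particle on a
  prescribed 1D free-energy landscape, dragged by a moving harmonic
  spring (default force constant 1000 kJ/mol/nm^2, pull rate 0.01 nm/ps).
* **Perturbed lattices** — isotropic Gaussian displacement of ideal
  cross-beta coordinates, emulating thermal broadening of RDF peaks.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fcs import (
    AutocorrelationCurve,
    ComponentDistribution,
    TripletParams,
    model_autocorrelation,
)
from .pmf import DEFAULT_RATE, DEFAULT_SPRING, KB, PullTrace

__all__ = [
    "FcsPreset",
    "LandscapeSpec",
    "FCS_PRESETS",
    "LANDSCAPE_PRESETS",
    "generate_fcs_curve",
    "generate_pull_traces",
    "perturb_lattice",
    "default_lag_grid",
]

#: Floor on the attached per-point sd so that noiseless curves remain
#: usable as chi-squared weights.
_SD_FLOOR = 1e-5


@dataclass(frozen=True)
class FcsPreset:
    """A named multi-component diffusion scenario.

    ``components`` maps fractions (summing to 1) to diffusion coefficients
    in um^2/s; ``focal_w_xy`` is the lateral focal radius in um used to
    convert them to diffusion times.
    """

    name: str
    components: tuple[tuple[float, float], ...]  # (fraction, D um^2/s)
    focal_w_xy: float = 0.3
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self):
        fracs = [f for f, _ in self.components]
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("component fractions must sum to 1")
        if any(d <= 0 for _, d in self.components):
            raise ValueError("diffusion coefficients must be positive")
        if self.focal_w_xy <= 0:
            raise ValueError("focal radius must be positive")
        if self.noise_level < 0:
            raise ValueError("noise level must be non-negative")

    def component_model(self, gamma: float = 6.0) -> ComponentDistribution:
        """Convert (fraction, D) pairs to (amplitude, tau_D seconds)."""
        comps = tuple(
            (f, self.focal_w_xy**2 / (4.0 * d)) for f, d in self.components
        )
        return ComponentDistribution(components=comps, aspect_ratio=gamma)


FCS_PRESETS: dict[str, FcsPreset] = {
    # Free calibration dye.
    "alexa647": FcsPreset("alexa647", ((1.0, 330.0),)),
    # Two-glutamate headgroup: large oligomers, ~100-fold below monomer D.
    "slp1_like": FcsPreset("slp1_like", ((0.4, 200.0), (0.6, 2.0))),
    # Three-glutamate headgroup: ~10-fold smaller oligomers than slp1.
    "slp3_like": FcsPreset("slp3_like", ((0.6, 200.0), (0.4, 20.0))),
    # Merged monomer/oligomer population near the size cutoff.
    "slp4_like": FcsPreset("slp4_like", ((1.0, 100.0),)),
}


def default_lag_grid(n: int = 160, lag_min: float = 1e-6, lag_max: float = 1.0) -> np.ndarray:
    """Log-spaced correlator lag times (seconds)."""
    return np.geomspace(lag_min, lag_max, n)


def generate_fcs_curve(
    preset: FcsPreset | str,
    lag_grid=None,
    gamma: float = 6.0,
    triplet: TripletParams | None = None,
    seed: int | None = None,
) -> AutocorrelationCurve:
    """Synthesize a (noisy) normalized autocorrelation curve from a preset.

    Multiplicative Gaussian noise is applied with per-point sd
    ``noise_level * G_i / sqrt(i + 1)`` (lag index ``i``), mimicking the
    heavier averaging of short correlator lags; the exact sd is attached
    to the curve as weights.  ``noise_level = 0`` returns the forward
    model exactly.  The same (preset, seed) always yields bit-identical
    output.
    """
    if isinstance(preset, str):
        preset = FCS_PRESETS[preset]
    if lag_grid is None:
        lag_grid = default_lag_grid()
    lag_grid = np.asarray(lag_grid, dtype=float)
    if seed is None:
        seed = preset.seed
    model = preset.component_model(gamma)
    g = model_autocorrelation(lag_grid, model, triplet)
    sd = preset.noise_level * g / np.sqrt(np.arange(lag_grid.size) + 1.0)
    if preset.noise_level > 0:
        rng = np.random.default_rng(seed)
        g = g + sd * rng.standard_normal(lag_grid.size)
    return AutocorrelationCurve(
        lags=lag_grid,
        values=g,
        weights=np.maximum(sd, _SD_FLOOR),
        normalized=True,
    )


@dataclass(frozen=True)
class LandscapeSpec:
    """An analytic 1D free-energy landscape for synthetic pulling runs.

    ``form="well_plateau"`` (default) rises smoothly from a minimum at
    r = 0 to a flat plateau of height ``depth`` beyond ``rise_width``:
    dissociating the particle costs exactly ``depth`` kJ/mol.
    ``form="harmonic"`` is a harmonic well of curvature
    ``2 depth / rise_width^2``.
    """

    name: str = "custom"
    form: str = "well_plateau"
    depth: float = 30.0  # kJ/mol
    rise_width: float = 0.5  # nm
    r_range: float = 2.0  # nm
    friction: float = 100.0  # kJ ps / mol / nm^2
    temperature: float = 300.0  # K

    def __post_init__(self):
        if self.form not in ("well_plateau", "harmonic", "flat"):
            raise ValueError(f"unknown landscape form {self.form!r}")
        if self.rise_width <= 0 or self.r_range <= 0 or self.friction <= 0:
            raise ValueError("rise_width, r_range and friction must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")

    def energy(self, r):
        r = np.asarray(r, dtype=float)
        if self.form == "flat":
            return np.zeros_like(r)
        if self.form == "harmonic":
            return self.depth * (r / self.rise_width) ** 2
        # smoothstep 3u^2 - 2u^3 rise to the plateau
        u = np.clip(r / self.rise_width, 0.0, 1.0)
        return self.depth * (3.0 * u**2 - 2.0 * u**3)

    def gradient(self, r):
        r = np.asarray(r, dtype=float)
        if self.form == "flat":
            return np.zeros_like(r)
        if self.form == "harmonic":
            return 2.0 * self.depth * r / self.rise_width**2
        u = np.clip(r / self.rise_width, 0.0, 1.0)
        return self.depth * 6.0 * (u - u**2) / self.rise_width


LANDSCAPE_PRESETS: dict[str, LandscapeSpec] = {
    # 3:1 depth contrast between the ordered fibril and the micellar
    # oligomer, mirroring the ~3-fold dissociation-energy difference.
    "fibril_like": LandscapeSpec(name="fibril_like", depth=30.0),
    "oligomer_like": LandscapeSpec(name="oligomer_like", depth=10.0),
}


def generate_pull_traces(
    spec: LandscapeSpec | str,
    spring: float = DEFAULT_SPRING,
    rate: float = DEFAULT_RATE,
    n: int = 50,
    dt: float = 0.01,
    seed: int = 0,
    save_every: int = 10,
) -> list[PullTrace]:
    """Simulate overdamped steered pulling on a prescribed landscape.

    A particle obeying overdamped Langevin dynamics on ``spec.energy`` is
    dragged by a harmonic spring (constant ``spring`` kJ/mol/nm^2) whose
    reference moves at ``rate`` nm/ps from r = 0 across ``spec.r_range``.
    Positions and spring forces are recorded every ``save_every`` steps.
    All ``n`` trajectories are integrated in parallel with a seeded
    generator; identical inputs give identical output.

    Raises
    ------
    ValueError
        If the time step is unstable for the given friction and stiffness
        (drift per step would exceed the spring length scale).
    """
    if isinstance(spec, str):
        spec = LANDSCAPE_PRESETS[spec]
    zeta = spec.friction
    stiffness = spring + 2.0 * spec.depth / spec.rise_width**2
    if dt * stiffness / zeta > 0.5:
        raise ValueError(
            f"time step {dt} ps unstable for friction {zeta} and stiffness "
            f"~{stiffness:.0f} kJ/mol/nm^2; reduce dt"
        )
    if rate > 0:
        n_steps = int(np.ceil(spec.r_range / (rate * dt)))
    else:
        # stationary spring: a fixed-length equilibration run
        n_steps = 50_000
    kbt = KB * spec.temperature
    noise_amp = np.sqrt(2.0 * kbt * dt / zeta)
    rng = np.random.default_rng(seed)

    x = np.zeros(n)
    times, positions, forces = [], [], []
    for step in range(n_steps + 1):
        t = step * dt
        lam = rate * t
        f_spring = spring * (lam - x)
        if step % save_every == 0 or step == n_steps:
            times.append(t)
            positions.append(x.copy())
            forces.append(f_spring.copy())
        drift = (f_spring - spec.gradient(x)) * dt / zeta
        kick = noise_amp * rng.standard_normal(n) if spec.temperature > 0 else 0.0
        x = x + drift + kick
        if not np.all(np.isfinite(x)):
            raise ValueError("numerical blow-up during Langevin integration; reduce dt")

    t_arr = np.asarray(times)
    pos = np.asarray(positions)  # (n_saved, n)
    frc = np.asarray(forces)
    return [
        PullTrace(
            time=t_arr,
            position=pos[:, m],
            force=frc[:, m],
            spring_constant=spring,
            pull_rate=rate,
        )
        for m in range(n)
    ]


def perturb_lattice(coords, sigma: float, seed: int = 0) -> np.ndarray:
    """Add seeded isotropic Gaussian displacement (A) to coordinates.

    ``sigma = 0`` returns the input unchanged.
    """
    coords = np.asarray(coords, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return coords.copy()
    rng = np.random.default_rng(seed)
    return coords + sigma * rng.standard_normal(coords.shape)
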