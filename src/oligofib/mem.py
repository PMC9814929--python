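"""Maximum-entropy inversion of FCS autocorrelation curves.

Instead of committing to a fixed number of diffusing species, the curve is
modelled as a quasi-continuous distribution of amplitudes over a log-spaced
grid of diffusion times.  Among all distributions compatible with the data,
the maximum entropy method (MEM) selects the one maximizing the
Shannon-Jaynes entropy

    S = - sum_j rho_j ln rho_j,    rho_j = alpha_j tau_Dj / sum_i alpha_i tau_Di,

i.e. the broadest, least-committal distribution whose forward model still
fits the curve to a prescribed chi-squared level.  ``rho_j`` is the
probability of detecting a species of diffusion time ``tau_Dj`` in the
focal volume (amplitudes weight inversely with residence time, hence the
``alpha tau`` product).

The constrained problem is solved as a Lagrangian trade-off
``min 0.5 chi^2 - mu S`` over log-amplitudes (non-negativity built in),
with an outer bisection on the entropy weight ``mu`` until chi^2 meets the
target (default: the number of fitted points).  The scheme is fully
deterministic for fixed inputs and iteration caps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.signal import find_peaks

from .fcs import (
    AutocorrelationCurve,
    FocalVolume,
    TripletParams,
    diffusion_coefficient,
    single_component_g,
)

__all__ = [
    "MemGrid",
    "MemSolution",
    "PopulationSummary",
    "shannon_jaynes_entropy",
    "mem_fit",
    "split_populations",
    "detect_modes",
    "DEFAULT_CUTOFF_D",
]

#: Monomer/oligomer boundary in µm²/s: species diffusing faster are counted
#: as monomeric, slower as oligomeric.
DEFAULT_CUTOFF_D = 150.0

#: Constant per-point standard deviation assumed when a curve carries no
#: weights (1% of a normalized G(0) amplitude).
DEFAULT_SIGMA = 0.01


@dataclass(frozen=True)
class MemGrid:
    """Log-spaced grid of candidate diffusion times (seconds)."""

    tau_grid: np.ndarray

    def __post_init__(self):
        tau = np.asarray(self.tau_grid, dtype=float)
        object.__setattr__(self, "tau_grid", tau)
        if tau.ndim != 1 or tau.size < 20:
            raise ValueError("MEM grid needs at least 20 diffusion times")
        if not np.all(tau > 0) or not np.all(np.diff(tau) > 0):
            raise ValueError("grid must be positive and strictly increasing")

    @classmethod
    def default(cls, n: int = 100, tau_min: float = 1e-6, tau_max: float = 1.0) -> "MemGrid":
        """100 log-spaced diffusion times from 1 µs to 1 s.

        Brackets everything from a free dye (tens of µs) to large oligomers
        (tens of ms) for a ~0.3 µm focal volume.
        """
        return cls(np.geomspace(tau_min, tau_max, n))

    def __len__(self) -> int:
        return self.tau_grid.size


@dataclass(frozen=True)
class MemSolution:
    """A MEM fit result: amplitudes and probabilities over the grid."""

    grid: MemGrid
    amplitudes: np.ndarray
    rho: np.ndarray
    entropy: float
    chi_squared: float
    converged: bool
    chi2_target: float

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        if abs(rho.sum() - 1.0) > 1e-8:
            raise ValueError("rho must be normalized to 1")
        if np.any(rho < 0):
            raise ValueError("rho must be non-negative")


@dataclass(frozen=True)
class PopulationSummary:
    """Monomer/oligomer split of a MEM distribution at a diffusivity cutoff.

    ``modal_d_*`` is the grid diffusion coefficient with maximal rho inside
    the population; NaN marks an empty population.
    """

    monomer_fraction: float
    oligomer_fraction: float
    modal_d_monomer: float
    modal_d_oligomer: float
    cutoff_d: float


def shannon_jaynes_entropy(rho) -> float:
    """Shannon-Jaynes entropy -sum rho ln rho with 0 ln 0 := 0."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(rho.sum() - 1.0) > 1e-8:
        raise ValueError("probabilities must sum to 1")
    pos = rho[rho > 0]
    return float(-np.sum(pos * np.log(pos)))


def _rho_from_amplitudes(alpha: np.ndarray, tau: np.ndarray) -> np.ndarray:
    mass = alpha * tau
    return mass / mass.sum()


def _design_matrix(lags, grid, gamma, triplet):
    k = np.empty((lags.size, len(grid)))
    for j, tau_d in enumerate(grid.tau_grid):
        k[:, j] = single_component_g(lags, tau_d, gamma)
    if triplet is not None:
        k *= triplet.factor(lags)[:, None]
    return k


def _solve_inner(kn, colnorm, yw, tau, mu, gamma0, maxiter):
    """Minimize 0.5 chi^2 - mu S over column-scaled amplitudes gamma >= 0.

    ``kn`` is the weighted design matrix with unit-norm columns
    (``alpha = gamma / colnorm``); the scaling keeps the quadratic part
    well conditioned across the large dynamic range of per-point weights.
    """

    def objective(gamma):
        gamma = np.maximum(gamma, 1e-300)
        alpha = gamma / colnorm
        resid = kn @ gamma - yw
        chi2 = resid @ resid
        mass = alpha * tau
        z = mass.sum()
        rho = mass / z
        logrho = np.log(rho)
        s = -np.sum(rho * logrho)
        # dS/dalpha_j = (tau_j / z) * (-ln rho_j - S)
        ds = (tau / z) * (-logrho - s)
        grad = kn.T @ resid - mu * ds / colnorm
        return 0.5 * chi2 - mu * s, grad

    res = minimize(
        objective,
        gamma0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * gamma0.size,
        options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-14},
    )
    return np.maximum(res.x, 1e-300)


def mem_fit(
    curve: AutocorrelationCurve,
    grid: MemGrid | None = None,
    gamma: float = 6.0,
    triplet: TripletParams | None = None,
    chi2_target: float | None = None,
    *,
    max_bisection: int = 40,
    max_inner: int = 3000,
) -> MemSolution:
    """Invert an autocorrelation curve into a diffusion-time distribution.

    Parameters
    ----------
    curve
        Curve to invert.  Per-point standard deviations are used as
        chi-squared weights when present; otherwise a constant 1% sd is
        assumed (and logged).
    grid
        Diffusion-time grid (default: 100 points, 1 µs - 1 s).
    chi2_target
        Target chi-squared for the entropy/misfit trade-off.  Defaults to
        the number of fitted points.  ``inf`` requests the zero-information
        limit and returns the uniform distribution analytically.

    Returns
    -------
    MemSolution
        With ``converged=False`` (and a warning) when the chi-squared
        target is unreachable within the iteration caps; the best iterate
        is still returned.
    """
    if grid is None:
        grid = MemGrid.default()
    tau = grid.tau_grid
    if tau[0] > curve.lags[0] or tau[-1] < curve.lags[-1]:
        warnings.warn("MEM grid does not span the full lag range of the curve", stacklevel=2)
    n_points = len(curve)
    if chi2_target is None:
        chi2_target = float(n_points)

    if np.isinf(chi2_target):
        # Zero-information limit: the entropy maximizer is exactly uniform.
        n = len(grid)
        rho = np.full(n, 1.0 / n)
        alpha = rho / tau
        alpha /= alpha.sum()
        k = _design_matrix(curve.lags, grid, gamma, triplet)
        sigma = curve.weights if curve.weights is not None else np.full(n_points, DEFAULT_SIGMA)
        resid = (k @ alpha - curve.values) / sigma
        return MemSolution(
            grid=grid,
            amplitudes=alpha,
            rho=rho,
            entropy=shannon_jaynes_entropy(rho),
            chi_squared=float(resid @ resid),
            converged=True,
            chi2_target=chi2_target,
        )

    if curve.weights is not None:
        sigma = curve.weights
    else:
        warnings.warn(
            "curve carries no per-point sd; assuming constant sigma = "
            f"{DEFAULT_SIGMA}",
            stacklevel=2,
        )
        sigma = np.full(n_points, DEFAULT_SIGMA)

    k = _design_matrix(curve.lags, grid, gamma, triplet)
    y = curve.values
    kw = k / sigma[:, None]
    yw = y / sigma
    colnorm = np.linalg.norm(kw, axis=0)
    kn = kw / colnorm

    def chi2_of(gam):
        r = kn @ gam - yw
        return float(r @ r)

    def entropy_of(gam):
        return shannon_jaynes_entropy(_rho_from_amplitudes(gam / colnorm, tau))

    # The mu -> 0 endpoint is a plain non-negative least-squares problem;
    # solve it exactly (active set): it sets the reachable chi^2 floor and
    # anchors the continuation in the entropy weight.
    gam_ls, _ = nnls(kn, yw)
    gam_ls = np.maximum(gam_ls, 1e-300)
    chi2_ls = chi2_of(gam_ls)
    if chi2_ls > chi2_target:
        warnings.warn(
            "chi-squared target unreachable even at vanishing entropy weight; "
            "returning the least-squares solution",
            stacklevel=2,
        )
        return _package(grid, gam_ls, colnorm, kn, yw, tau, chi2_target, converged=False)

    # Walk mu upward geometrically, warm-starting each solve, so every
    # inner problem is a small perturbation of the previous one.  Track the
    # highest-entropy solution that still satisfies chi^2 <= target.
    best_gam, best_s = gam_ls, entropy_of(gam_ls)
    mu_ladder = np.geomspace(1e-8, 1e6, 57)
    gam = gam_ls
    bracket = None
    mu_prev = 0.0
    for mu in mu_ladder:
        gam = _solve_inner(kn, colnorm, yw, tau, mu, gam, max_inner)
        chi2 = chi2_of(gam)
        if chi2 <= chi2_target:
            s = entropy_of(gam)
            if s > best_s:
                best_gam, best_s = gam, s
            gam_feasible = gam
            mu_prev = mu
        else:
            bracket = (mu_prev, mu)
            break

    if bracket is not None:
        # Refine the crossing point; each trial restarts from the feasible
        # side of the bracket.
        mu_lo, mu_hi = max(bracket[0], 1e-10), bracket[1]
        gam_feasible = best_gam if bracket[0] == 0.0 else gam_feasible
        for _ in range(max_bisection):
            if mu_hi / mu_lo < 1.0 + 1e-6:
                break
            mu_mid = np.sqrt(mu_lo * mu_hi)
            gam_mid = _solve_inner(kn, colnorm, yw, tau, mu_mid, gam_feasible, max_inner)
            chi2_mid = chi2_of(gam_mid)
            if chi2_mid <= chi2_target:
                s = entropy_of(gam_mid)
                if s > best_s:
                    best_gam, best_s = gam_mid, s
                gam_feasible, mu_lo = gam_mid, mu_mid
            else:
                mu_hi = mu_mid
        # Final polish at the feasible end of the bracket.
        gam_fin = _solve_inner(kn, colnorm, yw, tau, mu_lo, best_gam, 3 * max_inner)
        if chi2_of(gam_fin) <= chi2_target:
            s = entropy_of(gam_fin)
            if s > best_s:
                best_gam, best_s = gam_fin, s
    return _package(grid, best_gam, colnorm, kn, yw, tau, chi2_target, converged=True)


def _package(grid, gam, colnorm, kn, yw, tau, chi2_target, converged):
    alpha = gam / colnorm
    rho = _rho_from_amplitudes(alpha, tau)
    r = kn @ gam - yw
    return MemSolution(
        grid=grid,
        amplitudes=alpha,
        rho=rho,
        entropy=shannon_jaynes_entropy(rho),
        chi_squared=float(r @ r),
        converged=converged,
        chi2_target=float(chi2_target),
    )


def detect_modes(sol: MemSolution, prominence_fraction: float = 0.05) -> np.ndarray:
    """Diffusion times of local rho maxima (prominence >= 5% of max rho).

    Ties in peak height are broken toward slower diffusion (larger species).
    """
    rho = sol.rho
    idx, _ = find_peaks(rho, prominence=prominence_fraction * rho.max())
    if idx.size == 0 and rho.size:
        idx = np.array([int(np.nonzero(rho == rho.max())[0][-1])])
    return sol.grid.tau_grid[idx]


def split_populations(
    sol: MemSolution,
    focal: FocalVolume,
    cutoff_d: float = DEFAULT_CUTOFF_D,
    *,
    force: bool = False,
) -> PopulationSummary:
    """Split a MEM distribution into monomer (D > cutoff) and oligomer pools.

    Each grid point maps to a diffusion coefficient through the calibrated
    focal volume; rho mass is integrated on either side of ``cutoff_d``
    (default 150 µm²/s) and the modal diffusivity (grid point of maximal
    rho) is reported per population.
    """
    if not sol.converged and not force:
        raise ValueError("MEM solution did not converge; pass force=True to split anyway")
    d = diffusion_coefficient(sol.grid.tau_grid, focal)
    monomer = d > cutoff_d
    rho = sol.rho
    mono_frac = float(rho[monomer].sum())
    oligo_frac = float(rho[~monomer].sum())

    def modal(mask):
        if not mask.any() or rho[mask].sum() == 0:
            return float("nan")
        sub = np.where(mask, rho, -np.inf)
        # ties broken toward slower diffusion = larger tau = later index
        best = np.nonzero(sub == sub.max())[0][-1]
        return float(d[best])

    return PopulationSummary(
        monomer_fraction=mono_frac,
        oligomer_fraction=oligo_frac,
        modal_d_monomer=modal(monomer),
        modal_d_oligomer=modal(~monomer),
        cutoff_d=float(cutoff_d),
    )
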