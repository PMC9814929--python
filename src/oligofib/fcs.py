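"""Forward model for confocal FCS autocorrelation curves.

A fluorescent species diffusing in three dimensions through a Gaussian
focal volume contributes

    G_i(tau) = alpha_i * (1 + tau/tau_Di)^-1 * (1 + tau/(gamma^2 tau_Di))^-1/2

to the intensity autocorrelation, where ``tau_Di`` is the diffusion
(residence) time in the focal volume, ``gamma`` the axial/lateral aspect
ratio of the volume (~6 for a common confocal microscope) and ``alpha_i``
the relative amplitude of the component.  The diffusion coefficient
follows from the calibrated lateral focal radius ``w_xy`` as

    D = w_xy^2 / (4 tau_D).

Internal units: seconds for lag times and diffusion times, micrometres
for ``w_xy``, µm²/s for diffusion coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "AutocorrelationCurve",
    "ComponentDistribution",
    "TripletParams",
    "FocalVolume",
    "CalibrationError",
    "model_autocorrelation",
    "diffusion_coefficient",
    "diffusion_time",
    "calibrate_focal_volume",
]

#: Reference diffusion coefficient of the Alexa-647 calibration dye at 25 C,
#: in µm²/s.
ALEXA647_D = 330.0


class CalibrationError(RuntimeError):
    """Raised when the single-component calibration fit fails to converge."""


@dataclass(frozen=True)
class AutocorrelationCurve:
    """A measured or synthetic autocorrelation curve G(tau).

    Parameters
    ----------
    lags
        Lag times in seconds, strictly increasing, all positive.
    values
        Dimensionless correlation amplitudes G(tau).
    weights
        Optional per-point standard deviations of ``values``.
    normalized
        Whether the curve was amplitude-normalized so that G(0+) = 1.
    """

    lags: np.ndarray
    values: np.ndarray
    weights: np.ndarray | None = None
    normalized: bool = True

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.ndim != 1 or values.shape != lags.shape:
            raise ValueError("lags and values must be 1-D arrays of equal length")
        if not np.all(lags > 0):
            raise ValueError("lag times must be positive")
        if not np.all(np.diff(lags) > 0):
            raise ValueError("lag times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("G values must be finite")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != lags.shape:
                raise ValueError("weights must match lags in length")
            if not np.all(w > 0):
                raise ValueError("weights (standard deviations) must be positive")

    def __len__(self) -> int:
        return self.lags.size


@dataclass(frozen=True)
class ComponentDistribution:
    """A discrete set of diffusing species defining a multi-component model.

    ``components`` is a sequence of ``(amplitude, diffusion_time_s)`` pairs;
    amplitudes are relative (curves are typically normalized so they sum
    to one) and diffusion times must be positive and distinct.
    """

    components: tuple[tuple[float, float], ...]
    aspect_ratio: float = 6.0

    def __post_init__(self):
        comps = tuple((float(a), float(t)) for a, t in self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) == 0:
            raise ValueError("at least one component is required")
        for a, t in comps:
            if a < 0:
                raise ValueError("component amplitudes must be non-negative")
            if t <= 0:
                raise ValueError("diffusion times must be positive")
        taus = [t for _, t in comps]
        if len(set(taus)) != len(taus):
            raise ValueError("diffusion times must be distinct within a model")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect ratio must be positive")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def diffusion_times(self) -> np.ndarray:
        return np.array([t for _, t in self.components])


@dataclass(frozen=True)
class TripletParams:
    """Triplet-state blinking correction.

    The diffusion sum is multiplied by ``1 + T/(1-T) * exp(-tau/tau_T)``;
    ``fraction`` T = 0 disables the correction.
    """

    fraction: float = 0.0
    relaxation_time: float = 1e-6

    def __post_init__(self):
        if not (0.0 <= self.fraction < 1.0):
            raise ValueError("triplet fraction must lie in [0, 1)")
        if self.relaxation_time <= 0:
            raise ValueError("triplet relaxation time must be positive")

    def factor(self, lags: np.ndarray) -> np.ndarray:
        if self.fraction == 0.0:
            return np.ones_like(np.asarray(lags, dtype=float))
        T = self.fraction
        return 1.0 + T / (1.0 - T) * np.exp(-np.asarray(lags, float) / self.relaxation_time)


@dataclass(frozen=True)
class FocalVolume:
    """Calibrated lateral radius of the confocal focal volume, in µm."""

    lateral_radius: float

    def __post_init__(self):
        if self.lateral_radius <= 0:
            raise ValueError("lateral radius must be positive")


def single_component_g(lags, tau_d, gamma=6.0):
    """Unit-amplitude 3D-diffusion autocorrelation of one species."""
    lags = np.asarray(lags, dtype=float)
    if np.any(lags <= 0):
        raise ValueError("lag times must be positive")
    if tau_d <= 0:
        raise ValueError("diffusion time must be positive")
    x = lags / tau_d
    return 1.0 / (1.0 + x) / np.sqrt(1.0 + x / gamma**2)


def model_autocorrelation(
    lags,
    model: ComponentDistribution,
    triplet: TripletParams | None = None,
) -> np.ndarray:
    """Evaluate the multi-component 3D-diffusion model G(tau).

    With a non-zero triplet fraction the diffusion sum is multiplied by the
    standard triplet correction factor.  ``G(0+)`` equals the sum of the
    component amplitudes.
    """
    lags = np.asarray(lags, dtype=float)
    if np.any(lags <= 0):
        raise ValueError("lag times must be positive")
    g = np.zeros_like(lags)
    for a, tau_d in model.components:
        g += a * single_component_g(lags, tau_d, model.aspect_ratio)
    if triplet is not None:
        g *= triplet.factor(lags)
    return g


def diffusion_coefficient(tau_d: float, focal: FocalVolume):
    """Convert a diffusion time (s) to a diffusion coefficient (µm²/s)."""
    tau_d = np.asarray(tau_d, dtype=float)
    if np.any(tau_d <= 0):
        raise ValueError("diffusion time must be positive")
    return focal.lateral_radius**2 / (4.0 * tau_d)


def diffusion_time(d: float, focal: FocalVolume):
    """Inverse of :func:`diffusion_coefficient`: D (µm²/s) to tau_D (s)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diffusion coefficient must be positive")
    return focal.lateral_radius**2 / (4.0 * d)


def calibrate_focal_volume(
    curve: AutocorrelationCurve,
    d_ref: float = ALEXA647_D,
    gamma: float = 6.0,
    triplet: TripletParams | None = None,
) -> FocalVolume:
    """Calibrate w_xy from a single-species reference-dye curve.

    Fits the single-component model for ``tau_D`` (least squares, with the
    diffusion time initialized at the lag of half amplitude) and returns
    ``w_xy = sqrt(4 * d_ref * tau_D)``.

    Parameters
    ----------
    curve
        Autocorrelation curve of the calibration dye.
    d_ref
        Reference diffusion coefficient of the dye in µm²/s
        (Alexa-647: 330 µm²/s at 25 C).
    """
    lags, g = curve.lags, curve.values

    amp0 = float(g[0])
    half = amp0 / 2.0
    below = np.nonzero(g <= half)[0]
    tau0 = float(lags[below[0]]) if below.size else float(np.sqrt(lags[0] * lags[-1]))

    params = lmfit.Parameters()
    params.add("amplitude", value=amp0, min=0.0)
    params.add("log_tau", value=np.log(tau0))

    def residual(p):
        tau_d = np.exp(p["log_tau"].value)
        model = p["amplitude"].value * single_component_g(lags, tau_d, gamma)
        if triplet is not None:
            model = model * triplet.factor(lags)
        r = model - g
        if curve.weights is not None:
            r = r / curve.weights
        return r

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise CalibrationError(
            f"single-component calibration fit did not converge: {result.message}"
        )
    tau_d = float(np.exp(result.params["log_tau"].value))
    if not (lags[0] / 10 < tau_d < lags[-1] * 10):
        warnings.warn(
            "calibrated diffusion time lies outside the measured lag range",
            stacklevel=2,
        )
    # d_ref (µm²/s) * tau_d (s) -> µm², so w_xy comes out in µm directly
    w_xy = float(np.sqrt(4.0 * d_ref * tau_d))
    return FocalVolume(lateral_radius=w_xy)
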