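"""Hydrodynamics of the bead and of the membrane connection.

Forward models: the Stokes-Einstein relation D = k_B T / (6 pi eta r)
(with the lumped near-wall hindrance factor ~3), and the Evans-Sackmann
drag of a disk-like inclusion of radius r moving in a supported membrane
separated from the substrate by a thin water gap,

    gamma_m(r) = 4 pi eta_m [ eps^2 / 4 + eps K_1(eps) / K_0(eps) ],
    eps = r sqrt(mu_w / (h_g eta_m)),

where eta_m = h_m mu_m is the 2-D membrane viscosity and K_0, K_1 are
modified Bessel functions of the second kind.  An ``eight_pi`` variant
doubles the prefactor, reading the stalk as moving through two membrane
monolayers rather than one bilayer; both are exposed because the constant
in front of this drag is the least certain part of the model (the
inversion of a measured D_m to a radius shifts by roughly a factor of two
between them).

Inverse model: gamma_m(r) is strictly increasing, so D(r) = k_B T /
gamma_m(r) is strictly decreasing and the radius follows from a measured
D_m by bracketed root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import kve

from .trajectory import KB

PREFACTOR = {"four_pi": 4.0 * math.pi, "eight_pi": 8.0 * math.pi}


@dataclass(frozen=True)
class MembraneParams:
    """Everything the Evans-Sackmann inversion needs.

    Defaults are the DOPC-on-glass values: bilayer thickness
    ``h_m = 4.5 nm``, 3-D membrane viscosity ``mu_m = 0.11 Pa s`` (hence
    2-D viscosity ``eta_m = h_m mu_m = 4.95e-10 Pa s m``), water gap
    ``h_g = 0.4 nm`` and water viscosity ``mu_w = 1e-3 Pa s`` at 295 K.
    """

    h_m: float = 4.5e-9
    mu_m: float = 0.11
    eta_m: float | None = None
    h_g: float = 0.4e-9
    mu_w: float = 1e-3
    temperature: float = 295.0
    prefactor_variant: str = "four_pi"

    def __post_init__(self) -> None:
        if self.eta_m is None:
            object.__setattr__(self, "eta_m", self.h_m * self.mu_m)
        for name in ("h_m", "mu_m", "eta_m", "h_g", "mu_w", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.prefactor_variant not in PREFACTOR:
            raise ValueError(
                f"prefactor_variant must be one of {tuple(PREFACTOR)}"
            )

    def epsilon(self, radius: float) -> float:
        """Dimensionless screening parameter eps(r) = r sqrt(mu_w/(h_g eta_m))."""
        return radius * math.sqrt(self.mu_w / (self.h_g * self.eta_m))


@dataclass
class ContactRadiusResult:
    """Radius of the membrane connection inverted from a measured D_m."""

    radius: float  # nm
    d_m: float  # um^2/s, the input
    gamma_m: float  # N s/m
    variant: str
    epsilon: float
    iterations: int
    converged: bool


def stokes_einstein_diffusion(
    radius: float,
    viscosity: float,
    temperature: float,
    hindrance_factor: float = 1.0,
) -> float:
    """D = k_B T / (6 pi eta r * hindrance_factor), m^2/s.

    ``hindrance_factor = 3`` gives the lumped near-wall diffusion constant
    (about a third of the bulk value).
    """
    if radius <= 0 or viscosity <= 0 or temperature <= 0 or hindrance_factor <= 0:
        raise ValueError("all arguments must be positive")
    return KB * temperature / (6.0 * math.pi * viscosity * radius * hindrance_factor)


def _bessel_ratio(eps: float) -> float:
    """K_1(eps)/K_0(eps) via exponentially scaled functions.

    The e^eps factors cancel, so the ratio is stable over the whole
    eps in [1e-6, 1e3] range (and beyond) without overflow.
    """
    return float(kve(1, eps) / kve(0, eps))


def evans_sackmann_drag(radius: float, params: MembraneParams) -> float:
    """Drag gamma_m(r) of a disk in a substrate-coupled membrane, N s/m."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    eps = params.epsilon(radius)
    bracket = eps**2 / 4.0 + eps * _bessel_ratio(eps)
    return PREFACTOR[params.prefactor_variant] * params.eta_m * bracket


def evans_sackmann_diffusion(radius: float, params: MembraneParams) -> float:
    """D(r) = k_B T / gamma_m(r), m^2/s; strictly decreasing in r."""
    return KB * params.temperature / evans_sackmann_drag(radius, params)


def invert_contact_radius(
    d_m: float,
    params: MembraneParams,
    r_min: float = 1e-10,
    r_max: float = 1e-5,
) -> ContactRadiusResult:
    """Radius of the membrane connection from the measured D_m (um^2/s).

    Solves D(r) = D_m on ``[r_min, r_max]`` metres by Brent's method; the
    strict monotonicity of D(r) guarantees a unique root.
    """
    if d_m <= 0:
        raise ValueError("D_m must be positive")
    d_target = d_m * 1e-12  # um^2/s -> m^2/s
    d_lo = evans_sackmann_diffusion(r_max, params)
    d_hi = evans_sackmann_diffusion(r_min, params)
    if not d_lo <= d_target <= d_hi:
        raise ValueError(
            f"D_m = {d_m:g} um^2/s outside the invertible bracket: "
            f"D({r_min:g} m) = {d_hi * 1e12:g}, "
            f"D({r_max:g} m) = {d_lo * 1e12:g} um^2/s"
        )

    def objective(log_r: float) -> float:
        return evans_sackmann_diffusion(math.exp(log_r), params) - d_target

    # solve on a slightly widened bracket so a D_m equal to an endpoint
    # value (to rounding) still straddles a sign change
    log_root, info = brentq(
        objective,
        math.log(r_min) - 0.1,
        math.log(r_max) + 0.1,
        xtol=1e-14,
        rtol=8.9e-16,
        maxiter=200,
        full_output=True,
    )
    radius = math.exp(log_root)
    return ContactRadiusResult(
        radius=radius * 1e9,
        d_m=d_m,
        gamma_m=KB * params.temperature / d_target,
        variant=params.prefactor_variant,
        epsilon=params.epsilon(radius),
        iterations=info.iterations,
        converged=info.converged,
    )


def geometric_contact_radius(bead_radius: float, submersion_depth: float) -> float:
    """Chord radius of a sphere submerged by ``submersion_depth`` in a plane.

    r = sqrt(2 R h - h^2); for the 0.485 um bead submerged by one bilayer
    thickness (4.5 nm) this is ~66 nm, the geometric upper estimate for the
    hemifusion-diaphragm radius.  Units follow the inputs.
    """
    if bead_radius <= 0:
        raise ValueError("bead_radius must be positive")
    if not 0.0 <= submersion_depth <= 2.0 * bead_radius:
        raise ValueError("submersion depth must be within [0, 2 R]")
    return math.sqrt(2.0 * bead_radius * submersion_depth - submersion_depth**2)


def area_mismatch(delta_t: float, area_expansivity: float = 5e-3) -> float:
    """Fractional membrane/substrate area mismatch for a temperature change.

    ``area_expansivity`` defaults to 5e-3 per kelvin, i.e. ~5% mismatch for
    a 10 degC preparation/experiment temperature difference — the handle
    that sets membrane tension and hence fusion propensity in the assay.
    """
    if area_expansivity <= 0:
        raise ValueError("area_expansivity must be positive")
    return area_expansivity * abs(delta_t)
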