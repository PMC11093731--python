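"""Leaf-level radiative transfer: generalized plate model.

The leaf is modelled as ``N`` compact layers (plates) separated by air
spaces.  A single plate combines Fresnel reflection at rough air/cell
interfaces with Beer-Lambert absorption along the internal path; the stack
of ``N`` plates is then solved with the classical Stokes system.  Inputs
are the six familiar biochemical drivers: structure parameter N,
chlorophyll a+b, carotenoids, brown pigment, equivalent water thickness and
dry matter content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import exp1

from .optics import WAVELENGTHS, optical_constants


@dataclass(frozen=True)
class LeafParams:
    """Leaf biochemical and structural inputs.

    Defaults are the fixed values used throughout the retrieval
    (N 1.5, Cab 40 ug cm-2, Car 10 ug cm-2, Cbrown 0, Cw 0.01 cm,
    Cm 0.009 g cm-2).
    """

    n_layers: float = 1.5  # leaf structure parameter N, dimensionless
    cab: float = 40.0      # chlorophyll a+b, ug cm-2
    car: float = 10.0      # carotenoids, ug cm-2
    cbrown: float = 0.0    # brown pigment, arbitrary units
    cw: float = 0.01       # equivalent water thickness, cm
    cm: float = 0.009      # dry matter, g cm-2

    def __post_init__(self) -> None:
        if self.n_layers < 1.0:
            raise ValueError(f"leaf structure parameter N must be >= 1, got {self.n_layers}")
        for name in ("cab", "car", "cbrown", "cw", "cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SpectralSample:
    """Hemispherical reflectance (and optionally transmittance) on the
    400-2500 nm, 1 nm grid."""

    reflectance: np.ndarray
    transmittance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.reflectance.shape != WAVELENGTHS.shape:
            raise ValueError("reflectance must be on the 2101-point 400-2500 nm grid")
        if self.transmittance is not None and self.transmittance.shape != WAVELENGTHS.shape:
            raise ValueError("transmittance must be on the 2101-point 400-2500 nm grid")


def average_transmissivity(alpha_deg: float, n: np.ndarray) -> np.ndarray:
    """Transmissivity of a dielectric interface averaged over incidence
    angles within a cone of half-angle ``alpha_deg``.

    Computed by numerical quadrature of the unpolarized Fresnel
    transmissivity weighted by the solid-angle measure sin(t)cos(t)dt.
    """
    theta = np.linspace(0.0, np.radians(alpha_deg), 181)[:, None]
    n = np.asarray(n, dtype=float)[None, :]
    sin_t = np.sin(theta)
    # refraction angle; total internal reflection cannot occur entering the denser medium
    sin_r = sin_t / n
    cos_t = np.cos(theta)
    cos_r = np.sqrt(1.0 - sin_r**2)
    rs = ((cos_t - n * cos_r) / (cos_t + n * cos_r)) ** 2
    rp = ((n * cos_t - cos_r) / (n * cos_t + cos_r)) ** 2
    trans = 1.0 - 0.5 * (rs + rp)
    w = (sin_t * cos_t).ravel()
    return np.trapezoid(trans * w[:, None], theta.ravel(), axis=0) / np.trapezoid(
        w, theta.ravel()
    )


def _plate_transmission(k: np.ndarray) -> np.ndarray:
    # isotropic transmission through one absorbing plate:
    # tau(k) = (1-k) e^{-k} + k^2 E1(k), tau(0) = 1
    tau = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    tau[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return tau


def prospect_leaf(params: LeafParams | None = None) -> SpectralSample:
    """Simulate leaf hemispherical reflectance and transmittance.

    Parameters default to the fixed retrieval values.  The return satisfies
    the energy bound R + T <= 1 at every wavelength.
    """
    if params is None:
        params = LeafParams()
    const = optical_constants()
    n = const["n"]

    k = (
        params.cab * const["kab"]
        + params.car * const["kcar"]
        + params.cbrown * const["kbrown"]
        + params.cw * const["kw"]
        + params.cm * const["km"]
    ) / params.n_layers
    tau = _plate_transmission(k)

    # one plate with a rough upper surface (40 degree incidence cone)
    talf = average_transmissivity(40.0, n)
    ralf = 1.0 - talf
    t12 = average_transmissivity(90.0, n)
    r12 = 1.0 - t12
    t21 = t12 / n**2
    r21 = 1.0 - t21

    denom = 1.0 - r21**2 * tau**2
    Ta = talf * tau * t21 / denom
    Ra = ralf + r21 * tau * Ta
    t = t12 * tau * t21 / denom
    r = r12 + r21 * tau * t

    # Stokes solution for the remaining N-1 plates
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.sqrt(
            np.maximum((1 + r + t) * (1 + r - t) * (1 - r + t) * (1 - r - t), 0.0)
        )
        a = np.where(r > 0, (1 + r**2 - t**2 + D) / (2 * np.maximum(r, 1e-30)), 1.0)
        b = np.where(t > 0, (1 - r**2 + t**2 + D) / (2 * np.maximum(t, 1e-30)), 1.0)

        bNm1 = b ** (params.n_layers - 1.0)
        bN2 = bNm1**2
        a2 = a**2
        denom2 = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / denom2
        Tsub = bNm1 * (a2 - 1.0) / denom2

    # conservative-scattering limit (r + t -> 1): geometric-series form
    conservative = (r + t) >= 1.0 - 1e-9
    if np.any(conservative):
        tc = t[conservative]
        Tsub[conservative] = tc / (tc + (1.0 - tc) * (params.n_layers - 1.0))
        Rsub[conservative] = 1.0 - Tsub[conservative]

    denom3 = 1.0 - Rsub * r
    transmittance = Ta * Tsub / denom3
    reflectance = Ra + Ta * Rsub * t / denom3
    return SpectralSample(
        reflectance=np.clip(reflectance, 0.0, 1.0),
        transmittance=np.clip(transmittance, 0.0, 1.0),
    )
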