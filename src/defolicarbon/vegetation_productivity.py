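"""Vegetation indices and light-use-efficiency GPP.

Daily gross primary productivity is modelled as

    GPP = PAR x fPARchl x eps0 x Tscalar x Wscalar x 12.011   [g C m-2 d-1]

with PAR in mol photons m-2 d-1, fPARchl a linear function of EVI
(fPARchl = (EVI - 0.1) x 1.25, clamped to [0, 1]), eps0 the apparent
quantum yield (mol CO2 per mol photons), and temperature/water
down-regulation scalars in [0, 1].  eps0 is calibrated as the
through-origin least-squares slope of tower GPP on the modelled driver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CARBON_MOLAR_MASS = 12.011  # g C per mol CO2


@dataclass(frozen=True)
class LUEParams:
    """Light-use-efficiency model parameters.

    Temperature limits default to conventional temperate-forest values
    (Tmin 0, Topt 20, Tmax 40 degC); eps0 defaults to 0.05 mol mol-1 and is
    normally replaced by :func:`calibrate_epsilon0`.
    """

    epsilon0: float = 0.05  # mol CO2 per mol photons (apparent quantum yield)
    tmin: float = 0.0
    tmax: float = 40.0
    topt: float = 20.0
    lswi_max: float = 0.6

    def __post_init__(self) -> None:
        if not self.tmin < self.topt < self.tmax:
            raise ValueError("require tmin < topt < tmax")
        if self.epsilon0 <= 0:
            raise ValueError("epsilon0 must be positive")
        if not -1.0 <= self.lswi_max <= 1.0:
            raise ValueError("lswi_max must lie in [-1, 1]")


def _normalized_difference(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0.0, (a - b) / np.where(denom != 0, denom, 1.0), np.nan)
    return out if out.ndim else float(out)


def ndvi(r_nir, r_red):
    """(NIR - red) / (NIR + red); NaN where both bands are zero."""
    return _normalized_difference(r_nir, r_red)


def lswi(r_nir, r_swir):
    """(NIR - SWIR) / (NIR + SWIR); NaN where both bands are zero."""
    return _normalized_difference(r_nir, r_swir)


def evi(r_nir, r_red, r_blue):
    """2.5 (NIR - red) / (NIR + 6 red - 7.5 blue + 1); NaN when the
    denominator is not positive."""
    r_nir = np.asarray(r_nir, dtype=float)
    r_red = np.asarray(r_red, dtype=float)
    r_blue = np.asarray(r_blue, dtype=float)
    denom = r_nir + 6.0 * r_red - 7.5 * r_blue + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            denom > 0.0, 2.5 * (r_nir - r_red) / np.where(denom > 0, denom, 1.0), np.nan
        )
    return out if out.ndim else float(out)


def fpar_chl(evi_value):
    """Fraction of PAR absorbed by chlorophyll: (EVI - 0.1) x 1.25 in [0, 1]."""
    out = np.clip((np.asarray(evi_value, dtype=float) - 0.1) * 1.25, 0.0, 1.0)
    return out if out.ndim else float(out)


def t_scalar(ta, params: LUEParams):
    """Temperature down-regulation scalar in [0, 1]; zero outside [Tmin, Tmax]."""
    ta = np.asarray(ta, dtype=float)
    num = (ta - params.tmin) * (ta - params.tmax)
    denom = num - (ta - params.topt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0.0, num / np.where(denom != 0, denom, 1.0), 1.0)
    out = np.where((ta < params.tmin) | (ta > params.tmax), 0.0, out)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def w_scalar(lswi_value, lswi_max):
    """Water down-regulation scalar (1 + LSWI) / (1 + LSWImax) in [0, 1];
    NaN when LSWImax = -1."""
    lswi_value = np.asarray(lswi_value, dtype=float)
    lswi_max = np.asarray(lswi_max, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            lswi_max > -1.0,
            (1.0 + lswi_value) / np.where(lswi_max > -1.0, 1.0 + lswi_max, 1.0),
            np.nan,
        )
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def par_flux_to_daily_mol(ppfd_umol_m2_s):
    """Convert a daily-mean photon flux density (umol m-2 s-1) to a daily
    photon dose (mol m-2 d-1)."""
    return np.asarray(ppfd_umol_m2_s, dtype=float) * 86400.0 / 1e6


def gpp_driver(par_mol, evi_value, ta, lswi_value, params: LUEParams):
    """Model driver with unit quantum yield: PAR x fPARchl x Tscalar x
    Wscalar x 12.011.  Multiplying by eps0 gives GPP in g C m-2 d-1."""
    return (
        np.asarray(par_mol, dtype=float)
        * fpar_chl(evi_value)
        * t_scalar(ta, params)
        * w_scalar(lswi_value, params.lswi_max)
        * CARBON_MOLAR_MASS
    )


def gpp_daily(par_mol, evi_value, ta, lswi_value, params: LUEParams):
    """Daily GPP, g C m-2 d-1 (non-negative; NaN propagates from inputs)."""
    out = params.epsilon0 * gpp_driver(par_mol, evi_value, ta, lswi_value, params)
    out = np.maximum(out, 0.0)
    return out if np.ndim(out) else float(out)


def calibrate_epsilon0(
    tower_gpp: np.ndarray, driver: np.ndarray, min_pairs: int = 30
) -> float:
    """Apparent quantum yield from paired tower GPP and model driver days.

    Through-origin ordinary least squares: eps0 = sum(d*g) / sum(d^2) over
    days where both are finite.  Requires at least ``min_pairs`` pairs and a
    non-degenerate driver.
    """
    g = np.asarray(tower_gpp, dtype=float)
    d = np.asarray(driver, dtype=float)
    ok = np.isfinite(g) & np.isfinite(d)
    g, d = g[ok], d[ok]
    if g.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} paired days, got {g.size}")
    ss = float(np.sum(d * d))
    if ss <= 0.0:
        raise ValueError("degenerate (all-zero) model driver")
    return float(np.sum(d * g) / ss)
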