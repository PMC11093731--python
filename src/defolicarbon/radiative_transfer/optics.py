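"""Synthetic spectral constants for the leaf/canopy radiative-transfer chain.

Everything in this module is *synthetic*: smooth analytic stand-ins for the
published leaf specific-absorption coefficients, leaf refractive index and a
dry-soil background spectrum, generated on the fixed 400-2500 nm, 1 nm grid.
They reproduce the qualitative spectral physics that the retrieval relies on
(chlorophyll absorption in the blue and red, water absorption bands near
1450/1940 nm, dry-matter absorption rising into the SWIR, a bright NIR
plateau) without bundling any external data table.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Fixed wavelength grid, nm (2101 points, 1 nm step).
WL_MIN = 400
WL_MAX = 2500
WAVELENGTHS = np.arange(WL_MIN, WL_MAX + 1, dtype=float)
N_WAVELENGTHS = WAVELENGTHS.size


def _gauss(wl: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / width) ** 2)


@lru_cache(maxsize=1)
def optical_constants() -> dict[str, np.ndarray]:
    """Synthetic leaf optical constants on the 1 nm grid.

    Returns a dict with keys:

    ``n``
        leaf refractive index (dimensionless, ~1.5 in the visible,
        declining into the SWIR);
    ``kab``
        specific absorption of chlorophyll a+b, cm2 ug-1 (blue and red
        peaks, transparent beyond ~750 nm);
    ``kcar``
        specific absorption of carotenoids, cm2 ug-1 (blue only);
    ``kbrown``
        absorption per unit brown-pigment (arbitrary units), decaying
        from the blue edge;
    ``kw``
        specific absorption of liquid water, cm-1 (overtones at 970,
        1200, 1450, 1940 nm and the 2500 nm edge);
    ``km``
        specific absorption of dry matter, cm2 g-1 (rising into the SWIR).
    """
    wl = WAVELENGTHS
    n = 1.52 - 0.12 * (wl - WL_MIN) / (WL_MAX - WL_MIN)

    kab = (
        _gauss(wl, 430.0, 30.0, 0.065)
        + _gauss(wl, 605.0, 30.0, 0.018)
        + _gauss(wl, 668.0, 24.0, 0.100)
    )
    kab[wl > 780.0] = 0.0

    kcar = _gauss(wl, 450.0, 28.0, 0.055) + _gauss(wl, 482.0, 22.0, 0.045)
    kcar[wl > 560.0] = 0.0

    kbrown = 1.2 * np.exp(-(wl - WL_MIN) / 350.0)

    kw = (
        _gauss(wl, 970.0, 35.0, 0.45)
        + _gauss(wl, 1200.0, 45.0, 1.2)
        + _gauss(wl, 1450.0, 55.0, 32.0)
        + _gauss(wl, 1940.0, 85.0, 125.0)
        + _gauss(wl, 2500.0, 160.0, 85.0)
    )

    km = 0.6 + 45.0 / (1.0 + np.exp(-(wl - 1500.0) / 180.0))

    return {"n": n, "kab": kab, "kcar": kcar, "kbrown": kbrown, "kw": kw, "km": km}


@lru_cache(maxsize=1)
def default_soil_spectrum() -> np.ndarray:
    """Synthetic dry-soil background reflectance on the 1 nm grid.

    A smoothly brightening curve typical of bare dry soil, with shallow
    water-absorption dips; values stay well inside [0, 1].
    """
    wl = WAVELENGTHS
    rho = 0.12 + 0.20 * (1.0 - np.exp(-(wl - WL_MIN) / 900.0))
    rho -= _gauss(wl, 1450.0, 70.0, 0.05) + _gauss(wl, 1940.0, 100.0, 0.08)
    return np.clip(rho, 0.02, 0.95)
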