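"""Sensor band convolution and the LAI lookup table.

A band reflectance is the spectral-response-weighted mean of the simulated
hyperspectral reflectance over 400-2500 nm, evaluated as a plain weighted
sum on the 1 nm grid.  The lookup table tabulates band reflectance versus
LAI with every other leaf/canopy parameter held at its fixed value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .optics import WAVELENGTHS
from .prospect import LeafParams, SpectralSample, prospect_leaf
from .sail import CanopyParams, sail_canopy

BAND_ORDER = ("blue", "red", "nir", "swir")


@dataclass(frozen=True)
class SpectralResponse:
    """Per-band spectral response coefficients on the 1 nm grid."""

    bands: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for label, psi in self.bands.items():
            psi = np.asarray(psi, dtype=float)
            if psi.shape != WAVELENGTHS.shape:
                raise ValueError(f"band {label!r}: response not on the 1 nm grid")
            if np.any(psi < 0):
                raise ValueError(f"band {label!r}: response coefficients must be >= 0")
            if not np.any(psi > 0):
                raise ValueError(f"band {label!r}: all-zero spectral response")


def gaussian_srf(center_nm: float, fwhm_nm: float) -> np.ndarray:
    """Gaussian response curve centred at ``center_nm`` on the 1 nm grid."""
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((WAVELENGTHS - center_nm) / sigma) ** 2)


def sentinel2_like_srf() -> SpectralResponse:
    """Synthetic Gaussian response set at the Sentinel-2 blue/red/NIR/SWIR
    band centres (B2/B4/B8/B11) with their nominal widths.

    These are analytic stand-ins, not the instrument's measured response
    tables; band centres and FWHMs follow the published band definitions.
    """
    return SpectralResponse(
        bands={
            "blue": gaussian_srf(492.4, 66.0),
            "red": gaussian_srf(664.6, 31.0),
            "nir": gaussian_srf(832.8, 106.0),
            "swir": gaussian_srf(1613.7, 91.0),
        }
    )


def band_convolve(spectrum: SpectralSample, srf: SpectralResponse) -> dict[str, float]:
    """Response-weighted mean reflectance per band.

    Implements the discrete form sum(rho * psi) / sum(psi) over the
    400-2500 nm grid.
    """
    rho = np.asarray(spectrum.reflectance, dtype=float)
    out: dict[str, float] = {}
    for label, psi in srf.bands.items():
        out[label] = float(np.sum(rho * psi) / np.sum(psi))
    return out


def load_srf_csv(path) -> SpectralResponse:
    """Read a response table CSV with columns (wavelength_nm, band, response)."""
    df = pd.read_csv(path)
    bands = {}
    for label, grp in df.groupby("band"):
        psi = np.zeros_like(WAVELENGTHS)
        idx = grp["wavelength_nm"].to_numpy().astype(int) - int(WAVELENGTHS[0])
        psi[idx] = grp["response"].to_numpy()
        bands[str(label)] = psi
    return SpectralResponse(bands=bands)


def write_srf_csv(srf: SpectralResponse, path) -> None:
    rows = []
    for label, psi in srf.bands.items():
        nz = psi > 0
        rows.append(
            pd.DataFrame(
                {
                    "wavelength_nm": WAVELENGTHS[nz].astype(int),
                    "band": label,
                    "response": psi[nz],
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


@dataclass(frozen=True)
class LookupTable:
    """Band reflectance tabulated against LAI (all other parameters fixed)."""

    lai: np.ndarray                  # strictly increasing grid in [0, 8]
    reflectance: np.ndarray          # shape (n_lai, n_bands), columns follow `bands`
    bands: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.reflectance, columns=list(self.bands))
        df.insert(0, "lai", self.lai)
        return df


def build_lut(
    lai_grid: np.ndarray,
    fixed_leaf: LeafParams | None = None,
    fixed_canopy: CanopyParams | None = None,
    srf: SpectralResponse | None = None,
) -> LookupTable:
    """Forward-simulate band reflectance over an LAI grid.

    The grid must be strictly increasing within [0, 8]; leaf and canopy
    parameters default to the fixed retrieval values.
    """
    lai_grid = np.asarray(lai_grid, dtype=float)
    if lai_grid.ndim != 1 or lai_grid.size == 0:
        raise ValueError("lai_grid must be a non-empty 1-D array")
    if np.any(np.diff(lai_grid) <= 0):
        raise ValueError("lai_grid must be strictly increasing")
    if lai_grid[0] < 0.0 or lai_grid[-1] > 8.0:
        raise ValueError("lai_grid must lie within [0, 8]")
    if fixed_leaf is None:
        fixed_leaf = LeafParams()
    if fixed_canopy is None:
        fixed_canopy = CanopyParams()
    if srf is None:
        srf = sentinel2_like_srf()

    leaf = prospect_leaf(fixed_leaf)
    bands = tuple(srf.bands)
    refl = np.empty((lai_grid.size, len(bands)))
    for i, lai in enumerate(lai_grid):
        spectrum = sail_canopy(leaf, replace(fixed_canopy, lai=float(lai)))
        bv = band_convolve(spectrum, srf)
        refl[i] = [bv[b] for b in bands]
    return LookupTable(lai=lai_grid, reflectance=refl, bands=bands)


def forward_bands(
    lai: float,
    leaf: LeafParams | None = None,
    canopy: CanopyParams | None = None,
    srf: SpectralResponse | None = None,
    _leaf_spectrum: SpectralSample | None = None,
) -> dict[str, float]:
    """Convenience forward model: LAI -> band reflectance at fixed parameters."""
    if srf is None:
        srf = sentinel2_like_srf()
    if canopy is None:
        canopy = CanopyParams()
    if _leaf_spectrum is None:
        _leaf_spectrum = prospect_leaf(leaf if leaf is not None else LeafParams())
    spectrum = sail_canopy(_leaf_spectrum, replace(canopy, lai=float(lai)))
    return band_convolve(spectrum, srf)
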