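"""LAI inversion against the forward-model lookup table and seasonal
aggregation of the retrieved rasters.

The inversion is an exhaustive nearest-neighbour search in band space with a
root-mean-square-error cost, ties broken toward the smaller LAI.  It is
deterministic and exact on noise-free forward simulations up to the grid
step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .radiative_transfer.bands import LookupTable

#: Growing-season window, day of year (inclusive): Apr 1 - Oct 31, non-leap.
SEASON_START_DOY = 91
SEASON_END_DOY = 304
SEASON_LENGTH = SEASON_END_DOY - SEASON_START_DOY + 1  # 214 days


@dataclass(frozen=True)
class LAIEstimate:
    lai: float
    cost: float
    valid: bool = True


def invert_lai(obs: dict[str, float], lut: LookupTable) -> LAIEstimate:
    """Invert one band-reflectance observation to LAI.

    Returns the LUT entry minimizing the RMS band residual.  Observations
    with any band outside [0, 1] are flagged invalid and carry no estimate.
    """
    if lut.lai.size == 0:
        raise ValueError("empty lookup table")
    vec = np.array([obs[b] for b in lut.bands], dtype=float)
    if np.any(vec < 0.0) or np.any(vec > 1.0) or not np.all(np.isfinite(vec)):
        return LAIEstimate(lai=np.nan, cost=np.nan, valid=False)
    cost = np.sqrt(np.mean((lut.reflectance - vec) ** 2, axis=1))
    idx = int(np.argmin(cost))  # argmin returns the first (smallest-LAI) minimum
    return LAIEstimate(lai=float(lut.lai[idx]), cost=float(cost[idx]))


def invert_lai_cube(cube: np.ndarray, lut: LookupTable) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized inversion of a reflectance array.

    ``cube`` has band as its last axis, ordered as ``lut.bands``.  Returns
    (lai, cost) arrays of the leading shape; pixels with any band outside
    [0, 1] are NaN in both.
    """
    flat = cube.reshape(-1, cube.shape[-1])
    invalid = (
        np.any(flat < 0.0, axis=1)
        | np.any(flat > 1.0, axis=1)
        | ~np.all(np.isfinite(flat), axis=1)
    )
    # distance to every LUT entry; ties resolve to the first (smaller) LAI
    d2 = ((flat[:, None, :] - lut.reflectance[None, :, :]) ** 2).mean(axis=2)
    idx = np.argmin(d2, axis=1)
    lai = lut.lai[idx].astype(float)
    cost = np.sqrt(d2[np.arange(flat.shape[0]), idx])
    lai[invalid] = np.nan
    cost[invalid] = np.nan
    shape = cube.shape[:-1]
    return lai.reshape(shape), cost.reshape(shape)


def seasonal_lai_stats(
    lai_by_class: dict[str, np.ndarray],
    doy: np.ndarray,
    year: int | str,
    season: tuple[int, int] = (SEASON_START_DOY, SEASON_END_DOY),
) -> pd.DataFrame:
    """Growing-season mean and sd of LAI per class.

    ``lai_by_class`` maps class name to an array whose first axis aligns
    with ``doy`` (remaining axes are pixels); NaNs are treated as flagged
    observations.  sd uses ddof 1 (sample statistics over pixel-dates).
    Classes with no valid observation report NaN, never zero.
    """
    lo, hi = season
    rows = []
    for cls, arr in lai_by_class.items():
        arr = np.asarray(arr, dtype=float)
        sel = (doy >= lo) & (doy <= hi)
        vals = arr[sel].ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            mean = sd = np.nan
        else:
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {"class": cls, "year": year, "mean_lai": mean, "sd_lai": sd, "n": vals.size}
        )
    return pd.DataFrame(rows)
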