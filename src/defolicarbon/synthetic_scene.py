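"""Synthetic scenes, meteorology and flux-tower GPP.

Generates everything the downstream pipeline consumes, with the statistical
structure the analysis assumes: a six-class land-cover raster, smooth
per-class double-logistic seasonal LAI trajectories (with a prescribed
mid-season defoliation notch in deciduous and mixed classes in infestation
years), multiband reflectance rendered through the forward radiative-
transfer model plus Gaussian noise, sinusoid-plus-noise meteorology, and
tower GPP equal to truth plus noise.

Class areal fractions default to the mapped composition of the Great Lakes
study region (water 7.3%, urban 10.8%, agriculture 23.7%, conifer 24.2%,
deciduous 20.5%, mixed 13.4%); the infestation notch depths default to a
25% (deciduous) and 17% (mixed) seasonal-mean LAI depression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lai_retrieval import SEASON_END_DOY, SEASON_START_DOY

CLASS_NAMES = ("water", "urban", "agriculture", "conifer", "deciduous", "mixed")

#: Mapped class areas, km2 (water, urban, agriculture, conifer, deciduous, mixed).
CLASS_AREAS_KM2 = {
    "water": 13053.0,
    "urban": 19256.0,
    "agriculture": 42294.0,
    "conifer": 43017.0,
    "deciduous": 36574.0,
    "mixed": 23936.0,
}


def _default_fractions() -> dict[str, float]:
    total = sum(CLASS_AREAS_KM2.values())
    return {k: v / total for k, v in CLASS_AREAS_KM2.items()}


@dataclass(frozen=True)
class SceneConfig:
    """Scene dimensions, composition, years and noise levels."""

    n_rows: int = 64
    n_cols: int = 64
    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    years: tuple[tuple[int, str], ...] = (
        (2020, "normal"),
        (2021, "infestation"),
        (2022, "normal"),
    )
    season_start: int = SEASON_START_DOY  # Apr 1
    season_end: int = SEASON_END_DOY      # Oct 31
    noise_sd_reflectance: float = 0.01    # unitless reflectance
    noise_sd_gpp: float = 1.0             # g C m-2 d-1
    mean_annual_ta: float = 10.6          # degC
    ta_amplitude: float = 14.0            # degC, half peak-to-trough annual cycle
    depression: dict[str, float] = field(
        default_factory=lambda: {"deciduous": 0.25, "mixed": 0.17}
    )
    infestation_onset: int = 150    # day of year defoliation starts (late May)
    infestation_recovery: int = 240 # day of year canopy has rejoined normal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("scene must have at least one row and column")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        unknown = set(self.class_fractions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if self.noise_sd_reflectance < 0 or self.noise_sd_gpp < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def rng(self, op_offset: int) -> np.random.Generator:
        # one stream per operation: reproducible without cross-op coupling
        return np.random.default_rng((self.seed + op_offset) % 2**31)


#: Per-class baseline phenology: (winter LAI, peak LAI, green-up doy,
#: senescence doy, green-up rate, senescence rate) -- all m2 m-2 and day-1.
_PHENOLOGY = {
    "water": None,
    "urban": None,
    "agriculture": (0.2, 5.6, 160.0, 280.0, 0.10, 0.08),
    "conifer": (3.9, 4.7, 120.0, 300.0, 0.05, 0.04),
    "deciduous": (0.4, 5.2, 140.0, 288.0, 0.09, 0.06),
    "mixed": (1.4, 4.3, 138.0, 290.0, 0.08, 0.06),
}


@dataclass(frozen=True)
class PhenologyTruth:
    """Daily true LAI for one class-year (365 values, m2 m-2 in [0, 8])."""

    class_name: str
    year_type: str
    lai: np.ndarray  # index 0 = day of year 1


def _double_logistic(doy, winter, peak, sos, eos, k_up, k_down):
    amp = peak - winter
    up = 1.0 / (1.0 + np.exp(-k_up * (doy - sos)))
    down = 1.0 / (1.0 + np.exp(k_down * (doy - eos)))
    return winter + amp * up * down


def make_phenology(class_name: str, year_type: str, config: SceneConfig) -> PhenologyTruth:
    """Daily true LAI trajectory for a class and year type.

    Water and urban return all-zero LAI; conifers are untouched by
    infestation; deciduous and mixed classes in infestation years are
    multiplied by a smooth cosine-taper notch between onset and recovery,
    with the notch depth calibrated so the growing-season mean drops by
    exactly the prescribed fraction.
    """
    if class_name not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_name!r}")
    if year_type not in ("normal", "infestation"):
        raise ValueError(f"year_type must be normal|infestation, got {year_type!r}")
    doy = np.arange(1, 366, dtype=float)
    base = _PHENOLOGY[class_name]
    if base is None:
        return PhenologyTruth(class_name, year_type, np.zeros(365))
    lai = _double_logistic(doy, *base)

    target = config.depression.get(class_name, 0.0)
    if year_type == "infestation" and target > 0.0:
        onset, recovery = float(config.infestation_onset), float(config.infestation_recovery)
        # smooth notch: 0 outside [onset, recovery], cosine taper to 1 at centre
        phase = np.clip((doy - onset) / (recovery - onset), 0.0, 1.0)
        notch = np.where(
            (doy > onset) & (doy < recovery), 0.5 * (1.0 - np.cos(2.0 * np.pi * phase)), 0.0
        )
        sel = (doy >= config.season_start) & (doy <= config.season_end)
        # depth so that the seasonal-mean reduction equals `target`
        depth = target * lai[sel].sum() / (lai * notch)[sel].sum()
        if depth > 1.0:
            raise ValueError(
                f"prescribed depression {target} unreachable with this notch window"
            )
        lai = lai * (1.0 - depth * notch)
    return PhenologyTruth(class_name, year_type, np.clip(lai, 0.0, 8.0))


@dataclass(frozen=True)
class LULCMap:
    """Integer-coded class raster plus the code table."""

    labels: np.ndarray               # (n_rows, n_cols) int codes
    code_table: dict[int, str]

    def mask(self, class_name: str) -> np.ndarray:
        code = {v: k for k, v in self.code_table.items()}[class_name]
        return self.labels == code


def make_lulc_map(config: SceneConfig) -> LULCMap:
    """Random spatial arrangement whose class counts match the requested
    fractions to within one pixel per class (largest-remainder rounding)."""
    n = config.n_rows * config.n_cols
    names = [c for c in CLASS_NAMES if config.class_fractions.get(c, 0.0) > 0.0]
    fracs = np.array([config.class_fractions[c] for c in names])
    ideal = fracs * n
    counts = np.floor(ideal).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(ideal - counts))
    counts[order[:remainder]] += 1

    codes = {i: c for i, c in enumerate(CLASS_NAMES)}
    inv = {c: i for i, c in codes.items()}
    flat = np.concatenate([np.full(k, inv[c], dtype=int) for c, k in zip(names, counts)])
    config.rng(11).shuffle(flat)
    return LULCMap(labels=flat.reshape(config.n_rows, config.n_cols), code_table=codes)


@dataclass(frozen=True)
class ReflectanceCube:
    """Per-date multiband reflectance: (n_dates, n_rows, n_cols, n_bands)."""

    reflectance: np.ndarray
    doy: np.ndarray
    bands: tuple[str, ...]


def render_reflectance(
    truth_by_class: dict[str, PhenologyTruth],
    lulc: LULCMap,
    doy: np.ndarray,
    rt_forward,
    bands: tuple[str, ...],
    noise_sd: float,
    seed: int,
) -> ReflectanceCube:
    """Render a reflectance cube through the forward radiative-transfer model.

    ``rt_forward(lai) -> {band: reflectance}`` is evaluated once per
    class-date (pixels of a class share the true LAI), then independent
    Gaussian noise of sd ``noise_sd`` is added per pixel-date-band and the
    result clipped to [0, 1].
    """
    doy = np.asarray(doy, dtype=int)
    n_dates = doy.size
    cube = np.zeros((n_dates, lulc.labels.shape[0], lulc.labels.shape[1], len(bands)))
    for cls, truth in truth_by_class.items():
        m = lulc.mask(cls)
        if not m.any():
            continue
        for i, d in enumerate(doy):
            bv = rt_forward(float(truth.lai[d - 1]))
            cube[i, m, :] = [bv[b] for b in bands]
    if noise_sd > 0:
        rng = np.random.default_rng(seed % 2**31)
        cube = cube + rng.normal(0.0, noise_sd, size=cube.shape)
    return ReflectanceCube(reflectance=np.clip(cube, 0.0, 1.0), doy=doy, bands=bands)


def make_meteo(year: int, config: SceneConfig, with_noise: bool = True) -> pd.DataFrame:
    """Daily meteorology for one year: air temperature (degC), PAR
    (umol m-2 s-1 daily mean), precipitation (mm d-1) and volumetric water
    content (m3 m-3).

    Ta is a sinusoid with the configured annual mean (default 10.6 degC)
    peaking in late July; PAR covaries with the solar cycle and is floored
    at zero; precipitation is intermittent with a gamma intensity.
    """
    doy = np.arange(1, 366)
    rng = config.rng(23 + year)
    ta = config.mean_annual_ta - config.ta_amplitude * np.cos(
        2.0 * np.pi * (doy - 28.0) / 365.0
    )
    par = 320.0 * (1.0 - 0.72 * np.cos(2.0 * np.pi * (doy - 10.0) / 365.0))
    if with_noise:
        ta = ta + rng.normal(0.0, 1.6, size=doy.size)
        par = par + rng.normal(0.0, 35.0, size=doy.size)
    par = np.maximum(par, 0.0)
    wet = rng.random(doy.size) < 0.35
    precip = np.where(wet, rng.gamma(1.4, 6.0, size=doy.size), 0.0)
    vwc = np.clip(
        0.12 + 0.05 * np.tanh((precip - 4.0) / 8.0) + rng.normal(0.0, 0.01, doy.size),
        0.0,
        1.0,
    )
    return pd.DataFrame(
        {
            "date": pd.to_datetime(f"{year}-01-01") + pd.to_timedelta(doy - 1, unit="D"),
            "doy": doy,
            "ta": ta,
            "par": par,
            "precip": precip,
            "vwc": vwc,
        }
    )


def make_ec_gpp(true_gpp: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    """Tower GPP series: truth plus homoscedastic Gaussian noise, floored
    at zero.  Dormant days (true GPP exactly zero) stay zero -- the tower
    cannot record photosynthesis where there is none."""
    true_gpp = np.asarray(true_gpp, dtype=float)
    if np.any(true_gpp < 0):
        raise ValueError("true GPP must be non-negative")
    if noise_sd == 0:
        return true_gpp.copy()
    rng = np.random.default_rng(seed % 2**31)
    noisy = np.maximum(true_gpp + rng.normal(0.0, noise_sd, size=true_gpp.shape), 0.0)
    return np.where(true_gpp > 0.0, noisy, 0.0)
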