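"""Growing-season aggregation and carbon-loss accounting.

Daily per-class GPP is summed over the fixed Apr 1 - Oct 31 window
(214 days, non-leap), infestation impact is expressed as percent reductions
against the pre- and post-infestation years, converted to per-hectare
carbon losses (g C m-2 -> t C ha-1 is a factor 0.01) and upscaled to a
regional total through the mapped class areas (g -> Mt is a factor 1e-12,
km2 -> m2 a factor 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lai_retrieval import SEASON_END_DOY, SEASON_START_DOY


@dataclass(frozen=True)
class SeasonalSummary:
    """Per class-year growing-season statistics."""

    class_name: str
    year: int | str
    gpp_daily_mean: float   # g C m-2 d-1
    gpp_daily_sd: float
    gpp_total: float        # g C m-2 over the season
    lai_mean: float         # m2 m-2
    lai_sd: float


def seasonal_total(
    daily_gpp: np.ndarray,
    doy: np.ndarray,
    season: tuple[int, int] = (SEASON_START_DOY, SEASON_END_DOY),
    max_missing_frac: float = 0.5,
) -> float:
    """Sum daily GPP (g C m-2 d-1) over the growing-season window.

    ``daily_gpp`` aligns with ``doy``; NaNs count as missing, and more than
    ``max_missing_frac`` of the window missing is an error (missing days
    are expected to be interpolated by the fitted daily curve upstream).
    """
    daily_gpp = np.asarray(daily_gpp, dtype=float)
    doy = np.asarray(doy)
    lo, hi = season
    window = hi - lo + 1
    sel = (doy >= lo) & (doy <= hi)
    vals = daily_gpp[sel]
    n_valid = int(np.isfinite(vals).sum())
    if n_valid < (1.0 - max_missing_frac) * window:
        raise ValueError(
            f"only {n_valid}/{window} days of the season available"
        )
    return float(np.nansum(vals))


def percent_reduction(reference: float, value: float) -> float:
    """100 (reference - value) / reference; requires reference > 0."""
    if not reference > 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - value) / reference


def mean_reduction(reduction_vs_pre: float, reduction_vs_post: float) -> float:
    """Arithmetic mean of the reductions against pre- and post-disturbance
    years."""
    return 0.5 * (reduction_vs_pre + reduction_vs_post)


def per_hectare_loss(delta_pre: float, delta_post: float) -> float:
    """Mean of the two seasonal-total deficits (g C m-2), as t C ha-1."""
    return 0.5 * (delta_pre + delta_post) * 0.01


def regional_upscale(delta_by_class: dict[str, float], areas_km2: dict[str, float]) -> float:
    """Regional carbon loss, Mt C, from per-class seasonal-total deficits
    (g C m-2) and class areas (km2)."""
    total_g = 0.0
    for cls, delta in delta_by_class.items():
        area = areas_km2[cls]
        if area < 0:
            raise ValueError(f"negative area for class {cls!r}")
        total_g += delta * area * 1e6  # km2 -> m2
    return total_g * 1e-12  # g -> Mt


def round_half_up(x: float) -> int:
    """Reporting-layer integer rounding (half away from zero)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x))


def impact_report(
    summaries: pd.DataFrame,
    infestation_year: int,
    pre_year: int,
    post_year: int,
    impacted_classes: tuple[str, ...] = ("deciduous", "mixed"),
    areas_km2: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Percent reductions, per-hectare and regional losses per class.

    ``summaries`` is a long table with columns (class, year, gpp_total,
    lai_mean, ...) as produced by the pipeline.  Reductions are computed for
    every class; loss columns only for the impacted classes.
    """
    rows = []
    for cls, grp in summaries.groupby("class_name"):
        by_year = grp.set_index("year")
        if not {infestation_year, pre_year, post_year} <= set(by_year.index):
            continue
        g_inf = by_year.loc[infestation_year, "gpp_total"]
        g_pre = by_year.loc[pre_year, "gpp_total"]
        g_post = by_year.loc[post_year, "gpp_total"]
        row = {
            "class_name": cls,
            "gpp_reduction_vs_pre_pct": percent_reduction(g_pre, g_inf),
            "gpp_reduction_vs_post_pct": percent_reduction(g_post, g_inf),
        }
        if "lai_mean" in by_year.columns and np.isfinite(by_year["lai_mean"]).all():
            l_inf, l_pre, l_post = (
                by_year.loc[infestation_year, "lai_mean"],
                by_year.loc[pre_year, "lai_mean"],
                by_year.loc[post_year, "lai_mean"],
            )
            if l_pre > 0 and l_post > 0:
                row["lai_reduction_vs_pre_pct"] = percent_reduction(l_pre, l_inf)
                row["lai_reduction_vs_post_pct"] = percent_reduction(l_post, l_inf)
                row["lai_reduction_mean_pct"] = mean_reduction(
                    row["lai_reduction_vs_pre_pct"], row["lai_reduction_vs_post_pct"]
                )
        if cls in impacted_classes:
            row["carbon_loss_t_ha"] = per_hectare_loss(g_pre - g_inf, g_post - g_inf)
        rows.append(row)
    report = pd.DataFrame(rows)
    if areas_km2 is not None and not report.empty:
        deltas_pre = {}
        deltas_post = {}
        for cls in impacted_classes:
            sub = summaries[summaries["class_name"] == cls].set_index("year")
            if {infestation_year, pre_year, post_year} <= set(sub.index):
                deltas_pre[cls] = sub.loc[pre_year, "gpp_total"] - sub.loc[infestation_year, "gpp_total"]
                deltas_post[cls] = sub.loc[post_year, "gpp_total"] - sub.loc[infestation_year, "gpp_total"]
        report.attrs["regional_loss_vs_pre_mt"] = regional_upscale(deltas_pre, areas_km2)
        report.attrs["regional_loss_vs_post_mt"] = regional_upscale(deltas_post, areas_km2)
    return report
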