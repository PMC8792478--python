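"""Degree-day accumulation by single triangulation, with logger calibration.

The diurnal temperature curve is approximated by a triangle with base one
day running from tmin up to tmax and back.  Daily degree-days are the area
of that triangle above the lower developmental threshold (5.5 C for both
budworm species); an optional upper threshold subtracts the area above it
by the same geometry.  Station series are calibrated against on-site
loggers by the median daily difference, applied from 1 January.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BASE_C = 5.5


def single_triangulation(tmin, tmax, t_lower: float = DEFAULT_BASE_C, t_upper=None):
    """Daily degree-days (C*day) from daily extremes by single triangulation.

    Piecewise: 0 when the whole triangle is below ``t_lower``; the full
    mean-minus-threshold when above; otherwise the apex triangle
    ``(tmax - t_lower)^2 / (2 (tmax - tmin))``.  With ``t_upper`` set, the
    area above the upper threshold is subtracted by the same rule.
    Accepts scalars or arrays; requires tmax >= tmin.
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        bad = np.flatnonzero(np.atleast_1d(tmax < tmin))
        raise ValueError(f"tmax < tmin at day index {bad[:5].tolist()}")

    def area_above(threshold):
        span = tmax - tmin
        full = (tmax + tmin) / 2.0 - threshold
        with np.errstate(divide="ignore", invalid="ignore"):
            apex = np.where(span > 0, (tmax - threshold) ** 2 / (2.0 * span), 0.0)
        out = np.where(tmax <= threshold, 0.0, np.where(tmin >= threshold, full, apex))
        return out

    dd = area_above(t_lower)
    if t_upper is not None:
        dd = dd - area_above(t_upper)
    return dd if dd.ndim else float(dd)


@dataclass
class CalibrationResult:
    """Median logger-minus-station offsets and the accompanying rank test."""

    location: str
    median_diff_tmin: float
    median_diff_tmax: float
    n_paired_days: int
    statistic: float
    pvalue: float
    test: str
    correction_applied: bool

    def to_dict(self) -> dict:
        return {
            "location": self.location,
            "median_diff_tmin": self.median_diff_tmin,
            "median_diff_tmax": self.median_diff_tmax,
            "n_paired_days": self.n_paired_days,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "test": self.test,
            "correction_applied": self.correction_applied,
        }


def calibrate(
    logger: pd.DataFrame, station: pd.DataFrame, paired_test: bool = False
) -> tuple[CalibrationResult, pd.DataFrame]:
    """Calibrate a station temperature series against an on-site logger.

    Both inputs are single-location daily series (columns ``date, tmin_c,
    tmax_c``).  The additive correction is the median logger-minus-station
    difference over the overlapping days, computed separately for daily
    lows and highs, and applied to the *full* station series.  The
    difference between series is summarised by a Wilcoxon–Mann–Whitney
    test on the pooled daily means (or a signed-rank test on the paired
    differences when ``paired_test``).
    """
    merged = pd.merge(
        logger, station, on="date", suffixes=("_log", "_sta"), how="inner"
    )
    if merged.empty:
        raise ValueError("logger and station series share no days")
    d_tmin = (merged["tmin_c_log"] - merged["tmin_c_sta"]).to_numpy()
    d_tmax = (merged["tmax_c_log"] - merged["tmax_c_sta"]).to_numpy()
    med_tmin = float(np.median(d_tmin))
    med_tmax = float(np.median(d_tmax))

    mean_log = (merged["tmin_c_log"] + merged["tmax_c_log"]) / 2.0
    mean_sta = (merged["tmin_c_sta"] + merged["tmax_c_sta"]) / 2.0
    if paired_test:
        diffs = (mean_log - mean_sta).to_numpy()
        if np.allclose(diffs, 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(diffs)
            stat, p = float(res.statistic), float(res.pvalue)
        test = "wilcoxon_signed_rank"
    else:
        res = stats.mannwhitneyu(mean_log, mean_sta, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
        test = "mann_whitney_u"

    loc = str(logger["location"].iloc[0]) if "location" in logger.columns else ""
    corrected = station.copy()
    corrected["tmin_c"] = corrected["tmin_c"] + med_tmin
    corrected["tmax_c"] = corrected["tmax_c"] + med_tmax
    if "source" in corrected.columns:
        corrected["source"] = "station_corrected"
    result = CalibrationResult(
        location=loc,
        median_diff_tmin=med_tmin,
        median_diff_tmax=med_tmax,
        n_paired_days=len(merged),
        statistic=stat,
        pvalue=p,
        test=test,
        correction_applied=True,
    )
    return result, corrected


def accumulate(
    temperature: pd.DataFrame,
    t_lower: float = DEFAULT_BASE_C,
    t_upper=None,
) -> pd.DataFrame:
    """Daily and cumulative degree-days per location from 1 January.

    The running sum restarts at every 1 January (accumulation is always
    relative to the start of the collection year).  Missing calendar days
    inside each location-year's span are filled by linear interpolation of
    tmin/tmax (count reported in the ``interpolated`` column).  Returns
    columns ``location, date, dd, cum_dd, interpolated``.
    """
    temperature = temperature.assign(_year=pd.to_datetime(temperature["date"]).dt.year)
    frames = []
    for (loc, _year), grp in temperature.groupby(["location", "_year"], sort=True):
        grp = grp.drop(columns="_year").sort_values("date").set_index("date")
        full = pd.date_range(grp.index.min(), grp.index.max(), freq="D")
        grp = grp.reindex(full)
        interpolated = grp["tmin_c"].isna()
        grp[["tmin_c", "tmax_c"]] = grp[["tmin_c", "tmax_c"]].interpolate(
            method="linear"
        )
        dd = single_triangulation(
            grp["tmin_c"].to_numpy(), grp["tmax_c"].to_numpy(), t_lower, t_upper
        )
        frames.append(
            pd.DataFrame(
                {
                    "location": loc,
                    "date": full,
                    "dd": dd,
                    "cum_dd": np.cumsum(dd),
                    "interpolated": interpolated.to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def dd_at_collection(dd_table: pd.DataFrame, samples: pd.DataFrame) -> pd.Series:
    """Accumulated degree-days through each individual's collection date.

    Joins on (location, collection date); the collection day itself is
    included in the sum.  Raises if a sample's date precedes its
    location's temperature series.
    """
    key = dd_table.set_index(["location", "date"])["cum_dd"]
    out = []
    for _, row in samples.iterrows():
        loc, date = row["location"], pd.Timestamp(row["collection_date"])
        try:
            out.append(float(key.loc[(loc, date)]))
        except KeyError:
            start = dd_table.loc[dd_table["location"] == loc, "date"].min()
            raise ValueError(
                f"no degree-day record for {loc} on {date.date()} "
                f"(series starts {start})"
            ) from None
    return pd.Series(out, index=samples.index, name="cum_dd")
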