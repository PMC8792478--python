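"""Flight-period overlap indices and between-taxon flight comparisons.

Two co-occurrence indices quantify temporal overlap of the two taxa across
10-day trap intervals.  The presence index is the fraction of intervals in
which both taxa were caught among intervals in which either was; the
abundance index weights intervals by the individuals caught in them.  Both
are computed at two spatial grains: per sympatric location (then averaged,
unweighted) and after pooling all sympatric locations.  Years are never
merged: an interval is keyed (year, interval index).  F1 hybrids count
toward neither taxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError


@dataclass
class CollectionGrid:
    """Per (location, year, interval) genotyped counts of the two taxa."""

    counts: pd.DataFrame  # columns: location, year, interval, n_taxon1, n_taxon2
    taxa: tuple[str, str]

    def sympatric_locations(self) -> list[str]:
        per_loc = self.counts.groupby("location")[["n_taxon1", "n_taxon2"]].sum()
        return sorted(per_loc.index[(per_loc > 0).all(axis=1)])


def build_grid(
    samples: pd.DataFrame, labels: pd.Series, taxa: tuple[str, str]
) -> CollectionGrid:
    """Tabulate per-interval taxon counts from the sample table.

    ``labels`` maps sample id to a taxon label; only the two parental taxa
    are counted (hybrids and ambiguous individuals contribute zero).
    Intervals that were sampled but caught neither taxon remain in the
    grid with zero counts.
    """
    if samples["interval"].isna().any():
        bad = samples.loc[samples["interval"].isna(), "id"].tolist()
        raise ValidationError(f"samples with missing interval: {bad}")
    df = samples[["id", "location", "year", "interval"]].copy()
    df["label"] = df["id"].map(labels)
    grouped = df.groupby(["location", "year", "interval"])
    rows = []
    for (loc, year, iv), grp in grouped:
        rows.append(
            {
                "location": loc,
                "year": int(year),
                "interval": int(iv),
                "n_taxon1": int((grp["label"] == taxa[0]).sum()),
                "n_taxon2": int((grp["label"] == taxa[1]).sum()),
            }
        )
    counts = pd.DataFrame(
        rows, columns=["location", "year", "interval", "n_taxon1", "n_taxon2"]
    )
    return CollectionGrid(counts=counts, taxa=taxa)


@dataclass
class OverlapReport:
    """One co-occurrence index value with its bookkeeping."""

    index: str  # "presence" | "abundance"
    grain: str  # "by_location" | "pooled"
    value: float
    numerator: float
    denominator: float
    per_location: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "grain": self.grain,
            "value": self.value,
            "percent": 100.0 * self.value if np.isfinite(self.value) else None,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "per_location": self.per_location,
        }


def _presence_ratio(counts: pd.DataFrame) -> tuple[float, float]:
    """(n both present, n either present) over (year, interval) cells."""
    cell = counts.groupby(["year", "interval"])[["n_taxon1", "n_taxon2"]].sum()
    both = int(((cell["n_taxon1"] > 0) & (cell["n_taxon2"] > 0)).sum())
    either = int(((cell["n_taxon1"] > 0) | (cell["n_taxon2"] > 0)).sum())
    return both, either


def presence_index(
    grid: CollectionGrid, grain: str = "by_location", locations=None
) -> OverlapReport:
    """Fraction of trap intervals with both taxa among intervals with either.

    by_location: the ratio is computed within each sympatric location and
    the per-location values averaged unweighted.  pooled: counts are summed
    across locations per (year, interval) before the ratio.  Intervals with
    neither taxon never enter the denominator.
    """
    if grain not in {"by_location", "pooled"}:
        raise ValueError(f"unknown grain {grain!r}")
    locs = list(locations) if locations is not None else grid.sympatric_locations()
    sub = grid.counts[grid.counts["location"].isin(locs)]
    per_location = {}
    for loc in locs:
        both, either = _presence_ratio(sub[sub["location"] == loc])
        per_location[loc] = both / either if either else float("nan")
    if grain == "by_location":
        vals = [v for v in per_location.values() if np.isfinite(v)]
        value = float(np.mean(vals)) if vals else float("nan")
        num, den = float("nan"), float("nan")
    else:
        both, either = _presence_ratio(sub)
        value = both / either if either else float("nan")
        num, den = both, either
    return OverlapReport("presence", grain, value, num, den, per_location)


def abundance_index(
    grid: CollectionGrid,
    grain: str = "by_location",
    locations=None,
    numerator_rule: str = "both_taxa",
) -> OverlapReport:
    """Individuals caught in shared intervals as a fraction of all caught.

    The numerator sums, over intervals in which both taxa were caught (at
    the stated grain), the individuals of both taxa in those intervals
    (``numerator_rule="minority"`` counts only the rarer taxon per shared
    interval); the denominator is all parental individuals at that grain.
    """
    if numerator_rule not in {"both_taxa", "minority"}:
        raise ValueError(f"unknown numerator_rule {numerator_rule!r}")
    locs = list(locations) if locations is not None else grid.sympatric_locations()
    sub = grid.counts[grid.counts["location"].isin(locs)]

    def ratio(frame: pd.DataFrame) -> tuple[float, float]:
        cell = frame.groupby(["year", "interval"])[["n_taxon1", "n_taxon2"]].sum()
        shared = cell[(cell["n_taxon1"] > 0) & (cell["n_taxon2"] > 0)]
        if numerator_rule == "both_taxa":
            num = float(shared.sum().sum())
        else:
            num = float(shared.min(axis=1).sum())
        den = float(cell.sum().sum())
        return num, den

    per_location = {}
    for loc in locs:
        n, d = ratio(sub[sub["location"] == loc])
        per_location[loc] = n / d if d else float("nan")
    if grain == "by_location":
        vals = [v for v in per_location.values() if np.isfinite(v)]
        value = float(np.mean(vals)) if vals else float("nan")
        num, den = float("nan"), float("nan")
    elif grain == "pooled":
        num, den = ratio(sub)
        value = num / den if den else float("nan")
    else:
        raise ValueError(f"unknown grain {grain!r}")
    return OverlapReport("abundance", grain, value, num, den, per_location)


@dataclass
class FlightComparison:
    """Mann–Whitney comparison of flight timing between taxa."""

    value: str  # "date" | "degree_days"
    n1: int
    n2: int
    median1: float
    median2: float
    quartiles1: tuple[float, float]
    quartiles2: tuple[float, float]
    u1: float
    u2: float
    z: float
    pvalue: float
    r_rank_biserial: float
    r_z_over_sqrt_n: float

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "n1": self.n1,
            "n2": self.n2,
            "median1": self.median1,
            "median2": self.median2,
            "q1_q3_taxon1": list(self.quartiles1),
            "q1_q3_taxon2": list(self.quartiles2),
            "U1": self.u1,
            "U2": self.u2,
            "z": self.z,
            "pvalue": self.pvalue,
            "effect_r_rank_biserial": self.r_rank_biserial,
            "effect_r_z_over_sqrt_n": self.r_z_over_sqrt_n,
        }


def _tie_corrected_z(x: np.ndarray, y: np.ndarray, u1: float) -> float:
    """Normal-approximation Z for U with midrank tie correction
    (no continuity correction; sign from U1 - mean)."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 0.0
    return (u1 - mu) / np.sqrt(sigma2)


def flight_summary(
    values1, values2, value: str = "date"
) -> FlightComparison:
    """Compare flight timing (collection dates or accumulated degree-days).

    U comes from the Wilcoxon–Mann–Whitney test with midranks for ties and
    the tie-corrected normal approximation for p.  Both U1 and U2 are
    reported, as are both common effect-size conventions:
    rank-biserial |1 - 2U/(n1 n2)| and |Z|/sqrt(N).
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    u1 = float(res.statistic)
    u2 = len(x) * len(y) - u1
    z = _tie_corrected_z(x, y, u1)
    n = len(x) + len(y)
    r_rb = abs(1.0 - 2.0 * u1 / (len(x) * len(y)))
    r_z = abs(z) / np.sqrt(n)
    q1 = np.percentile(x, [25, 75])
    q2 = np.percentile(y, [25, 75])
    return FlightComparison(
        value=value,
        n1=len(x),
        n2=len(y),
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        quartiles1=(float(q1[0]), float(q1[1])),
        quartiles2=(float(q2[0]), float(q2[1])),
        u1=u1,
        u2=float(u2),
        z=float(z),
        pvalue=float(res.pvalue),
        r_rank_biserial=float(r_rb),
        r_z_over_sqrt_n=float(r_z),
    )


def dates_to_day_of_year(dates) -> np.ndarray:
    """Collection dates -> days since 1 January (1-based day of year)."""
    return pd.to_datetime(pd.Series(dates)).dt.dayofyear.to_numpy(dtype=float)
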