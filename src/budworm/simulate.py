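"""Synthetic budworm study generator.

Emulates the field design the analysis assumes: two moth taxa diverged at a
target F_ST (Balding–Nichols beta model), rare F1/F2/backcross hybrids,
ten trap locations sampled at 10-day intervals over two flight seasons,
degree-day-driven adult emergence with the second taxon biennial (flying in
a parity year), and daily station/logger temperature pairs with a fixed
per-location logger offset.  A single :class:`SimConfig` plus its seed
fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import degreedays
from .io import MISSING, LOCUS_COLUMNS, GenotypeMatrix

CLASSES = ("P1", "P2", "F1", "F2", "BC1", "BC2")

#: probability that a single allele copy is of parental-1 origin, per gamete
_GAMETE_P1 = {
    "P1": (1.0, 1.0),
    "P2": (0.0, 0.0),
    "F1": (1.0, 0.0),
    "F2": (0.5, 0.5),
    "BC1": (1.0, 0.5),
    "BC2": (0.0, 0.5),
}


@dataclass(frozen=True)
class LocationSpec:
    """One trap location: thermal offset, resident taxa, voltinism."""

    id: str
    temp_offset_c: float = 0.0
    logger_offset_c: float = 0.0
    taxa: tuple[str, ...] = ("sp1", "sp2")
    sp2_biennial: bool = True
    parity_year: int | None = None  # flight year of the biennial taxon


def default_locations(years=(2017, 2018)) -> list[LocationSpec]:
    """Ten locations mirroring the study: 3 western (taxon-2 only),
    6 sympatric, 1 eastern (taxon-1 only); biennial parity = second year."""
    parity = years[1]
    west = [
        LocationSpec(i, o, lo, ("sp2",), True, parity)
        for i, o, lo in [("a", 2.0, 0.8), ("b", 1.5, -0.4), ("c", 1.0, 1.2)]
    ]
    sympatric = [
        LocationSpec(i, o, lo, ("sp1", "sp2"), True, parity)
        for i, o, lo in [
            ("d", 0.5, 0.5),
            ("e", 0.0, -0.6),
            ("f", -0.5, 1.0),
            ("g", -1.0, 0.2),
            ("h", -1.5, -0.8),
            ("i", 1.2, 0.6),
        ]
    ]
    east = [LocationSpec("j", -2.0, 0.3, ("sp1",), False, None)]
    return west + sympatric + east


@dataclass
class SimConfig:
    """Study-design parameters; the defaults are the paper-scale conditions."""

    n_pop1: int = 102
    n_pop2: int = 153
    n_f1: int = 5
    n_f2: int = 0
    n_bc1: int = 0
    n_bc2: int = 0
    n_loci: int = 2831
    fst_target: float = 0.34
    ancestral_maf_range: tuple[float, float] = (0.15, 0.5)
    missing_rate: float = 0.0279
    seed: int = 0
    locations: list[LocationSpec] = field(default_factory=default_locations)
    years: tuple[int, int] = (2017, 2018)
    dd_threshold_sp1: float = 400.0
    dd_threshold_sp2: float = 650.0
    dd_noise_sd: float = 80.0
    off_year_fraction: float = 0.05
    season: tuple[str, str] = ("06-01", "09-03")  # month-day, per year
    interval_len_days: int = 10
    subsample_floor: int = 3
    subsample_cap: int = 10
    n_scaffolds: int = 200
    scaffold_len: int = 1_000_000
    # temperature model
    temp_mean_c: float = 2.0
    temp_amp_c: float = 16.0
    diurnal_range_c: float = 10.0
    temp_noise_sd: float = 3.0
    temp_ar: float = 0.7
    logger_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        counts = (self.n_pop1, self.n_pop2, self.n_f1, self.n_f2, self.n_bc1, self.n_bc2)
        if any(c < 0 for c in counts):
            raise ValueError("class counts must be non-negative")
        if not 0.0 <= self.fst_target <= 1.0:
            raise ValueError("fst_target must be in [0, 1]")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "P1": self.n_pop1,
            "P2": self.n_pop2,
            "F1": self.n_f1,
            "F2": self.n_f2,
            "BC1": self.n_bc1,
            "BC2": self.n_bc2,
        }


def simulate_allele_freqs(n_loci, fst_target, ancestral_maf_range, seed):
    """Per-locus allele frequencies for two demes under Balding–Nichols.

    The ancestral frequency is uniform on ``ancestral_maf_range``; each
    deme's frequency is Beta(p (1-F)/F, (1-p)(1-F)/F), whose variance
    parameter equals the target F_ST.  F=0 collapses to identical
    frequencies; F=1 fixes each deme for one allele.
    """
    if not 0.0 <= fst_target <= 1.0:
        raise ValueError("fst_target must be in [0, 1]")
    lo, hi = ancestral_maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(lo, hi, size=n_loci)
    if fst_target == 0.0:
        return p_anc.copy(), p_anc.copy()
    if fst_target == 1.0:
        p1 = (rng.random(n_loci) < p_anc).astype(float)
        p2 = (rng.random(n_loci) < p_anc).astype(float)
        return p1, p2
    theta = (1.0 - fst_target) / fst_target
    p1 = rng.beta(p_anc * theta, (1.0 - p_anc) * theta)
    p2 = rng.beta(p_anc * theta, (1.0 - p_anc) * theta)
    return p1, p2


def simulate_positions(n_loci, n_scaffolds, scaffold_len, seed) -> pd.DataFrame:
    """Uniform random locus placements on synthetic scaffolds (sorted)."""
    rng = np.random.default_rng(seed)
    scaf = rng.integers(0, n_scaffolds, size=n_loci)
    pos = rng.integers(1, scaffold_len + 1, size=n_loci)
    order = np.lexsort((pos, scaf))
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_loci)
    alt_i = (ref_i + rng.integers(1, 4, size=n_loci)) % 4
    df = pd.DataFrame(
        {
            "scaffold": [f"scaffold_{s:04d}" for s in scaf[order]],
            "pos": pos[order],
            "ref": bases[ref_i],
            "alt": bases[alt_i],
        }
    )
    # collisions on the same scaffold+position would not be distinct SNPs
    df = df.drop_duplicates(subset=["scaffold", "pos"]).reset_index(drop=True)
    return df[LOCUS_COLUMNS]


def simulate_genotypes(
    p1, p2, class_counts: dict[str, int], missing_rate: float, seed
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw genotypes for parental and hybrid classes.

    Parental individuals are Hardy–Weinberg within their deme; an F1
    carries one gamete from each parental pool, an F2 two F1 gametes, and
    a backcross one F1 and one parental gamete.  Missing calls are set
    independently at ``missing_rate``.  Returns the matrix plus a truth
    table of true classes.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_loci = len(p1)
    ids, classes, rows = [], [], []
    for cls in CLASSES:
        n = class_counts.get(cls, 0)
        if n == 0:
            continue
        geno = np.zeros((n, n_loci), dtype=np.int8)
        for w in _GAMETE_P1[cls]:
            if w == 1.0:
                pa = np.broadcast_to(p1, (n, n_loci))
            elif w == 0.0:
                pa = np.broadcast_to(p2, (n, n_loci))
            else:
                from_p1 = rng.random((n, n_loci)) < w
                pa = np.where(from_p1, p1, p2)
            geno += (rng.random((n, n_loci)) < pa).astype(np.int8)
        rows.append(geno)
        ids.extend(f"{cls}_{i:03d}" for i in range(n))
        classes.extend([cls] * n)
    calls = np.vstack(rows) if rows else np.empty((0, n_loci), dtype=np.int8)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = MISSING
    loci = simulate_positions(n_loci, 200, 1_000_000, rng.integers(2**31))
    # positions may have deduplicated; trim calls to match
    calls = calls[:, : len(loci)]
    gm = GenotypeMatrix(ids, loci, calls)
    truth = pd.DataFrame({"id": ids, "true_class": classes})
    return gm, truth


def simulate_temperature(location: LocationSpec, year: int, config: SimConfig, seed):
    """Daily station and logger series for one location-year.

    Annual sinusoid plus AR(1) noise; the logger equals the station series
    shifted by the location's fixed offset plus observation noise.  Covers
    1 January through the season end; tmax - tmin is clamped non-negative.
    """
    rng = np.random.default_rng(seed)
    end = pd.Timestamp(f"{year}-{config.season[1]}")
    dates = pd.date_range(f"{year}-01-01", end, freq="D")
    doy = dates.dayofyear.to_numpy()
    seasonal = config.temp_mean_c + location.temp_offset_c - config.temp_amp_c * np.cos(
        2 * np.pi * (doy - 15) / 365.25
    )
    noise = np.empty(len(dates))
    eps = rng.normal(0.0, config.temp_noise_sd, size=len(dates))
    noise[0] = eps[0]
    for i in range(1, len(dates)):
        noise[i] = config.temp_ar * noise[i - 1] + eps[i] * np.sqrt(
            1 - config.temp_ar**2
        )
    mean_t = seasonal + noise
    half_range = np.maximum(
        config.diurnal_range_c / 2.0 + rng.normal(0, 1.0, len(dates)), 0.0
    )
    station = pd.DataFrame(
        {
            "location": location.id,
            "date": dates,
            "tmin_c": mean_t - half_range,
            "tmax_c": mean_t + half_range,
            "source": "station",
        }
    )
    logger = station.copy()
    obs = rng.normal(0.0, config.logger_noise_sd, size=(len(dates), 2))
    logger["tmin_c"] = station["tmin_c"] + location.logger_offset_c + obs[:, 0]
    logger["tmax_c"] = np.maximum(
        station["tmax_c"] + location.logger_offset_c + obs[:, 1], logger["tmin_c"]
    )
    logger["source"] = "logger"
    return station, logger


def _hybrid_threshold(config: SimConfig) -> float:
    return 0.5 * (config.dd_threshold_sp1 + config.dd_threshold_sp2)


def class_taxon(cls: str) -> str:
    """Taxon whose voltinism/phenology a class follows (hybrids: 'hybrid')."""
    return {"P1": "sp1", "P2": "sp2"}.get(cls, "hybrid")


def simulate_emergence(
    truth: pd.DataFrame, temperature: pd.DataFrame, config: SimConfig, seed
) -> pd.DataFrame:
    """Assign each individual a location, flight year and emergence date.

    Emergence is the first day the location's cumulative degree-days (base
    5.5 C, single triangulation from 1 January, on the logger series)
    reach the individual's threshold: the taxon threshold for parentals,
    the parental midpoint for hybrids, plus Gaussian noise.  Individuals
    of the biennial taxon fly only in their location's parity year except
    an ``off_year_fraction``; individuals whose threshold is never reached
    in season are recorded as non-emerging (NaT).
    """
    rng = np.random.default_rng(seed)
    logger = temperature[temperature["source"] == "logger"]
    cum = degreedays.accumulate(logger)
    cum["year"] = cum["date"].dt.year

    loc_by_taxon = {
        "sp1": [l for l in config.locations if "sp1" in l.taxa],
        "sp2": [l for l in config.locations if "sp2" in l.taxa],
        "hybrid": [l for l in config.locations if set(l.taxa) >= {"sp1", "sp2"}],
    }
    thresholds = {
        "P1": config.dd_threshold_sp1,
        "P2": config.dd_threshold_sp2,
        "F1": _hybrid_threshold(config),
        "F2": _hybrid_threshold(config),
        "BC1": _hybrid_threshold(config),
        "BC2": _hybrid_threshold(config),
    }

    out = truth.copy()
    locs, years, dates = [], [], []
    for cls in out["true_class"]:
        taxon = class_taxon(cls)
        pool = loc_by_taxon[taxon]
        if not pool:
            raise ValueError(f"no location hosts taxon of class {cls}")
        spec = pool[rng.integers(len(pool))]
        if taxon == "sp2" and spec.sp2_biennial and spec.parity_year is not None:
            if rng.random() < config.off_year_fraction:
                year = [y for y in config.years if y != spec.parity_year][0]
            else:
                year = spec.parity_year
        elif taxon == "hybrid" and spec.sp2_biennial and spec.parity_year is not None:
            year = spec.parity_year
        else:
            year = config.years[int(rng.integers(len(config.years)))]
        locs.append(spec.id)
        years.append(year)
    out["location"] = locs
    out["year"] = years

    for i, row in out.iterrows():
        thr = thresholds[row["true_class"]] + rng.normal(0.0, config.dd_noise_sd)
        series = cum[(cum["location"] == row["location"]) & (cum["year"] == row["year"])]
        hit = series[series["cum_dd"] >= thr]
        dates.append(hit["date"].iloc[0] if len(hit) else pd.NaT)
    out["emergence_date"] = dates
    return out


def season_intervals(config: SimConfig, year: int) -> pd.DataFrame:
    """Consecutive trap intervals for one season (1-based index)."""
    start = pd.Timestamp(f"{year}-{config.season[0]}")
    end = pd.Timestamp(f"{year}-{config.season[1]}")
    starts = pd.date_range(start, end, freq=f"{config.interval_len_days}D")
    rows = []
    for k, s in enumerate(starts, start=1):
        e = min(s + pd.Timedelta(days=config.interval_len_days - 1), end)
        rows.append({"year": year, "interval": k, "start": s, "end": e})
    return pd.DataFrame(rows)


def simulate_trapping(truth: pd.DataFrame, config: SimConfig, seed) -> pd.DataFrame:
    """Bin emerged individuals into trap intervals and subsample for genotyping.

    Per (location, year, interval) at most ``subsample_cap`` individuals are
    retained (all are kept when no more than that are available; the design
    floor of ``subsample_floor`` is always satisfiable since fewer than the
    floor means everyone is kept).  The earliest- and latest-emerging
    individual of each location-season is always retained.  Individuals
    emerging outside the season are excluded.  Collection date is the
    interval end (trap-emptying day).
    """
    rng = np.random.default_rng(seed)
    intervals = pd.concat(
        [season_intervals(config, y) for y in config.years], ignore_index=True
    )
    flown = truth.dropna(subset=["emergence_date"]).copy()
    rows = []
    for _, ind in flown.iterrows():
        year = ind["year"]
        span = intervals[intervals["year"] == year]
        date = ind["emergence_date"]
        inside = span[(span["start"] <= date) & (date <= span["end"])]
        if inside.empty:
            continue  # pre/post-season emergence: trap not deployed
        iv = inside.iloc[0]
        rows.append(
            {
                "id": ind["id"],
                "location": ind["location"],
                "year": int(year),
                "interval": int(iv["interval"]),
                "collection_date": iv["end"],
                "emergence_date": date,
            }
        )
    caught = pd.DataFrame(
        rows,
        columns=["id", "location", "year", "interval", "collection_date", "emergence_date"],
    )
    if caught.empty:
        return caught.drop(columns=["emergence_date"])

    keep_ids: set[str] = set()
    for (_, _), grp in caught.groupby(["location", "year"]):
        keep_ids.add(grp.loc[grp["emergence_date"].idxmin(), "id"])
        keep_ids.add(grp.loc[grp["emergence_date"].idxmax(), "id"])
    retained = []
    for (_, _, _), grp in caught.groupby(["location", "year", "interval"]):
        forced = grp[grp["id"].isin(keep_ids)]
        free = grp[~grp["id"].isin(keep_ids)]
        room = max(config.subsample_cap - len(forced), 0)
        if len(free) > room:
            pick = rng.choice(free.index.to_numpy(), size=room, replace=False)
            free = free.loc[np.sort(pick)]
        retained.append(pd.concat([forced, free]))
    out = pd.concat(retained).sort_values(["location", "year", "interval", "id"])
    return out.drop(columns=["emergence_date"]).reset_index(drop=True)


def simulate_environment(config: SimConfig, seed) -> pd.DataFrame:
    """Per-location climate-normal variables (WorldClim-style names),
    driven by each location's thermal offset plus noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for spec in config.locations:
        o = spec.temp_offset_c
        n = rng.normal(0, 1, size=8)
        rows.append(
            {
                "location": spec.id,
                "mean_annual_temp": 2.0 + o + 0.2 * n[0],
                "mean_temp_warmest_month": 17.0 + 1.1 * o + 0.3 * n[1],
                "mean_temp_coldest_month": -12.0 + 0.9 * o + 0.4 * n[2],
                "mean_temp_warmest_quarter": 14.5 + o + 0.3 * n[3],
                "mean_temp_coldest_quarter": -9.5 + 0.9 * o + 0.4 * n[4],
                "mean_annual_precip": 500.0 - 20.0 * o + 15.0 * n[5],
                "mean_precip_warmest_quarter": 220.0 - 8.0 * o + 8.0 * n[6],
                "mean_precip_coldest_quarter": 90.0 - 4.0 * o + 5.0 * n[7],
            }
        )
    return pd.DataFrame(rows).set_index("location")


@dataclass
class SimulatedDataset:
    """Everything one simulated study produces."""

    config: SimConfig
    genotypes: GenotypeMatrix
    truth: pd.DataFrame
    samples: pd.DataFrame
    temperature: pd.DataFrame  # station + logger rows, all locations/years
    environment: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: genotypes, phenology, trapping, climate."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(2**31, size=6)
    p1, p2 = simulate_allele_freqs(
        config.n_loci, config.fst_target, config.ancestral_maf_range, seeds[0]
    )
    gm, truth = simulate_genotypes(
        p1, p2, config.class_counts, config.missing_rate, seeds[1]
    )
    temp_rng = np.random.default_rng(seeds[2])
    frames = []
    for spec in config.locations:
        for year in config.years:
            st, lg = simulate_temperature(
                spec, year, config, temp_rng.integers(2**31)
            )
            frames.append(st)
            frames.append(lg)
    temperature = pd.concat(frames, ignore_index=True)
    truth = simulate_emergence(truth, temperature, config, seeds[3])
    samples = simulate_trapping(truth, config, seeds[4])
    environment = simulate_environment(config, seeds[5])
    # genotyping covers only trapped+retained individuals
    gm = gm.subset_individuals([s for s in gm.individuals if s in set(samples["id"])])
    return SimulatedDataset(config, gm, truth, samples, temperature, environment)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write VCF + TSV/CSV artefacts; returns the path map."""
    from pathlib import Path

    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": str(outdir / "genotypes.vcf"),
        "samples": str(outdir / "samples.tsv"),
        "truth": str(outdir / "truth.tsv"),
        "temperature": str(outdir / "temperature.csv"),
        "environment": str(outdir / "environment.tsv"),
    }
    gio.write_vcf(ds.genotypes, paths["vcf"])
    gio.write_samples(ds.samples, paths["samples"])
    truth = ds.truth.copy()
    truth["emergence_date"] = pd.to_datetime(truth["emergence_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    gio.write_temperature(ds.temperature, paths["temperature"])
    ds.environment.reset_index().to_csv(paths["environment"], sep="\t", index=False)
    return paths
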