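"""End-to-end orchestration: simulate/load, filter, cluster, classify,
overlap, degree-days, scans — one report bundle per run.

Defaults reproduce the published thresholds: SNP call rate 0.95, MAF 0.10,
10-kb thinning, species membership >0.90, reference panels >0.99,
subspecies split at 0.5, q-value 0.05, degree-day base 5.5 C.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, degreedays, gea, hybrids, phenology, selscan
from . import io as gio
from .simulate import SimConfig, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds, seeds and problem sizes for one full run."""

    outdir: str = "budworm_run"
    seed: int = 0
    call_rate_min: float = 0.95
    maf_min: float = 0.10
    thin_bp: int = 10_000
    species_threshold: float = 0.90
    panel_threshold: float = 0.99
    subspecies_threshold: float = 0.5
    q_threshold: float = 0.05
    dd_base_c: float = 5.5
    kmax: int = 4
    n_replicates: int = 3
    classifier_n_snps: int = 400
    n_scan_runs: int = 2
    scan_preset: str = "reduced"  # "full" | "reduced" | "tiny"
    sim: SimConfig = field(default_factory=SimConfig)
    # optional real inputs; when set, the generator is bypassed
    input_vcf: str | None = None
    input_samples: str | None = None
    input_temperature: str | None = None
    input_environment: str | None = None

    def filter_kwargs(self) -> dict:
        return {
            "call_rate_min": self.call_rate_min,
            "maf_min": self.maf_min,
            "thin_bp": self.thin_bp,
        }


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _scan_settings(config: "RunConfig") -> selscan.ScanSettings:
    if config.scan_preset == "full":
        return selscan.ScanSettings(q_threshold=config.q_threshold)
    if config.scan_preset == "tiny":
        return selscan.reduced_settings(
            n_pilot=2, pilot_len=100, burn_in=300, n_out=200, thin=2,
            q_threshold=config.q_threshold,
        )
    return selscan.reduced_settings(q_threshold=config.q_threshold)


def _load_inputs(config: "RunConfig"):
    """Read genotype/sample/temperature/environment files; any missing
    path is reported by name."""
    from .simulate import SimulatedDataset

    paths = {
        "vcf": config.input_vcf,
        "samples": config.input_samples,
        "temperature": config.input_temperature,
        "environment": config.input_environment,
    }
    missing = [p for p in paths.values() if p and not Path(p).exists()]
    if missing:
        raise FileNotFoundError(", ".join(missing))
    gm = gio.read_vcf(paths["vcf"])
    samples = gio.read_samples(paths["samples"])
    temperature = gio.read_temperature(paths["temperature"])
    environment = (
        gio.read_environment(paths["environment"]) if paths["environment"] else None
    )
    return SimulatedDataset(
        config=config.sim,
        genotypes=gm,
        truth=None,
        samples=samples,
        temperature=temperature,
        environment=environment,
    )


def run_all(config: RunConfig) -> dict:
    """Run every stage on a simulated study; returns the summary dict.

    Writes a bundle of TSV/JSON artefacts under ``config.outdir``.  A
    stage failure is recorded in ``failures`` and later stages that do
    not depend on it still run.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "failures": {}}
    _dump(asdict(config), out / "resolved_config.json")

    if config.input_vcf:
        try:
            ds = _load_inputs(config)
        except (FileNotFoundError, OSError) as exc:
            summary["failures"]["inputs"] = str(exc)
            _dump(summary, out / "summary.json")
            return summary
        truth = None
    else:
        ds = simulate_dataset(config.sim)
        truth = ds.truth.set_index("id")

    # --- filtering -------------------------------------------------------
    gm, report = gio.filter_variants(ds.genotypes, **config.filter_kwargs())
    (out / "filter_report.json").write_text(report.to_json() + "\n")
    summary["filter"] = json.loads(report.to_json())

    # --- PCA + admixture -------------------------------------------------
    scores, evf = ancestry.pca(gm, n_components=4)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    summary["pca_explained_variance"] = [float(v) for v in evf]

    rng = np.random.default_rng(config.seed)
    logliks: dict[int, list[float]] = {}
    fits_by_k: dict[int, list[ancestry.AdmixtureFit]] = {}
    for k in range(1, config.kmax + 1):
        fits = [
            ancestry.fit_admixture(gm, k, seed=int(rng.integers(2**31)))
            for _ in range(config.n_replicates)
        ]
        fits_by_k[k] = fits
        logliks[k] = [f.loglik for f in fits]
    ksel = ancestry.select_k(logliks)
    ksel.table.to_csv(out / "k_selection.tsv", sep="\t", index=False)
    summary["k_selection"] = {
        "chosen_k": ksel.chosen_k,
        "criterion": ksel.criterion,
        "ambiguous": ksel.ambiguous,
    }

    fit2 = ancestry.average_replicates(fits_by_k[2])
    if truth is not None:
        anchors = {
            s: ("taxon1" if truth.loc[s, "true_class"] == "P1" else "taxon2")
            for s in fit2.individuals
            if truth.loc[s, "true_class"] in ("P1", "P2")
        }
    else:
        anchors = None  # cluster naming stays generic without anchor samples
    species = ancestry.assign_species(
        fit2, threshold=config.species_threshold, anchors=anchors
    )
    species.to_csv(out / "species_labels.tsv", sep="\t", index=False)
    fit2.q_frame().to_csv(out / "q_matrix.tsv", sep="\t")
    summary["species_counts"] = species["label"].value_counts().to_dict()

    # --- hybrid classification ------------------------------------------
    panel1 = species.loc[species["q1"] > config.panel_threshold, "id"].tolist()
    panel2 = species.loc[species["q2"] > config.panel_threshold, "id"].tolist()
    sub = hybrids.subset_snps(gm, "first_n", n=config.classifier_n_snps)
    model = hybrids.build_model(sub, panel1, panel2)
    posterior = hybrids.classify(model, sub)
    posterior.to_frame().to_csv(out / "hybrid_posteriors.tsv", sep="\t", index=False)
    name1, name2 = ("taxon1", "taxon2") if anchors else ("cluster1", "cluster2")
    class_map = {name1: "P1", name2: "P2"}
    sp_label = species.set_index("id")["label"]
    merged_labels = pd.Series(
        {
            s: class_map.get(sp_label.loc[s], posterior.labels.loc[s])
            for s in gm.individuals
        },
        name="label",
    )

    # --- phenology -------------------------------------------------------
    taxon_of = merged_labels.map({"P1": "taxon1", "P2": "taxon2"})
    grid = phenology.build_grid(ds.samples, taxon_of, ("taxon1", "taxon2"))
    if truth is not None:
        sympatric = [
            l.id for l in config.sim.locations if set(l.taxa) >= {"sp1", "sp2"}
        ]
    else:
        sympatric = grid.sympatric_locations()
    region_ids = ds.samples.loc[
        ds.samples["location"].isin(sympatric), "id"
    ].tolist()
    rate = hybrids.hybridization_rate(merged_labels, region_ids=region_ids)
    _dump(rate, out / "hybridization_rate.json")
    summary["hybridization_rate"] = rate
    overlap = {}
    for index_fn, name in (
        (phenology.presence_index, "presence"),
        (phenology.abundance_index, "abundance"),
    ):
        for grain in ("by_location", "pooled"):
            overlap[f"{name}_{grain}"] = index_fn(grid, grain=grain).to_dict()
    _dump(overlap, out / "overlap_indices.json")
    summary["overlap"] = {k: v["value"] for k, v in overlap.items()}

    # --- degree-days + flight comparison --------------------------------
    station = ds.temperature[ds.temperature["source"] == "station"]
    logger = ds.temperature[ds.temperature["source"] == "logger"]
    calibrations = {}
    corrected = []
    for loc in sorted(station["location"].unique()):
        res, corr = degreedays.calibrate(
            logger[logger["location"] == loc], station[station["location"] == loc]
        )
        calibrations[loc] = res.to_dict()
        corrected.append(corr)
    _dump(calibrations, out / "calibration.json")
    dd_table = degreedays.accumulate(
        pd.concat(corrected, ignore_index=True), t_lower=config.dd_base_c
    )
    dd_table_out = dd_table.copy()
    dd_table_out["date"] = dd_table_out["date"].dt.strftime("%Y-%m-%d")
    dd_table_out.to_csv(out / "degree_days.csv", index=False)

    in_region = ds.samples[ds.samples["location"].isin(sympatric)].copy()
    in_region["taxon"] = in_region["id"].map(taxon_of)
    in_region["cum_dd"] = degreedays.dd_at_collection(dd_table, in_region)
    comparisons = {}
    g1 = in_region[in_region["taxon"] == "taxon1"]
    g2 = in_region[in_region["taxon"] == "taxon2"]
    if len(g1) and len(g2):
        comparisons["date"] = phenology.flight_summary(
            phenology.dates_to_day_of_year(g1["collection_date"]),
            phenology.dates_to_day_of_year(g2["collection_date"]),
            value="date",
        ).to_dict()
        comparisons["degree_days"] = phenology.flight_summary(
            g1["cum_dd"], g2["cum_dd"], value="degree_days"
        ).to_dict()
    _dump(comparisons, out / "flight_comparisons.json")
    summary["flight_comparisons"] = comparisons

    # --- F_ST + outlier scan --------------------------------------------
    taxon_labels = taxon_of.dropna()
    try:
        fst = selscan.wc_fst(gm, taxon_labels)
        fst.per_locus.to_csv(out / "fst_per_locus.tsv", sep="\t", index=False)
        summary["fst_overall"] = fst.overall
        alt, tot, _ = selscan.allele_counts(gm, taxon_labels)
        settings = _scan_settings(config)
        scans = [
            selscan.bayescan_scan(alt, tot, settings, seed=int(rng.integers(2**31)))
            for _ in range(config.n_scan_runs)
        ]
        scans[0].table.to_csv(out / "outlier_scan.tsv", sep="\t")
        union = selscan.union_outliers(scans)
        union.to_csv(out / "outlier_union.tsv", sep="\t", index=False)
        summary["n_outliers_union"] = int(len(union))
    except Exception as exc:  # pragma: no cover - failure manifest path
        log.exception("selscan stage failed")
        summary["failures"]["selscan"] = str(exc)

    # --- GEA -------------------------------------------------------------
    try:
        if ds.environment is None:
            raise ValueError("no environment table provided")
        locations = ds.samples.set_index("id")["location"]
        scan = gea.gea_scan(
            gm, ds.environment, locations, k=2, q_threshold=config.q_threshold
        )
        scan.table.to_csv(out / "gea_scan.tsv", sep="\t", index=False)
        summary["gea"] = {
            "k": scan.k,
            "n_discoveries": int(len(scan.discoveries())),
            "inflation": scan.inflation,
        }
    except Exception as exc:  # pragma: no cover
        log.exception("gea stage failed")
        summary["failures"]["gea"] = str(exc)

    _dump(summary, out / "summary.json")
    return summary
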