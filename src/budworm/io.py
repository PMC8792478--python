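"""Genotype and metadata I/O plus the study's SNP filters.

The central container is :class:`GenotypeMatrix`: individuals x biallelic
loci with alt-allele dosages in {0, 1, 2} and -1 for missing calls.  Loci
carry (scaffold, 1-based position, ref, alt) so that physical-distance
thinning can be applied.  Filtering follows the ddRAD convention used for
the budworm dataset: per-SNP call rate, pooled minor-allele frequency, then
10-kb thinning within scaffolds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

LOCUS_COLUMNS = ["scaffold", "pos", "ref", "alt"]


class ValidationError(ValueError):
    """Raised when an input table violates referential integrity."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNP loci, alt-allele dosage coded.

    Parameters
    ----------
    individuals : list of str
        Ordered sample identifiers.
    loci : pandas.DataFrame
        One row per locus with columns ``scaffold, pos, ref, alt``;
        positions are 1-based.
    calls : numpy.ndarray of int8, shape (n_individuals, n_loci)
        Alt-allele dosage 0/1/2, or -1 for a missing call.
    """

    individuals: list[str]
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.loci = self.loci.reset_index(drop=True)
        if self.calls.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("duplicate individual ids in GenotypeMatrix")
        if (self.loci["pos"] <= 0).any():
            raise ValidationError("locus positions must be strictly positive")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def dosages(self) -> np.ndarray:
        """Calls as float with NaN in place of missing."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.individuals)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown individuals: {missing}")
        rows = [index[s] for s in ids]
        return GenotypeMatrix(list(ids), self.loci.copy(), self.calls[rows])

    def subset_loci(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            list(self.individuals), self.loci.iloc[idx], self.calls[:, idx]
        )

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-locus alt-allele frequency over non-missing calls (NaN if none)."""
        called = self.calls != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)


@dataclass
class FilterReport:
    """Per-step locus removal counts; input = output + sum(removed)."""

    input_loci: int
    removed: dict[str, int] = field(default_factory=dict)
    output_loci: int = 0

    def check(self) -> None:
        if self.input_loci != self.output_loci + sum(self.removed.values()):
            raise AssertionError("FilterReport counts not conserved")

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_loci": self.input_loci,
                "removed": self.removed,
                "output_loci": self.output_loci,
            },
            sort_keys=True,
        )


def filter_variants(
    gm: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.10,
    thin_bp: int = 10_000,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP filters in the study's order.

    1. keep loci with call rate >= ``call_rate_min``;
    2. keep loci with minor-allele frequency >= ``maf_min`` computed over
       non-missing calls of all individuals pooled;
    3. within each scaffold, scanning loci in position order, drop any locus
       closer than ``thin_bp`` to the last *retained* locus.

    Returns the filtered matrix plus a :class:`FilterReport`.  An empty
    result is returned as an empty matrix, not an error.
    """
    if not (0.0 <= call_rate_min <= 1.0 and 0.0 <= maf_min <= 0.5 and thin_bp >= 0):
        raise ValueError("filter thresholds out of range")
    report = FilterReport(input_loci=gm.n_loci)

    keep = gm.call_rate() >= call_rate_min
    report.removed["call_rate"] = int((~keep).sum())
    gm = gm.subset_loci(keep)

    af = gm.allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(af, 1.0 - af)
    keep = np.nan_to_num(maf, nan=-1.0) >= maf_min
    report.removed["maf"] = int((~keep).sum())
    gm = gm.subset_loci(keep)

    order = np.lexsort((gm.loci["pos"].to_numpy(), gm.loci["scaffold"].to_numpy()))
    keep_mask = np.zeros(gm.n_loci, dtype=bool)
    last_scaffold, last_pos = None, None
    for i in order:
        scaf = gm.loci["scaffold"].iat[i]
        pos = int(gm.loci["pos"].iat[i])
        if scaf != last_scaffold or pos - last_pos >= thin_bp:
            keep_mask[i] = True
            last_scaffold, last_pos = scaf, pos
    report.removed["thin"] = int((~keep_mask).sum())
    gm = gm.subset_loci(keep_mask)

    report.output_loci = gm.n_loci
    report.check()
    if gm.n_loci == 0:
        log.warning("all loci removed by filtering")
    return gm, report


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path) -> GenotypeMatrix:
    """Read a biallelic-SNP GenotypeMatrix from a VCF 4.x file.

    Multiallelic or non-SNP records are skipped with a logged count; phased
    and unphased genotypes are treated identically.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise IOError(f"cannot open VCF {path}: {exc}") from exc
    individuals = list(vcf.samples)
    rows, records = [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(dose.astype(np.int8))
        records.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    loci = pd.DataFrame(records, columns=LOCUS_COLUMNS)
    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, loci, calls)


_VCF_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only biallelic VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaf in pd.unique(gm.loci["scaffold"]):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individuals)
            + "\n"
        )
        for j in range(gm.n_loci):
            row = gm.loci.iloc[j]
            gts = "\t".join(_VCF_GT[int(g)] for g in gm.calls[:, j])
            fh.write(
                f"{row.scaffold}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Tabular metadata

SAMPLE_COLUMNS = ["id", "location", "year", "interval", "collection_date"]
TEMPERATURE_COLUMNS = ["location", "date", "tmin_c", "tmax_c", "source"]


def read_samples(path, locations=None) -> pd.DataFrame:
    """Read the per-individual sample table (TSV with header).

    Checks id uniqueness and, when ``locations`` is given, that every
    sample's location is listed there.  Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "location": str})
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"sample table missing columns: {missing_cols}")
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate sample ids: {sorted(set(dup))}")
    df["collection_date"] = pd.to_datetime(df["collection_date"], format="ISO8601")
    if locations is not None:
        unknown = sorted(set(df["location"]) - set(locations))
        if unknown:
            raise ValidationError(f"samples at unlisted locations: {unknown}")
    return df


def write_samples(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["collection_date"] = pd.to_datetime(out["collection_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    out.to_csv(path, sep="\t", index=False)


def read_temperature(path) -> pd.DataFrame:
    """Read a daily temperature series CSV (location, date, tmin_c, tmax_c, source)."""
    df = pd.read_csv(path, dtype={"location": str, "source": str})
    missing_cols = [c for c in TEMPERATURE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"temperature table missing columns: {missing_cols}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df


def write_temperature(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_environment(path) -> pd.DataFrame:
    """Read the per-location environment table (TSV, keyed by ``location``)."""
    df = pd.read_csv(path, sep="\t", dtype={"location": str})
    if "location" not in df.columns:
        raise ValidationError("environment table missing 'location' column")
    dup = df["location"][df["location"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate locations: {sorted(set(dup))}")
    return df.set_index("location")
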