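"""Latent-factor genotype–environment association scan.

Population structure is absorbed by K latent factors taken from a rank-K
truncated SVD of the centered genotype matrix; each locus' dosage is then
regressed on one standardized environment variable at a time with the
factors as covariates.  Environment-coefficient z-scores are recalibrated
by the genomic-inflation factor (median z^2 / 0.456) before p-values, and
discoveries are controlled per variable by Benjamini–Hochberg at q <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix

log = logging.getLogger(__name__)

#: chi-square(1) median, the genomic-control normalizer
_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


@dataclass
class GEAScan:
    """Per-locus, per-variable association results."""

    table: pd.DataFrame  # locus, variable, beta, z, z_calibrated, pvalue, qvalue
    k: int
    inflation: dict[str, float]  # per-variable genomic-inflation factor
    variables: list[str]
    excluded_variables: list[str] = field(default_factory=list)
    q_threshold: float = 0.05

    def discoveries(self) -> pd.DataFrame:
        return self.table[self.table["qvalue"] <= self.q_threshold]


def latent_factors(gm: GenotypeMatrix, k: int) -> np.ndarray:
    """Rank-k SVD factors of the mean-imputed, centered dosage matrix."""
    if k == 0:
        return np.empty((gm.n_individuals, 0))
    d = gm.dosages()
    col_mean = np.nanmean(d, axis=0)
    keep = ~np.isnan(col_mean)
    d = np.where(np.isnan(d), col_mean, d)[:, keep]
    d -= d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    return u[:, :k] * s[:k]


def gea_scan(
    gm: GenotypeMatrix,
    environment: pd.DataFrame,
    sample_locations: pd.Series,
    k: int,
    q_threshold: float = 0.05,
) -> GEAScan:
    """Scan every locus against every environment variable.

    ``environment`` is indexed by location; ``sample_locations`` maps each
    individual id to its location (every individual must resolve).
    Constant variables are excluded with a warning; exactly collinear
    pairs are reported in the log.
    """
    if k >= gm.n_individuals:
        raise ValueError("K must be smaller than the number of individuals")
    locs = sample_locations.reindex(gm.individuals)
    if locs.isna().any():
        missing = [s for s, l in locs.items() if pd.isna(l)]
        raise ValueError(f"individuals without a location: {missing}")
    unknown = sorted(set(locs) - set(environment.index))
    if unknown:
        raise ValueError(f"locations without environment data: {unknown}")
    env = environment.loc[locs.to_numpy()]

    variables, excluded = [], []
    for col in environment.columns:
        if np.isclose(env[col].std(ddof=0), 0.0):
            excluded.append(col)
            log.warning("environment variable %r is constant; excluded", col)
        else:
            variables.append(col)
    env_z = (env[variables] - env[variables].mean()) / env[variables].std(ddof=0)
    corr = env_z.corr().to_numpy()
    collinear = np.argwhere(np.triu(np.abs(corr) > 0.999, k=1))
    for i, j in collinear:
        log.warning(
            "environment variables %r and %r are collinear",
            variables[i],
            variables[j],
        )

    d = gm.dosages()
    col_mean = np.nanmean(d, axis=0)
    Y = np.where(np.isnan(d), col_mean, d)  # (n, L)
    factors = latent_factors(gm, k)
    n, L = Y.shape

    frames = []
    inflation = {}
    for var in variables:
        X = np.column_stack([np.ones(n), env_z[var].to_numpy(), factors])
        pdim = X.shape[1]
        XtX_inv = np.linalg.pinv(X.T @ X)
        B = XtX_inv @ X.T @ Y  # (p, L)
        resid = Y - X @ B
        dof = max(n - pdim, 1)
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(XtX_inv[1, 1] * sigma2, 1e-300))
        beta = B[1]
        z = beta / se
        lam = float(np.median(z**2) / _CHI2_MEDIAN)
        lam = max(lam, 1e-12)
        z_cal = z / np.sqrt(lam)
        pvals = 2.0 * stats.norm.sf(np.abs(z_cal))
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        inflation[var] = lam
        frames.append(
            pd.DataFrame(
                {
                    "locus": np.arange(L),
                    "variable": var,
                    "beta": beta,
                    "z": z,
                    "z_calibrated": z_cal,
                    "pvalue": pvals,
                    "qvalue": qvals,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return GEAScan(
        table=table,
        k=k,
        inflation=inflation,
        variables=variables,
        excluded_variables=excluded,
        q_threshold=q_threshold,
    )


def strongest_variable(scans: list[GEAScan]) -> pd.DataFrame:
    """Resolve multi-variable hits by the largest median |z| across replicates.

    For each locus significant for more than one variable (in any
    replicate), the winning variable maximizes the median of |z_calibrated|
    over the replicate scans; exact ties break lexicographically and are
    flagged.
    """
    if not scans:
        raise ValueError("need at least one scan")
    sig = pd.concat(
        [s.table[s.table["qvalue"] <= s.q_threshold] for s in scans],
        ignore_index=True,
    )
    if sig.empty:
        return pd.DataFrame(columns=["locus", "variable", "median_abs_z", "tie"])
    all_z = pd.concat([s.table for s in scans], ignore_index=True)
    med = (
        all_z.assign(abs_z=all_z["z_calibrated"].abs())
        .groupby(["locus", "variable"])["abs_z"]
        .median()
    )
    rows = []
    for locus in sorted(sig["locus"].unique()):
        candidates = sorted(sig.loc[sig["locus"] == locus, "variable"].unique())
        scores = {v: float(med.loc[(locus, v)]) for v in candidates}
        best_score = max(scores.values())
        winners = sorted(v for v, sc in scores.items() if sc == best_score)
        rows.append(
            {
                "locus": locus,
                "variable": winners[0],
                "median_abs_z": best_score,
                "tie": len(winners) > 1,
            }
        )
    return pd.DataFrame(rows)


def grouped_scans(
    gm: GenotypeMatrix,
    environment: pd.DataFrame,
    sample_locations: pd.Series,
    group_labels: pd.Series,
    k_by_group: dict[str, int],
    filter_kwargs: dict | None = None,
) -> dict[str, GEAScan]:
    """Independent scans for each group (plus "all" for everyone).

    Each group's individuals are subset, refiltered with the standard SNP
    filters, and scanned with its own K.  A group whose individuals span
    fewer than 3 distinct environments is refused (rank-deficient design).
    """
    from .io import filter_variants

    scans: dict[str, GEAScan] = {}
    groups = {"all": list(gm.individuals)}
    for g in sorted(group_labels.dropna().unique()):
        groups[g] = [s for s in gm.individuals if group_labels.get(s) == g]
    for name, ids in groups.items():
        if name not in k_by_group:
            continue
        locs = sample_locations.reindex(ids)
        if locs.nunique() < 3:
            raise ValueError(
                f"group {name!r} spans {locs.nunique()} locations; "
                "need >= 3 distinct environments"
            )
        sub = gm.subset_individuals(ids)
        sub, _ = filter_variants(sub, **(filter_kwargs or {}))
        scans[name] = gea_scan(sub, environment, sample_locations, k_by_group[name])
    return scans
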