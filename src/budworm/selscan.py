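"""Per-locus F_ST and a Bayesian F_ST outlier scan.

Weir & Cockerham's (1984) theta is computed from the a/b/c variance
components per locus, with the genome-wide value as the ratio of sums.

The outlier scan reimplements the logistic-regression decomposition of
locus-by-population F_ST used by Bayesian outlier methods: allele counts
in population j at locus i follow a beta-binomial around an ancestral
frequency p_i with logit(F_ij) = alpha_i + beta_j.  A reversible-jump
MCMC toggles the locus effect alpha_i in and out of the model with prior
odds favouring neutrality; the posterior inclusion probability yields
q-values under the Bayesian false-discovery-rate convention, with
decisions at q <= 0.05.  Pilot runs adapt the proposal scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from .io import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# Weir & Cockerham


@dataclass
class FstTable:
    """Per-locus W&C variance components and the genome-wide ratio of sums."""

    per_locus: pd.DataFrame  # columns a, b, c, theta, defined
    overall: float
    groups: dict[str, int]  # group name -> n individuals

    @property
    def mean_theta(self) -> float:
        t = self.per_locus.loc[self.per_locus["defined"], "theta"]
        return float(t.mean())

    @property
    def sd_theta(self) -> float:
        t = self.per_locus.loc[self.per_locus["defined"], "theta"]
        return float(t.std(ddof=1))


def wc_fst(gm: GenotypeMatrix, labels: pd.Series) -> FstTable:
    """Weir–Cockerham theta per locus between labelled groups.

    ``labels`` maps individual id -> group; individuals without a label
    are ignored.  Loci where any group has no called genotype, or that are
    monomorphic across all groups, are flagged undefined and excluded from
    the genome-wide ratio of sums.
    """
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    members = {
        g: [i for i, s in enumerate(gm.individuals) if labels.get(s) == g]
        for g in groups
    }
    r = len(groups)
    L = gm.n_loci
    n = np.zeros((r, L))  # called individuals
    p = np.zeros((r, L))  # alt allele frequency
    h = np.zeros((r, L))  # observed het proportion
    for gi, g in enumerate(groups):
        calls = gm.calls[members[g]]
        called = calls != MISSING
        n[gi] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[gi] = np.where(called, calls, 0).sum(axis=0) / (2.0 * n[gi])
            h[gi] = np.where(called & (calls == 1), 1, 0).sum(axis=0) / n[gi]

    defined = (n > 0).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (
            nbar
            / nc
            * (
                s2
                - 1.0
                / (nbar - 1)
                * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            )
        )
        b = (
            nbar
            / (nbar - 1)
            * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        )
        c = hbar / 2.0
        theta = a / (a + b + c)
    mono = (pbar <= 0) | (pbar >= 1)
    defined = defined & ~mono & np.isfinite(theta)
    per_locus = pd.DataFrame(
        {"a": a, "b": b, "c": c, "theta": theta, "defined": defined}
    )
    d = defined
    denom = (a[d] + b[d] + c[d]).sum()
    overall = float(a[d].sum() / denom) if denom > 0 else float("nan")
    return FstTable(
        per_locus=per_locus,
        overall=overall,
        groups={g: len(members[g]) for g in groups},
    )


def allele_counts(gm: GenotypeMatrix, labels: pd.Series):
    """(alt allele counts, total called alleles) per locus x group."""
    groups = sorted(labels.dropna().unique())
    alt = np.zeros((gm.n_loci, len(groups)), dtype=int)
    tot = np.zeros((gm.n_loci, len(groups)), dtype=int)
    for gi, g in enumerate(groups):
        rows = [i for i, s in enumerate(gm.individuals) if labels.get(s) == g]
        calls = gm.calls[rows]
        called = calls != MISSING
        alt[:, gi] = np.where(called, calls, 0).sum(axis=0)
        tot[:, gi] = 2 * called.sum(axis=0)
    return alt, tot, groups


# ---------------------------------------------------------------------------
# Bayesian outlier scan


@dataclass(frozen=True)
class ScanSettings:
    """MCMC chain settings (the defaults match the published analysis)."""

    prior_odds: float = 10.0  # prior odds for the neutral model
    n_pilot: int = 20
    pilot_len: int = 5000
    burn_in: int = 50_000
    n_out: int = 10_000  # retained samples
    thin: int = 10
    alpha_prior_sd: float = 3.0
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.0
    q_threshold: float = 0.05


def reduced_settings(**overrides) -> ScanSettings:
    """Desk-scale preset: same model, shorter chains."""
    base = ScanSettings(n_pilot=8, pilot_len=500, burn_in=5000, n_out=2000, thin=10)
    return replace(base, **overrides)


@dataclass
class OutlierScan:
    """Posterior summaries of the outlier scan plus chain diagnostics."""

    table: pd.DataFrame  # locus, fst, alpha, posterior_prob, qvalue, decision
    settings: ScanSettings
    seed: int
    groups: list[str]
    acceptance: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def outliers(self) -> list[int]:
        return self.table.index[self.table["decision"]].tolist()


def _betabin_loglik(alt, tot, p, theta, lgamma_const):
    """Beta-binomial log-likelihood, elementwise over (L, J)."""
    a1 = theta * p[:, None]
    a2 = theta * (1.0 - p)[:, None]
    return (
        lgamma_const
        + betaln(alt + a1, tot - alt + a2)
        - betaln(a1, a2)
    )


def bayescan_scan(
    alt: np.ndarray,
    tot: np.ndarray,
    settings: ScanSettings | None = None,
    seed: int = 0,
) -> OutlierScan:
    """Reversible-jump MCMC scan for F_ST outlier loci.

    ``alt``/``tot`` are (loci x groups) alt-allele and total called-allele
    counts.  Model: a_ij ~ BetaBinomial(n_ij; theta_ij p_i, theta_ij
    (1-p_i)) with theta_ij = (1-F_ij)/F_ij and logit F_ij = alpha_i +
    beta_j.  alpha_i is toggled by reversible jump with
    ``settings.prior_odds`` favouring exclusion (neutrality); q-values are
    cumulative means of (1 - posterior inclusion probability) down the
    ranked locus list.
    """
    settings = settings or ScanSettings()
    alt = np.asarray(alt, dtype=float)
    tot = np.asarray(tot, dtype=float)
    L, J = alt.shape
    if L < 2:
        raise ValueError("scan needs at least two loci to estimate group effects")
    if J < 2:
        raise ValueError("scan needs at least two groups")
    rng = np.random.default_rng(seed)

    lgamma_const = (
        gammaln(tot + 1) - gammaln(alt + 1) - gammaln(tot - alt + 1)
    )

    # initial state
    with np.errstate(invalid="ignore"):
        p = np.clip((alt.sum(axis=1) + 1.0) / (tot.sum(axis=1) + 2.0), 0.01, 0.99)
    alpha = np.zeros(L)
    included = np.zeros(L, dtype=bool)
    beta = np.full(J, settings.beta_prior_mean)

    step_p, step_alpha, step_beta, step_rj = 0.05, 0.5, 0.2, 1.0

    def loglik_rows(p_vec, alpha_vec, beta_vec):
        f_logit = alpha_vec[:, None] + beta_vec[None, :]
        theta = np.exp(-f_logit)
        return _betabin_loglik(alt, tot, p_vec, theta, lgamma_const).sum(axis=1)

    ll_rows = loglik_rows(p, alpha, beta)

    def sweep(collect_acc=None):
        nonlocal p, alpha, included, beta, ll_rows
        # p update: reflected random walk, uniform prior
        prop = p + rng.normal(0, step_p, L)
        prop = np.abs(prop)
        prop = np.where(prop > 1, 2 - prop, prop)
        prop = np.clip(prop, 1e-6, 1 - 1e-6)
        ll_prop = loglik_rows(prop, alpha, beta)
        acc = np.log(rng.random(L)) < (ll_prop - ll_rows)
        p = np.where(acc, prop, p)
        ll_rows = np.where(acc, ll_prop, ll_rows)
        acc_p = acc.mean()

        # alpha update for included loci
        acc_a = np.nan
        if included.any():
            prop_a = np.where(included, alpha + rng.normal(0, step_alpha, L), alpha)
            ll_prop = loglik_rows(p, prop_a, beta)
            lp_ratio = (prop_a**2 - alpha**2) / (-2.0 * settings.alpha_prior_sd**2)
            acc = np.log(rng.random(L)) < (ll_prop - ll_rows + lp_ratio)
            acc &= included
            alpha = np.where(acc, prop_a, alpha)
            ll_rows = np.where(acc, ll_prop, ll_rows)
            acc_a = acc[included].mean()

        # reversible jump: toggle inclusion per locus
        prop_a = np.where(
            included, 0.0, rng.normal(0, step_rj, L)
        )  # birth draws, death proposes alpha=0
        ll_prop = loglik_rows(p, prop_a, beta)
        sd_r, sd_p = step_rj, settings.alpha_prior_sd
        birth_ratio = (
            ll_prop
            - ll_rows
            + (-0.5 * (prop_a / sd_p) ** 2 - np.log(sd_p))
            - (-0.5 * (prop_a / sd_r) ** 2 - np.log(sd_r))
            - np.log(settings.prior_odds)
        )
        death_ratio = (
            ll_prop
            - ll_rows
            - (-0.5 * (alpha / sd_p) ** 2 - np.log(sd_p))
            + (-0.5 * (alpha / sd_r) ** 2 - np.log(sd_r))
            + np.log(settings.prior_odds)
        )
        ratio = np.where(included, death_ratio, birth_ratio)
        acc = np.log(rng.random(L)) < ratio
        alpha = np.where(acc, prop_a, alpha)
        ll_rows = np.where(acc, ll_prop, ll_rows)
        included = np.where(acc, ~included, included)
        acc_rj = acc.mean()

        # beta update (group effects), full-likelihood Metropolis
        acc_b = 0.0
        for j in range(J):
            prop_b = beta.copy()
            prop_b[j] += rng.normal(0, step_beta)
            ll_prop = loglik_rows(p, alpha, prop_b)
            lp = (
                (beta[j] - settings.beta_prior_mean) ** 2
                - (prop_b[j] - settings.beta_prior_mean) ** 2
            ) / (2.0 * settings.beta_prior_sd**2)
            if np.log(rng.random()) < (ll_prop.sum() - ll_rows.sum() + lp):
                beta = prop_b
                ll_rows = ll_prop
                acc_b += 1.0 / J
        if collect_acc is not None:
            collect_acc.append((acc_p, acc_a, acc_rj, acc_b))

    # pilot runs: adapt proposal scales toward 25-45% acceptance
    for _ in range(settings.n_pilot):
        acc_log: list[tuple] = []
        for _ in range(settings.pilot_len):
            sweep(acc_log)
        rates = np.nanmean(np.array(acc_log, dtype=float), axis=0)

        def tune(step, rate):
            if not np.isfinite(rate):
                return step
            if rate < 0.25:
                return step * 0.8
            if rate > 0.45:
                return step * 1.25
            return step

        step_p = min(tune(step_p, rates[0]), 0.4)
        step_alpha = tune(step_alpha, rates[1])
        step_beta = tune(step_beta, rates[3])
        step_rj = float(np.clip(tune(step_rj, rates[2]), 0.2, settings.alpha_prior_sd))

    for _ in range(settings.burn_in):
        sweep()

    incl_sum = np.zeros(L)
    alpha_sum = np.zeros(L)
    fst_sum = np.zeros(L)
    acc_log = []
    for _ in range(settings.n_out):
        for _ in range(settings.thin):
            sweep(acc_log)
        incl_sum += included
        alpha_sum += alpha
        f = 1.0 / (1.0 + np.exp(-(alpha[:, None] + beta[None, :])))
        fst_sum += f.mean(axis=1)
    pip = incl_sum / settings.n_out
    alpha_hat = alpha_sum / settings.n_out
    fst_hat = fst_sum / settings.n_out

    order = np.argsort(-pip, kind="stable")
    cm = np.cumsum(1.0 - pip[order]) / np.arange(1, L + 1)
    # tied posterior probabilities share one q (cumulative mean at block end)
    pip_sorted = pip[order]
    block_end = np.r_[np.flatnonzero(np.diff(pip_sorted) != 0), L - 1]
    q_sorted = np.empty(L)
    start = 0
    for end in block_end:
        q_sorted[start : end + 1] = cm[end]
        start = end + 1
    qvals = np.empty(L)
    qvals[order] = q_sorted
    decision = qvals <= settings.q_threshold

    rates = np.nanmean(np.array(acc_log, dtype=float), axis=0)
    acceptance = {
        "p": float(rates[0]),
        "alpha": float(rates[1]) if np.isfinite(rates[1]) else float("nan"),
        "rj": float(rates[2]),
        "beta": float(rates[3]),
    }
    warnings = []
    if acceptance["p"] < 0.05 or acceptance["beta"] < 0.05:
        warnings.append("chain acceptance below 5% after pilot adaptation")

    table = pd.DataFrame(
        {
            "fst": fst_hat,
            "alpha": alpha_hat,
            "posterior_prob": pip,
            "qvalue": qvals,
            "decision": decision,
        }
    )
    return OutlierScan(
        table=table,
        settings=settings,
        seed=seed,
        groups=[str(j) for j in range(J)],
        acceptance=acceptance,
        warnings=warnings,
    )


def union_outliers(scans: list[OutlierScan]) -> pd.DataFrame:
    """Union of per-run outlier locus sets, with per-run provenance."""
    hits: dict[int, list[int]] = {}
    for run_idx, scan in enumerate(scans):
        for locus in scan.outliers():
            hits.setdefault(locus, []).append(run_idx)
    rows = [
        {"locus": locus, "n_runs": len(runs), "runs": runs}
        for locus, runs in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["locus", "n_runs", "runs"])
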