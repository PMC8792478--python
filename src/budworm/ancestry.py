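"""Genetic clustering: PCA, maximum-likelihood admixture, and k selection.

The admixture model treats each individual's dosage at a locus as
Binomial(2, sum_k Q_ik P_kl): Q holds per-individual cluster memberships,
P per-cluster allele frequencies.  It is fit by expectation–maximization
over latent allele origins, which increases the binomial log-likelihood
monotonically.  Missing genotypes are skipped per locus.  Cluster number
is selected with both the mean log-likelihood curve and Evanno's delta-k
over replicate fits; species identities come from a strict >90% membership
threshold with cluster-to-taxon naming anchored on designated samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

_EPS = 1e-9


def pca(gm: GenotypeMatrix, n_components: int = 10):
    """Principal components of the dosage matrix.

    Missing entries are replaced by the locus mean, loci are mean-centered,
    and the matrix decomposed by truncated SVD.  All-missing loci are
    dropped.  Returns (scores DataFrame indexed by individual,
    explained-variance fractions).
    """
    if gm.n_individuals < 2 or gm.n_loci < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 loci")
    d = gm.dosages()
    col_mean = np.nanmean(d, axis=0)
    keep = ~np.isnan(col_mean)
    d = np.where(np.isnan(d), col_mean, d)[:, keep]
    d -= d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    total_var = (s**2).sum()
    evf = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    df = pd.DataFrame(
        scores, index=gm.individuals, columns=[f"PC{i+1}" for i in range(k)]
    )
    return df, evf


@dataclass
class AdmixtureFit:
    """EM admixture solution for one k and seed."""

    k: int
    individuals: list[str]
    Q: np.ndarray  # (n, k) memberships, rows sum to 1
    P: np.ndarray  # (k, L) cluster allele frequencies
    loglik: float
    loglik_trace: list[float]
    n_iter: int
    converged: bool
    seed: int

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q,
            index=self.individuals,
            columns=[f"cluster{j+1}" for j in range(self.k)],
        )


def _admixture_loglik(calls, Q, P) -> float:
    theta = np.clip(Q @ P, _EPS, 1 - _EPS)
    called = calls != MISSING
    g = np.where(called, calls, 0).astype(float)
    ll = g * np.log(theta) + (2.0 - g) * np.log1p(-theta)
    return float(ll[called].sum())


def fit_admixture(
    gm: GenotypeMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    init: str = "pca",
) -> AdmixtureFit:
    """Fit the binomial admixture model by EM.

    The E-step attributes each observed allele copy to a cluster; the
    M-step re-estimates P (cluster frequencies) and Q (memberships).  The
    log-likelihood is non-decreasing; iteration stops when its change
    falls below ``tol`` or at ``max_iter``.

    ``init="pca"`` (default) seeds memberships from k-means clusters on the
    leading principal components, jittered by the seed so replicate runs
    explore different starts; ``init="random"`` uses Dirichlet rows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > gm.n_individuals:
        raise ValueError(f"k={k} exceeds {gm.n_individuals} individuals")
    rng = np.random.default_rng(seed)
    calls = gm.calls
    called = calls != MISSING
    g = np.where(called, calls, 0).astype(float)
    g_ref = np.where(called, 2.0 - g, 0.0)
    g_alt = np.where(called, g, 0.0)
    n_called = called.sum(axis=1).astype(float)  # per individual

    if init == "pca" and k >= 2 and gm.n_loci >= 2:
        from scipy.cluster.vq import kmeans2

        scores, _ = pca(gm, n_components=max(k - 1, 1))
        _, assign = kmeans2(
            scores.to_numpy(), k, minit="++", seed=np.random.default_rng(seed)
        )
        Q = np.full((gm.n_individuals, k), 0.1 / max(k - 1, 1))
        Q[np.arange(gm.n_individuals), assign] = 0.9
        Q += rng.dirichlet(np.ones(k), size=gm.n_individuals) * 0.1
        Q /= Q.sum(axis=1, keepdims=True)
    else:
        Q = rng.dirichlet(np.ones(k), size=gm.n_individuals)
    base = np.clip(gm.allele_freq(), 0.05, 0.95)
    base = np.nan_to_num(base, nan=0.5)
    P = np.clip(base + rng.normal(0, 0.1, size=(k, gm.n_loci)), 0.01, 0.99)

    trace = []
    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        theta = np.clip(Q @ P, _EPS, 1 - _EPS)  # (n, L)
        # responsibilities per allele copy: alt copies ~ Q_ik P_kl / theta
        A = np.zeros_like(Q)
        B_num = np.zeros((k, gm.n_loci))
        B_den = np.zeros((k, gm.n_loci))
        for j in range(k):
            r_alt = Q[:, j : j + 1] * P[j] / theta  # (n, L)
            r_ref = Q[:, j : j + 1] * (1 - P[j]) / (1 - theta)
            a = g_alt * r_alt
            b = g_ref * r_ref
            A[:, j] = a.sum(axis=1) + b.sum(axis=1)
            B_num[j] = a.sum(axis=0)
            B_den[j] = (a + b).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(B_den > 0, B_num / B_den, P)
        P = np.clip(P, _EPS, 1 - _EPS)
        Q = A / (2.0 * np.maximum(n_called, 1.0))[:, None]
        Q = np.clip(Q, _EPS, None)
        Q /= Q.sum(axis=1, keepdims=True)
        ll = _admixture_loglik(calls, Q, P)
        trace.append(ll)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    return AdmixtureFit(
        k=k,
        individuals=list(gm.individuals),
        Q=Q,
        P=P,
        loglik=trace[-1],
        loglik_trace=trace,
        n_iter=len(trace),
        converged=converged,
        seed=seed,
    )


def align_replicates(fits: list[AdmixtureFit]) -> list[AdmixtureFit]:
    """Align replicate fits to the first by greedy cluster matching on P
    correlation, so replicate Q matrices can be averaged."""
    if not fits:
        return fits
    ref = fits[0]
    aligned = [ref]
    for fit in fits[1:]:
        k = fit.k
        corr = np.corrcoef(np.vstack([ref.P, fit.P]))[:k, k:]
        corr = np.nan_to_num(corr, nan=-1.0)
        perm = np.full(k, -1)
        used_rows, used_cols = set(), set()
        for _ in range(k):
            masked = corr.copy()
            for r in used_rows:
                masked[r, :] = -np.inf
            for c in used_cols:
                masked[:, c] = -np.inf
            r, c = np.unravel_index(np.argmax(masked), masked.shape)
            perm[r] = c
            used_rows.add(r)
            used_cols.add(c)
        aligned.append(
            AdmixtureFit(
                k=k,
                individuals=fit.individuals,
                Q=fit.Q[:, perm],
                P=fit.P[perm],
                loglik=fit.loglik,
                loglik_trace=fit.loglik_trace,
                n_iter=fit.n_iter,
                converged=fit.converged,
                seed=fit.seed,
            )
        )
    return aligned


def average_replicates(fits: list[AdmixtureFit]) -> AdmixtureFit:
    """Mean Q/P over aligned replicates (the CLUMPAK-style average)."""
    fits = align_replicates(fits)
    Q = np.mean([f.Q for f in fits], axis=0)
    Q /= Q.sum(axis=1, keepdims=True)
    P = np.mean([f.P for f in fits], axis=0)
    best = max(fits, key=lambda f: f.loglik)
    return AdmixtureFit(
        k=best.k,
        individuals=best.individuals,
        Q=Q,
        P=P,
        loglik=best.loglik,
        loglik_trace=best.loglik_trace,
        n_iter=best.n_iter,
        converged=all(f.converged for f in fits),
        seed=best.seed,
    )


@dataclass
class KSelection:
    """Log-likelihood and Evanno delta-k summary over candidate k."""

    table: pd.DataFrame  # k, mean_loglik, sd_loglik, delta_k
    chosen_k: int
    criterion: str  # "delta_k" or "loglik_fallback"
    ambiguous: bool


def select_k(replicate_logliks: dict[int, list[float]]) -> KSelection:
    """Choose the cluster number from replicate log-likelihoods.

    delta-k for interior k is mean(|L(k+1) - 2 L(k) + L(k-1)|) over
    replicate-paired triples divided by sd(L(k)); the chosen k is its
    argmax, with the LnP(k) curve reported alongside.  With no interior k
    (or all sds zero) selection falls back to the best mean log-likelihood,
    flagged ambiguous when the curve is flat.
    """
    ks = sorted(replicate_logliks)
    means = {k: float(np.mean(replicate_logliks[k])) for k in ks}
    sds = {k: float(np.std(replicate_logliks[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        delta = np.nan
        if k != ks[0] and k != ks[-1]:
            lo, mid, hi = (
                np.asarray(replicate_logliks[k - 1], dtype=float),
                np.asarray(replicate_logliks[k], dtype=float),
                np.asarray(replicate_logliks[k + 1], dtype=float),
            )
            n = min(len(lo), len(mid), len(hi))
            if n < 3:
                raise ValueError("select_k needs >=3 replicates per k")
            second = np.abs(hi[:n] - 2 * mid[:n] + lo[:n])
            delta = float(np.mean(second) / sds[k]) if sds[k] > 0 else np.nan
        rows.append(
            {"k": k, "mean_loglik": means[k], "sd_loglik": sds[k], "delta_k": delta}
        )
    table = pd.DataFrame(rows)
    deltas = table["delta_k"].to_numpy()
    if np.isfinite(deltas).any():
        idx = int(np.nanargmax(deltas))
        chosen = int(table["k"].iat[idx])
        criterion = "delta_k"
        finite = deltas[np.isfinite(deltas)]
        ambiguous = bool(np.all(np.abs(finite) < 1e-6))
    else:
        chosen = int(max(ks, key=lambda k: means[k]))
        criterion = "loglik_fallback"
        spread = max(means.values()) - min(means.values())
        ambiguous = bool(spread < 1e-6)
    return KSelection(table=table, chosen_k=chosen, criterion=criterion, ambiguous=ambiguous)


def assign_species(
    fit: AdmixtureFit,
    threshold: float = 0.90,
    anchors: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Label individuals by strict >threshold membership to one of two clusters.

    ``anchors`` maps sample id -> taxon name; each taxon name is attached to
    the cluster with the higher mean membership among its anchors.  Without
    anchors, labels are "cluster1"/"cluster2".  Individuals exceeding the
    threshold for neither cluster are "ambiguous" (candidate hybrids).
    """
    if fit.k != 2:
        raise ValueError("species assignment expects a k=2 fit")
    names = ["cluster1", "cluster2"]
    if anchors:
        taxa = sorted(set(anchors.values()))
        if len(taxa) != 2:
            raise ValueError("anchors must name exactly two taxa")
        idx = {s: i for i, s in enumerate(fit.individuals)}
        mean_q = {}
        for taxon in taxa:
            members = [idx[s] for s in anchors if anchors[s] == taxon and s in idx]
            if not members:
                raise ValueError(f"no anchor samples present for taxon {taxon}")
            mean_q[taxon] = fit.Q[members].mean(axis=0)
        first = max(taxa, key=lambda t: mean_q[t][0])
        second = [t for t in taxa if t != first][0]
        names = [first, second]
    labels = []
    for q in fit.Q:
        if q[0] > threshold:
            labels.append(names[0])
        elif q[1] > threshold:
            labels.append(names[1])
        else:
            labels.append("ambiguous")
    return pd.DataFrame(
        {
            "id": fit.individuals,
            "q1": fit.Q[:, 0],
            "q2": fit.Q[:, 1],
            "label": labels,
        }
    )


def substructure(
    gm: GenotypeMatrix,
    species_labels: pd.DataFrame,
    species: str,
    exclude: list[str] | None = None,
    k: int = 2,
    n_replicates: int = 3,
    seed: int = 0,
    filter_kwargs: dict | None = None,
):
    """Rerun clustering within one species to resolve subspecies.

    The species' individuals (minus ``exclude``, e.g. F1 hybrids) are
    subset, their loci refiltered with the standard SNP filters, and the
    admixture model refit.  Returns (averaged fit, per-individual majority
    labels at 0.5, KSelection over k in {1..k}).
    """
    from .io import filter_variants

    wanted = species_labels.loc[species_labels["label"] == species, "id"].tolist()
    if exclude:
        wanted = [s for s in wanted if s not in set(exclude)]
    if len(wanted) < 2:
        raise ValueError(f"species {species!r} has <2 individuals")
    sub = gm.subset_individuals(wanted)
    sub, _ = filter_variants(sub, **(filter_kwargs or {}))
    if sub.n_loci == 0:
        raise ValueError("no loci survive refiltering in substructure run")
    rng = np.random.default_rng(seed)
    logliks: dict[int, list[float]] = {}
    fits_by_k: dict[int, list[AdmixtureFit]] = {}
    for kk in range(1, k + 1):
        fits = [
            fit_admixture(sub, kk, seed=int(rng.integers(2**31)))
            for _ in range(n_replicates)
        ]
        fits_by_k[kk] = fits
        logliks[kk] = [f.loglik for f in fits]
    ksel = select_k(logliks)
    fit = average_replicates(fits_by_k[k])
    majority = np.argmax(fit.Q, axis=1)
    labels = pd.DataFrame(
        {
            "id": fit.individuals,
            "subcluster": [f"{species}_sub{j+1}" for j in majority],
            "majority_q": fit.Q[np.arange(len(majority)), majority],
        }
    )
    return fit, labels, ksel
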