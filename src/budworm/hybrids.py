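"""Six-class hybrid assignment from fixed parental allele frequencies.

Each individual is scored against the classes P1, P2, F1, F2, BC1 and BC2.
A class is a distribution (pi0, pi1, pi2) over the number of allele copies
of parental-1 origin a genotype carries; given per-locus parental
frequencies (p1, p2) the genotype likelihood mixes Hardy–Weinberg terms
for 0 or 2 parental-1 copies with a cross term for exactly one.  Parental
frequencies are estimated once from high-confidence reference panels
(>99% cluster membership) with additive smoothing, rather than updated in
an MCMC.  Posteriors are uniform-prior by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

HYBRID_CLASSES = ("P1", "P2", "F1", "F2", "BC1", "BC2")

#: (pi0, pi1, pi2): probability a genotype carries 0/1/2 parental-1-origin alleles
MIXING = {
    "P1": (0.0, 0.0, 1.0),
    "P2": (1.0, 0.0, 0.0),
    "F1": (0.0, 1.0, 0.0),
    "F2": (0.25, 0.5, 0.25),
    "BC1": (0.0, 0.5, 0.5),
    "BC2": (0.5, 0.5, 0.0),
}


@dataclass
class HybridModel:
    """Fixed parental allele frequencies plus the class mixing table."""

    p1: np.ndarray  # parental-1 alt frequency per locus, in (0, 1)
    p2: np.ndarray
    smoothing: float
    n_panel1: int
    n_panel2: int


def build_model(
    gm: GenotypeMatrix,
    panel1: list[str],
    panel2: list[str],
    smoothing: float = 0.5,
) -> HybridModel:
    """Estimate parental frequencies from two reference panels.

    p-hat = (alt count + smoothing) / (2 n_called + 2 smoothing) per panel,
    keeping frequencies strictly inside (0, 1) even at fixed differences.
    """
    if not panel1 or not panel2:
        raise ValueError("both parental panels must be non-empty")

    def freqs(ids):
        sub = gm.subset_individuals(ids)
        called = sub.calls != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, sub.calls, 0).sum(axis=0)
        return (alt + smoothing) / (2.0 * n_called + 2.0 * smoothing)

    return HybridModel(
        p1=freqs(panel1),
        p2=freqs(panel2),
        smoothing=smoothing,
        n_panel1=len(panel1),
        n_panel2=len(panel2),
    )


def _genotype_probs(p: np.ndarray) -> np.ndarray:
    """Hardy–Weinberg P(g) for g=0,1,2; shape (3, L)."""
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def _cross_probs(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """P(g) when one allele is drawn from each parental pool; shape (3, L)."""
    return np.stack(
        [(1 - p1) * (1 - p2), p1 * (1 - p2) + p2 * (1 - p1), p1 * p2]
    )


def class_likelihoods(model: HybridModel) -> dict[str, np.ndarray]:
    """Per-class genotype probability tables P(g | class, locus), (3, L)."""
    hw1 = _genotype_probs(model.p1)
    hw2 = _genotype_probs(model.p2)
    cross = _cross_probs(model.p1, model.p2)
    return {
        cls: pi0 * hw2 + pi1 * cross + pi2 * hw1
        for cls, (pi0, pi1, pi2) in MIXING.items()
    }


@dataclass
class HybridPosterior:
    """Per-individual class posteriors (rows sum to 1) and max labels."""

    posteriors: pd.DataFrame  # individuals x classes
    labels: pd.Series
    n_loci_used: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.posteriors.copy()
        out["label"] = self.labels
        out["n_loci"] = self.n_loci_used
        return out.reset_index(names="id")


def classify(
    model: HybridModel, gm: GenotypeMatrix, prior: dict[str, float] | None = None
) -> HybridPosterior:
    """Posterior over the six classes for every individual in ``gm``.

    Log-likelihoods are summed over non-missing loci; the posterior is
    prior x likelihood, normalized.  An individual with zero non-missing
    loci gets a NaN posterior and the label "undefined".
    """
    if prior is None:
        prior = {c: 1.0 / len(HYBRID_CLASSES) for c in HYBRID_CLASSES}
    tables = class_likelihoods(model)
    called = gm.calls != MISSING
    g = np.where(called, gm.calls, 0).astype(int)
    n_used = called.sum(axis=1)

    logliks = np.zeros((gm.n_individuals, len(HYBRID_CLASSES)))
    for ci, cls in enumerate(HYBRID_CLASSES):
        table = np.log(np.clip(tables[cls], 1e-300, None))  # (3, L)
        per_locus = table[g, np.arange(gm.n_loci)[None, :]]  # (n, L)
        logliks[:, ci] = np.where(called, per_locus, 0.0).sum(axis=1)
        logliks[:, ci] += np.log(prior[cls])

    shifted = logliks - logliks.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    post[n_used == 0] = np.nan
    labels = pd.Series(
        np.where(
            n_used > 0,
            np.asarray(HYBRID_CLASSES)[np.argmax(logliks, axis=1)],
            "undefined",
        ),
        index=gm.individuals,
        name="label",
    )
    return HybridPosterior(
        posteriors=pd.DataFrame(post, index=gm.individuals, columns=HYBRID_CLASSES),
        labels=labels,
        n_loci_used=pd.Series(n_used, index=gm.individuals, name="n_loci"),
    )


def subset_snps(
    gm: GenotypeMatrix, mode: str = "first_n", n: int = 400, seed: int = 0
) -> GenotypeMatrix:
    """Take the first n loci, or n random loci, for the classifier run.

    Mirrors the practice of running the classifier on a 400-SNP subset and
    re-running on a random subset as a congruence check.  Asking for more
    loci than exist returns the full matrix with a warning.
    """
    import logging

    if mode not in {"first_n", "random_n"}:
        raise ValueError(f"unknown subset mode {mode!r}")
    if n >= gm.n_loci:
        if n > gm.n_loci:
            logging.getLogger(__name__).warning(
                "requested %d loci, only %d available; using all", n, gm.n_loci
            )
        return gm
    if mode == "first_n":
        return gm.subset_loci(np.arange(n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(gm.n_loci, size=n, replace=False))
    return gm.subset_loci(idx)


def label_agreement(a: pd.Series, b: pd.Series) -> float:
    """Fraction of individuals with identical class labels in two runs."""
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no shared individuals")
    return float((a.loc[common] == b.loc[common]).mean())


def hybridization_rate(labels: pd.Series, region_ids=None) -> dict:
    """F1 rate relative to the parental clusters.

    rate = n_F1 / (n_F1 + n_P1 + n_P2) over individuals passing the region
    filter; later-generation hybrids (F2/BC) are counted separately and
    excluded from the denominator.  Returns the rate (percent) with its
    numerator and denominator, echoing an "x% (a of b)" style report.
    """
    if region_ids is not None:
        labels = labels.loc[labels.index.intersection(region_ids)]
    counts = labels.value_counts()
    n_f1 = int(counts.get("F1", 0))
    n_parental = int(counts.get("P1", 0) + counts.get("P2", 0))
    denom = n_f1 + n_parental
    rate = 100.0 * n_f1 / denom if denom else float("nan")
    return {
        "rate_percent": rate,
        "n_f1": n_f1,
        "n_parental": n_parental,
        "denominator": denom,
        "n_later_generation": int(
            sum(counts.get(c, 0) for c in ("F2", "BC1", "BC2"))
        ),
        "display": f"{rate:.1f}% ({n_f1} of {denom})" if denom else "undefined",
    }
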