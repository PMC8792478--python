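"""Assign taxon identities and hybrid classes from genotypes.

Fits the binomial admixture model at k=2, labels individuals by the
strict >90% membership rule, builds >99%-membership parental reference
panels, and classifies everyone into the six classes
(P1, P2, F1, F2, BC1, BC2).  Ends with the F1 hybridization rate.
"""

from budworm import ancestry, hybrids
from budworm.io import filter_variants
from budworm.simulate import SimConfig, simulate_dataset

ds = simulate_dataset(SimConfig(seed=42, n_loci=800))
gm, report = filter_variants(ds.genotypes)
print("SNP filtering         :", report.to_json())

fit = ancestry.fit_admixture(gm, k=2, seed=0)
species = ancestry.assign_species(fit, threshold=0.90)
print("species labels        :", species["label"].value_counts().to_dict())

panel1 = species.loc[species["q1"] > 0.99, "id"].tolist()
panel2 = species.loc[species["q2"] > 0.99, "id"].tolist()
sub = hybrids.subset_snps(gm, "first_n", n=400)
model = hybrids.build_model(sub, panel1, panel2)
posterior = hybrids.classify(model, sub)
print("hybrid classes        :", posterior.labels.value_counts().to_dict())

rate = hybrids.hybridization_rate(posterior.labels)
print("hybridization rate    :", rate["display"])
# "x% (a of b)": F1 individuals relative to F1 + both parental classes;
# the 'ambiguous' admixture individuals are the classifier's F1 calls.
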