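"""Genotype an inversion in an admixed two-ancestry cohort.

In structured cohorts the region's haplotypes separate by ancestry as well
as by inversion state; calling genotypes without modeling ancestry merges
clusters across groups.  The joint model fits a per-ancestry allele
frequency and cluster geometry, using the second embedding component as the
ancestry-informative variable.
"""

import numpy as np

import invkit as ik

cfg = ik.SimConfig(n_ind=1500, n_snp=300, f_by_ancestry=(0.48, 0.74),
                   ancestry_props=(0.5, 0.5), pool_divergence=0.15,
                   ancestry_divergence=0.02, admix_fraction=0.05, seed=11)
gm, truth = ik.simulate_cohort(cfg)
emb = ik.embed_region(gm, k=2)

af = ik.fit_invclust_ancestry(emb, G=2, cfg=ik.InvClustConfig(seed=3))

print(f"{cfg.n_ind} individuals, true frequencies {cfg.f_by_ancestry}, "
      f"{cfg.admix_fraction:.0%} admixed")
for g, info in enumerate(af.per_ancestry_fits()):
    print(f"  group {g + 1}: weight {info['pi']:.2f}, "
          f"inverted-allele frequency {info['f']:.3f} "
          f"(or {1 - info['f']:.3f} under the flipped labeling)")
anc = truth.table["ancestry_hap1"].to_numpy()
pure = truth.ancestry != "Mixed"
lab = af.ancestry_labels
acc = max(np.mean(lab[pure] == anc[pure]), np.mean((1 - lab[pure]) == anc[pure]))
print(f"ancestry assignment accuracy (non-admixed individuals): {acc:.3f}")
# per-group frequencies match the simulated 0.48/0.74 (up to the global
# label orientation); admixed individuals split their ancestry posterior
# without disturbing the genotype layer.
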