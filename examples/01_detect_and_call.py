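"""Detect an inversion signal and call genotypes in a simulated cohort.

Simulates 1000 individuals over a 300-SNP region whose core segment carries
an inversion at allele frequency 0.4, embeds the region by MDS of IBS
distances, tests for the three-cluster signal and calls genotypes.
"""

import invkit as ik

cfg = ik.SimConfig(n_ind=1000, n_snp=300, f_by_ancestry=(0.4,),
                   pool_divergence=0.05, seed=7)
gm, truth = ik.simulate_cohort(cfg)
emb = ik.embed_region(gm, k=2)

sig = ik.detect_signal(emb, ik.InvClustConfig(seed=1))
fit = sig.fit
calls = ik.call_genotypes(fit, call_threshold=0.9, sample_ids=gm.samples["sample_id"])

print(f"region {cfg.region} | {gm.n_individuals} individuals x {gm.n_variants} SNPs")
print(f"inversion signal detected: {sig.detected} (delta BIC = {sig.delta_bic:.1f})")
print(f"inverted-allele frequency estimate: {fit.f:.3f} "
      "(labeling orientation is a convention: f and 1-f describe the same fit)")
print(calls.table["label"].value_counts().to_string())
acc = (calls.labels[calls.called] ==
       truth.genotypes[calls.called]).mean()
flip = {"NN": "II", "NI": "NI", "II": "NN"}
acc = max(acc, (calls.table["label"][calls.called].map(flip).to_numpy()
                == truth.genotypes[calls.called]).mean())
print(f"call accuracy vs simulated truth (orientation-resolved): {acc:.3f}")
# delta BIC > 0 means the HWE-constrained three-cluster model explains the
# embedding better than one Gaussian: the region behaves like an inversion
# polymorphism; the frequency and the cluster sizes follow Hardy-Weinberg.
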