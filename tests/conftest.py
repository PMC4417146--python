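import numpy as np
import pytest

import invkit as ik

#: global genotype-label flip (orientation of the biallelic labeling is a
#: convention; which cluster is physically inverted needs external anchoring)
FLIP = {"NN": "II", "NI": "NI", "II": "NN", "uncalled": "uncalled"}


def flip_labels(labels):
    return np.array([FLIP[str(v)] for v in labels], dtype=object)


def oriented_accuracy(labels, truth_labels):
    """3-class accuracy after resolving the global label orientation.

    Returns (accuracy, flipped) where flipped says whether the f -> 1-f
    relabeling was the better match.
    """
    labels = np.asarray(labels, dtype=object)
    truth_labels = np.asarray(truth_labels, dtype=object)
    a1 = float(np.mean(labels == truth_labels))
    a2 = float(np.mean(flip_labels(labels) == truth_labels))
    return (a1, False) if a1 >= a2 else (a2, True)


@pytest.fixture(scope="session")
def separable_cohort():
    """Well-separated single-ancestry inversion cohort (the standard
    recovery setting: N=1000, 300 SNPs, f=0.4, founder divergence 5%)."""
    cfg = ik.SimConfig(n_ind=1000, n_snp=300, f_by_ancestry=(0.4,),
                       pool_divergence=0.05, seed=7)
    gm, truth = ik.simulate_cohort(cfg)
    return cfg, gm, truth


@pytest.fixture(scope="session")
def separable_fit(separable_cohort):
    _, gm, truth = separable_cohort
    emb = ik.embed_region(gm, k=2)
    fit = ik.fit_invclust(emb, ik.InvClustConfig(seed=1))
    return emb, fit, truth


@pytest.fixture(scope="session")
def two_ancestry_cohort():
    """Deeply diverged inversion with two ancestries at inverted-allele
    frequencies 0.48 / 0.74 (admixed-cohort setting)."""
    cfg = ik.SimConfig(n_ind=1500, n_snp=300, f_by_ancestry=(0.48, 0.74),
                       ancestry_props=(0.5, 0.5), pool_divergence=0.15,
                       ancestry_divergence=0.02, seed=11)
    gm, truth = ik.simulate_cohort(cfg)
    emb = ik.embed_region(gm, k=2)
    return cfg, gm, truth, emb


@pytest.fixture(scope="session")
def trio_cohort():
    """200 simulated father-mother-child trios in the separable setting,
    with fitted genotype calls."""
    cfg = ik.SimConfig(n_ind=0, n_snp=300, n_trios=200, seed=9)
    gm, truth = ik.simulate_trios(cfg)
    emb = ik.embed_region(gm, k=2)
    fit = ik.fit_invclust(emb, ik.InvClustConfig(seed=1))
    calls = ik.call_genotypes(fit, sample_ids=gm.samples["sample_id"])
    return gm, truth, calls


@pytest.fixture(scope="session")
def ldscan_cohort():
    """Deeply diverged inversion at known SNP breakpoints (30..90) with
    carrier allele frequency 0.3, for breakpoint-scan tests."""
    cfg = ik.SimConfig(n_ind=300, n_snp=120, f_by_ancestry=(0.3,),
                       inv_start=30, inv_end=89, pool_divergence=0.3, seed=5)
    gm, truth = ik.simulate_cohort(cfg)
    return cfg, gm, truth
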