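"""Synthetic cohorts with the footprint of an inversion polymorphism.

The generator emulates the statistical structure the detection methods rely
on: two haplotype pools (inverted / non-inverted) whose founders diverge at
a per-site rate ``pool_divergence`` inside the inverted segment because
recombination is suppressed in heterozygotes; star-shaped within-pool
variation (per-site mutation at ``within_pool_mut`` plus within-pool-only
recombination); one or more ancestries whose allele-frequency backgrounds
differ by ``ancestry_divergence``; haplotype-level admixture; parent-child
trios with Mendelian transmission of pool labels; and a binary low-trait
phenotype with a recessive effect of the inverted-homozygote genotype.

It is a founder-divergence model, not a coalescent: within-pool genealogy is
a star, and background LD decay is absent.  That is sufficient to produce
the three-cluster MDS footprint and the cross-breakpoint LD disruption the
callers exploit, and it keeps ground truth exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import GenotypeMatrix, RegionSpec

GENOTYPE_LABELS = ("NN", "NI", "II")


@dataclass
class PhenotypeConfig:
    """Recessive binary outcome, or a quantitative trait dichotomized at a
    percentile (the low-BMI style case definition)."""

    model: str = "recessive"       # "recessive" (binary) or "quantitative"
    odds_ratio: float = 2.0
    baseline_prev: float = 0.05
    effect: float = -0.5           # quantitative shift for II individuals
    noise_sd: float = 1.0
    case_percentile: float = 5.0   # cases strictly below this percentile


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults produce a well-separated single-ancestry cohort: a 300-SNP
    region whose middle ~87% is inverted, founder pools diverged at 5% of
    segment sites, within-pool mutation 0.5% per site, inverted-allele
    frequency 0.4.
    """

    n_ind: int = 1000
    n_snp: int = 300
    region: RegionSpec = field(default_factory=lambda: RegionSpec("8", 6_909_899, 12_617_968))
    inv_start: int | None = None   # SNP indices, inclusive; default ~7%/93% of n_snp
    inv_end: int | None = None
    f_by_ancestry: tuple = (0.4,)
    ancestry_props: tuple = (1.0,)
    ancestry_divergence: float = 0.015
    pool_divergence: float = 0.05
    within_pool_mut: float = 0.005
    recomb_within: float = 0.01
    n_trios: int = 0
    admix_fraction: float = 0.0
    phenotype: PhenotypeConfig | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.inv_start is None:
            self.inv_start = round(0.07 * self.n_snp)
        if self.inv_end is None:
            self.inv_end = round(0.93 * self.n_snp) - 1
        if len(self.f_by_ancestry) != len(self.ancestry_props):
            raise ValueError("f_by_ancestry and ancestry_props lengths differ")
        if not np.isclose(sum(self.ancestry_props), 1.0):
            raise ValueError("ancestry_props must sum to 1")
        for v in (*self.f_by_ancestry, self.pool_divergence, self.within_pool_mut,
                  self.recomb_within, self.admix_fraction):
            if not 0 <= v <= 1:
                raise ValueError("rates and frequencies must be in [0, 1]")
        if not (0 <= self.inv_start <= self.inv_end < self.n_snp):
            raise ValueError("inverted segment must lie within the SNP range")

    @property
    def n_ancestries(self) -> int:
        return len(self.f_by_ancestry)

    @property
    def segment(self) -> slice:
        return slice(self.inv_start, self.inv_end + 1)


@dataclass
class SimTruth:
    """Ground truth: per-individual genotypes, ancestries, trio roles and
    phenotype parameters, plus the founder haplotypes."""

    table: pd.DataFrame
    founders: dict
    config: SimConfig

    @property
    def genotypes(self) -> np.ndarray:
        return self.table["genotype"].to_numpy()

    @property
    def dosage(self) -> np.ndarray:
        return self.table["inv_dosage"].to_numpy()

    @property
    def ancestry(self) -> np.ndarray:
        return self.table["ancestry"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


class Pools:
    """Founder haplotypes per (ancestry, pool) and the within-pool sampler.

    The inverted/non-inverted founder divergence is shared across
    ancestries (the inversion predates the ancestry split), so inversion
    state loads on the leading embedding component; each ancestry then
    perturbs both of its pool founders with one common flip pattern at rate
    ``ancestry_divergence``, displacing ancestries along an orthogonal
    direction (typically the second component).
    """

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        m = cfg.n_snp
        base = rng.uniform(0.15, 0.85, size=m)
        ancestral = {"N": (rng.random(m) < base).astype(np.int8)}
        inv = ancestral["N"].copy()
        seg = cfg.segment
        flip = rng.random(cfg.inv_end - cfg.inv_start + 1) < cfg.pool_divergence
        inv[seg] = np.where(flip, 1 - inv[seg], inv[seg])
        ancestral["I"] = inv
        self.founders = {}
        for a in range(cfg.n_ancestries):
            anc_flip = (rng.random(m) < cfg.ancestry_divergence) if cfg.n_ancestries > 1 \
                else np.zeros(m, dtype=bool)
            for pool in ("N", "I"):
                h = ancestral[pool].copy()
                h[anc_flip] = 1 - h[anc_flip]
                self.founders[(a, pool)] = h

    def _mutated_copy(self, ancestry: int, pool: str, rng) -> np.ndarray:
        h = self.founders[(ancestry, pool)].copy()
        mut = rng.random(self.cfg.n_snp) < self.cfg.within_pool_mut
        h[mut] = 1 - h[mut]
        return h

    def draw_haplotype(self, ancestry: int, inverted: bool, rng) -> np.ndarray:
        """One pool member: a within-pool recombinant mosaic of two mutated
        founder copies.  Recombination never crosses pool identity."""
        pool = "I" if inverted else "N"
        h1 = self._mutated_copy(ancestry, pool, rng)
        if self.cfg.recomb_within <= 0:
            return h1
        h2 = self._mutated_copy(ancestry, pool, rng)
        cross = rng.random(self.cfg.n_snp - 1) < self.cfg.recomb_within
        which = np.empty(self.cfg.n_snp, dtype=bool)
        which[0] = rng.random() < 0.5
        which[1:] = (np.cumsum(cross) % 2).astype(bool) ^ which[0]
        return np.where(which, h2, h1)


def simulate_pools(cfg: SimConfig, rng: np.random.Generator | None = None) -> Pools:
    """Build the founder haplotype pools for a configuration."""
    rng = rng or np.random.default_rng(cfg.seed)
    return Pools(cfg, rng)


def _variant_map(cfg: SimConfig) -> pd.DataFrame:
    # evenly spaced positions starting at region.start; strictly increasing
    span = cfg.region.end - cfg.region.start
    step = max(span // max(cfg.n_snp - 1, 1), 1)
    pos = cfg.region.start + np.arange(cfg.n_snp) * step
    return pd.DataFrame({
        "chrom": cfg.region.chrom, "pos": pos,
        "id": [f"snp{i + 1}" for i in range(cfg.n_snp)],
        "alleleA": "A", "alleleB": "B",
    })


@dataclass
class _Individual:
    hap1: np.ndarray
    hap2: np.ndarray
    inv1: bool
    inv2: bool
    anc1: int
    anc2: int

    @property
    def inv_dosage(self) -> int:
        return int(self.inv1) + int(self.inv2)


def _draw_individual(cfg: SimConfig, pools: Pools, rng) -> _Individual:
    probs = np.asarray(cfg.ancestry_props)
    a1 = int(rng.choice(cfg.n_ancestries, p=probs))
    if cfg.n_ancestries > 1 and rng.random() < cfg.admix_fraction:
        others = [a for a in range(cfg.n_ancestries) if a != a1]
        w = probs[others] / probs[others].sum()
        a2 = int(rng.choice(others, p=w))
    else:
        a2 = a1
    inv1 = rng.random() < cfg.f_by_ancestry[a1]
    inv2 = rng.random() < cfg.f_by_ancestry[a2]
    return _Individual(
        pools.draw_haplotype(a1, inv1, rng), pools.draw_haplotype(a2, inv2, rng),
        inv1, inv2, a1, a2)


def _truth_row(sid: str, ind: _Individual, role: str = "") -> dict:
    anc = (f"A{ind.anc1}" if ind.anc1 == ind.anc2 else "Mixed")
    return {
        "sample_id": sid, "genotype": GENOTYPE_LABELS[ind.inv_dosage],
        "inv_dosage": ind.inv_dosage, "ancestry": anc,
        "ancestry_hap1": ind.anc1, "ancestry_hap2": ind.anc2, "trio_role": role,
    }


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Unrelated cohort: per individual draw ancestry (or an admixed pair of
    ancestries), inversion alleles under HWE(f_ancestry), and one haplotype
    from each matching pool; dosage is the haplotype sum."""
    rng = np.random.default_rng(cfg.seed)
    pools = Pools(cfg, rng)
    dosages = np.empty((cfg.n_ind, cfg.n_snp), dtype=np.int8)
    rows = []
    for i in range(cfg.n_ind):
        ind = _draw_individual(cfg, pools, rng)
        dosages[i] = ind.hap1 + ind.hap2
        rows.append(_truth_row(f"S{i + 1}", ind))
    truth = pd.DataFrame(rows)
    samples = pd.DataFrame({
        "sample_id": truth["sample_id"], "father_id": "", "mother_id": "",
        "ancestry_label": truth["ancestry"],
    })
    gm = GenotypeMatrix(dosages, _variant_map(cfg), samples)
    st = SimTruth(truth, pools.founders, cfg)
    if cfg.phenotype is not None:
        simulate_phenotype(st, cfg, rng=rng)
        gm.samples = gm.samples.join(st.table[[c for c in ("case", "trait") if c in st.table]])
    return gm, st


def _child_haplotype(cfg: SimConfig, parent: _Individual, rng):
    """Transmit one parental haplotype (with its pool label and ancestry);
    within-pool recombination only when both parental haplotypes share pool
    and ancestry — crossovers never join different pools inside the segment."""
    pick = rng.random() < 0.5
    h, inv, anc = ((parent.hap1, parent.inv1, parent.anc1) if pick
                   else (parent.hap2, parent.inv2, parent.anc2))
    same_pool = parent.inv1 == parent.inv2 and parent.anc1 == parent.anc2
    if same_pool and cfg.recomb_within > 0:
        other = parent.hap2 if pick else parent.hap1
        cross = rng.random(cfg.n_snp - 1) < cfg.recomb_within
        which = np.zeros(cfg.n_snp, dtype=bool)
        which[1:] = (np.cumsum(cross) % 2).astype(bool)
        h = np.where(which, other, h)
    return h.copy(), inv, anc


def simulate_trios(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """``cfg.n_trios`` father-mother-child families; children inherit one
    haplotype per parent under Mendelian transmission of the pool label."""
    if cfg.n_trios < 1:
        raise ValueError("n_trios must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    pools = Pools(cfg, rng)
    dosages = []
    rows = []
    samples = []
    for t in range(cfg.n_trios):
        fa = _draw_individual(cfg, pools, rng)
        mo = _draw_individual(cfg, pools, rng)
        h1, i1, a1 = _child_haplotype(cfg, fa, rng)
        h2, i2, a2 = _child_haplotype(cfg, mo, rng)
        ch = _Individual(h1, h2, i1, i2, a1, a2)
        fid, mid, cid = f"T{t + 1}F", f"T{t + 1}M", f"T{t + 1}C"
        for sid, ind, role, (pf, pm) in (
            (fid, fa, "father", ("", "")), (mid, mo, "mother", ("", "")),
            (cid, ch, "child", (fid, mid)),
        ):
            dosages.append(ind.hap1 + ind.hap2)
            rows.append(_truth_row(sid, ind, role))
            samples.append({"sample_id": sid, "father_id": pf, "mother_id": pm,
                            "ancestry_label": rows[-1]["ancestry"]})
    gm = GenotypeMatrix(np.asarray(dosages, dtype=np.int8), _variant_map(cfg),
                        pd.DataFrame(samples))
    return gm, SimTruth(pd.DataFrame(rows), pools.founders, cfg)


def simulate_phenotype(
    truth: SimTruth, cfg: SimConfig | None = None, rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach a phenotype to a simulated cohort (in place; also returned).

    Recessive binary mode: logit P(case) = logit(baseline_prev) +
    log(odds_ratio) · 1[genotype = II].  Quantitative mode: trait =
    effect · 1[II] + Normal(0, noise_sd) noise, with cases strictly below
    the ``case_percentile`` of the realized trait.
    """
    cfg = cfg or truth.config
    pheno = cfg.phenotype or PhenotypeConfig()
    rng = rng or np.random.default_rng((cfg.seed or 0) + 1)
    is_ii = (truth.table["inv_dosage"] == 2).to_numpy()
    if pheno.model == "recessive":
        p = expit(logit(pheno.baseline_prev) + np.log(pheno.odds_ratio) * is_ii)
        truth.table["case"] = (rng.random(len(p)) < p).astype(int)
    elif pheno.model == "quantitative":
        trait = pheno.effect * is_ii + rng.normal(0, pheno.noise_sd, size=len(is_ii))
        truth.table["trait"] = trait
        thr = np.quantile(trait, pheno.case_percentile / 100.0)
        truth.table["case"] = (trait < thr).astype(int)
    else:
        raise ValueError(f"unknown phenotype model {pheno.model!r}")
    return truth.table
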