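"""Breakpoint-based inversion detection from local LD disruption.

An inversion reverses the segment between its breakpoints on carrier
chromosomes, so block haplotypes that are adjacent on non-carrier
chromosomes (outside-left with inside-left, inside-right with outside-right)
become associated *across* the segment on carriers (outside-left with
inside-right, inside-left with outside-right).  The scan slides candidate
breakpoint pairs over a region at several window sizes and, at each pair,
compares by BIC:

* **null model** — every chromosome's block classes follow two independent
  adjacency multinomials over the pairs (A,B) and (C,D), where A/D are the
  blocks just outside the left/right breakpoints and B/C just inside;
* **inversion model** — a latent per-chromosome carrier indicator with
  prevalence ρ; non-carriers follow the adjacency multinomials, carriers
  follow cross multinomials over (A,C) and (B,D).

ΔBIC = BIC_null − BIC_inv > 0 is an inversion signal.  Block haplotypes are
reconstructed by the standard EM for multilocus haplotype frequencies from
unphased genotypes; the phase linking blocks is summed out as a latent
variable.  This likelihood is a deliberately simplified variant of the
published LD-scan approach (whose exact likelihood lives in its own
software), reconstructed from the adjacency-disruption idea.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, RegionSpec, extract_region


@dataclass
class ScanConfig:
    block_size: int = 10
    window_fractions: tuple = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    step: int | None = None      # breakpoint grid step; default = block_size
                                 # (localization resolution is ~ the block size)
    min_haplotype_freq: float = 0.05
    max_het_sites: int = 14      # fall back to genotype classes beyond this
    max_iter: int = 500
    tol: float = 1e-9
    hap_tol: float = 1e-8        # haplotype-frequency EM convergence (absolute)

    def __post_init__(self):
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.step is None:
            self.step = self.block_size
        if not all(0 < w <= 1 for w in self.window_fractions):
            raise ValueError("window fractions must be in (0, 1]")


@dataclass
class CandidateResult:
    left_bp: int
    right_bp: int
    window_fraction: float
    delta_bic: float
    carrier_responsibilities: np.ndarray | None  # P(>=1 carrier chromosome)
    rho: float
    loglik_null: float
    loglik_inv: float
    n_params_null: int
    n_params_inv: int
    n_classes: tuple
    #: (N, 3) posterior over the number of carrier chromosomes per
    #: individual.  The carrier/non-carrier labeling is identified only up
    #: to a swap (rho -> 1-rho with the count reversed) when the outside
    #: blocks are uninformative; reverse columns to flip orientation.
    carrier_count_posterior: np.ndarray | None = None


@dataclass
class ScanResult:
    candidates: list = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"left_bp": c.left_bp, "right_bp": c.right_bp,
             "window_fraction": c.window_fraction, "delta_bic": c.delta_bic,
             "rho": c.rho, "n_classes": "x".join(map(str, c.n_classes))}
            for c in self.candidates
        ])

    @property
    def detected(self) -> bool:
        return any(np.isfinite(c.delta_bic) and c.delta_bic > 0 for c in self.candidates)

    def best(self) -> CandidateResult:
        finite = [c for c in self.candidates if np.isfinite(c.delta_bic)]
        if not finite:
            raise ValueError("no candidate with a defined BIC difference")
        return max(finite, key=lambda c: c.delta_bic)

    def best_per_fraction(self) -> pd.DataFrame:
        t = self.table
        return t.loc[t.groupby("window_fraction")["delta_bic"].idxmax()]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(gm: GenotypeMatrix, region: RegionSpec, cfg: ScanConfig) -> list:
    """Breakpoint-pair grid ``(left_bp, right_bp, window_fraction)``.

    Breakpoints are SNP indices within the region: the segment is
    ``[left_bp, right_bp)`` and the four flanking blocks A=[l−B,l),
    B=[l,l+B), C=[r−B,r), D=[r,r+B) must all fit.  Separation equals
    ``round(fraction * n_region_snps)``.
    """
    sub = extract_region(gm, region)
    m = sub.n_variants
    b = cfg.block_size
    if m < 4 * b:
        raise ValueError(f"region has {m} SNPs; need at least 4*block_size = {4 * b}")
    out = []
    for frac in cfg.window_fractions:
        w = min(int(round(frac * m)), m - 2 * b)
        if w < 2 * b:
            continue
        for left in range(b, m - b - w + 1, max(cfg.step, 1)):
            out.append((left, left + w, frac))
    if not out:
        raise ValueError("region too small for any requested window fraction")
    return out


# ---------------------------------------------------------------------------
# within-block haplotype classes
# ---------------------------------------------------------------------------

def _compatible_pairs(geno: np.ndarray) -> list:
    """Unordered haplotype pairs (as bit-tuples) compatible with one
    unphased genotype vector.  The first heterozygous site is fixed to allele
    0 on the first haplotype to avoid double counting."""
    het = np.where(geno == 1)[0]
    base = (geno // 2).astype(int)  # 0->0, 2->1
    if len(het) == 0:
        h = tuple(base)
        return [(h, h)]
    pairs = []
    for bits in product((0, 1), repeat=len(het) - 1):
        h1, h2 = base.copy(), base.copy()
        h1[het[0]], h2[het[0]] = 0, 1
        for site, bit in zip(het[1:], bits):
            h1[site], h2[site] = bit, 1 - bit
        pairs.append(tuple(sorted((tuple(h1), tuple(h2)))))
    return pairs


def block_haplotype_classes(gm: GenotypeMatrix, block: slice | tuple, cfg: ScanConfig | None = None):
    """Most-probable within-block haplotype pair per individual.

    Haplotype frequencies are estimated by the standard EM for multilocus
    haplotypes from unphased genotypes (HWE random pairing); each individual
    is then assigned its maximum-posterior pair, ties broken
    lexicographically.  Haplotypes rarer than ``min_haplotype_freq`` are
    pooled into one rare class.  Returns ``(classes, class_of)`` where
    ``classes`` is an (N, 2) integer label array and ``class_of`` maps
    haplotype tuples to labels.
    """
    cfg = cfg or ScanConfig()
    if isinstance(block, tuple):
        block = slice(*block)
    g = gm.dosages[:, block].astype(int)
    if (g < 0).any():
        # blocks must be complete; impute missing to the per-SNP major genotype
        maj = np.array([np.bincount(col[col >= 0], minlength=3).argmax() for col in g.T])
        g = np.where(g < 0, maj[None, :], g)
    n, b = g.shape

    pair_lists = []
    fallback = False
    for i in range(n):
        n_het = int((g[i] == 1).sum())
        if n_het > cfg.max_het_sites:
            fallback = True
            break
        pair_lists.append(_compatible_pairs(g[i]))
    if fallback:
        warnings.warn("too many heterozygous sites for haplotype EM; using genotype-vector classes")
        _, inv = np.unique(g, axis=0, return_inverse=True)
        return np.stack([inv, inv], axis=1), None

    haps = sorted({h for pl in pair_lists for pr in pl for h in pr})
    hap_idx = {h: i for i, h in enumerate(haps)}
    nh = len(haps)
    freq = np.full(nh, 1.0 / nh)
    pair_arr = [
        np.array([[hap_idx[a], hap_idx[bb]] for a, bb in pl], dtype=int) for pl in pair_lists
    ]
    converged = False
    for _ in range(cfg.max_iter):
        counts = np.zeros(nh)
        for pa in pair_arr:
            w = freq[pa[:, 0]] * freq[pa[:, 1]] * np.where(pa[:, 0] != pa[:, 1], 2.0, 1.0)
            tot = w.sum()
            w = w / tot if tot > 0 else np.full(len(pa), 1.0 / len(pa))
            np.add.at(counts, pa[:, 0], w)
            np.add.at(counts, pa[:, 1], w)
        new = counts / (2 * n)
        if np.abs(new - freq).max() < cfg.hap_tol:
            freq = new
            converged = True
            break
        freq = new
    if not converged:
        warnings.warn("haplotype-frequency EM did not converge; using genotype-vector classes")
        _, inv = np.unique(g, axis=0, return_inverse=True)
        return np.stack([inv, inv], axis=1), None

    # assignment: max posterior pair, lexicographic tie-break (pair lists are
    # built in lexicographic order, argmax takes the first maximum)
    assign = np.empty((n, 2), dtype=int)
    for i, pa in enumerate(pair_arr):
        w = freq[pa[:, 0]] * freq[pa[:, 1]] * np.where(pa[:, 0] != pa[:, 1], 2.0, 1.0)
        assign[i] = pa[int(np.argmax(w))]

    # relabel by descending frequency; pool rare haplotypes into one class
    order = np.argsort(-freq, kind="stable")
    common = [h for h in order if freq[h] >= cfg.min_haplotype_freq]
    label = np.full(nh, len(common), dtype=int)  # rare class = last label
    for new_lab, h in enumerate(common):
        label[h] = new_lab
    classes = label[assign]
    class_of = {haps[h]: int(label[h]) for h in range(nh)}
    return classes, class_of


# ---------------------------------------------------------------------------
# BIC difference at one breakpoint pair
# ---------------------------------------------------------------------------

def _phase_configs(a, b, c, d):
    """Distinct assignments of the four per-block class pairs to two
    chromosomes; chromosome order is canonicalized to avoid double counting."""
    seen = set()
    for sb, sc, sd in product((0, 1), repeat=3):
        c1 = (a[0], b[sb], c[sc], d[sd])
        c2 = (a[1], b[1 - sb], c[1 - sc], d[1 - sd])
        key = tuple(sorted((c1, c2)))
        seen.add(key)
    return sorted(seen)


def _fit_carrier_model(chrom_pairs, sizes, cfg, rho0=0.25, fix_rho=None):
    """EM over (phase, per-chromosome carrier status).

    ``chrom_pairs[i]`` lists the distinct phase configurations of individual
    i, each a pair of chromosome class tuples (a, b, c, d).  Returns
    (loglik, rho, tables, carrier_responsibility).
    """
    na, nb, nc, nd = sizes
    eps = 1e-12
    n_ind = len(chrom_pairs)

    # flatten configurations: one row per (individual, phase config, chromosome 1/2)
    ind = np.array([i for i, cfgs in enumerate(chrom_pairs) for _ in cfgs])
    ch1 = np.array([c1 for cfgs in chrom_pairs for c1, _ in cfgs])  # (n_cfg, 4)
    ch2 = np.array([c2 for cfgs in chrom_pairs for _, c2 in cfgs])
    n_cfg_per_ind = np.bincount(ind, minlength=n_ind)

    def norm(t):
        return t / max(t.sum(), eps)

    # initialize tables from configuration-averaged counts
    tab = {"AB": np.full((na, nb), 1.0), "CD": np.full((nc, nd), 1.0),
           "AC": np.full((na, nc), 1.0), "BD": np.full((nb, nd), 1.0)}
    w0 = np.repeat(1.0 / (2 * n_cfg_per_ind), n_cfg_per_ind)
    for ch in (ch1, ch2):
        np.add.at(tab["AB"], (ch[:, 0], ch[:, 1]), w0)
        np.add.at(tab["CD"], (ch[:, 2], ch[:, 3]), w0)
        np.add.at(tab["AC"], (ch[:, 0], ch[:, 2]), w0)
        np.add.at(tab["BD"], (ch[:, 1], ch[:, 3]), w0)
    for k in tab:
        tab[k] = norm(tab[k])
    rho = rho0 if fix_rho is None else fix_rho

    loglik = -np.inf
    counts = np.zeros((n_ind, 3))
    for _ in range(cfg.max_iter):
        e0 = [tab["AB"][ch[:, 0], ch[:, 1]] * tab["CD"][ch[:, 2], ch[:, 3]] for ch in (ch1, ch2)]
        e1 = [tab["AC"][ch[:, 0], ch[:, 2]] * tab["BD"][ch[:, 1], ch[:, 3]] for ch in (ch1, ch2)]
        mix = [(1 - rho) * a + rho * b for a, b in zip(e0, e1)]
        lik_cfg = mix[0] * mix[1]
        tot = np.bincount(ind, weights=lik_cfg, minlength=n_ind)
        tot_safe = np.maximum(tot, eps)
        loglik_new = float(np.log(tot_safe[tot > 0]).sum())
        p_cfg = lik_cfg / tot_safe[ind]
        pz1 = [rho * b / np.maximum(m, eps) for b, m in zip(e1, mix)]
        # posterior carrier-chromosome count per individual
        p0 = np.bincount(ind, weights=p_cfg * (1 - pz1[0]) * (1 - pz1[1]), minlength=n_ind)
        p2 = np.bincount(ind, weights=p_cfg * pz1[0] * pz1[1], minlength=n_ind)
        counts = np.column_stack([p0, np.clip(1.0 - p0 - p2, 0.0, 1.0), p2])
        if abs(loglik_new - loglik) < cfg.tol * max(abs(loglik_new), 1.0):
            loglik = loglik_new
            break
        loglik = loglik_new
        new_tab = {k: np.full(t.shape, eps) for k, t in tab.items()}
        rho_num = 0.0
        for ch, pz in zip((ch1, ch2), pz1):
            w_std, w_inv = p_cfg * (1 - pz), p_cfg * pz
            np.add.at(new_tab["AB"], (ch[:, 0], ch[:, 1]), w_std)
            np.add.at(new_tab["CD"], (ch[:, 2], ch[:, 3]), w_std)
            np.add.at(new_tab["AC"], (ch[:, 0], ch[:, 2]), w_inv)
            np.add.at(new_tab["BD"], (ch[:, 1], ch[:, 3]), w_inv)
            rho_num += w_inv.sum()
        for k in ("AB", "CD"):
            tab[k] = norm(new_tab[k])
        if fix_rho is None:
            rho = float(np.clip(rho_num / (2 * n_ind), 0.0, 1.0))
        if rho > 0:
            for k in ("AC", "BD"):
                tab[k] = norm(new_tab[k])
    return loglik, rho, tab, counts


def bic_difference(
    gm: GenotypeMatrix, left_bp: int, right_bp: int, cfg: ScanConfig | None = None,
    window_fraction: float = np.nan, fix_rho: float | None = None,
) -> CandidateResult:
    """BIC comparison of the carrier (inversion) model against the null at
    one breakpoint pair.  ``left_bp``/``right_bp`` are SNP indices into
    ``gm`` (segment = [left_bp, right_bp)); the four flanking blocks of
    ``cfg.block_size`` SNPs must fit.
    """
    cfg = cfg or ScanConfig()
    b = cfg.block_size
    m = gm.n_variants
    if left_bp - b < 0 or right_bp + b > m or right_bp - left_bp < 2 * b:
        raise ValueError("flanking blocks do not fit around the breakpoints")
    blocks = [(left_bp - b, left_bp), (left_bp, left_bp + b),
              (right_bp - b, right_bp), (right_bp, right_bp + b)]
    classes = []
    sizes = []
    for lo, hi in blocks:
        cl, _ = block_haplotype_classes(gm, (lo, hi), cfg)
        classes.append(cl)
        sizes.append(int(cl.max()) + 1)
    sizes = tuple(sizes)
    if any(s < 2 for s in sizes):
        return CandidateResult(left_bp, right_bp, window_fraction, np.nan, None, 0.0,
                               np.nan, np.nan, 0, 0, sizes)

    n = gm.n_individuals
    chrom_pairs = [
        _phase_configs(classes[0][i], classes[1][i], classes[2][i], classes[3][i])
        for i in range(n)
    ]
    na, nb, nc, nd = sizes
    ll_null, _, _, _ = _fit_carrier_model(chrom_pairs, sizes, cfg, fix_rho=0.0)
    ll_inv, rho, _, counts = _fit_carrier_model(
        chrom_pairs, sizes, cfg, fix_rho=fix_rho)
    p_null = (na * nb - 1) + (nc * nd - 1)
    p_inv = p_null + (na * nc - 1) + (nb * nd - 1) + 1
    n_chrom = 2 * n
    bic_null = -2 * ll_null + p_null * np.log(n_chrom)
    bic_inv = -2 * ll_inv + p_inv * np.log(n_chrom)
    return CandidateResult(
        left_bp, right_bp, window_fraction, float(bic_null - bic_inv),
        1.0 - counts[:, 0], float(rho), float(ll_null), float(ll_inv),
        p_null, p_inv, sizes, carrier_count_posterior=counts)


def scan(gm: GenotypeMatrix, region: RegionSpec, cfg: ScanConfig | None = None) -> ScanResult:
    """Scan all candidate breakpoint pairs in a region at each window size."""
    cfg = cfg or ScanConfig()
    sub = extract_region(gm, region)
    cands = enumerate_candidates(gm, region, cfg)
    results = [
        bic_difference(sub, left, right, cfg, window_fraction=frac)
        for left, right, frac in cands
    ]
    return ScanResult(results)
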