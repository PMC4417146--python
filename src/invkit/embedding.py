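"""Low-dimensional embeddings of SNP genotypes in a candidate inverted region.

Recombination suppression in inversion heterozygotes makes inverted and
non-inverted haplotypes diverge, so individuals fall into three clusters
(NN, NI, II) in the leading components of a multidimensional scaling of an
identity-by-state (allele-sharing) distance matrix.  PCA of the dosage
matrix is an equivalent alternative; for Euclidean distances of the centered
dosages the two coincide up to per-column sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair counts of SNPs used."""

    values: np.ndarray        # (N, N), zero diagonal
    n_pairs_used: np.ndarray  # (N, N) ints, non-missing SNPs shared by each pair

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v


@dataclass
class Embedding:
    """Coordinates of individuals in k components, ordered by eigenvalue."""

    coords: np.ndarray       # (N, k)
    eigenvalues: np.ndarray  # (k,), non-increasing
    method: str              # "mds" or "pca"
    sample_ids: list | None = None

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def to_tsv(self, path) -> None:
        """Export sample coordinates as TSV with eigenvalues in a header comment."""
        ids = self.sample_ids or [f"S{i}" for i in range(len(self.coords))]
        df = pd.DataFrame(self.coords, columns=[f"C{i + 1}" for i in range(self.k)])
        df.insert(0, "sample_id", ids)
        with open(path, "w") as fh:
            fh.write(f"# method={self.method} eigenvalues={','.join(f'{e:.6g}' for e in self.eigenvalues)}\n")
            df.to_csv(fh, sep="\t", index=False)


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1 − mean identity-by-state sharing over non-missing SNPs.

    For dosages g, h at one SNP the sharing is (2 − |g − h|)/2, so the
    distance is mean(|g − h|)/2 over SNPs called in both individuals.  The
    measure is invariant to which allele is counted (g → 2 − g columnwise).
    Pairs sharing zero called SNPs get distance NaN (flagged via
    ``n_pairs_used``).
    """
    if gm.n_individuals < 2 or gm.n_variants < 1:
        raise ValueError("need at least 2 individuals and 1 variant")
    d = gm.dosages
    mask = (d != -1).astype(float)
    x = np.where(d == -1, 0, d).astype(float)
    # sum over shared SNPs of (g-h)^2, via BLAS
    x2 = x * x
    s2 = x2 @ mask.T + mask @ x2.T - 2.0 * (x @ x.T)
    # |g-h| = (g-h)^2 - 2*[{g,h}={0,2}]
    i0 = ((d == 0).astype(float))
    i2 = ((d == 2).astype(float))
    n02 = i0 @ i2.T + i2 @ i0.T
    sum_abs = s2 - 2.0 * n02
    n_pairs = (mask @ mask.T).round().astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = sum_abs / (2.0 * n_pairs)
    if (n_pairs == 0).any():
        warnings.warn("some pairs share zero called SNPs; distance set to NaN")
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 0.0, 1.0)  # NaN propagates for zero-overlap pairs
    vals = (vals + vals.T) / 2.0
    return DistanceMatrix(vals, n_pairs)


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Fix each column's sign so its largest-magnitude entry is positive.

    Eigenvectors are sign-ambiguous; downstream model fits must not depend
    on orientation.
    """
    for j in range(coords.shape[1]):
        col = coords[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            coords[:, j] = -col
    return coords


def classical_mds(D: DistanceMatrix, k: int = 2, sample_ids=None) -> Embedding:
    """Torgerson classical scaling of a distance matrix.

    Double-centers the squared distances (B = −½ J D∘D J), eigendecomposes B
    and returns the top-k eigenvectors scaled by the square roots of their
    (positive) eigenvalues.  Components with non-positive eigenvalues are
    dropped with a warning, truncating k if necessary.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(D.values, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN; handle all-missing pairs first")
    n = d.shape[0]
    d2 = d * d
    # B = -1/2 J d2 J  with J = I - 11'/n
    row = d2.mean(axis=1, keepdims=True)
    b = -0.5 * (d2 - row - row.T + d2.mean())
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(evals[0]), 1.0)
    n_pos = int((evals > tol).sum())
    if n_pos < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k from {k}")
        k = max(n_pos, 1)
    lam = evals[:k].clip(min=0.0)
    coords = _fix_signs(evecs[:, :k] * np.sqrt(lam))
    return Embedding(coords, lam, "mds", sample_ids=list(sample_ids) if sample_ids is not None else None)


def pca(gm: GenotypeMatrix, k: int = 2, scale: bool = False) -> Embedding:
    """Principal-component scores of the dosage matrix.

    Missing dosages are mean-imputed per variant; columns are centered and
    optionally scaled to unit variance.  Scores are U·S from the SVD (so for
    unscaled input they match classical MDS of Euclidean row distances up to
    column sign); eigenvalues are the per-component variances s²/(N−1).
    """
    x = gm.dosages_float()
    col_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = np.take(col_mean, idx[1])
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    if not np.any(x):
        raise ValueError("zero-variance genotype matrix")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(k, len(s))
    coords = _fix_signs(u[:, :k] * s[:k])
    eigenvalues = (s[:k] ** 2) / max(gm.n_individuals - 1, 1)
    return Embedding(coords, eigenvalues, "pca", sample_ids=list(gm.samples["sample_id"]))


def embed_region(gm: GenotypeMatrix, k: int = 2, method: str = "mds") -> Embedding:
    """Convenience: IBS-distance MDS (default) or PCA of a region's genotypes."""
    if method == "mds":
        return classical_mds(ibs_distance(gm), k=k, sample_ids=gm.samples["sample_id"])
    if method == "pca":
        return pca(gm, k=k)
    raise ValueError(f"unknown method {method!r}")
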