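"""Constrained Gaussian-mixture genotyping of inversion polymorphisms.

An inversion is a biallelic locus (non-inverted N, inverted I).  On the
leading components of an MDS/PCA embedding of the SNPs inside the inverted
segment, individuals form three clusters — NN, NI and II — because
recombination suppression in heterozygotes lets the two haplotype pools
diverge.  The model fitted here is a three-component Gaussian mixture with
two hard constraints that encode this genetic structure:

* **Hardy–Weinberg equilibrium** — the mixture weights are tied to a single
  inverted-allele frequency f: w = ((1−f)², 2f(1−f), f²).
* **Equidistance** — the heterozygote cluster mean is exactly the midpoint
  of the two homozygote means: μ_NI = (μ_NN + μ_II)/2, i.e. μ_j = a + j·b
  for j ∈ {0, 1, 2}.

Both constraints hold exactly at every EM iteration.  The constrained fit
is compared with a single-Gaussian null by BIC; ΔBIC = BIC_null − BIC_fit
> 0 is an inversion signal.  An optional ancestry layer fits a separate
allele frequency and cluster geometry per (possibly latent) haplotype
ancestry, guarding against miscalls in admixed cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

GENOTYPE_LABELS = ("NN", "NI", "II")
_COV_MODES = ("shared-isotropic", "shared-diagonal", "per-cluster-diagonal")
_F_EPS = 1e-6  # keep f in the open interval so no HWE weight degenerates


@dataclass
class InvClustConfig:
    n_components_used: int = 2
    covariance_mode: str = "shared-diagonal"
    max_iter: int = 500
    tol: float = 1e-8          # relative log-likelihood change
    n_restarts: int = 5
    init_axis: str = "first-component"  # or "highest-variance-direction"
    seed: int = 0
    var_floor: float = 1e-10
    track_history: bool = False

    def __post_init__(self):
        if self.covariance_mode not in _COV_MODES:
            raise ValueError(f"covariance_mode must be one of {_COV_MODES}")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class InvClustFit:
    """Fitted constrained mixture.  ``mu`` stacks (μ_NN, μ_NI, μ_II)."""

    f: float
    mu: np.ndarray              # (3, k)
    sigma2: np.ndarray          # (k,) shared-diag, (1,) isotropic, (3, k) per-cluster
    covariance_mode: str
    responsibilities: np.ndarray  # (N, 3)
    loglik: float
    bic: float
    n_iter: int
    converged: bool
    history: list = field(default_factory=list, repr=False)

    @property
    def mu_NN(self) -> np.ndarray:
        return self.mu[0]

    @property
    def mu_NI(self) -> np.ndarray:
        return self.mu[1]

    @property
    def mu_II(self) -> np.ndarray:
        return self.mu[2]

    @property
    def weights(self) -> np.ndarray:
        return hwe_weights(self.f)

    @property
    def n(self) -> int:
        return self.responsibilities.shape[0]

    @property
    def k(self) -> int:
        return self.mu.shape[1]


@dataclass
class SignalResult:
    detected: bool
    delta_bic: float   # BIC(null) − BIC(constrained three-cluster fit)
    fit: InvClustFit
    null_bic: float
    null_loglik: float


@dataclass
class GenotypeCalls:
    """Per-sample inversion genotype calls with posterior probabilities."""

    table: pd.DataFrame  # sample_id, label, p_NN, p_NI, p_II, certainty

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    @property
    def posterior(self) -> np.ndarray:
        return self.table[["p_NN", "p_NI", "p_II"]].to_numpy()

    @property
    def called(self) -> np.ndarray:
        return self.labels != "uncalled"

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def hwe_weights(f: float) -> np.ndarray:
    """Hardy–Weinberg genotype proportions ((1−f)², 2f(1−f), f²)."""
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f ** 2])


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def _expand_sigma2(sigma2: np.ndarray, mode: str, k: int) -> np.ndarray:
    """Per-cluster per-dimension variances, shape (3, k)."""
    if mode == "shared-isotropic":
        return np.full((3, k), float(sigma2.reshape(-1)[0]))
    if mode == "shared-diagonal":
        return np.tile(sigma2.reshape(1, k), (3, 1))
    return sigma2.reshape(3, k)


def _log_gauss_diag(y: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    """(N, 3) log-densities of diagonal Gaussians; mu, var are (3, k)."""
    n, k = y.shape
    out = np.empty((n, 3))
    for j in range(3):
        z2 = ((y - mu[j]) ** 2 / var[j]).sum(axis=1)
        out[:, j] = -0.5 * (k * np.log(2 * np.pi) + np.log(var[j]).sum() + z2)
    return out


def _m_step_f(resp: np.ndarray) -> float:
    """HWE-constrained allele-frequency maximizer of the expected multinomial
    log-likelihood: f = (Σ r_II + ½ Σ r_NI) / N."""
    n = resp.shape[0]
    f = (resp[:, 2].sum() + 0.5 * resp[:, 1].sum()) / n
    return float(np.clip(f, _F_EPS, 1.0 - _F_EPS))


def _m_step_means(y: np.ndarray, resp: np.ndarray, inv_var: np.ndarray | None = None) -> np.ndarray:
    """Weighted-least-squares update of the equidistant means.

    Parameterizes μ_j = a + j·b and solves the 2x2 normal equations per
    dimension.  ``inv_var`` (3, k) supplies per-cluster precision weights in
    the per-cluster-covariance mode; with shared covariance it cancels.
    """
    n, k = y.shape
    j = np.array([0.0, 1.0, 2.0])
    mu = np.empty((3, k))
    s_jd = resp.T @ y  # (3, k)
    r_j = resp.sum(axis=0)  # (3,)
    for d in range(k):
        w = r_j if inv_var is None else r_j * inv_var[:, d]
        s = s_jd[:, d] if inv_var is None else s_jd[:, d] * inv_var[:, d]
        a11, a12, a22 = w.sum(), (j * w).sum(), (j * j * w).sum()
        b1, b2 = s.sum(), (j * s).sum()
        mat = np.array([[a11, a12], [a12, a22]])
        rhs = np.array([b1, b2])
        try:
            ab = np.linalg.solve(mat, rhs)
        except np.linalg.LinAlgError:
            ab = np.linalg.lstsq(mat, rhs, rcond=None)[0]
        mu[:, d] = ab[0] + j * ab[1]
    return mu


def _m_step_sigma2(y, resp, mu, mode, var_floor):
    n, k = y.shape
    scatter = np.empty((3, k))
    for j in range(3):
        scatter[j] = resp[:, j] @ ((y - mu[j]) ** 2)
    if mode == "shared-isotropic":
        s2 = np.array([max(scatter.sum() / (n * k), var_floor)])
    elif mode == "shared-diagonal":
        s2 = np.maximum(scatter.sum(axis=0) / n, var_floor)
    else:
        r_j = np.maximum(resp.sum(axis=0), 1e-12)
        s2 = scatter / r_j[:, None]
        if (s2 < var_floor).any():
            warnings.warn("collapsed cluster variance floored")
        s2 = np.maximum(s2, var_floor)
    return s2


def _cov_dof(mode: str, k: int) -> int:
    return {"shared-isotropic": 1, "shared-diagonal": k, "per-cluster-diagonal": 3 * k}[mode]


def _coords(emb) -> np.ndarray:
    return emb.coords if hasattr(emb, "coords") else np.asarray(emb, dtype=float)


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _init_params(y: np.ndarray, cfg: InvClustConfig, rng: np.random.Generator, jitter: bool):
    if cfg.init_axis == "highest-variance-direction":
        yc = y - y.mean(axis=0)
        _, _, vt = np.linalg.svd(yc, full_matrices=False)
        proj = yc @ vt[0]
    else:
        proj = y[:, 0]
    # split the projection into three initial clusters; the first start uses
    # the 1/3, 2/3 quantiles, later restarts place the splits at the HWE
    # quantiles of a random starting frequency so skewed f is reachable
    q1, q2 = 1 / 3, 2 / 3
    if jitter:
        f0 = rng.uniform(0.05, 0.95)
        q1, q2 = (1 - f0) ** 2, (1 - f0) ** 2 + 2 * f0 * (1 - f0)
        q1 = float(np.clip(q1 + rng.uniform(-0.05, 0.05), 0.01, 0.9))
        q2 = float(np.clip(q2 + rng.uniform(-0.05, 0.05), q1 + 0.05, 0.99))
    t1, t2 = np.quantile(proj, [q1, q2])
    hard = np.where(proj <= t1, 0, np.where(proj <= t2, 1, 2))
    resp = np.zeros((len(y), 3))
    resp[np.arange(len(y)), hard] = 1.0
    f = _m_step_f(resp)
    mu = _m_step_means(y, resp)
    sigma2 = _m_step_sigma2(y, resp, mu, cfg.covariance_mode, cfg.var_floor)
    return f, mu, sigma2


def _em_run(y: np.ndarray, cfg: InvClustConfig, f, mu, sigma2):
    n, k = y.shape
    loglik_prev = -np.inf
    history = []
    converged = False
    resp = None
    it = 0
    for it in range(1, cfg.max_iter + 1):
        var = _expand_sigma2(sigma2, cfg.covariance_mode, k)
        log_joint = np.log(hwe_weights(f))[None, :] + _log_gauss_diag(y, mu, var)
        norm = logsumexp(log_joint, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(log_joint - norm[:, None])
        if cfg.track_history:
            history.append({
                "iter": it, "f": f, "weights": hwe_weights(f), "mu": mu.copy(),
                "loglik": loglik,
            })
        if loglik - loglik_prev <= cfg.tol * max(abs(loglik), 1.0) and it > 1:
            converged = True
            loglik_prev = max(loglik, loglik_prev)
            break
        loglik_prev = loglik
        # M-step
        f = _m_step_f(resp)
        if cfg.covariance_mode == "per-cluster-diagonal":
            inv_var = 1.0 / _expand_sigma2(sigma2, cfg.covariance_mode, k)
            mu = _m_step_means(y, resp, inv_var)
        else:
            mu = _m_step_means(y, resp)
        sigma2 = _m_step_sigma2(y, resp, mu, cfg.covariance_mode, cfg.var_floor)
    p = 1 + 2 * k + _cov_dof(cfg.covariance_mode, k)
    bic = -2.0 * loglik_prev + p * np.log(n)
    return InvClustFit(
        f=f, mu=mu, sigma2=np.atleast_1d(sigma2), covariance_mode=cfg.covariance_mode,
        responsibilities=resp, loglik=loglik_prev, bic=bic, n_iter=it,
        converged=converged, history=history,
    )


def fit_invclust(emb, cfg: InvClustConfig | None = None) -> InvClustFit:
    """Fit the HWE + equidistance constrained three-cluster mixture by EM.

    Runs ``cfg.n_restarts`` initializations (quantile splits along
    ``cfg.init_axis``, jittered after the first) and keeps the best
    log-likelihood.  Free parameters: f (1), means (2k via a, b), covariance
    (mode-dependent); BIC = −2·loglik + p·log N counts only these.
    """
    cfg = cfg or InvClustConfig()
    y = _coords(emb)[:, : cfg.n_components_used]
    if y.ndim != 2:
        y = y.reshape(len(y), -1)
    if len(y) < 10:
        raise ValueError(f"need at least 10 samples, got {len(y)}")
    if not np.isfinite(y).all():
        raise ValueError("embedding coordinates must be finite")
    rng = np.random.default_rng(cfg.seed)
    best = None
    for r in range(cfg.n_restarts):
        f0, mu0, s0 = _init_params(y, cfg, rng, jitter=(r > 0))
        fit = _em_run(y, cfg, f0, mu0, s0)
        if best is None or fit.loglik > best.loglik:
            best = fit
    if not best.converged:
        warnings.warn(f"EM did not converge in {cfg.max_iter} iterations")
    return best


def fit_null(emb, cfg: InvClustConfig | None = None) -> tuple[float, float]:
    """Single-Gaussian null fit on the same coordinates: (loglik, bic)."""
    cfg = cfg or InvClustConfig()
    y = _coords(emb)[:, : cfg.n_components_used]
    n, k = y.shape
    mu = y.mean(axis=0)
    scatter = ((y - mu) ** 2).mean(axis=0)
    if cfg.covariance_mode == "shared-isotropic":
        var = np.full(k, max(scatter.mean(), cfg.var_floor))
        cov_dof = 1
    else:
        var = np.maximum(scatter, cfg.var_floor)
        cov_dof = k
    z2 = ((y - mu) ** 2 / var).sum()
    loglik = -0.5 * (n * k * np.log(2 * np.pi) + n * np.log(var).sum() + z2)
    p = k + cov_dof
    return float(loglik), float(-2 * loglik + p * np.log(n))


def detect_signal(emb, cfg: InvClustConfig | None = None) -> SignalResult:
    """Inversion signal test: constrained three-cluster fit vs one-Gaussian null.

    ``detected`` iff ΔBIC = BIC_null − BIC_fit > 0 (strict, no evidence
    categories).
    """
    cfg = cfg or InvClustConfig()
    fit = fit_invclust(emb, cfg)
    null_loglik, null_bic = fit_null(emb, cfg)
    delta = null_bic - fit.bic
    return SignalResult(detected=bool(delta > 0), delta_bic=float(delta), fit=fit,
                        null_bic=null_bic, null_loglik=null_loglik)


def call_genotypes(
    fit: InvClustFit, call_threshold: float = 0.9, sample_ids=None,
    posterior: np.ndarray | None = None,
) -> GenotypeCalls:
    """Argmax-posterior genotype calls; below-threshold samples are uncalled.

    Cluster j=0 carries weight (1−f)² and is labeled NN; which physical
    orientation is "inverted" cannot be decided from SNP data alone, so the
    labeling is a consistent biallelic convention, anchored by external
    reference genotypes when available.
    """
    post = fit.responsibilities if posterior is None else np.asarray(posterior)
    idx = post.argmax(axis=1)
    certainty = post.max(axis=1)
    labels = np.array(GENOTYPE_LABELS, dtype=object)[idx]
    labels[certainty < call_threshold] = "uncalled"
    ids = list(sample_ids) if sample_ids is not None else [f"S{i}" for i in range(len(post))]
    table = pd.DataFrame({
        "sample_id": ids, "label": labels,
        "p_NN": post[:, 0], "p_NI": post[:, 1], "p_II": post[:, 2],
        "certainty": certainty,
    })
    return GenotypeCalls(table)


# ---------------------------------------------------------------------------
# ancestry-aware model
# ---------------------------------------------------------------------------

@dataclass
class AncestryFit:
    """Joint ancestry x inversion-genotype mixture fit.

    The density is p(y, x) = Σ_g π_g N(x; ν_g, τ_g²) Σ_j w_j(f_g)
    N(y; μ_gj, Σ_g): a Gaussian ancestry layer on a scalar ancestry variable
    x (for admixed cohorts, typically the second embedding component) and a
    per-ancestry constrained genotype layer on coordinates y.
    """

    G: int
    pi: np.ndarray            # (G,)
    nu: np.ndarray            # (G,) ancestry-layer means (NaN when clamped to labels)
    tau2: np.ndarray          # (G,)
    f: np.ndarray             # (G,) per-ancestry inverted-allele frequency
    mu: np.ndarray            # (G, 3, k)
    sigma2: np.ndarray        # (G, k)
    responsibilities: np.ndarray  # (N, G, 3)
    loglik: float             # joint log p(y, x)
    loglik_y: float           # genotype-layer mixture log-likelihood of y alone
    bic: float
    n_iter: int
    converged: bool
    hard_labels: bool = False
    group_names: list | None = None

    @property
    def ancestry_posterior(self) -> np.ndarray:
        return self.responsibilities.sum(axis=2)

    @property
    def ancestry_labels(self) -> np.ndarray:
        idx = self.ancestry_posterior.argmax(axis=1)
        if self.group_names is not None:
            return np.asarray(self.group_names, dtype=object)[idx]
        return idx

    def genotype_posterior(self) -> np.ndarray:
        """(N, 3) posterior over NN/NI/II, marginalized over ancestry."""
        return self.responsibilities.sum(axis=1)

    def per_ancestry_fits(self) -> list[dict]:
        return [
            {"f": float(self.f[g]), "pi": float(self.pi[g]),
             "mu_NN": self.mu[g, 0], "mu_NI": self.mu[g, 1], "mu_II": self.mu[g, 2]}
            for g in range(self.G)
        ]


def _ancestry_em(y, x, hard, G, cfg, pi, nu, tau2, f, mu, sigma2):
    n, k = y.shape
    loglik_prev = -np.inf
    converged = False
    it = 0
    resp = None
    for it in range(1, cfg.max_iter + 1):
        log_parts = np.empty((n, G, 3))
        for g in range(G):
            var = np.tile(sigma2[g].reshape(1, k), (3, 1))
            lg = _log_gauss_diag(y, mu[g], var)  # (n, 3)
            if hard is not None:
                lx = np.where(hard == g, 0.0, -np.inf)
            else:
                lx = -0.5 * (np.log(2 * np.pi * tau2[g]) + (x - nu[g]) ** 2 / tau2[g])
            log_parts[:, g, :] = np.log(pi[g]) + lx[:, None] + np.log(hwe_weights(f[g]))[None, :] + lg
        flat = log_parts.reshape(n, -1)
        norm = logsumexp(flat, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(flat - norm[:, None]).reshape(n, G, 3)
        if loglik - loglik_prev <= cfg.tol * max(abs(loglik), 1.0) and it > 1:
            converged = True
            loglik_prev = max(loglik, loglik_prev)
            break
        loglik_prev = loglik
        # M-step
        rg = resp.sum(axis=2)                    # (n, G)
        ng = np.maximum(rg.sum(axis=0), 1e-12)   # (G,)
        pi = np.maximum(ng / n, 1e-12)
        pi = pi / pi.sum()
        if hard is None:
            nu = (rg * x[:, None]).sum(axis=0) / ng
            tau2 = np.maximum((rg * (x[:, None] - nu) ** 2).sum(axis=0) / ng, cfg.var_floor)
        for g in range(G):
            rgj = resp[:, g, :]
            f[g] = float(np.clip(
                (rgj[:, 2].sum() + 0.5 * rgj[:, 1].sum()) / ng[g], _F_EPS, 1 - _F_EPS))
            mu[g] = _m_step_means(y, rgj)
            scatter = np.zeros(k)
            for j in range(3):
                scatter += rgj[:, j] @ ((y - mu[g, j]) ** 2)
            sigma2[g] = np.maximum(scatter / ng[g], cfg.var_floor)
    return pi, nu, tau2, f, mu, sigma2, resp, loglik_prev, it, converged


def fit_invclust_ancestry(
    emb, ancestry_var=None, G: int | None = None,
    cfg: InvClustConfig | None = None, y_cols=None,
) -> AncestryFit:
    """Fit the ancestry-controlled inversion-genotype mixture.

    Parameters
    ----------
    emb
        Embedding (or raw coordinate array).  The genotype layer uses
        columns ``y_cols`` (default: the first ``cfg.n_components_used``
        components — genotype clusters of different ancestries tilt across
        components, and the per-ancestry equidistant mean vectors capture
        that in the full space); the ancestry layer uses ``ancestry_var``.
    ancestry_var
        Continuous per-sample score (default: the second embedding
        component, where ancestry typically loads) or hard ancestry labels
        (string array), in which case the ancestry layer is clamped.
    G
        Number of ancestry groups.  ``None`` selects G over {1, 2, 3} by
        BIC of the joint fit.
    """
    cfg = cfg or InvClustConfig()
    coords = _coords(emb)
    if y_cols is None:
        y_cols = tuple(range(min(cfg.n_components_used, coords.shape[1])))
    y = coords[:, list(y_cols)]
    n, k = y.shape
    if ancestry_var is None:
        if coords.shape[1] < 2:
            raise ValueError("need >= 2 embedding components when ancestry_var is not given")
        ancestry_var = coords[:, 1]
    ancestry_var = np.asarray(ancestry_var)
    hard_mode = not np.issubdtype(ancestry_var.dtype, np.number)

    group_names = None
    if hard_mode:
        group_names, hard = np.unique(ancestry_var, return_inverse=True)
        group_names = list(group_names)
        g_obs = len(group_names)
        if G is not None and G != g_obs:
            warnings.warn(f"{g_obs} distinct labels observed; using G={g_obs}")
        G = g_obs
        x = np.zeros(n)
    else:
        hard = None
        x = ancestry_var.astype(float)

    if G is None:
        fits = [fit_invclust_ancestry(emb, ancestry_var, g, cfg, y_cols) for g in (1, 2, 3)]
        return min(fits, key=lambda a: a.bic)
    if 3 * G > n / 5:
        raise ValueError(f"G*3 = {3 * G} latent classes exceeds N/5 = {n / 5:.0f}")

    rng = np.random.default_rng(cfg.seed)
    best = None
    for r in range(cfg.n_restarts):
        # initial ancestry split: hard labels, or jittered quantiles of x
        if hard is not None:
            grp = hard
        else:
            qs = np.linspace(0, 1, G + 1)[1:-1]
            if r > 0 and len(qs):
                qs = np.clip(qs + rng.uniform(-0.1, 0.1, size=len(qs)), 0.02, 0.98)
                qs.sort()
            edges = np.quantile(x, qs) if len(qs) else np.array([])
            grp = np.searchsorted(edges, x)
        counts = np.bincount(grp, minlength=G)
        if (counts == 0).any():
            warnings.warn("empty ancestry group at initialization; reducing G")
            keep = counts > 0
            remap = -np.ones(G, dtype=int)
            remap[keep] = np.arange(keep.sum())
            return fit_invclust_ancestry(emb, ancestry_var, int(keep.sum()), cfg, y_cols)
        pi = counts / n
        nu = np.array([x[grp == g].mean() for g in range(G)])
        tau2 = np.array([max(x[grp == g].var(), cfg.var_floor) for g in range(G)])
        f = np.empty(G)
        mu = np.empty((G, 3, k))
        sigma2 = np.empty((G, k))
        sub_cfg = InvClustConfig(
            n_components_used=k, covariance_mode="shared-diagonal",
            max_iter=1, tol=cfg.tol, n_restarts=1, seed=cfg.seed, var_floor=cfg.var_floor)
        for g in range(G):
            yg = y[grp == g]
            f0, mu0, s0 = _init_params(yg, sub_cfg, rng, jitter=(r > 0))
            f[g], mu[g], sigma2[g] = f0, mu0, np.broadcast_to(
                _expand_sigma2(s0, "shared-diagonal", k)[0], (k,)).copy()
        out = _ancestry_em(y, x, hard, G, cfg, pi, nu, tau2, f, mu, sigma2)
        if best is None or out[7] > best[7]:
            best = out
    pi, nu, tau2, f, mu, sigma2, resp, loglik, it, converged = best

    # genotype-layer likelihood of y alone (marginal over classes, x ignored)
    log_parts = np.empty((n, G, 3))
    for g in range(G):
        var = np.tile(sigma2[g].reshape(1, k), (3, 1))
        log_parts[:, g, :] = (np.log(pi[g]) + np.log(hwe_weights(f[g]))[None, :]
                              + _log_gauss_diag(y, mu[g], var))
    loglik_y = float(logsumexp(log_parts.reshape(n, -1), axis=1).sum())

    p = (G - 1) + G * (1 + 2 * k + k) + (0 if hard_mode else 2 * G)
    bic = -2.0 * loglik + p * np.log(n)
    if not converged:
        warnings.warn(f"ancestry EM did not converge in {cfg.max_iter} iterations")
    return AncestryFit(
        G=G, pi=pi, nu=(np.full(G, np.nan) if hard_mode else nu), tau2=tau2, f=f,
        mu=mu, sigma2=sigma2, responsibilities=resp, loglik=loglik, loglik_y=loglik_y,
        bic=bic, n_iter=it, converged=converged, hard_labels=hard_mode,
        group_names=group_names,
    )
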