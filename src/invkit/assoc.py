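"""Validation metrics and case-control association for inversion genotypes.

Covers the downstream half of an inversion study: checking calls against
trio structure (Mendelian consistency) and external reference genotypes
(concordance, carrier sensitivity/specificity), defining a binary low-trait
outcome at an empirical percentile, logistic association under recessive /
dominant / additive codings of the inversion genotype, stratified analyses,
fixed-effect pooling across cohorts, and Levin's population attributable
risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

GENOTYPE_LABELS = ("NN", "NI", "II")
_CODINGS = {
    "recessive": lambda d: (d == 2).astype(float),
    "dominant": lambda d: (d >= 1).astype(float),
    "additive": lambda d: d.astype(float),
}


def _labels_to_dosage(labels) -> np.ndarray:
    """NN/NI/II/uncalled -> 0/1/2/NaN.  Accepts a GenotypeCalls, a label
    array, or a numeric dosage array."""
    if hasattr(labels, "labels"):
        labels = labels.labels
    arr = np.asarray(labels)
    if np.issubdtype(arr.dtype, np.number):
        return arr.astype(float)
    lut = {"NN": 0.0, "NI": 1.0, "II": 2.0}
    return np.array([lut.get(str(v), np.nan) for v in arr])


@dataclass
class AssocResult:
    model: str
    stratum: str
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float
    n_cases: int
    n_controls: int
    covariates: list
    log_or: float
    se: float
    separation: bool = False

    def __post_init__(self):
        if np.isfinite(self.odds_ratio) and self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass
class ConcordanceReport:
    accuracy: float
    sensitivity: float
    specificity: float
    n_compared: int
    confusion: pd.DataFrame  # rows = reference, cols = called


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

#: child dosages producible from one allele of each parent
_MENDEL = {
    (0, 0): {0}, (0, 1): {0, 1}, (0, 2): {1},
    (1, 1): {0, 1, 2}, (1, 2): {1, 2}, (2, 2): {2},
}


def mendelian_consistent(father: int, mother: int, child: int) -> bool:
    """Is a biallelic child genotype transmissible from the parents?"""
    key = tuple(sorted((int(father), int(mother))))
    return int(child) in _MENDEL[key]


def mendelian_consistency(calls, pedigree: pd.DataFrame, sample_ids=None):
    """Fraction of complete trios whose called genotypes obey Mendelian
    transmission.  Trios with any uncalled member are excluded from the
    denominator.  Returns ``(fraction, per_trio DataFrame)``.

    ``pedigree`` needs columns child/father/mother (as produced by
    :meth:`GenotypeMatrix.trios`) or sample_id/father_id/mother_id.
    """
    dose = _labels_to_dosage(calls)
    if sample_ids is None:
        if hasattr(calls, "table"):
            sample_ids = calls.table["sample_id"]
        else:
            raise ValueError("sample_ids required when calls is a plain array")
    idx = {s: i for i, s in enumerate(sample_ids)}
    if "child" not in pedigree.columns:
        ped = pedigree[(pedigree["father_id"] != "") & (pedigree["mother_id"] != "")]
        ped = pd.DataFrame({"child": ped["sample_id"], "father": ped["father_id"],
                            "mother": ped["mother_id"]})
    else:
        ped = pedigree
    rows = []
    for _, t in ped.iterrows():
        if not all(s in idx for s in (t.child, t.father, t.mother)):
            continue
        dc, df_, dm = (dose[idx[t.child]], dose[idx[t.father]], dose[idx[t.mother]])
        if np.isnan([dc, df_, dm]).any():
            rows.append({"child": t.child, "consistent": np.nan})
            continue
        rows.append({"child": t.child,
                     "consistent": mendelian_consistent(df_, dm, dc)})
    per_trio = pd.DataFrame(rows)
    if per_trio.empty:
        raise ValueError("no complete trios")
    ok = per_trio["consistent"].dropna()
    if ok.empty:
        raise ValueError("no trio with all three members called")
    return float(ok.mean()), per_trio


def concordance(calls, reference) -> ConcordanceReport:
    """Three-class concordance of calls against reference genotypes.

    Accuracy is the exact 3-class match rate over samples called in both;
    sensitivity/specificity collapse to carrier status (NI or II vs NN).
    """
    called = _labels_to_dosage(calls)
    ref = _labels_to_dosage(reference)
    if len(called) != len(ref):
        raise ValueError("calls and reference must align sample-wise")
    ok = ~np.isnan(called) & ~np.isnan(ref)
    if not ok.any():
        raise ValueError("zero overlapping called samples")
    c, r = called[ok].astype(int), ref[ok].astype(int)
    confusion = pd.DataFrame(0, index=list(GENOTYPE_LABELS), columns=list(GENOTYPE_LABELS))
    for ri, ci in zip(r, c):
        confusion.iloc[ri, ci] += 1
    acc = float((c == r).mean())
    ref_carrier, call_carrier = r >= 1, c >= 1
    tp = (ref_carrier & call_carrier).sum()
    tn = (~ref_carrier & ~call_carrier).sum()
    sens = float(tp / ref_carrier.sum()) if ref_carrier.any() else np.nan
    spec = float(tn / (~ref_carrier).sum()) if (~ref_carrier).any() else np.nan
    return ConcordanceReport(acc, sens, spec, int(ok.sum()), confusion)


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def define_cases_percentile(trait, pct: float = 5.0, direction: str = "below") -> np.ndarray:
    """Binary outcome from a quantitative trait at an empirical percentile.

    The threshold is the linear-interpolation quantile; cases lie strictly
    below (or above) it, so ties at the threshold are controls.  Missing
    trait values yield -1 (excluded downstream).
    """
    trait = np.asarray(trait, dtype=float)
    vals = trait[~np.isnan(trait)]
    if len(vals) < 20:
        raise ValueError("need at least 20 non-missing trait values")
    if np.ptp(vals) == 0:
        raise ValueError("constant trait")
    if direction == "below":
        out = trait < np.quantile(vals, pct / 100.0)
    elif direction == "above":
        out = trait > np.quantile(vals, 1.0 - pct / 100.0)
    else:
        raise ValueError("direction must be 'below' or 'above'")
    out = out.astype(int)
    out[np.isnan(trait)] = -1
    return out


def genetic_model_test(
    calls, outcome, covariates=None, model: str = "recessive",
    stratum: str = "ALL", min_counts: int = 10,
) -> AssocResult:
    """Logistic regression of a binary outcome on the coded inversion genotype.

    Codings — recessive: 1[II]; dominant: 1[NI or II]; additive: dosage.
    Uncalled samples and outcome < 0 are dropped.  OR = exp(coefficient)
    with Wald 95% CI and p-value.  Quasi-separation is flagged
    (``separation=True``) and the CI marked unreliable by ±inf bounds.
    """
    if model not in _CODINGS:
        raise ValueError(f"model must be one of {sorted(_CODINGS)}")
    dose = _labels_to_dosage(calls)
    y = np.asarray(outcome, dtype=float)
    keep = ~np.isnan(dose) & ~np.isnan(y) & (y >= 0)
    x = _CODINGS[model](dose[keep])
    y = y[keep]
    cov_names = []
    design = x[:, None]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if isinstance(covariates, pd.DataFrame):
            cov_names = list(covariates.columns)
        else:
            cov_names = [f"cov{i + 1}" for i in range(cov.shape[1])]
        design = np.column_stack([x, cov[keep]])
    n_cases, n_controls = int(y.sum()), int((1 - y).sum())
    if n_cases < min_counts or n_controls < min_counts:
        raise ValueError(f"need >= {min_counts} cases and controls "
                         f"(got {n_cases}/{n_controls})")
    design = sm.add_constant(design, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=False, maxiter=200)
            beta, se = res.params[1], res.bse[1]
        except Exception:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=200)
            beta, se = res.params[1], res.bse[1]
    separation = bool(abs(beta) > 15 or se > 50 or not np.isfinite(se))
    if separation:
        lo, hi, p = -np.inf, np.inf, np.nan
    else:
        z = beta / se
        lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
        p = 2 * stats.norm.sf(abs(z))
    return AssocResult(
        model=model, stratum=stratum, odds_ratio=float(np.exp(beta)),
        ci95_low=float(np.exp(lo)), ci95_high=float(np.exp(hi)), p_value=float(p),
        n_cases=n_cases, n_controls=n_controls, covariates=cov_names,
        log_or=float(beta), se=float(se), separation=separation)


def stratified_association(
    calls, outcome, covariates=None, strata=None, model: str = "recessive",
    min_cases: int = 10,
) -> list[AssocResult]:
    """Per-stratum genetic_model_test; strata with too few cases/controls are
    skipped with a warning."""
    strata = np.asarray(strata)
    results = []
    for s in pd.unique(strata):
        m = strata == s
        dose = _labels_to_dosage(calls)
        cov_s = None
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)
            cov_s = cov[m] if cov.ndim == 1 else cov[m, :]
        try:
            results.append(genetic_model_test(
                dose[m], np.asarray(outcome)[m], cov_s, model,
                stratum=str(s), min_counts=min_cases))
        except ValueError as e:
            warnings.warn(f"stratum {s!r} skipped: {e}")
    return results


def combine_fixed_effect(results: list[AssocResult]) -> AssocResult:
    """Inverse-variance fixed-effect pooling of log odds ratios.

    Results without a finite standard error (e.g. separated fits) are
    excluded with a warning; at least two poolable results are required.
    """
    usable = [r for r in results if np.isfinite(r.se) and r.se > 0 and not r.separation]
    if len(usable) < len(results):
        warnings.warn(f"excluded {len(results) - len(usable)} result(s) without finite SE")
    if len(usable) < 2:
        raise ValueError("need at least two results with finite standard errors")
    w = np.array([1 / r.se**2 for r in usable])
    beta = float(np.sum(w * [r.log_or for r in usable]) / w.sum())
    se = float(np.sqrt(1 / w.sum()))
    z = beta / se
    return AssocResult(
        model=usable[0].model, stratum="combined", odds_ratio=float(np.exp(beta)),
        ci95_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci95_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_cases=sum(r.n_cases for r in usable), n_controls=sum(r.n_controls for r in usable),
        covariates=[], log_or=beta, se=se)


def pooled_individual_regression(
    calls_list, outcome_list, model: str = "recessive",
) -> AssocResult:
    """Alternative combination: single logistic fit on concatenated cohorts
    with cohort-indicator covariates."""
    doses = [_labels_to_dosage(c) for c in calls_list]
    dose = np.concatenate(doses)
    y = np.concatenate([np.asarray(o, float) for o in outcome_list])
    cohort = np.concatenate([np.full(len(d), i) for i, d in enumerate(doses)])
    dummies = pd.get_dummies(cohort, drop_first=True).to_numpy(dtype=float)
    return genetic_model_test(dose, y, dummies, model, stratum="pooled")


def population_attributable_risk(odds_ratio: float, exposure_prev_controls: float) -> float:
    """Levin's attributable risk: PAR = p(OR−1) / (1 + p(OR−1))."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0 <= exposure_prev_controls <= 1:
        raise ValueError("prevalence must be in [0, 1]")
    p = exposure_prev_controls
    return float(p * (odds_ratio - 1) / (1 + p * (odds_ratio - 1)))


def adjust_multiple_models(
    calls, outcome, covariates=None, n_perm: int = 1000, seed: int = 0,
    method: str = "permutation",
) -> pd.DataFrame:
    """Correction over the three genetic-model codings.

    ``permutation``: max-|z| permutation test — the outcome is permuted and
    all three codings refit, and each model's adjusted p-value is the
    fraction of permutations whose largest |z| beats its observed |z|.
    ``bonferroni``: observed p-values multiplied by 3.
    """
    models = list(_CODINGS)
    obs = {m: genetic_model_test(calls, outcome, covariates, m) for m in models}
    obs_z = {m: abs(obs[m].log_or / obs[m].se) for m in models}
    if method == "bonferroni":
        adj = {m: min(obs[m].p_value * 3, 1.0) for m in models}
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        y = np.asarray(outcome, float)
        exceed = {m: 0 for m in models}
        for _ in range(n_perm):
            yp = rng.permutation(y)
            zmax = 0.0
            for m in models:
                try:
                    r = genetic_model_test(calls, yp, covariates, m)
                    if np.isfinite(r.se) and r.se > 0:
                        zmax = max(zmax, abs(r.log_or / r.se))
                except ValueError:
                    continue
            for m in models:
                if zmax >= obs_z[m]:
                    exceed[m] += 1
        adj = {m: (exceed[m] + 1) / (n_perm + 1) for m in models}
    else:
        raise ValueError("method must be 'permutation' or 'bonferroni'")
    return pd.DataFrame({
        "model": models,
        "p_raw": [obs[m].p_value for m in models],
        "p_adjusted": [adj[m] for m in models],
        "odds_ratio": [obs[m].odds_ratio for m in models],
    })
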