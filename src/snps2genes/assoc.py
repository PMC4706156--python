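"""Covariate-adjusted case-control association.

Single-marker logistic regression of disease status on minor-allele dosage
(Wald tests, odds ratios with 95% CIs), the Bonferroni genome-wide threshold,
suggestive-tier selection, sex-stratified and sex x dosage interaction models,
haplotype association from phased data, and tag-SNP diplotype classification
(the H1/H2-style two-haplotype system).

The standard adjustment set is sex plus the first four principal components;
callers pass any covariate matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import EstimationError

Z95 = 1.959963984540054


@dataclass
class AssocResult:
    snp_id: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_used: int
    converged: bool = True


@dataclass
class StratifiedResult:
    snp_id: str
    female: AssocResult | None
    male: AssocResult | None
    or_int: float
    ci95_int: tuple[float, float]
    p_int: float
    or_ratio: float  # OR(female) / OR(male), the ratio the interaction estimates


@dataclass
class HaplotypeResult:
    haplotype: str
    freq_all: float
    freq_case: float
    freq_control: float
    or_: float
    ci95: tuple[float, float]
    p: float
    beta: float = np.nan
    se: float = np.nan


def _fit_logit(y: np.ndarray, x: np.ndarray, maxiter: int = 100):
    """Newton fit returning the statsmodels result, or None when the likelihood
    cannot be maximised (separation / collinearity)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(disp=0, method="newton", maxiter=maxiter)
        except Exception:
            try:
                res = sm.Logit(y, x).fit(disp=0, method="bfgs", maxiter=maxiter)
            except Exception:
                return None
    if not res.mle_retvals.get("converged", False):
        return None
    if not np.all(np.isfinite(res.bse)):
        return None
    return res


def _design(predictor: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    predictor = np.asarray(predictor, dtype=float)
    cols = [np.ones_like(predictor), predictor]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov = cov[:, np.ptp(cov, axis=0) > 0]  # constant columns duplicate the intercept
        if cov.shape[1]:
            return np.column_stack(cols + [cov])
    return np.column_stack(cols)


def logistic_assoc(
    dosage: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_id: str = "",
) -> AssocResult:
    """Logistic regression of status on one dosage column (plus covariates).

    Wald z = beta/se, p = 2 Phi(-|z|). Separation or non-convergence yields a
    flagged result (``converged=False``, NaN estimates) rather than an exception.
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=int)
    keep = ~np.isnan(dosage)
    dosage, status = dosage[keep], status[keep]
    cov = None if covariates is None else np.asarray(covariates, dtype=float)[keep]
    if status.min() == status.max():
        raise EstimationError("need at least one case and one control")
    if np.ptp(dosage) == 0:
        raise EstimationError("constant dosage column")
    res = _fit_logit(status, _design(dosage, cov))
    n = int(status.size)
    if res is None:
        return AssocResult(snp_id, np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, n, False)
    beta, se = float(res.params[1]), float(res.bse[1])
    p = float(res.pvalues[1])
    return AssocResult(
        snp_id, beta, se, float(np.exp(beta)),
        (float(np.exp(beta - Z95 * se)), float(np.exp(beta + Z95 * se))),
        max(p, np.finfo(float).tiny), n,
    )


def assoc_scan(
    dosages: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP adjusted association over a dosage matrix; monomorphic columns
    yield NaN rows rather than aborting the scan."""
    m = dosages.shape[1]
    ids = snp_ids if snp_ids is not None else [f"snp{j}" for j in range(m)]
    rows = []
    for j in range(m):
        try:
            r = logistic_assoc(dosages[:, j], status, covariates, snp_id=ids[j])
        except EstimationError:
            r = AssocResult(ids[j], np.nan, np.nan, np.nan, (np.nan, np.nan), np.nan, 0, False)
        rows.append(
            {"snp": r.snp_id, "beta": r.beta, "se": r.se, "or": r.or_,
             "ci_lo": r.ci95[0], "ci_hi": r.ci95[1], "p": r.p,
             "n_used": r.n_used, "converged": r.converged}
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Genome-wide significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def select_suggestive(
    results: pd.DataFrame, p_suggestive: float = 1e-5, p_candidate: float = 1e-4
) -> dict[str, pd.DataFrame]:
    """Split results into suggestive tiers.

    tier1: p <= p_suggestive (boundary included); tier2: the follow-up band
    1e-8 < p < p_candidate. Both ordered by (p, snp id).
    """
    res = results.dropna(subset=["p"]).sort_values(["p", "snp"], kind="stable")
    tier1 = res[res["p"] <= p_suggestive].reset_index(drop=True)
    tier2 = res[(res["p"] > 1e-8) & (res["p"] < p_candidate)].reset_index(drop=True)
    return {"tier1": tier1, "tier2": tier2}


def stratified_interaction(
    dosage: np.ndarray,
    status: np.ndarray,
    sex: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_id: str = "",
) -> StratifiedResult:
    """Sex-stratified fits plus a pooled sex x dosage interaction model.

    The pooled model is status ~ dosage + female + dosage:female (+ covariates);
    ``or_int`` = exp(interaction beta) estimates OR(female)/OR(male), and the
    plain ratio of the stratum ORs is reported alongside as ``or_ratio``.
    """
    dosage = np.asarray(dosage, dtype=float)
    status = np.asarray(status, dtype=int)
    female = (np.asarray(sex) == 2).astype(float)

    strata: dict[str, AssocResult | None] = {}
    for label, mask in (("female", female == 1), ("male", female == 0)):
        sub_status = status[mask]
        if mask.sum() == 0 or sub_status.min() == sub_status.max():
            strata[label] = None
            continue
        cov = None if covariates is None else np.asarray(covariates, dtype=float)[mask]
        try:
            strata[label] = logistic_assoc(dosage[mask], sub_status, cov, snp_id=snp_id)
        except EstimationError:
            strata[label] = None

    x = [np.ones_like(dosage), dosage, female, dosage * female]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        x.append(cov if cov.ndim == 2 else cov[:, None])
    res = _fit_logit(status, np.column_stack(x))
    if res is None:
        or_int, ci_int, p_int = np.nan, (np.nan, np.nan), np.nan
    else:
        b, se = float(res.params[3]), float(res.bse[3])
        or_int = float(np.exp(b))
        ci_int = (float(np.exp(b - Z95 * se)), float(np.exp(b + Z95 * se)))
        p_int = float(res.pvalues[3])
    fr, ml = strata["female"], strata["male"]
    or_ratio = fr.or_ / ml.or_ if fr is not None and ml is not None else np.nan
    return StratifiedResult(snp_id, fr, ml, or_int, ci_int, p_int, or_ratio)


def _hap_strings(haps: np.ndarray, allele_labels: list[tuple[str, str]] | None) -> np.ndarray:
    """(2n, m) allele-code rows -> string labels (major char for 0, minor for 1)."""
    if allele_labels is None:
        return np.array(["".join(map(str, row)) for row in haps])
    return np.array(
        ["".join(allele_labels[j][a] for j, a in enumerate(row)) for row in haps]
    )


def haplotype_assoc(
    haplotypes: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    min_freq: float = 0.01,
    allele_labels: list[tuple[str, str]] | None = None,
) -> list[HaplotypeResult]:
    """Additive haplotype association from phased data.

    ``haplotypes`` is (n, 2, m) allele codes {0, 1} over the SNP set. Each
    observed haplotype with frequency >= min_freq is tested (count 0/1/2 per
    individual vs all other haplotypes) in an adjusted logistic model; case and
    control haplotype frequencies are reported. ``allele_labels[j] = (major,
    minor)`` characters render the haplotype strings.
    """
    status = np.asarray(status, dtype=int)
    n = haplotypes.shape[0]
    flat = haplotypes.reshape(2 * n, -1)
    labels = _hap_strings(flat, allele_labels)
    uniq, inv, counts = np.unique(labels, return_inverse=True, return_counts=True)
    freqs = counts / (2.0 * n)
    results = []
    case = status == 1
    for h in np.argsort(-freqs, kind="stable"):
        if freqs[h] < min_freq:
            continue
        carrier = (inv.reshape(n, 2) == h).sum(axis=1).astype(float)
        freq_case = float(carrier[case].sum() / (2.0 * case.sum()))
        freq_ctrl = float(carrier[~case].sum() / (2.0 * (~case).sum()))
        try:
            r = logistic_assoc(carrier, status, covariates, snp_id=str(uniq[h]))
            results.append(
                HaplotypeResult(str(uniq[h]), float(freqs[h]), freq_case, freq_ctrl,
                                r.or_, r.ci95, r.p, r.beta, r.se)
            )
        except EstimationError:
            continue
    if not results:
        warnings.warn(f"no haplotype reaches min_freq={min_freq}")
    return results


def mapt_diplotype(
    haplotypes: np.ndarray,
    status: np.ndarray,
    covariates: np.ndarray | None = None,
    r_min: float = 0.99,
):
    """Two-haplotype (H1/H2) diplotype classification at tag SNPs in complete LD.

    H2 is the haplotype carrying the minor alleles (all 1s). Each chromosome is
    labelled by the majority of its tag alleles (recombinants counted and kept
    under the majority vote; ties at an even SNP count go to H1). Returns
    (classes per sample in {H1/H1, H1/H2, H2/H2}, per-class summary DataFrame)
    where each class is tested as an indicator against the rest.
    """
    n, _, m = haplotypes.shape
    dos = haplotypes.sum(axis=1).astype(float)
    r = np.corrcoef(dos.T)
    off = np.abs(r[np.triu_indices(m, k=1)])
    if off.size and (off < r_min).any():
        warnings.warn(
            f"tag SNPs not in complete LD (min |r| = {off.min():.3f} < {r_min})"
        )
    minor_count = haplotypes.sum(axis=2)  # (n, 2)
    is_h2 = minor_count > m / 2.0
    recomb = int(((minor_count != 0) & (minor_count != m)).sum())
    if recomb:
        warnings.warn(f"{recomb} recombinant tag haplotypes; kept under majority vote")
    n_h2 = is_h2.sum(axis=1)
    class_names = np.array(["H1/H1", "H1/H2", "H2/H2"])
    classes = class_names[n_h2]

    status = np.asarray(status, dtype=int)
    rows = []
    for ci, name in enumerate(class_names):
        ind = (n_h2 == ci).astype(float)
        n_case = int(ind[status == 1].sum())
        n_ctrl = int(ind[status == 0].sum())
        try:
            r_ = logistic_assoc(ind, status, covariates, snp_id=name)
            rows.append({"diplotype": name, "n_case": n_case, "n_control": n_ctrl,
                         "or": r_.or_, "ci_lo": r_.ci95[0], "ci_hi": r_.ci95[1], "p": r_.p})
        except EstimationError:
            rows.append({"diplotype": name, "n_case": n_case, "n_control": n_ctrl,
                         "or": np.nan, "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan})
    return classes, pd.DataFrame(rows)
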