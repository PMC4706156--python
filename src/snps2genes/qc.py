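"""Sample and SNP quality control.

Covers population-structure PCA on standardised dosages, iterative PCA-outlier
removal, PLINK-style method-of-moments identity-by-descent relatedness, and the
MAF/Rsq marker filters. All thresholds default to the values used throughout the
package's reference analysis (MAF >= 0.01, Rsq >= 0.80, 6.0 SD outliers,
PI_HAT > 0.1875 relatedness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError
from .io import impute_missing


@dataclass
class QcReport:
    removed_samples: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["sample", "reason"]))
    removed_snps: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["snp", "reason"]))
    eigenvalues: np.ndarray | None = None
    scores: np.ndarray | None = None


def _standardise(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centre columns and scale by sqrt(2 p (1-p)); returns (X, kept column mask)."""
    x = impute_missing(dosages)
    p = x.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = (scale > 0) & (x.std(axis=0) > 0)
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-variance SNPs from PCA")
    x = (x[:, keep] - 2.0 * p[keep]) / scale[keep]
    return x, keep


def pca_axes(dosages: np.ndarray, k: int):
    """Principal axes of genetic variation.

    Columns are centred and scaled by sqrt(2 p̂ (1-p̂)) (unit variance under
    Hardy-Weinberg); returns (scores (n, k), loadings (m_kept, k), eigenvalues (k,))
    with axes orthonormal, eigenvalues = sample-covariance eigenvalues in
    non-increasing order, and the sign convention that each axis's largest-magnitude
    loading is positive.
    """
    n = dosages.shape[0]
    if n < 2:
        raise EstimationError("PCA needs at least 2 samples")
    if k > min(dosages.shape):
        raise ValueError("k exceeds min(n_samples, n_snps)")
    x, _keep = _standardise(dosages)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    flip = np.sign(vt[np.arange(k), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = (u * s) * flip
    loadings = (vt * flip[:, None]).T
    eigenvalues = s**2 / (n - 1)
    return scores, loadings, eigenvalues


def outlier_samples(scores: np.ndarray, n_sd: float = 6.0, max_rounds: int = 5) -> np.ndarray:
    """Indices of samples whose |score| exceeds ``n_sd`` axis SDs on any axis,
    iterated to a fixed point (SDs recomputed on the retained set, <= 5 rounds)."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    flagged = np.zeros(scores.shape[0], dtype=bool)
    for _ in range(max_rounds):
        kept = ~flagged
        if kept.sum() < 2:
            break
        mu = scores[kept].mean(axis=0)
        sd = scores[kept].std(axis=0)
        sd[sd == 0] = np.inf
        new = (np.abs(scores - mu) > n_sd * sd).any(axis=1) & kept
        if not new.any():
            break
        flagged |= new
    return np.flatnonzero(flagged)


def _ibd_terms(geno: np.ndarray, freqs: np.ndarray):
    p = freqs
    q = 1.0 - p
    e_ibs0_ibd0 = 2.0 * p**2 * q**2
    e_ibs1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e_ibs2_ibd0 = p**4 + q**4 + 4.0 * p**2 * q**2
    e_ibs1_ibd1 = 2.0 * p**2 * q + 2.0 * p * q**2
    e_ibs2_ibd1 = p**3 + q**3 + p**2 * q + p * q**2
    return e_ibs0_ibd0, e_ibs1_ibd0, e_ibs2_ibd0, e_ibs1_ibd1, e_ibs2_ibd1


def ibd_pihat(dosages: np.ndarray, pair: tuple[int, int]) -> float:
    """Method-of-moments IBS->IBD estimate of the kinship proportion PI_HAT
    for one sample pair, PI_HAT = P(IBD=2) + 0.5 P(IBD=1), clipped to [0, 1].

    Dosages are rounded to hard genotypes; allele frequencies come from the
    whole matrix. Monomorphic SNPs are dropped (all monomorphic -> error).
    """
    geno = np.round(impute_missing(dosages)).astype(int)
    freqs = geno.mean(axis=0) / 2.0
    poly = (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise EstimationError("all SNPs monomorphic; IBD estimation undefined")
    if poly.sum() < 100:
        warnings.warn(f"only {int(poly.sum())} polymorphic SNPs; PI_HAT estimate unstable")
    geno, freqs = geno[:, poly], freqs[poly]
    i, j = pair
    ibs = 2 - np.abs(geno[i] - geno[j])
    n0, n1, n2 = (int((ibs == v).sum()) for v in (0, 1, 2))
    e00, e10, e20, e11, e21 = (t.sum() for t in _ibd_terms(geno, freqs))
    m = geno.shape[1]
    p0 = n0 / e00 if e00 > 0 else 0.0
    p1 = (n1 - p0 * e10) / e11 if e11 > 0 else 0.0
    p2 = (n2 - p0 * e20 - p1 * e21) / m
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    if probs.sum() > 0:
        probs = probs / probs.sum()
    return float(np.clip(probs[2] + 0.5 * probs[1], 0.0, 1.0))


def pihat_matrix(dosages: np.ndarray) -> np.ndarray:
    """PI_HAT for all sample pairs at once (indicator matrix products for the
    IBS sharing counts; same estimator as :func:`ibd_pihat`)."""
    geno = np.round(impute_missing(dosages)).astype(int)
    freqs = geno.mean(axis=0) / 2.0
    poly = (freqs > 0) & (freqs < 1)
    if not poly.any():
        raise EstimationError("all SNPs monomorphic; IBD estimation undefined")
    if poly.sum() < 100:
        warnings.warn(f"only {int(poly.sum())} polymorphic SNPs; PI_HAT estimate unstable")
    geno, freqs = geno[:, poly], freqs[poly]
    m = geno.shape[1]
    a = [(geno == v).astype(np.float64) for v in (0, 1, 2)]
    n0 = a[0] @ a[2].T
    n0 = n0 + n0.T
    n2 = a[0] @ a[0].T + a[1] @ a[1].T + a[2] @ a[2].T
    n1 = m - n0 - n2
    e00, e10, e20, e11, e21 = (t.sum() for t in _ibd_terms(geno, freqs))
    p0 = n0 / e00 if e00 > 0 else np.zeros_like(n0)
    p1 = (n1 - p0 * e10) / e11 if e11 > 0 else np.zeros_like(n1)
    p2 = (n2 - p0 * e20 - p1 * e21) / m
    p0, p1, p2 = (np.clip(p, 0.0, 1.0) for p in (p0, p1, p2))
    tot = p0 + p1 + p2
    tot[tot == 0] = 1.0
    return np.clip((p2 + 0.5 * p1) / tot, 0.0, 1.0)


def related_pairs(dosages: np.ndarray, threshold: float = 0.1875) -> list[tuple[int, int, float]]:
    """All sample pairs with PI_HAT above ``threshold`` (default: midpoint between
    2nd- and 3rd-degree relatives)."""
    ph = pihat_matrix(dosages)
    iu = np.triu_indices_from(ph, k=1)
    hits = ph[iu] > threshold
    return [(int(i), int(j), float(v))
            for i, j, v in zip(iu[0][hits], iu[1][hits], ph[iu][hits])]


def relatedness_removals(dosages: np.ndarray, pairs: list[tuple[int, int, float]]) -> set[int]:
    """For each related pair drop the member with the lower call rate (ties: the
    higher index), until no flagged pair remains intact."""
    call_rate = 1.0 - np.isnan(dosages).mean(axis=1)
    removed: set[int] = set()
    for i, j, _ in sorted(pairs, key=lambda t: -t[2]):
        if i in removed or j in removed:
            continue
        if call_rate[i] < call_rate[j]:
            removed.add(i)
        elif call_rate[j] < call_rate[i]:
            removed.add(j)
        else:
            removed.add(max(i, j))
    return removed


def snp_qc(variants: pd.DataFrame, maf_min: float = 0.01, rsq_min: float = 0.80) -> pd.Series:
    """Boolean retain mask: keep iff maf >= maf_min AND rsq >= rsq_min
    (boundary values retained)."""
    return (variants["maf"] >= maf_min) & (variants["rsq"] >= rsq_min)


def ld_thin(dosages: np.ndarray, r2_max: float = 0.2, window: int = 50) -> np.ndarray:
    """Greedy LD thinning: scan left to right, keep a SNP unless its r² with an
    already-kept SNP inside the trailing ``window`` reaches ``r2_max``."""
    x = impute_missing(dosages)
    m = x.shape[1]
    kept: list[int] = []
    sd = x.std(axis=0)
    for j in range(m):
        if sd[j] == 0:
            continue
        ok = True
        for i in reversed(kept):
            if j - i > window:
                break
            r = np.corrcoef(x[:, i], x[:, j])[0, 1]
            if r * r >= r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.array(kept, dtype=int)


def run_qc(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    *,
    n_axes: int = 4,
    maf_min: float = 0.01,
    rsq_min: float = 0.80,
    outlier_sd: float = 6.0,
    pihat_max: float = 0.1875,
    check_relatedness: bool = True,
):
    """Full QC pass: SNP filters -> LD-thinned PCA -> outlier removal ->
    relatedness removal -> final PCA axes appended to the sample table as
    PC1..PCk. Returns (dosages, variants, samples, QcReport)."""
    report = QcReport()

    keep_snp = snp_qc(variants, maf_min=maf_min, rsq_min=rsq_min)
    removed = variants.loc[~keep_snp, "snp"]
    reasons = np.where(variants.loc[~keep_snp, "maf"] < maf_min, "maf", "rsq")
    report.removed_snps = pd.DataFrame({"snp": removed.to_numpy(), "reason": reasons})
    dosages = dosages[:, keep_snp.to_numpy()]
    variants = variants.loc[keep_snp].reset_index(drop=True)

    thin = ld_thin(dosages)
    scores, _, _ = pca_axes(dosages[:, thin], min(n_axes, len(thin), dosages.shape[0]))
    out_idx = set(outlier_samples(scores, n_sd=outlier_sd).tolist())

    rel_idx: set[int] = set()
    # PI_HAT noise scales as 1/sqrt(markers); below ~500 markers the all-pairs
    # screen false-flags unrelated pairs, so it is skipped
    if check_relatedness and dosages.shape[1] >= 500 and dosages.shape[0] <= 2000:
        pairs = related_pairs(dosages, threshold=pihat_max)
        rel_idx = relatedness_removals(dosages, pairs) - out_idx

    drop = sorted(out_idx | rel_idx)
    rows = [{"sample": samples.iloc[i]["sample"], "reason": "outlier" if i in out_idx else "related"}
            for i in drop]
    report.removed_samples = pd.DataFrame(rows, columns=["sample", "reason"])
    keep_mask = np.ones(dosages.shape[0], dtype=bool)
    keep_mask[drop] = False
    dosages = dosages[keep_mask]
    samples = samples.loc[keep_mask].reset_index(drop=True)

    thin = ld_thin(dosages)
    k = min(n_axes, len(thin), dosages.shape[0])
    scores, _, eigenvalues = pca_axes(dosages[:, thin], k)
    samples = samples.copy()
    for a in range(k):
        samples[f"PC{a + 1}"] = scores[:, a]
    report.eigenvalues = eigenvalues
    report.scores = scores
    return dosages, variants, samples, report
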