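"""Gene-based association tests: GATES, supervised PCA and the SKAT kernel test.

GATES combines the single-marker p-values of a gene's SNPs through the extended
Simes procedure: the SNP correlation (LD) matrix is mapped to a p-value
correlation matrix via a sixth-order polynomial, the effective number of
independent tests m_e(j) is the eigenvalue-excess count of the top-j submatrix,
and the gene p-value is min_j m_e * p_(j) / m_e(j).

Supervised PCA ranks a gene's SNPs by their univariate logistic log-likelihood,
keeps the top quarter, and tests the first principal component score
("eigengene") of the retained, standardised dosages in a logistic model. The
selection step uses the outcome, so under the null its p-values run small; this
is a property of the method as defined, reproduced deliberately (see docs).

SKAT is the variance-component score test of the logistic kernel-machine model
with an unweighted linear kernel: Q = (y - mu)' G G' (y - mu), whose null law is
a mixture of chi-squares with weights from the eigenvalues of the projected
kernel. Tail probabilities come from exact characteristic-function inversion
(the Davies/Imhof integral) with a Liu-type moment-matching fallback, the
fallback flagged per gene.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.linalg
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .assoc import _design, _fit_logit, assoc_scan
from .errors import EstimationError

# genotype-correlation -> p-value-correlation polynomial of the extended Simes test
_GATES_POLY = (0.2982, -0.0127, 0.0588, 0.0099, 0.6281, -0.0009, 0.0)


def ld_r(dosages: np.ndarray, snp_indices=None) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of dosage columns (composite-LD surrogate for r).

    Constant columns are excluded with a warning; returns (r matrix, kept
    indices). All-constant input raises.
    """
    idx = np.arange(dosages.shape[1]) if snp_indices is None else np.asarray(snp_indices)
    x = dosages[:, idx]
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise EstimationError("all dosage columns constant; LD undefined")
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant SNPs from LD matrix")
    x = x[:, keep]
    if x.shape[1] == 1:
        return np.ones((1, 1)), idx[keep]
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r, idx[keep]


def _effective_tests(rho: np.ndarray) -> float:
    """m_e = M - sum(max(lambda_i - 1, 0)) over eigenvalues of a correlation matrix."""
    lam = scipy.linalg.eigvalsh(rho)
    return rho.shape[0] - float(np.sum(np.maximum(lam - 1.0, 0.0)))


def gates_p(snp_pvalues: np.ndarray, ld: np.ndarray) -> float:
    """Extended Simes gene p-value from SNP p-values and their LD matrix."""
    p = np.asarray(snp_pvalues, dtype=float)
    if p.ndim != 1 or p.size != ld.shape[0] or ld.shape[0] != ld.shape[1]:
        raise ValueError("p-value vector and LD matrix dimensions do not match")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    r = ld[np.ix_(order, order)]
    rho = np.polyval(_GATES_POLY, r)
    np.fill_diagonal(rho, 1.0)
    m = p.size
    me_full = _effective_tests(rho)
    best = np.inf
    for j in range(1, m + 1):
        me_j = _effective_tests(rho[:j, :j])
        best = min(best, me_full * p_sorted[j - 1] / me_j)
    return float(np.clip(best, np.finfo(float).tiny, 1.0))


def prune_maf(mafs: np.ndarray, snp_indices: np.ndarray, maf_min: float = 0.01) -> np.ndarray:
    """Keep SNPs with MAF strictly above ``maf_min`` (the GATES/sPCA pruning rule;
    SKAT bypasses this)."""
    idx = np.asarray(snp_indices)
    return idx[np.asarray(mafs)[idx] > maf_min]


def _univariate_logistic_loglik(dosages: np.ndarray, status: np.ndarray,
                                n_iter: int = 25) -> np.ndarray:
    """Fitted log-likelihood of status ~ 1 + dosage for every column at once
    (vectorised Newton; columns with degenerate fits get -inf)."""
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)[:, None]
    a = np.zeros(x.shape[1])
    b = np.zeros(x.shape[1])
    for _ in range(n_iter):
        eta = a[None, :] + b[None, :] * x
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        r = y - mu
        g_a = r.sum(axis=0)
        g_b = (r * x).sum(axis=0)
        h_aa = w.sum(axis=0)
        h_ab = (w * x).sum(axis=0)
        h_bb = (w * x * x).sum(axis=0)
        det = h_aa * h_bb - h_ab**2
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        da = (h_bb * g_a - h_ab * g_b) / det
        db = (h_aa * g_b - h_ab * g_a) / det
        a = a + np.nan_to_num(da)
        b = b + np.nan_to_num(db)
    eta = a[None, :] + b[None, :] * x
    ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=0)
    ll[~np.isfinite(ll)] = -np.inf
    return ll


def loglik_filter(dosages: np.ndarray, status: np.ndarray, percentile: float = 75) -> np.ndarray:
    """Supervised SNP filter: rank columns by univariate logistic log-likelihood
    and retain the top (100 - percentile)% — ceil, minimum one SNP; ties broken
    by lower column index."""
    m = dosages.shape[1]
    n_keep = max(int(np.ceil((1.0 - percentile / 100.0) * m)), 1)
    ll = _univariate_logistic_loglik(dosages, status)
    order = np.lexsort((np.arange(m), -ll))
    return np.sort(order[:n_keep])


def spca_p(dosages: np.ndarray, status: np.ndarray,
           covariates: np.ndarray | None = None, adjust: bool = False):
    """Eigengene test: logistic regression of status on the first PC score of the
    standardised dosage submatrix. Unadjusted by default; ``adjust=True`` adds
    the covariates. Returns (p, pc1 scores); sign-flip invariant."""
    x = np.asarray(dosages, dtype=float)
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return np.nan, None
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, _vt = np.linalg.svd(x, full_matrices=False)
    pc1 = u[:, 0] * s[0]
    if pc1.std() == 0:
        return np.nan, None
    res = _fit_logit(np.asarray(status, dtype=int),
                     _design(pc1, covariates if adjust else None))
    if res is None:
        return np.nan, pc1
    return float(res.pvalues[1]), pc1


def _davies_tail(q: float, lam: np.ndarray) -> float | None:
    """P(sum lam_i chi2_1 > q) by numerical inversion of the characteristic
    function (the Davies/Imhof integral); None when the quadrature is
    untrustworthy. The oscillatory tail is handled by Fourier-weighted
    quadrature on the two slowly-varying amplitude components."""
    lam = np.asarray(lam, dtype=float)
    scale = lam.mean()
    lam = lam / scale
    q = q / scale
    if lam.size == 1:  # exact: a single scaled chi-square
        return float(scipy.stats.chi2.sf(q / lam[0], 1))

    def phi(u):
        return 0.5 * np.sum(np.arctan(lam * u))

    def inv_rho(u):
        return np.exp(-0.25 * np.sum(np.log1p((lam * u) ** 2)))

    def head(u):
        return np.sin(phi(u) - 0.5 * q * u) * inv_rho(u) / u

    w = 0.5 * q
    cut = 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            i1, e1 = scipy.integrate.quad(head, 0.0, cut, limit=200, epsabs=1e-12)
            # sin(phi - wu) = sin(phi)cos(wu) - cos(phi)sin(wu)
            i2, e2 = scipy.integrate.quad(
                lambda u: np.sin(phi(u)) * inv_rho(u) / u, cut, np.inf,
                weight="cos", wvar=w, limit=200,
            )
            i3, e3 = scipy.integrate.quad(
                lambda u: np.cos(phi(u)) * inv_rho(u) / u, cut, np.inf,
                weight="sin", wvar=w, limit=200,
            )
    except Exception:
        return None
    val = i1 + i2 - i3
    err = e1 + e2 + e3
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-6:
        return None
    return float(min(max(p, 0.0), 1.0))


def _liu_tail(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation of the mixture tail
    (noncentral chi-square matched on skewness/kurtosis)."""
    c1, c2, c3, c4 = (float(np.sum(lam**k)) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        df = c2**3 / c3**2
    x = (q - c1) / np.sqrt(2.0 * c2) * np.sqrt(2.0) * a + df + delta
    return float(scipy.stats.ncx2.sf(x, df, delta) if delta > 0
                 else scipy.stats.chi2.sf(x, df))


def _set_partitions(items: list[int]):
    """All set partitions of ``items`` (Bell number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


@functools.lru_cache(maxsize=16)
def _partition_coarser(n_slots: int):
    """All partitions of ``n_slots`` slots plus, per partition, the indices of
    all strictly coarser partitions (for Mobius inversion on the lattice)."""
    parts = [tuple(frozenset(b) for b in p) for p in _set_partitions(list(range(n_slots)))]
    pair_idx = {}
    for i in range(n_slots):
        for j in range(i + 1, n_slots):
            pair_idx[(i, j)] = len(pair_idx)
    masks = np.zeros(len(parts), dtype=np.uint64)
    for pi, p in enumerate(parts):
        m = 0
        for b in p:
            bb = sorted(b)
            for x in range(len(bb)):
                for y in range(x + 1, len(bb)):
                    m |= 1 << pair_idx[(bb[x], bb[y])]
        masks[pi] = m
    coarser = []
    sizes = np.array([len(p) for p in parts])
    for pi in range(len(parts)):
        # q strictly coarser than p: pairs(p) subset pairs(q), fewer blocks
        sub = (masks[pi] & ~masks) == 0
        coarser.append(np.flatnonzero(sub & (sizes < sizes[pi])))
    return parts, coarser


@functools.lru_cache(maxsize=8)
def _perm_lattice(n_slots: int):
    """Data-independent machinery for permutation moments of order n_slots/2:
    all partitions of the slots, strictly-coarser indices, the connected
    components of each contraction multigraph, and block-size multisets."""
    parts, coarser = _partition_coarser(n_slots)
    k = n_slots // 2
    comp_specs = []
    mults = []
    for p in parts:
        slot_block = {}
        for bi, b in enumerate(p):
            for slot in b:
                slot_block[slot] = bi
        edges = [(slot_block[2 * t], slot_block[2 * t + 1]) for t in range(k)]
        remaining = list(range(k))
        comps = []
        while remaining:
            comp = {remaining[0]}
            verts = set(edges[remaining[0]])
            grown = True
            while grown:
                grown = False
                for e in remaining:
                    if e not in comp and (set(edges[e]) & verts):
                        comp.add(e)
                        verts |= set(edges[e])
                        grown = True
            letters = sorted({v for e in (edges[e] for e in comp) for v in e})
            sub = {v: chr(ord("a") + i) for i, v in enumerate(letters)}
            spec = ",".join(sub[edges[e][0]] + sub[edges[e][1]] for e in sorted(comp)) + "->"
            comps.append((spec, len(comp)))
            remaining = [e for e in remaining if e not in comp]
        comp_specs.append(comps)
        mults.append(tuple(sorted(len(b) for b in p)))
    return parts, coarser, comp_specs, mults


def _distinct_value_sum(a: np.ndarray, mults: tuple[int, ...]) -> float:
    """Sum over tuples of pairwise-distinct indices of prod a[i_t]**mults[t]."""
    r = len(mults)
    parts, coarser = _partition_coarser(r)
    power = {m: float(np.sum(a.astype(float) ** m)) for m in range(1, sum(mults) + 1)}
    all_sums = np.empty(len(parts))
    for pi, p in enumerate(parts):
        val = 1.0
        for b in p:
            val *= power[sum(mults[t] for t in b)]
        all_sums[pi] = val
    dist = np.zeros(len(parts))
    for pi in np.argsort([len(p) for p in parts]):  # coarsest first
        dist[pi] = all_sums[pi] - dist[coarser[pi]].sum()
    finest = next(i for i, p in enumerate(parts) if len(p) == r)
    return float(dist[finest])


def _perm_moments_q(s: np.ndarray, a: np.ndarray, k_max: int = 4) -> list[float]:
    """Exact E[Q^k], k = 1..k_max, of Q = a_pi' S a_pi over uniformly random
    permutations pi of the entries of ``a`` (S symmetric, n x n)."""
    n = a.size
    moments = []
    value_sums: dict[tuple[int, ...], float] = {}
    for k in range(1, k_max + 1):
        parts, coarser, comp_specs, mults_list = _perm_lattice(2 * k)
        spec_cache: dict[str, float] = {}
        t_all = np.empty(len(parts))
        for pi, comps in enumerate(comp_specs):
            val = 1.0
            for spec, n_edges in comps:
                if spec not in spec_cache:
                    spec_cache[spec] = float(
                        np.einsum(spec, *([s] * n_edges), optimize=True)
                    )
                val *= spec_cache[spec]
                if val == 0.0:
                    break
            t_all[pi] = val
        t_dist = np.zeros(len(parts))
        order = np.argsort([len(p) for p in parts])  # coarsest first
        for pi in order:
            t_dist[pi] = t_all[pi] - t_dist[coarser[pi]].sum()
        total = 0.0
        for pi, p in enumerate(parts):
            r = len(p)
            if r > n or t_dist[pi] == 0.0:
                continue
            mults = mults_list[pi]
            if mults not in value_sums:
                value_sums[mults] = _distinct_value_sum(a, mults)
            falling = 1.0
            for t in range(r):
                falling *= n - t
            total += t_dist[pi] * value_sums[mults] / falling
        moments.append(total)
    return moments


def _perm_tail(q: float, g_centered: np.ndarray, resid: np.ndarray) -> float:
    """Small-sample SKAT tail: exact first four moments of Q under permutation
    of the null residuals, fitted Liu-style with a (non)central chi-square
    matched on mean, variance, skewness and kurtosis."""
    s = g_centered @ g_centered.T
    m1, m2, m3, m4 = _perm_moments_q(s, resid)
    k2 = m2 - m1**2  # central cumulants
    if k2 <= 0:
        return 1.0
    k3 = m3 - 3 * m1 * m2 + 2 * m1**3
    k4 = m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4 - 3 * k2**2
    # Liu's s1/s2 live on the sum-of-lambda-powers scale: c_k = kappa_k / (2^(k-1) (k-1)!)
    s1 = (k3 / k2**1.5) / (2.0 * np.sqrt(2.0))
    s2 = (k4 / k2**2) / 12.0
    if s1 <= 1e-8:
        return float(scipy.stats.norm.sf((q - m1) / np.sqrt(k2)))
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        df = 1.0 / s1**2
    if df <= 0 or delta < 0:  # degenerate fit: 3-moment chi-square
        a, delta, df = 1.0 / s1, 0.0, 1.0 / s1**2
    x = (q - m1) / np.sqrt(k2) * np.sqrt(2.0) * a + df + delta
    return float(scipy.stats.ncx2.sf(x, df, delta) if delta > 0
                 else scipy.stats.chi2.sf(x, df))


@dataclass
class SkatResult:
    p: float
    q_stat: float
    method: str  # "davies", "liu" (fallback) or "perm3" (small-sample)
    converged: bool = True


def skat_null_model(status: np.ndarray, covariates: np.ndarray | None = None):
    """Fit the SKAT null logistic model (intercept + covariates); reusable across
    genes tested against the same covariate set."""
    y = np.asarray(status, dtype=int)
    x = np.ones((y.size, 1)) if covariates is None else np.column_stack(
        [np.ones(y.size), np.asarray(covariates, dtype=float)]
    )
    res = _fit_logit(y, x)
    if res is None:
        raise EstimationError("SKAT null model did not converge")
    mu = res.predict(x)
    return {"y": y, "x": x, "mu": mu}


SMALL_SAMPLE_N = 100  # below this (and without covariates) use permutation moments


def skat_p(
    dosages: np.ndarray,
    status: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    null_model: dict | None = None,
    small_sample: bool | None = None,
) -> SkatResult:
    """SKAT score test with the unweighted linear kernel.

    Q = (y - mu)' G G' (y - mu); the null distribution is sum lambda_i chi2_1
    with lambda the eigenvalues of G' P G, P = V - V X (X'VX)^-1 X'V and
    V = diag(mu(1-mu)) from the null logistic fit.

    ``small_sample`` (default: automatic, covariate-free models with
    n < SMALL_SAMPLE_N) replaces the asymptotic mixture with a null matched to
    the exact first three moments of Q under permutation of the residuals —
    the asymptotic tail is visibly off at such sizes.
    """
    if null_model is None:
        if status is None:
            raise ValueError("need status or a fitted null model")
        null_model = skat_null_model(status, covariates)
    y, x, mu = null_model["y"], null_model["x"], null_model["mu"]
    g = np.asarray(dosages, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    resid = y - mu
    q_stat = float(np.sum((g.T @ resid) ** 2))

    if small_sample is None:
        small_sample = x.shape[1] == 1 and y.size < SMALL_SAMPLE_N
    if small_sample:
        if x.shape[1] != 1:
            raise ValueError("small-sample permutation moments require a "
                             "covariate-free null model")
        gc = g - g.mean(axis=0)
        p = _perm_tail(q_stat, gc, resid)
        return SkatResult(max(p, np.finfo(float).tiny), q_stat, "perm3")

    v = mu * (1.0 - mu)
    vx = x * v[:, None]
    xtvx = x.T @ vx
    vg = g * v[:, None]
    xtvg = x.T @ vg
    try:
        correction = vx @ np.linalg.solve(xtvx, xtvg)
    except np.linalg.LinAlgError:
        correction = vx @ (np.linalg.pinv(xtvx) @ xtvg)
    a = vg - correction  # P G
    k = g.T @ a
    lam = scipy.linalg.eigvalsh((k + k.T) / 2.0)
    lam = lam[lam > 1e-10 * max(lam.max(), 1e-30)]
    if lam.size == 0:
        return SkatResult(1.0, q_stat, "davies", converged=False)
    p = _davies_tail(q_stat, lam)
    if p is not None and p > 1e-14:
        return SkatResult(max(p, np.finfo(float).tiny), q_stat, "davies")
    return SkatResult(max(_liu_tail(q_stat, lam), np.finfo(float).tiny), q_stat, "liu")


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significant(p_fdr, cutoff: float = 0.05) -> np.ndarray:
    return np.flatnonzero(np.asarray(p_fdr, dtype=float) < cutoff)


def gene_based_scan(
    dosages: np.ndarray,
    status: np.ndarray,
    variants: pd.DataFrame,
    gene_map: dict[str, list[int]],
    covariates: np.ndarray | None = None,
    methods: tuple[str, ...] = ("gates", "spca", "skat"),
    snp_pvalues: np.ndarray | None = None,
    maf_min: float = 0.01,
    loglik_percentile: float = 75,
) -> pd.DataFrame:
    """Run the requested gene-based tests over a SNP-to-gene map.

    GATES consumes single-marker p-values (computed here with ``covariates``
    when not supplied) plus within-gene LD; sPCA and SKAT consume raw dosages.
    Returns a long DataFrame (gene, method, n_snps, n_retained, p_raw, p_fdr,
    note) with BH-FDR applied per method across genes.
    """
    status = np.asarray(status, dtype=int)
    mafs = variants["maf"].to_numpy()
    if "gates" in methods and snp_pvalues is None:
        snp_pvalues = assoc_scan(dosages, status, covariates)["p"].to_numpy()
    null = skat_null_model(status, covariates) if "skat" in methods else None

    rows = []
    for gene in sorted(gene_map):
        idx = np.asarray(gene_map[gene])
        n_snps = idx.size
        if "gates" in methods:
            kept = prune_maf(mafs, idx, maf_min)
            pv = snp_pvalues[kept]
            ok = np.isfinite(pv) & (pv > 0)
            kept, pv = kept[ok], pv[ok]
            if kept.size == 0:
                rows.append((gene, "gates", n_snps, 0, np.nan, "all SNPs pruned"))
            else:
                try:
                    r, sub = ld_r(dosages, kept)
                    pos = {s: i for i, s in enumerate(kept)}
                    pv_kept = pv[[pos[s] for s in sub]]
                    rows.append((gene, "gates", n_snps, int(sub.size),
                                 gates_p(pv_kept, r), ""))
                except EstimationError as exc:
                    rows.append((gene, "gates", n_snps, 0, np.nan, str(exc)))
        if "spca" in methods:
            kept = prune_maf(mafs, idx, maf_min)
            if kept.size == 0:
                rows.append((gene, "spca", n_snps, 0, np.nan, "all SNPs pruned"))
            else:
                sel = kept[loglik_filter(dosages[:, kept], status, loglik_percentile)]
                p, _ = spca_p(dosages[:, sel], status)
                rows.append((gene, "spca", n_snps, int(sel.size), p,
                             "" if np.isfinite(p) else "degenerate PC1"))
        if "skat" in methods:
            res = skat_p(dosages[:, idx], null_model=null)
            note = "" if res.method == "davies" else "liu fallback"
            rows.append((gene, "skat", n_snps, n_snps, res.p, note))

    df = pd.DataFrame(rows, columns=["gene", "method", "n_snps", "n_retained", "p_raw", "note"])
    df["p_fdr"] = np.nan
    for method in df["method"].unique():
        sel = (df["method"] == method) & df["p_raw"].notna()
        df.loc[sel, "p_fdr"] = fdr_bh(df.loc[sel, "p_raw"].to_numpy())
    return df


def dag_select(
    assoc_results: pd.DataFrame,
    gene_map: dict[str, list[int]],
    gene_results: pd.DataFrame,
    p_assoc: float = 1e-4,
    p_fdr: float = 0.1,
) -> pd.DataFrame:
    """Disease-associated gene list: genes holding a single-marker p below
    ``p_assoc`` union genes with any gene-based FDR-adjusted p below ``p_fdr``;
    deduplicated, sorted, with a provenance flag."""
    snp_p = assoc_results.set_index("snp")["p"]
    snp_ids = assoc_results["snp"].to_numpy()
    assoc_genes = set()
    for gene, idx in gene_map.items():
        pv = snp_p.reindex(snp_ids[np.asarray(idx)]).to_numpy(dtype=float)
        if np.nanmin(pv, initial=np.inf) < p_assoc:
            assoc_genes.add(gene)
    gb = gene_results.dropna(subset=["p_fdr"])
    gene_based = set(gb.loc[gb["p_fdr"] < p_fdr, "gene"])
    rows = []
    for gene in sorted(assoc_genes | gene_based):
        src = ("both" if gene in assoc_genes and gene in gene_based
               else "association" if gene in assoc_genes else "gene_based")
        rows.append({"gene": gene, "source": src})
    return pd.DataFrame(rows, columns=["gene", "source"])
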