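"""Synthetic case-control cohort generator with LD blocks and implanted effects.

The generator emulates an imputed-dosage case-control GWAS cohort: haplotypes are
mosaics of a small pool of founder haplotypes per LD block (so haplotype identity is
known exactly), disease status follows a logistic model on minor-allele dosages with
optional sex, haplotype/diplotype and population-structure effects, and cases/controls
are collected by retrospective quota sampling from the population model.

Allele coding: within each block allele ``1`` is the minor allele by construction
(founder-pool frequency <= 0.5); a dosage is the per-sample sum of the two phased
allele codes, hence lies in {0, 1, 2}.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: ``n_snps`` markers whose haplotypes are mosaics of
    ``n_founders`` founder haplotypes, switching founders between adjacent
    SNPs with probability ``recomb_rate``."""

    n_snps: int
    n_founders: int
    recomb_rate: float = 0.0
    founder_weights: tuple[float, ...] | None = None  # default: equal frequency

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ConfigError("block needs at least 1 SNP")
        if self.n_founders < 2:
            raise ConfigError("block needs at least 2 founder haplotypes")
        if not 0.0 <= self.recomb_rate <= 1.0:
            raise ConfigError("recomb_rate must be a probability")
        if self.founder_weights is not None:
            w = np.asarray(self.founder_weights, dtype=float)
            if w.size != self.n_founders or (w <= 0).any():
                raise ConfigError("founder_weights must be positive, one per founder")
            object.__setattr__(self, "founder_weights", tuple(w / w.sum()))

    def weights(self) -> np.ndarray:
        if self.founder_weights is None:
            return np.full(self.n_founders, 1.0 / self.n_founders)
        return np.asarray(self.founder_weights, dtype=float)


@dataclass
class SimConfig:
    """Full description of a simulated cohort.

    Defaults mirror a mid-size imputed case-control study: 530 cases vs 926
    controls, a rare-disease baseline (logit -4 so odds ratios approximate
    risk ratios), and no implanted effects.

    causal_snps: list of (global SNP index, odds ratio per minor allele).
    causal_haplotype: (block index, founder index, OR per matching haplotype copy).
    causal_diplotype: (block index, founder index, OR when BOTH haplotypes match) —
        a genotype-level contrast for recessive-style protective/risk diplotypes.
    """

    n_cases: int = 530
    n_controls: int = 926
    blocks: list[BlockSpec] = field(default_factory=lambda: [BlockSpec(12, 8, 0.01)])
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_snps: list[tuple[int, float]] = field(default_factory=list)
    causal_haplotype: tuple[int, int, float] | None = None
    causal_diplotype: tuple[int, int, float] | None = None
    sex_odds_ratio: float = 1.0
    n_structure_axes: int = 0
    structure_effect: float = 0.0
    fst: float = 0.02
    baseline_logit: float = -4.0
    rsq_range: tuple[float, float] = (0.80, 1.0)
    rsq_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.blocks = [b if isinstance(b, BlockSpec) else BlockSpec(*b) for b in self.blocks]
        if self.n_cases + self.n_controls <= 0:
            raise ConfigError("need at least one sample")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("sample counts must be non-negative")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0, 0.5]")
        rlo, rhi = self.rsq_range
        if not (0.0 < rlo <= rhi <= 1.0):
            raise ConfigError("rsq_range must lie within (0, 1]")
        for _, or_ in self.causal_snps:
            if or_ <= 0:
                raise ConfigError("odds ratios must be positive")
        for trip in (self.causal_haplotype, self.causal_diplotype):
            if trip is not None and trip[2] <= 0:
                raise ConfigError("odds ratios must be positive")
        if self.sex_odds_ratio <= 0:
            raise ConfigError("sex_odds_ratio must be positive")
        m = sum(b.n_snps for b in self.blocks)
        for idx, _ in self.causal_snps:
            if not 0 <= idx < m:
                raise ConfigError(f"causal SNP index {idx} out of range (M={m})")

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.blocks)


@dataclass
class SimulatedCohort:
    """Simulated data plus ground truth.

    haplotypes: (n_samples, 2, n_snps) int8 allele codes {0, 1}.
    dosages: (n_samples, n_snps) float, equal to ``haplotypes.sum(axis=1)`` unless
        Rsq noise was requested.
    variants / samples: tables as produced by :mod:`snps2genes.io` readers.
    founders: per-block founder haplotype matrices.
    truth: causal indices, true ORs, haplotype labels and subpopulation assignment.
    """

    haplotypes: np.ndarray
    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    founders: list[np.ndarray]
    truth: dict

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


def _feasible_counts(n_founders: int, maf_range: tuple[float, float]) -> np.ndarray:
    lo, hi = maf_range
    counts = np.arange(1, n_founders // 2 + 1)
    ok = counts[(counts / n_founders >= lo - 1e-12) & (counts / n_founders <= hi + 1e-12)]
    return ok


def _choose_carriers(weights: np.ndarray, target: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Greedy subset of founders whose total sampling weight approaches
    ``target`` without exceeding 0.5 (keeps allele 1 the minor allele)."""
    chosen = np.zeros(weights.size, dtype=bool)
    total = 0.0
    for f in rng.permutation(weights.size):
        new = total + weights[f]
        if new <= 0.5 + 1e-9 and abs(new - target) < abs(total - target):
            chosen[f] = True
            total = new
    return chosen


def simulate_founder_pool(
    block: BlockSpec, maf_range: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Draw a founder haplotype pool for one block.

    Each SNP's set of minor-allele-carrying founders is chosen so the frequency
    induced by founder sampling (equal weights unless the block specifies
    ``founder_weights``) lies inside ``maf_range``. Founders are resampled a few
    times to be pairwise distinct where the design permits it
    (2**n_snps >= n_founders).

    Raises ConfigError when no founder carrier set can realise maf_range.
    """
    lo, hi = maf_range
    weights = block.weights()
    if block.founder_weights is None and _feasible_counts(block.n_founders, maf_range).size == 0:
        raise ConfigError(
            f"maf_range {maf_range} infeasible with {block.n_founders} founders: "
            "no minor-allele count k has k/n_founders inside the range"
        )
    can_be_distinct = 2 ** min(block.n_snps, 30) >= block.n_founders
    pool = None
    for _ in range(200):
        cand = np.zeros((block.n_founders, block.n_snps), dtype=np.int8)
        target = rng.uniform(lo, hi, size=block.n_snps)
        feasible = True
        for s in range(block.n_snps):
            carriers = _choose_carriers(weights, target[s], rng)
            freq = float(weights[carriers].sum())
            if not (lo - 1e-9 <= freq <= hi + 1e-9):
                feasible = False
                break
            cand[carriers, s] = 1
        if not feasible:
            continue
        pool = cand
        if not can_be_distinct or len({row.tobytes() for row in pool}) == block.n_founders:
            return pool
    if pool is None:
        raise ConfigError(
            f"maf_range {maf_range} infeasible with founder weights {weights.tolist()}"
        )
    return pool  # accept a rare duplicate rather than loop forever


def _mosaic_haplotypes(
    pool: np.ndarray,
    n_hap: int,
    recomb: float,
    founder_cdf: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Build ``n_hap`` mosaic haplotypes; returns (alleles, founder index per SNP)."""
    n_f, m = pool.shape
    fid = np.empty((n_hap, m), dtype=np.int32)
    fid[:, 0] = np.searchsorted(founder_cdf, rng.random(n_hap))
    for j in range(1, m):
        switch = rng.random(n_hap) < recomb
        fresh = np.searchsorted(founder_cdf, rng.random(n_hap))
        fid[:, j] = np.where(switch, fresh, fid[:, j - 1])
    alleles = pool[fid, np.arange(m)[None, :]]
    return alleles.astype(np.int8), fid


def _subpop_founder_cdfs(
    base_weights: np.ndarray, fst: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Balding-Nichols-style founder-weight divergence between two subpopulations."""
    if fst <= 0:
        return [np.cumsum(base_weights), np.cumsum(base_weights)]
    conc = (1.0 - fst) / fst
    cdfs = []
    for _ in range(2):
        w = rng.dirichlet(base_weights * conc)
        w = np.maximum(w, 1e-9)
        w /= w.sum()
        cdfs.append(np.cumsum(w))
    return cdfs


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Simulate a case-control cohort under ``config``.

    Individuals are drawn from the population model (haplotypes, sex, subpopulation),
    their case probability evaluated on the logistic scale, and sampled into the
    case/control pools until both quotas are met (retrospective ascertainment).

    Raises SimulationError when the quotas cannot be met in a bounded number of
    draws (pathological ``baseline_logit``).
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_cases + config.n_controls
    m = config.n_snps

    pools = [simulate_founder_pool(b, config.maf_range, rng) for b in config.blocks]
    structured = config.n_structure_axes > 0
    block_cdfs = []  # per block: [cdf subpop0, cdf subpop1]
    for spec in config.blocks:
        w = spec.weights()
        if structured:
            block_cdfs.append(_subpop_founder_cdfs(w, config.fst, rng))
        else:
            block_cdfs.append([np.cumsum(w), np.cumsum(w)])

    beta = np.zeros(m)
    for idx, or_ in config.causal_snps:
        beta[idx] += np.log(or_)
    hap_block = dip_block = None
    hap_founder = dip_founder = None
    log_or_hap = log_or_dip = 0.0
    if config.causal_haplotype is not None:
        hap_block, hap_founder, or_h = config.causal_haplotype
        log_or_hap = np.log(or_h)
    if config.causal_diplotype is not None:
        dip_block, dip_founder, or_d = config.causal_diplotype
        log_or_dip = np.log(or_d)
    log_or_sex = np.log(config.sex_odds_ratio)

    kept_h: list[np.ndarray] = []
    kept_sex: list[np.ndarray] = []
    kept_sub: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    kept_axes: list[np.ndarray] = []
    n_case_have = n_ctrl_have = 0
    drawn = 0
    max_draws = max(500 * n_total, 50_000)

    while n_case_have < config.n_cases or n_ctrl_have < config.n_controls:
        if drawn >= max_draws:
            raise SimulationError(
                f"case/control quotas not met after {drawn} draws "
                f"(have {n_case_have}/{config.n_cases} cases, "
                f"{n_ctrl_have}/{config.n_controls} controls); "
                "check baseline_logit"
            )
        batch = int(min(max(2048, 4 * n_total), max_draws - drawn))
        drawn += batch

        subpop = (
            rng.integers(0, 2, size=batch) if structured else np.zeros(batch, dtype=np.int64)
        )
        hap = np.empty((batch, 2, m), dtype=np.int8)
        hap_match = np.zeros((batch, 2), dtype=bool)
        dip_match = np.zeros((batch, 2), dtype=bool)
        col = 0
        for bi, (pool, cdfs) in enumerate(zip(pools, block_cdfs)):
            mb = pool.shape[1]
            for h in range(2):
                alleles = np.empty((batch, mb), dtype=np.int8)
                for sp in (0, 1):
                    sel = subpop == sp
                    if not sel.any():
                        continue
                    a, fid = _mosaic_haplotypes(
                        pool, int(sel.sum()), config.blocks[bi].recomb_rate, cdfs[sp], rng
                    )
                    alleles[sel] = a
                hap[:, h, col : col + mb] = alleles
                if bi == hap_block:
                    hap_match[:, h] = (alleles == pool[hap_founder][None, :]).all(axis=1)
                if bi == dip_block:
                    dip_match[:, h] = (alleles == pool[dip_founder][None, :]).all(axis=1)
            col += mb

        g = hap.sum(axis=1).astype(np.float64)
        sex = rng.integers(1, 3, size=batch)  # 1 male, 2 female, Bernoulli(0.5)
        logit = config.baseline_logit + g @ beta + log_or_sex * (sex == 2)
        if hap_block is not None:
            logit = logit + log_or_hap * hap_match.sum(axis=1)
        if dip_block is not None:
            logit = logit + log_or_dip * dip_match.all(axis=1)
        axes = np.zeros((batch, config.n_structure_axes))
        if structured:
            axes[:, 0] = subpop - 0.5
            if config.n_structure_axes > 1:
                axes[:, 1:] = rng.normal(size=(batch, config.n_structure_axes - 1))
            logit = logit + config.structure_effect * axes.sum(axis=1)
        p_case = 1.0 / (1.0 + np.exp(-logit))
        status = (rng.random(batch) < p_case).astype(np.int8)

        need_case = config.n_cases - n_case_have
        need_ctrl = config.n_controls - n_ctrl_have
        case_idx = np.flatnonzero(status == 1)[:need_case]
        ctrl_idx = np.flatnonzero(status == 0)[:need_ctrl]
        keep = np.concatenate([case_idx, ctrl_idx])
        n_case_have += case_idx.size
        n_ctrl_have += ctrl_idx.size
        if keep.size:
            kept_h.append(hap[keep])
            kept_sex.append(sex[keep])
            kept_sub.append(subpop[keep])
            kept_status.append(status[keep])
            kept_axes.append(axes[keep])

    haplotypes = np.concatenate(kept_h)
    sex = np.concatenate(kept_sex)
    subpop = np.concatenate(kept_sub)
    status = np.concatenate(kept_status)
    axes = np.concatenate(kept_axes)
    # stable order: cases first is an artefact of pooling; shuffle deterministically
    order = rng.permutation(haplotypes.shape[0])
    haplotypes, sex, subpop, status, axes = (
        haplotypes[order],
        sex[order],
        subpop[order],
        status[order],
        axes[order],
    )

    dosages = haplotypes.sum(axis=1).astype(np.float64)
    rsq = rng.uniform(*config.rsq_range, size=m)
    if config.rsq_noise:
        maf_pop = dosages.mean(axis=0) / 2.0
        mu = 2.0 * maf_pop
        sd = np.sqrt(np.maximum((1.0 - rsq) * 2.0 * maf_pop * (1.0 - maf_pop), 0.0))
        dosages = mu + np.sqrt(rsq) * (dosages - mu) + rng.normal(size=dosages.shape) * sd
        dosages = np.clip(dosages, 0.0, 2.0)

    ids, chroms, poss = [], [], []
    col = 0
    for bi, b in enumerate(config.blocks):
        for j in range(b.n_snps):
            ids.append(f"snp{col:05d}")
            chroms.append(str(bi + 1))
            poss.append(10_000 + 1_000 * j)
            col += 1
    freq = haplotypes.sum(axis=(0, 1)) / (2.0 * haplotypes.shape[0])
    variants = pd.DataFrame(
        {
            "snp": ids,
            "chrom": chroms,
            "pos": poss,
            "minor_allele": "A",
            "major_allele": "G",
            "maf": np.minimum(freq, 1.0 - freq),
            "rsq": rsq,
        }
    )
    samples = pd.DataFrame(
        {
            "sample": [f"S{i:05d}" for i in range(haplotypes.shape[0])],
            "status": status.astype(int),
            "sex": sex.astype(int),
        }
    )
    for k in range(config.n_structure_axes):
        samples[f"axis{k + 1}"] = axes[:, k]

    truth = {
        "causal_snps": [(ids[i], float(or_)) for i, or_ in config.causal_snps],
        "causal_haplotype": config.causal_haplotype,
        "causal_diplotype": config.causal_diplotype,
        "sex_odds_ratio": config.sex_odds_ratio,
        "subpop": subpop.astype(int),
        "config": config,
    }
    return SimulatedCohort(haplotypes, dosages, variants, samples, pools, truth)


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write PED/MAP, a truth TSV (snp, true_OR, causal flag) and a JSON manifest."""
    from . import io as genio  # local import: io imports nothing from here

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": out / "cohort.ped",
        "map": out / "cohort.map",
        "truth": out / "truth.tsv",
        "manifest": out / "simconfig.json",
    }
    genio.write_ped_map(cohort.dosages, cohort.variants, cohort.samples, paths["ped"], paths["map"])
    causal = dict(cohort.truth["causal_snps"])
    truth_df = pd.DataFrame(
        {
            "snp": cohort.variants["snp"],
            "true_or": [causal.get(s, 1.0) for s in cohort.variants["snp"]],
            "causal": [int(s in causal) for s in cohort.variants["snp"]],
        }
    )
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    cfg = asdict(cohort.truth["config"])
    cfg["blocks"] = [asdict(b) if isinstance(b, BlockSpec) else b for b in cohort.truth["config"].blocks]
    paths["manifest"].write_text(json.dumps(cfg, indent=2, default=str))
    return paths
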