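import warnings

import numpy as np
import pandas as pd
import pytest

import snps2genes as s2g
from snps2genes.enrich import GoGraph


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Logistic fits on tiny fixtures emit convergence chatter; keep output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """300-sample cohort, two LD blocks, one implanted common risk SNP."""
    cfg = s2g.SimConfig(
        n_cases=120,
        n_controls=180,
        blocks=[s2g.BlockSpec(8, 8, 0.02), s2g.BlockSpec(5, 6, 0.0)],
        causal_snps=[(3, 1.8)],
        seed=11,
    )
    return s2g.simulate_cohort(cfg)


def make_variants(mafs, chrom="1", rsq=1.0, start=10_000, step=1_000):
    mafs = np.asarray(mafs, dtype=float)
    return pd.DataFrame(
        {
            "snp": [f"snp{j:05d}" for j in range(mafs.size)],
            "chrom": str(chrom),
            "pos": start + step * np.arange(mafs.size),
            "minor_allele": "A",
            "major_allele": "G",
            "maf": mafs,
            "rsq": rsq,
        }
    )


def toy_go(annotations, edges=()):
    """GoGraph from (term, namespace, gene) records and (child, parent) edges."""
    return GoGraph.from_records(list(annotations), list(edges))
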