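"""Assign SNPs to genes with symmetric flanking windows.

A SNP belongs to a gene when it lies inside the gene's primary-transcript range
extended by ``flank`` bp on both sides (boundaries inclusive, 1-based); a SNP may
belong to several overlapping genes. Strand is ignored (flanks are symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import Snps2GenesError


@dataclass
class CoverageStats:
    n_input_snps: int
    n_assigned_snps: int
    pct_snps: float
    n_genes: int
    n_genes_hit: int
    pct_genes: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def coverage_percent(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else 0.0


def assign_snps(
    variants: pd.DataFrame, gene_ranges: pd.DataFrame, flank: int = 5000
) -> tuple[dict[str, list[int]], CoverageStats]:
    """Map SNPs to genes under the +/- ``flank`` rule.

    Returns ``(gene -> position-sorted SNP column indices, coverage stats)``.
    Raises when the two inputs share no chromosome names (build/naming mismatch).
    """
    v_chroms = set(variants["chrom"].astype(str))
    g_chroms = set(gene_ranges["chrom"].astype(str))
    if len(gene_ranges) and len(variants) and not (v_chroms & g_chroms):
        raise Snps2GenesError(
            "no chromosome name shared between variants and gene ranges: "
            f"variants have {sorted(v_chroms)}, genes have {sorted(g_chroms)}"
        )

    pos = variants["pos"].to_numpy()
    chrom = variants["chrom"].astype(str).to_numpy()
    mapping: dict[str, list[int]] = {}
    assigned = np.zeros(len(variants), dtype=bool)
    for _, g in gene_ranges.iterrows():
        on_chrom = chrom == str(g["chrom"])
        hit = on_chrom & (pos >= g["start"] - flank) & (pos <= g["end"] + flank)
        idx = np.flatnonzero(hit)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        if idx.size:
            mapping[str(g["gene"])] = idx.tolist()
            assigned[idx] = True

    stats = CoverageStats(
        n_input_snps=len(variants),
        n_assigned_snps=int(assigned.sum()),
        pct_snps=coverage_percent(int(assigned.sum()), len(variants)),
        n_genes=len(gene_ranges),
        n_genes_hit=len(mapping),
        pct_genes=coverage_percent(len(mapping), len(gene_ranges)),
    )
    return mapping, stats
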