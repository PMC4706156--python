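"""Readers and writers for the on-disk formats the pipeline touches.

Formats (all plain text, 1-based inclusive coordinates throughout):

* PED/MAP — PLINK-era pedigree text. MAP: ``chrom  snp_id  cM  pos``.
  PED: ``FID IID PAT MAT SEX PHENO`` followed by two allele columns per SNP
  (``0`` = missing). Phenotype 1 = control, 2 = case.
* Dosage TSV — header of SNP ids, one row per sample (first column = sample id),
  values in [0, 2]; supports imputed non-integer dosages.
* Gene ranges — whitespace-separated ``chrom start end name``.
* GO annotation TSV — ``term_id  namespace  gene`` with namespace in {BP, CC, MF};
  GO edges TSV — ``child  parent`` (is_a), must be acyclic.

Readers reject malformed records with :class:`FormatError` naming the line; they
never silently coerce.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GraphError

log = logging.getLogger(__name__)

VARIANT_COLUMNS = ["snp", "chrom", "pos", "minor_allele", "major_allele", "maf", "rsq"]
SAMPLE_COLUMNS = ["sample", "status", "sex"]


def _chrom_sort_key(c: pd.Series) -> pd.Series:
    return c.map(lambda x: (0, int(x)) if str(x).isdigit() else (1, str(x)))


def read_ped_map(ped_path: str | Path, map_path: str | Path):
    """Read a PED/MAP pair into ``(dosages, variants, samples)``.

    The minor allele is determined per SNP by overall frequency (tie broken by
    the lexicographically smaller allele); dosage counts minor alleles; missing
    genotypes become NaN dosages. Variants (and dosage columns) are sorted by
    (chrom, pos) after load.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{map_path}:{ln}: expected 4 MAP fields, got {len(parts)}")
        chrom, snp, _cm, pos = parts
        try:
            pos_i = int(pos)
        except ValueError as exc:
            raise FormatError(f"{map_path}:{ln}: position {pos!r} is not an integer") from exc
        if pos_i < 1:
            raise FormatError(f"{map_path}:{ln}: position must be >= 1")
        map_rows.append((snp, chrom, pos_i))
    if len({r[0] for r in map_rows}) != len(map_rows):
        raise FormatError(f"{map_path}: duplicate SNP ids")
    m = len(map_rows)

    sample_ids, statuses, sexes, geno_rows = [], [], [], []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise FormatError(
                f"{ped_path}:{ln}: expected {6 + 2 * m} PED fields for {m} SNPs, got {len(parts)}"
            )
        _fid, iid, _pat, _mat, sex, pheno = parts[:6]
        if sex not in {"1", "2"}:
            raise FormatError(f"{ped_path}:{ln}: sex must be 1 or 2, got {sex!r}")
        if pheno not in {"1", "2"}:
            raise FormatError(f"{ped_path}:{ln}: phenotype must be 1 or 2, got {pheno!r}")
        sample_ids.append(iid)
        sexes.append(int(sex))
        statuses.append(int(pheno) - 1)
        geno_rows.append(parts[6:])
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{ped_path}: duplicate sample ids")
    n = len(sample_ids)
    geno = np.array(geno_rows, dtype=object).reshape(n, m, 2)

    dosages = np.full((n, m), np.nan)
    minor_alleles, major_alleles, mafs = [], [], []
    for j in range(m):
        col = geno[:, j, :]
        observed = col[col != "0"]
        alleles = sorted(set(observed.tolist()))
        if len(alleles) > 2:
            raise FormatError(
                f"{ped_path}: SNP {map_rows[j][0]} has >2 alleles: {alleles}"
            )
        counts = {a: int((observed == a).sum()) for a in alleles}
        if len(alleles) < 2:
            # monomorphic (or all-missing): the observed allele is major, dosage 0
            major = alleles[0] if alleles else "N"
            minor = "N"
            counts[minor] = 0
        else:
            # minor by frequency, lexicographic tie-break (smaller allele is minor)
            minor = min(alleles, key=lambda a: (counts[a], a))
            major = next(a for a in alleles if a != minor)
        dose = (col == minor).sum(axis=1).astype(float)
        dose[(col == "0").any(axis=1)] = np.nan
        dosages[:, j] = dose
        tot = sum(counts.values())
        minor_alleles.append(minor)
        major_alleles.append(major)
        mafs.append(counts.get(minor, 0) / tot if tot else 0.0)

    variants = pd.DataFrame(
        {
            "snp": [r[0] for r in map_rows],
            "chrom": [r[1] for r in map_rows],
            "pos": [r[2] for r in map_rows],
            "minor_allele": minor_alleles,
            "major_allele": major_alleles,
            "maf": mafs,
            "rsq": 1.0,
        }
    )
    order = variants.assign(_k=_chrom_sort_key(variants["chrom"])).sort_values(
        ["_k", "pos"], kind="stable"
    ).index.to_numpy()
    variants = variants.loc[order].reset_index(drop=True)
    dosages = dosages[:, order]
    samples = pd.DataFrame({"sample": sample_ids, "status": statuses, "sex": sexes})
    return dosages, variants, samples


def write_ped_map(
    dosages: np.ndarray,
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write hard-call PED/MAP. Fractional dosages are rounded to the nearest
    genotype; NaN becomes the missing code ``0 0``."""
    n, m = dosages.shape
    with open(map_path, "w") as fh:
        for _, v in variants.iterrows():
            fh.write(f"{v['chrom']}\t{v['snp']}\t0\t{int(v['pos'])}\n")
    minor = variants["minor_allele"].to_numpy()
    major = variants["major_allele"].to_numpy()
    with open(ped_path, "w") as fh:
        for i in range(n):
            row = samples.iloc[i]
            fields = [str(row["sample"]), str(row["sample"]), "0", "0",
                      str(int(row["sex"])), str(int(row["status"]) + 1)]
            for j in range(m):
                d = dosages[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                else:
                    k = int(round(float(d)))
                    k = min(max(k, 0), 2)
                    fields += [minor[j]] * k + [major[j]] * (2 - k)
            fh.write(" ".join(fields) + "\n")


def write_dosage_tsv(dosages: np.ndarray, variants: pd.DataFrame,
                     samples: pd.DataFrame, path: str | Path) -> None:
    df = pd.DataFrame(dosages, columns=variants["snp"].tolist())
    df.insert(0, "sample", samples["sample"].to_numpy())
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | Path):
    """Read the dosage dialect: header = SNP ids, one row per sample."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "sample":
        raise FormatError(f"{path}: first column must be 'sample'")
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(dosages) < -1e-9 or np.nanmax(dosages) > 2 + 1e-9:
            raise FormatError(f"{path}: dosages must lie in [0, 2]")
    return dosages, df.columns[1:].tolist(), df["sample"].tolist()


def impute_missing(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP mean imputation of missing dosages (standard for dosage GWAS)."""
    out = dosages.copy()
    miss = np.isnan(out)
    if miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, out), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        idx = np.where(miss)
        out[idx] = col_mean[idx[1]]
        for j in np.unique(idx[1]):
            log.info("SNP column %d: imputed %d missing dosages", j, int(miss[:, j].sum()))
    return out


def read_gene_ranges(path: str | Path) -> pd.DataFrame:
    """Read PLINK gene-range text: ``chrom start end name`` per line,
    1-based inclusive coordinates."""
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{ln}: expected 4 fields (chrom start end name)")
        chrom, start, end, name = parts
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: start/end must be integers") from exc
        if start_i > end_i:
            raise FormatError(f"{path}:{ln}: start > end for gene {name}")
        rows.append({"gene": name, "chrom": chrom, "start": start_i, "end": end_i})
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])
    dup = genes.duplicated(subset=["gene", "chrom"], keep=False)
    if dup.any():
        names = sorted(genes.loc[dup, "gene"].unique().tolist())
        raise FormatError(f"{path}: duplicate gene names per chromosome: {names}")
    return genes


def read_go(annotation_path: str | Path, edges_path: str | Path):
    """Read the GO subset (annotation + is_a edges) into a :class:`GoGraph`.

    The edge list is cycle-checked; annotations are propagated to ancestors on
    construction. An empty annotation file yields an empty graph with a warning.
    """
    from .enrich import GoGraph

    ann_rows = []
    for ln, line in enumerate(Path(annotation_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise FormatError(f"{annotation_path}:{ln}: expected term_id namespace gene")
        term, ns, gene = parts
        if ns not in {"BP", "CC", "MF"}:
            raise FormatError(f"{annotation_path}:{ln}: namespace {ns!r} not in BP/CC/MF")
        ann_rows.append((term, ns, gene))
    if not ann_rows:
        warnings.warn(f"{annotation_path}: empty GO annotation; empty graph returned")

    edge_rows = []
    for ln, line in enumerate(Path(edges_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise FormatError(f"{edges_path}:{ln}: expected child parent")
        edge_rows.append((parts[0], parts[1]))
    return GoGraph.from_records(ann_rows, edge_rows)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write each result table as ``<name>.tsv`` under ``out_dir``; deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in sorted(tables.items()):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep="NA")
        written[name] = p
    return written
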