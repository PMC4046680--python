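"""I/O and SNP-set construction: genotype matrices, phenotypes, gene
intervals, GMT pathways, and SNP -> gene -> pathway mapping.

Conventions
-----------
* Genotypes are minor-allele counts coded 0/1/2 and treated downstream as
  three unordered categories.
* Gene coordinates are 1-based inclusive internally; BED input (0-based,
  half-open) is converted at read time.
* A SNP belongs to a gene iff its position lies within ``window_bp`` base
  pairs of the gene body, boundary inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Phenotype",
    "GeneInterval",
    "SnpSet",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "read_gene_intervals",
    "map_snps_to_genes",
    "read_gmt_pathways",
    "pathway_snpsets",
]

MissingPolicy = Literal["fail", "drop-snp", "mode-impute"]


@dataclass
class GenotypeMatrix:
    """n_samples x d_snps integer matrix with entries in {0, 1, 2}."""

    values: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    snp_positions: Optional[list[tuple[str, int]]] = None  # (chrom, 1-based bp)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must form a 2-d matrix")
        n, d = self.values.shape
        if len(self.snp_ids) != d:
            raise ValueError(f"{len(self.snp_ids)} snp_ids for {d} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(set(self.snp_ids)) != d:
            raise ValueError("snp_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 2):
            bad = np.argwhere((self.values < 0) | (self.values > 2))[0]
            raise ValueError(
                f"genotype outside {{0,1,2}} at sample {self.sample_ids[bad[0]]},"
                f" SNP {self.snp_ids[bad[1]]}"
            )
        if self.snp_positions is not None and len(self.snp_positions) != d:
            raise ValueError("snp_positions length must match number of SNPs")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset(self, snp_indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(snp_indices)
        return GenotypeMatrix(
            values=self.values[:, idx],
            snp_ids=[self.snp_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            snp_positions=None
            if self.snp_positions is None
            else [self.snp_positions[i] for i in idx],
        )


@dataclass
class Phenotype:
    """Binary case-control status (1 = case) aligned to a GenotypeMatrix."""

    y: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.y = np.ascontiguousarray(self.y, dtype=np.int8)
        if self.y.ndim != 1:
            raise ValueError("phenotype must be a vector")
        if len(self.sample_ids) != self.y.shape[0]:
            raise ValueError("sample_ids length must match phenotype length")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("phenotype entries must be 0 or 1")
        if self.y.sum() == 0 or self.y.sum() == len(self.y):
            raise ValueError("phenotype needs at least one case and one control")

    @property
    def case_fraction(self) -> float:
        return float(self.y.mean())


@dataclass(frozen=True)
class GeneInterval:
    """Gene body on a chromosome, 1-based inclusive coordinates."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class SnpSet:
    """Named set of SNP column indices into a GenotypeMatrix."""

    set_id: str
    snp_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.snp_indices, dtype=np.int64)
        if idx.ndim != 1 or idx.size == 0:
            raise ValueError(f"SNP set {self.set_id} must be a non-empty index vector")
        if len(np.unique(idx)) != idx.size:
            raise ValueError(f"SNP set {self.set_id} has duplicate indices")
        if idx.min() < 0:
            raise ValueError(f"SNP set {self.set_id} has negative indices")
        object.__setattr__(self, "snp_indices", np.sort(idx))

    def __len__(self) -> int:
        return int(self.snp_indices.size)


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------


def _apply_missing(
    raw: np.ndarray, snp_ids: list[str], policy: MissingPolicy
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Resolve missing (< 0) or out-of-domain entries; returns kept columns."""
    bad = (raw < 0) | (raw > 2)
    keep = np.ones(raw.shape[1], dtype=bool)
    if not bad.any():
        return raw, snp_ids, keep
    if policy == "fail":
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid/missing genotype at row {i}, SNP {snp_ids[j]} with missing_policy='fail'"
        )
    if policy == "drop-snp":
        keep = ~bad.any(axis=0)
        if not keep.any():
            raise ValueError("all SNPs dropped by missing_policy='drop-snp'")
        return raw[:, keep], [s for s, k in zip(snp_ids, keep) if k], keep
    if policy == "mode-impute":
        out = raw.copy()
        for j in np.flatnonzero(bad.any(axis=0)):
            col = out[:, j]
            ok = ~bad[:, j]
            if not ok.any():
                raise ValueError(f"SNP {snp_ids[j]} has no observed genotypes to impute from")
            vals, counts = np.unique(col[ok], return_counts=True)
            col[bad[:, j]] = vals[np.argmax(counts)]
        return out, snp_ids, keep
    raise ValueError(f"unknown missing_policy {policy!r}")


def _read_matrix_tsv(path: Path, missing_policy: MissingPolicy) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"failed to parse genotype TSV {path}: {exc}") from exc
    snp_ids = [str(c) for c in df.columns]
    sample_ids = [str(i) for i in df.index]
    raw = np.full(df.shape, -1, dtype=np.int64)
    for j, col in enumerate(df.columns):
        series = df[col].str.strip()
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.isna().any() and missing_policy == "fail":
            line = int(np.flatnonzero(numeric.isna())[0]) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric genotype on line {line}")
        raw[:, j] = numeric.fillna(-1).astype(np.int64)
    values, snp_ids, _ = _apply_missing(raw, snp_ids, missing_policy)
    return GenotypeMatrix(values=values, snp_ids=snp_ids, sample_ids=sample_ids)


def _read_vcf(path: Path, missing_policy: MissingPolicy) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    positions: list[tuple[str, int]] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic record at {variant.CHROM}:{variant.POS}"
            )
            continue
        col = np.empty(len(sample_ids), dtype=np.int64)
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                col[i] = -1
            else:
                col[i] = int(alleles[0] > 0) + int(alleles[1] > 0)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        positions.append((str(variant.CHROM), int(variant.POS)))
        columns.append(col)
    if not columns:
        raise ValueError(f"no usable biallelic records in {path}")
    raw = np.stack(columns, axis=1)
    values, snp_ids_kept, keep = _apply_missing(raw, snp_ids, missing_policy)
    positions = [p for p, k in zip(positions, keep) if k]
    return GenotypeMatrix(
        values=values, snp_ids=snp_ids_kept, sample_ids=sample_ids, snp_positions=positions
    )


def read_genotypes(
    path: str | Path,
    format: Literal["matrix-tsv", "vcf"] = "matrix-tsv",
    missing_policy: MissingPolicy = "mode-impute",
) -> GenotypeMatrix:
    """Read a genotype matrix from a TSV matrix or a VCF (GT field).

    VCF diploid genotypes are coded by alternate-allele count: 0/0 -> 0,
    0/1 or 1/0 -> 1, 1/1 -> 2.  Multi-allelic records are skipped with a
    warning.  ``missing_policy`` resolves missing or out-of-domain entries.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "matrix-tsv":
        return _read_matrix_tsv(path, missing_policy)
    if format == "vcf":
        return _read_vcf(path, missing_policy)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix-tsv representation (header of SNP ids, first column
    sample id)."""
    df = pd.DataFrame(G.values, index=G.sample_ids, columns=G.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_phenotype(path: str | Path) -> Phenotype:
    """Read a two-column TSV (sample_id, status) of 0/1 case-control labels."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: phenotype TSV needs sample_id and status columns")
    return Phenotype(
        y=df.iloc[:, 1].astype(int).to_numpy(), sample_ids=[str(s) for s in df.iloc[:, 0]]
    )


def read_gene_intervals(path: str | Path, coords: Literal["bed", "one-based"] = "bed") -> list[GeneInterval]:
    """Read gene intervals from a BED-like TSV (chrom, start, end, gene_id).

    BED coordinates (0-based half-open) are converted to 1-based inclusive.
    """
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected chrom, start, end, gene_id")
            chrom, start, end, gene_id = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if coords == "bed":
                start, end = start + 1, end
            genes.append(GeneInterval(gene_id=gene_id, chromosome=chrom, start=start, end=end))
    if not genes:
        raise ValueError(f"{path}: no gene intervals found")
    return genes


# ---------------------------------------------------------------------------
# SNP -> gene -> pathway mapping
# ---------------------------------------------------------------------------


def map_snps_to_genes(
    snp_positions: Sequence[tuple[str, int]],
    genes: Sequence[GeneInterval],
    window_bp: int = 5000,
) -> list[SnpSet]:
    """Assign SNPs to genes within ``window_bp`` of the gene body (inclusive).

    A SNP inside the windows of several genes joins every one of them.
    Genes with no assigned SNP are omitted.
    """
    chroms = np.array([c for c, _ in snp_positions])
    pos = np.array([p for _, p in snp_positions], dtype=np.int64)
    out: list[SnpSet] = []
    for gene in genes:
        mask = (
            (chroms == gene.chromosome)
            & (pos >= gene.start - window_bp)
            & (pos <= gene.end + window_bp)
        )
        idx = np.flatnonzero(mask)
        if idx.size:
            out.append(SnpSet(set_id=gene.gene_id, snp_indices=idx))
    if not out:
        warnings.warn("no SNP mapped to any gene")
    return out


def read_gmt_pathways(
    path: str | Path, gene_sets_max: int = 250
) -> list[tuple[str, list[str]]]:
    """Read a GMT file; pathways with more than ``gene_sets_max`` genes are
    filtered out (overly broad sets hurt specificity)."""
    pathways: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{ln}: malformed GMT line (need name, description, >=1 gene)"
                )
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{ln}: pathway {name} lists no genes")
            if len(genes) > gene_sets_max:
                continue
            pathways.append((name, genes))
    if not pathways:
        raise ValueError(f"{path}: no pathways retained")
    return pathways


def pathway_snpsets(
    pathways: Sequence[tuple[str, Sequence[str]]],
    gene_snpsets: Sequence[SnpSet],
) -> list[SnpSet]:
    """Union the member genes' SNP indices into one SnpSet per pathway.

    A SNP shared by several member genes is counted once.  Pathways whose
    genes carry no mapped SNPs are dropped with a warning.
    """
    by_gene = {s.set_id: s.snp_indices for s in gene_snpsets}
    out: list[SnpSet] = []
    for name, genes in pathways:
        pieces = [by_gene[g] for g in genes if g in by_gene]
        if not pieces:
            warnings.warn(f"pathway {name} has no mapped SNPs; dropped")
            continue
        out.append(SnpSet(set_id=name, snp_indices=np.unique(np.concatenate(pieces))))
    return out


def align_phenotype(G: GenotypeMatrix, pheno: Phenotype) -> Phenotype:
    """Reorder a phenotype to the genotype matrix's sample order."""
    lookup = {s: i for i, s in enumerate(pheno.sample_ids)}
    missing = [s for s in G.sample_ids if s not in lookup]
    if missing:
        raise ValueError(f"phenotype missing samples: {missing[:5]}")
    order = [lookup[s] for s in G.sample_ids]
    return Phenotype(y=pheno.y[order], sample_ids=list(G.sample_ids))
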