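"""Readers and writers for genotype, annotation, phenotype and result tables.

Genotypes are held as minor-allele dosage matrices (individuals x SNPs,
entries 0/1/2).  All readers enforce the same contract: missing genotypes are
imputed to the rounded per-SNP mean dosage, columns are oriented so that the
counted allele is the minor one, and monomorphic columns are dropped (their
MAF-based weight would be undefined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("wavescore")

__all__ = [
    "SnpRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_vcf",
    "read_matrix_tsv",
    "read_annotation",
    "read_phenotypes",
    "write_matrix_tsv",
    "write_results",
]


class EmptyInputError(ValueError):
    """No individuals or no SNPs survive parsing/filtering."""


@dataclass
class SnpRecord:
    """One biallelic SNP: identity, location, gene annotation and MAF."""

    id: str
    chromosome: str
    position: int  # 1-based, VCF convention
    gene: str = ""
    is_nonsynonymous: bool = False
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1, got {self.position}")


def _chrom_sort_key(chrom: str) -> tuple[int, int | str]:
    c = chrom.removeprefix("chr")
    try:
        return (0, int(c))
    except ValueError:
        return (1, c)


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix with per-SNP and per-individual metadata.

    Invariants: entries in {0,1,2}; SNPs sorted by (chromosome, position)
    with strictly increasing positions within a chromosome; every retained
    SNP is polymorphic (MAF in (0, 0.5]).
    """

    dosages: np.ndarray
    individual_ids: list[str]
    snps: list[SnpRecord]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix (individuals x SNPs)")
        n, p = self.dosages.shape
        if n != len(self.individual_ids):
            raise ValueError("row count does not match number of individual ids")
        if p != len(self.snps):
            raise ValueError("column count does not match number of SNP records")
        if p and not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosage entries must be in {0, 1, 2}")
        order = sorted(
            range(p),
            key=lambda j: (_chrom_sort_key(self.snps[j].chromosome), self.snps[j].position),
        )
        if order != list(range(p)):
            self.dosages = self.dosages[:, order]
            self.snps = [self.snps[j] for j in order]
        for a, b in zip(self.snps, self.snps[1:]):
            if a.chromosome == b.chromosome and a.position >= b.position:
                raise ValueError(
                    f"positions not strictly increasing on {a.chromosome}: "
                    f"{a.position} then {b.position}"
                )

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.individual_ids), [replace(self.snps[j]) for j in idx]
        )

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {iid: i for i, iid in enumerate(self.individual_ids)}
        rows = [pos[i] for i in ids]
        return GenotypeMatrix(self.dosages[rows], list(ids), [replace(s) for s in self.snps])


@dataclass
class PhenotypeTable:
    """Trait and covariate columns aligned to a genotype matrix's individuals."""

    individual_ids: list[str]
    traits: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if len(self.traits) != len(self.individual_ids):
            raise ValueError("trait rows do not match individual ids")
        if len(self.covariates) and len(self.covariates) != len(self.individual_ids):
            raise ValueError("covariate rows do not match individual ids")

    def trait(self, name: str) -> np.ndarray:
        return self.traits[name].to_numpy(dtype=float)

    def covariate(self, name: str) -> np.ndarray:
        frame = self.covariates if name in self.covariates.columns else self.traits
        return frame[name].to_numpy(dtype=float)


def _impute_and_orient(
    raw: np.ndarray, snps: list[SnpRecord], individual_ids: list[str]
) -> GenotypeMatrix:
    """Impute missing entries (NaN) to rounded column means, orient each
    column to count the minor allele, and drop monomorphic columns."""
    raw = np.asarray(raw, dtype=float)
    n, p = raw.shape
    if n == 0 or p == 0:
        raise EmptyInputError("empty genotype matrix")
    out = raw.copy()
    for j in range(p):
        col = out[:, j]
        miss = np.isnan(col)
        if miss.all():
            col[:] = 0.0
        elif miss.any():
            col[miss] = np.round(col[~miss].mean())
    freq = out.mean(axis=0) / 2.0
    flip = freq > 0.5
    out[:, flip] = 2 - out[:, flip]
    maf = out.mean(axis=0) / 2.0
    keep = maf > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d monomorphic SNP(s) after minor-allele orientation", n_dropped)
    if not keep.any():
        raise EmptyInputError("no polymorphic SNPs remain after filtering")
    kept_snps = [replace(s, maf=float(maf[j])) for j, s in enumerate(snps) if keep[j]]
    return GenotypeMatrix(out[:, keep].astype(np.int64), list(individual_ids), kept_snps)


def read_annotation(path: str) -> pd.DataFrame:
    """Read a SNP annotation sidecar (TSV with snp_id, and any of
    chromosome, position, gene, is_nonsynonymous)."""
    ann = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if "snp_id" not in ann.columns:
        raise ValueError(f"annotation file {path} lacks a snp_id column")
    return ann.set_index("snp_id")


def _apply_annotation(snps: list[SnpRecord], annotation: pd.DataFrame | None) -> list[SnpRecord]:
    if annotation is None:
        return snps
    out = []
    n_missing = 0
    for s in snps:
        if s.id in annotation.index:
            row = annotation.loc[s.id]
            s = replace(
                s,
                chromosome=str(row["chromosome"]) if "chromosome" in row else s.chromosome,
                position=int(row["position"]) if "position" in row else s.position,
                gene=str(row["gene"]) if "gene" in row and not pd.isna(row["gene"]) else "",
                is_nonsynonymous=bool(row["is_nonsynonymous"])
                if "is_nonsynonymous" in row
                else s.is_nonsynonymous,
            )
        else:
            n_missing += 1
        out.append(s)
    if n_missing:
        logger.warning("%d SNP(s) absent from annotation; kept with empty gene", n_missing)
    return out


def read_vcf(path: str, annotation_path: str | None = None) -> GenotypeMatrix:
    """Read biallelic GT records from a VCF into a GenotypeMatrix.

    Multiallelic records are skipped with a log entry.  Orientation,
    imputation and monomorphic filtering follow the module contract.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    ids = list(vcf.samples)
    if not ids:
        raise EmptyInputError(f"{path}: VCF contains no samples")
    cols: list[np.ndarray] = []
    snps: list[SnpRecord] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.array(var.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
        alleles[alleles < 0] = np.nan
        dose = alleles.sum(axis=1)  # NaN if either allele missing
        cols.append(dose)
        vid = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        snps.append(SnpRecord(id=vid, chromosome=str(var.CHROM), position=int(var.POS)))
    if n_multi:
        logger.info("skipped %d multiallelic record(s)", n_multi)
    if not snps:
        raise EmptyInputError(f"{path}: no biallelic records")
    raw = np.column_stack(cols)
    snps = _apply_annotation(snps, read_annotation(annotation_path) if annotation_path else None)
    return _impute_and_orient(raw, snps, ids)


def read_matrix_tsv(path: str, annotation_path: str | None = None) -> GenotypeMatrix:
    """Read a plain individuals x SNPs dosage table (header = SNP ids,
    first column = individual ids, entries 0/1/2/NA)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise EmptyInputError(f"{path}: empty genotype table")
    vals = df.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: invalid dosage {vals[i, j]!r} for individual "
            f"{df.index[i]!r}, SNP {df.columns[j]!r} (expected 0/1/2/NA)"
        )
    annotation = read_annotation(annotation_path) if annotation_path else None
    snps = [
        SnpRecord(id=str(c), chromosome="1", position=j + 1) for j, c in enumerate(df.columns)
    ]
    snps = _apply_annotation(snps, annotation)
    return _impute_and_orient(vals, snps, [str(i) for i in df.index])


def read_phenotypes(
    path: str,
    trait_names: Sequence[str],
    covariate_names: Sequence[str] = (),
    individual_ids: Sequence[str] | None = None,
    binary_traits: Iterable[str] = (),
    id_column: str | None = None,
) -> PhenotypeTable:
    """Read a phenotype/covariate TSV and align rows to a genotype matrix.

    Rows are reordered to `individual_ids` (genotype order); individuals
    present in only one of the two sources are dropped with a log entry.
    Columns named in `binary_traits` must contain only 0/1.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = id_column or df.columns[0]
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    for name in list(trait_names) + list(covariate_names):
        if name not in df.columns:
            raise ValueError(f"{path}: column {name!r} not found")
        col = pd.to_numeric(df[name], errors="coerce")
        if col.isna().any() and not df[name].isna().any():
            raise ValueError(f"{path}: non-numeric value in column {name!r}")
        df[name] = col
    for name in binary_traits:
        vals = set(df[name].dropna().unique())
        if not vals <= {0, 1}:
            raise ValueError(f"{path}: binary column {name!r} contains values {sorted(vals)}")
    if individual_ids is not None:
        wanted = [i for i in individual_ids if i in df.index]
        n_pheno_only = len(df.index.difference(wanted))
        n_geno_only = len(individual_ids) - len(wanted)
        if not wanted:
            raise ValueError("no overlapping individuals between genotypes and phenotypes")
        if n_pheno_only or n_geno_only:
            logger.info(
                "dropped %d phenotype-only and %d genotype-only individual(s)",
                n_pheno_only,
                n_geno_only,
            )
        df = df.loc[wanted]
    ids = [str(i) for i in df.index]
    return PhenotypeTable(
        individual_ids=ids,
        traits=df[list(trait_names)].reset_index(drop=True),
        covariates=df[list(covariate_names)].reset_index(drop=True),
    )


def write_matrix_tsv(G: GenotypeMatrix, path: str) -> None:
    """Write dosages as a TSV readable by read_matrix_tsv (round-trips exactly)."""
    df = pd.DataFrame(G.dosages, index=G.individual_ids, columns=[s.id for s in G.snps])
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


RESULT_COLUMNS = [
    "window_id",
    "chromosome",
    "first_snp",
    "last_snp",
    "genes",
    "n_snps",
    "T",
    "p_empirical",
    "p_bonferroni",
    "p_maxstat",
    "n_permutations",
]


def write_results(results: Sequence, path: str, header_lines: Sequence[str] = ()) -> None:
    """Write per-window test results as a TSV in genome order.

    `results` are assoc_test.WindowTestResult objects.  Optional
    `header_lines` are emitted first as '#'-prefixed provenance comments.
    Identical inputs yield byte-identical files.
    """
    if not results:
        raise ValueError("no results to write")
    rows = []
    for r in results:
        w = r.window
        rows.append(
            {
                "window_id": w.id,
                "chromosome": w.chromosome,
                "first_snp": w.first_snp_id,
                "last_snp": w.last_snp_id,
                "genes": w.label,
                "n_snps": w.size,
                "T": f"{r.T:.10g}",
                "p_empirical": f"{r.p_empirical:.10g}",
                "p_bonferroni": f"{r.p_bonferroni:.10g}",
                "p_maxstat": "" if r.p_maxstat is None else f"{r.p_maxstat:.10g}",
                "n_permutations": r.n_permutations,
            }
        )
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in RESULT_COLUMNS) + "\n")
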