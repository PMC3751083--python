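"""Readers, writers and containers for genotype, annotation and expression data.

Two genotype dialects are supported: PLINK text ``.ped``/``.map`` pairs
(whitespace-delimited, ``0`` as the missing allele, phenotype ``2`` = case)
and a simple project TSV (one subject per row, cells ``A/G``, missing
``./.``).  Genotypes are unordered allele pairs: ``A G`` and ``G A`` are the
same genotype, so pairs are stored sorted.  Each SNP may carry at most two
distinct allele symbols; a third symbol is a load error.

SNP-to-gene annotation is a local TSV table (columns ``snp_id``, ``gene``,
``chromosome``, ``position``); SNPs with an empty gene field are treated as
intergenic and excluded from analysis.  Expression data arrive as a
genes x subjects TSV with replicate column suffixes ``_r1``/``_r2``/``_r3``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING_ALLELE = "0"
VALID_ALLELES = frozenset("ACGT")

CASE = True
CONTROL = False


class MalformedLocusError(ValueError):
    """A SNP column is not a valid biallelic locus (bad arity or >2 alleles)."""


class AnnotationConflictError(ValueError):
    """The same SNP id maps to two different genes in the annotation table."""


class LoadError(ValueError):
    """Structural problem in an input file (duplicate ids, bad labels, ...)."""


# ---------------------------------------------------------------------------
# Genotype container
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """A subjects x SNPs matrix of unordered allele-pair genotypes.

    Attributes
    ----------
    subject_ids : list of str
        Unique subject identifiers, row order of ``alleles``.
    labels : ndarray of bool
        ``True`` for cases (HT), ``False`` for controls (NC).
    snp_ids : list of str
        Unique SNP (rs) identifiers, column order of ``alleles``.
    alleles : ndarray, shape (n_subjects, n_snps, 2), dtype ``<U1``
        Sorted allele pairs; a missing genotype is ``("0", "0")``.
    name : str
        Dataset / platform tag used in multi-dataset bookkeeping.
    ethnic_group, platform : str
        Stratification metadata for the S1 / S2 classification scenarios.
    """

    subject_ids: list[str]
    labels: np.ndarray
    snp_ids: list[str]
    alleles: np.ndarray
    name: str = "dataset"
    ethnic_group: str = "pop"
    platform: str = "platform"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        self.validate()

    # -- basic accessors ----------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_cases(self) -> int:
        return int(self.labels.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.labels).sum())

    @property
    def case_ids(self) -> list[str]:
        return [s for s, l in zip(self.subject_ids, self.labels) if l]

    @property
    def control_ids(self) -> list[str]:
        return [s for s, l in zip(self.subject_ids, self.labels) if not l]

    def snp_index(self, snp_id: str) -> int:
        return self.snp_ids.index(snp_id)

    def allele_census(self) -> list[dict[str, int]]:
        """Per-SNP counts of non-missing allele symbols."""
        out: list[dict[str, int]] = []
        for j in range(self.n_snps):
            col = self.alleles[:, j, :].ravel()
            symbols, counts = np.unique(col[col != MISSING_ALLELE], return_counts=True)
            out.append(dict(zip(symbols.tolist(), counts.tolist())))
        return out

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise LoadError(f"duplicate subject ids in dataset {self.name!r}")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise LoadError(f"duplicate SNP ids in dataset {self.name!r}")
        if self.alleles.shape != (len(self.subject_ids), len(self.snp_ids), 2):
            raise LoadError("allele array shape does not match id lists")
        if len(self.labels) != len(self.subject_ids):
            raise LoadError("label vector length does not match subjects")
        for j, census in enumerate(self.allele_census()):
            bad = set(census) - VALID_ALLELES
            if bad:
                raise MalformedLocusError(
                    f"SNP {self.snp_ids[j]}: invalid allele symbol(s) {sorted(bad)}"
                )
            if len(census) > 2:
                raise MalformedLocusError(
                    f"SNP {self.snp_ids[j]}: {len(census)} alleles observed "
                    f"({sorted(census)}); at most 2 allowed"
                )

    def subset_subjects(self, keep: Sequence[str]) -> "GenotypeDataset":
        idx = [self.subject_ids.index(s) for s in keep]
        return GenotypeDataset(
            subject_ids=[self.subject_ids[i] for i in idx],
            labels=self.labels[idx],
            snp_ids=list(self.snp_ids),
            alleles=self.alleles[idx],
            name=self.name,
            ethnic_group=self.ethnic_group,
            platform=self.platform,
        )

    def subset_snps(self, keep: Sequence[str]) -> "GenotypeDataset":
        idx = [self.snp_ids.index(s) for s in keep]
        return GenotypeDataset(
            subject_ids=list(self.subject_ids),
            labels=self.labels.copy(),
            snp_ids=[self.snp_ids[i] for i in idx],
            alleles=self.alleles[:, idx],
            name=self.name,
            ethnic_group=self.ethnic_group,
            platform=self.platform,
        )


def _normalize_pair(a: str, b: str) -> tuple[str, str]:
    a, b = a.upper(), b.upper()
    if (a == MISSING_ALLELE) != (b == MISSING_ALLELE):
        # half-missing genotypes are treated as fully missing
        return (MISSING_ALLELE, MISSING_ALLELE)
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Genotype readers / writers
# ---------------------------------------------------------------------------


def read_genotypes(path_prefix: str | Path, dialect: str = "plink-ped",
                   name: str | None = None, **meta: str) -> GenotypeDataset:
    """Read a case-control genotype dataset.

    ``dialect`` is ``"plink-ped"`` (reads ``<prefix>.ped`` + ``<prefix>.map``)
    or ``"tsv"`` (reads ``<prefix>.tsv``, or the path itself if it already
    ends in ``.tsv``).
    """
    path_prefix = Path(path_prefix)
    if name is None:
        name = path_prefix.stem or path_prefix.name
    if dialect == "plink-ped":
        return _read_ped(path_prefix, name, **meta)
    if dialect == "tsv":
        p = path_prefix if path_prefix.suffix == ".tsv" else path_prefix.with_suffix(".tsv")
        return _read_tsv(p, name, **meta)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(data: GenotypeDataset, path_prefix: str | Path,
                    dialect: str = "plink-ped",
                    annotation: "SnpAnnotation | None" = None) -> None:
    path_prefix = Path(path_prefix)
    if dialect == "plink-ped":
        _write_ped(data, path_prefix, annotation)
    elif dialect == "tsv":
        p = path_prefix if path_prefix.suffix == ".tsv" else path_prefix.with_suffix(".tsv")
        _write_tsv(data, p)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_ped(prefix: Path, name: str, **meta: str) -> GenotypeDataset:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    snp_ids: list[str] = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise LoadError(f"{map_path}: expected 4 columns, got {len(parts)}")
            snp_ids.append(parts[1])
    n_snps = len(snp_ids)
    subject_ids: list[str] = []
    labels: list[bool] = []
    rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise MalformedLocusError(
                    f"{ped_path} line {ln}: expected {6 + 2 * n_snps} fields "
                    f"(6 + 2 per SNP), got {len(parts)}"
                )
            subject_ids.append(parts[1])
            pheno = parts[5]
            if pheno not in ("1", "2"):
                raise LoadError(f"{ped_path} line {ln}: phenotype must be 1/2, got {pheno!r}")
            labels.append(pheno == "2")
            geno = parts[6:]
            rows.append([_normalize_pair(geno[2 * j], geno[2 * j + 1]) for j in range(n_snps)])
    alleles = np.array(rows, dtype="<U1").reshape(len(rows), n_snps, 2)
    return GenotypeDataset(subject_ids, np.array(labels), snp_ids, alleles, name=name, **meta)


def _write_ped(data: GenotypeDataset, prefix: Path,
               annotation: "SnpAnnotation | None") -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for snp in data.snp_ids:
            chrom, pos = "0", "0"
            if annotation is not None and snp in annotation.by_snp.index:
                row = annotation.by_snp.loc[snp]
                chrom, pos = str(row["chromosome"]), str(row["position"])
            fh.write(f"{chrom}\t{snp}\t0\t{pos}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(data.subject_ids):
            pheno = "2" if data.labels[i] else "1"
            cells = " ".join(f"{a} {b}" for a, b in data.alleles[i])
            fh.write(f"{sid} {sid} 0 0 0 {pheno} {cells}\n")


_TSV_CELL = re.compile(r"^([ACGT.])/([ACGT.])$", re.IGNORECASE)


def _read_tsv(path: Path, name: str, **meta: str) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "label"}
    if not required.issubset(df.columns):
        raise LoadError(f"{path}: TSV dialect requires columns {sorted(required)}")
    snp_ids = [c for c in df.columns if c not in required]
    subject_ids = df["subject_id"].tolist()
    raw_labels = df["label"].tolist()
    bad = [l for l in raw_labels if l not in ("HT", "NC")]
    if bad:
        raise LoadError(f"{path}: labels must be HT/NC, got {bad[:3]}")
    labels = np.array([l == "HT" for l in raw_labels])
    rows = []
    for _, rec in df.iterrows():
        row = []
        for snp in snp_ids:
            cell = str(rec[snp])
            m = _TSV_CELL.match(cell)
            if m is None:
                raise MalformedLocusError(f"{path}: SNP {snp}: bad genotype cell {cell!r}")
            a, b = m.group(1), m.group(2)
            if a == "." or b == ".":
                row.append((MISSING_ALLELE, MISSING_ALLELE))
            else:
                row.append(_normalize_pair(a, b))
        rows.append(row)
    alleles = np.array(rows, dtype="<U1").reshape(len(rows), len(snp_ids), 2)
    return GenotypeDataset(subject_ids, labels, snp_ids, alleles, name=name, **meta)


def _write_tsv(data: GenotypeDataset, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("subject_id\tlabel\t" + "\t".join(data.snp_ids) + "\n")
        for i, sid in enumerate(data.subject_ids):
            label = "HT" if data.labels[i] else "NC"
            cells = []
            for a, b in data.alleles[i]:
                cells.append("./." if a == MISSING_ALLELE else f"{a}/{b}")
            fh.write(f"{sid}\t{label}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# SNP-gene annotation
# ---------------------------------------------------------------------------


@dataclass
class SnpAnnotation:
    """SNP-to-gene annotation table (local replacement for a SNPper query).

    ``table`` has columns snp_id, gene, chromosome, position; SNPs with an
    empty gene are flagged intergenic.  A SNP occurring twice with the same
    gene keeps the first row (deterministic primary annotation); with two
    different genes it is an annotation conflict.
    """

    table: pd.DataFrame
    by_snp: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy()
        t["gene"] = t["gene"].fillna("").astype(str)
        dup = t[t.duplicated("snp_id", keep=False)]
        for snp, grp in dup.groupby("snp_id"):
            if grp["gene"].nunique() > 1:
                raise AnnotationConflictError(
                    f"SNP {snp} maps to multiple genes: {sorted(grp['gene'].unique())}"
                )
        t = t.drop_duplicates("snp_id", keep="first")
        self.table = t.reset_index(drop=True)
        self.by_snp = self.table.set_index("snp_id")

    def gene_of(self, snp_id: str) -> str | None:
        """Primary gene symbol, or None for unknown / intergenic SNPs."""
        if snp_id not in self.by_snp.index:
            return None
        g = self.by_snp.loc[snp_id, "gene"]
        return g if g else None

    @property
    def intragenic_snps(self) -> set[str]:
        return set(self.table.loc[self.table["gene"] != "", "snp_id"])

    @property
    def intergenic_snps(self) -> set[str]:
        return set(self.table.loc[self.table["gene"] == "", "snp_id"])

    def snps_of_gene(self, gene: str) -> list[str]:
        return self.table.loc[self.table["gene"] == gene, "snp_id"].tolist()


def read_snp_gene_map(path: str | Path) -> SnpAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene": str,
                                            "chromosome": str})
    missing = {"snp_id", "gene", "chromosome", "position"} - set(df.columns)
    if missing:
        raise LoadError(f"{path}: annotation TSV missing columns {sorted(missing)}")
    return SnpAnnotation(df)


def write_snp_gene_map(ann: SnpAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def filter_intragenic(data: GenotypeDataset, ann: SnpAnnotation) -> GenotypeDataset:
    """Retain exactly the SNPs with a primary gene, preserving order."""
    keep = [s for s in data.snp_ids if ann.gene_of(s) is not None]
    if not keep:
        import warnings

        warnings.warn("filter_intragenic: no annotated SNPs retained", stacklevel=2)
    return data.subset_snps(keep)


# ---------------------------------------------------------------------------
# Minor-allele dose coding (implementation cache; allele pairs stay canonical)
# ---------------------------------------------------------------------------


@dataclass
class DoseCoding:
    """Per-SNP (minor, major) allele assignment pooled over training data.

    SNPs whose observed allele sets conflict across datasets are listed in
    ``conflicts`` and must be excluded from multi-dataset qualification.
    """

    minor: dict[str, str | None]
    major: dict[str, str | None]
    conflicts: set[str]


def pooled_dose_coding(datasets: Iterable[GenotypeDataset]) -> DoseCoding:
    pooled: dict[str, dict[str, int]] = {}
    seen_sets: dict[str, list[frozenset[str]]] = {}
    for ds in datasets:
        for snp, census in zip(ds.snp_ids, ds.allele_census()):
            acc = pooled.setdefault(snp, {})
            for a, c in census.items():
                acc[a] = acc.get(a, 0) + c
            if census:
                seen_sets.setdefault(snp, []).append(frozenset(census))
    conflicts: set[str] = set()
    for snp, sets in seen_sets.items():
        union = frozenset().union(*sets)
        if len(union) > 2:
            conflicts.add(snp)
    minor: dict[str, str | None] = {}
    major: dict[str, str | None] = {}
    for snp, acc in pooled.items():
        if not acc:
            minor[snp] = major[snp] = None
            continue
        # minor = least frequent pooled allele; tie broken alphabetically last
        order = sorted(acc.items(), key=lambda kv: (kv[1], [-ord(c) for c in kv[0]]))
        minor[snp] = order[0][0] if len(order) > 1 else None
        major[snp] = order[-1][0]
        if len(order) == 1:
            minor[snp] = None
    return DoseCoding(minor=minor, major=major, conflicts=conflicts)


def dose_matrix(data: GenotypeDataset, coding: DoseCoding) -> np.ndarray:
    """Minor-allele dose recode: int8 (n_subjects, n_snps), -1 = missing."""
    out = np.full((data.n_subjects, data.n_snps), -1, dtype=np.int8)
    for j, snp in enumerate(data.snp_ids):
        m = coding.minor.get(snp)
        col = data.alleles[:, j]
        present = col[:, 0] != MISSING_ALLELE
        if m is None:
            out[present, j] = 0
        else:
            out[present, j] = (col[present] == m).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Expression container + TSV
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """Raw replicate intensities and (after QC) a merged normalized matrix.

    ``replicates`` maps subject id -> array (n_replicates, n_genes) of raw
    intensities.  ``merged`` (filled by ``expression_select.merge_replicates``)
    is subjects x genes with 0 encoding a missing value.
    """

    subject_ids: list[str]
    gene_ids: list[str]
    replicates: dict[str, np.ndarray]
    merged: np.ndarray | None = None
    merged_subjects: list[str] | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def read_expression(path: str | Path) -> ExpressionDataset:
    """Read a genes x subject-replicate TSV (columns like ``S01_r1``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_ids = df.index.astype(str).tolist()
    groups: dict[str, dict[int, np.ndarray]] = {}
    for col in df.columns:
        m = re.match(r"^(.*)_r(\d)$", col)
        if m is None:
            raise LoadError(f"{path}: column {col!r} lacks a _rN replicate suffix")
        sid, rep = m.group(1), int(m.group(2))
        groups.setdefault(sid, {})[rep] = df[col].to_numpy(dtype=float)
    replicates = {
        sid: np.vstack([reps[k] for k in sorted(reps)]) for sid, reps in groups.items()
    }
    return ExpressionDataset(sorted(groups), gene_ids, replicates)


def write_expression(expr: ExpressionDataset, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {}
    for sid in expr.subject_ids:
        reps = expr.replicates[sid]
        for r in range(reps.shape[0]):
            cols[f"{sid}_r{r + 1}"] = reps[r]
    pd.DataFrame(cols, index=pd.Index(expr.gene_ids, name="gene")).to_csv(path, sep="\t")
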