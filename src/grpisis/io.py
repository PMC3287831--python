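"""Readers and writers for genotype, group-map, phenotype and report tables.

All tables are plain delimited text.  Genotype tables are sample-major: one
row per sample, one column per SNP, entries 0/1/2 or NA.  The group map is a
2-3 column table ``snp_id, gene_id[, nonsynonymous]``.  Phenotype tables
carry the three covariates (sex, age, smoking) followed by replicate columns
``Q.rep1 ... Q.repR``.  VCF ingestion (biallelic GT fields) is provided as a
convenience.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GroupedDesign
from .errors import AlignmentError, EmptyDesignError, InputError, ParseError

log = logging.getLogger(__name__)

_ALLOWED = {0.0, 1.0, 2.0}


@dataclass
class GenotypeTable:
    """Samples x SNPs dosage table; missing calls are NaN until imputation."""

    data: pd.DataFrame  # raw, float with NaN for missing

    def __post_init__(self):
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ParseError("sample or SNP identifiers are not unique")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def snp_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def imputed(self) -> pd.DataFrame:
        """Column-mean imputation of missing calls (for model fitting only)."""
        if self.n_missing == 0:
            return self.data.astype(float)
        filled = self.data.astype(float)
        means = filled.mean(axis=0, skipna=True).fillna(0.0)
        return filled.fillna(means)


@dataclass
class GroupMap:
    """SNP -> gene assignment, optionally with a nonsynonymous flag."""

    gene_of: dict[str, str]
    annotation: dict[str, bool] | None = None

    def __post_init__(self):
        for snp, gene in self.gene_of.items():
            if not gene:
                raise ParseError(f"SNP {snp!r} mapped to empty gene id")

    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.gene_of.values()))


@dataclass
class PhenotypeTable:
    """Covariates (sex, age, smoking) plus replicate phenotype columns."""

    covariates: pd.DataFrame
    replicates: pd.DataFrame

    def __post_init__(self):
        if not self.covariates.index.equals(self.replicates.index):
            raise AlignmentError("covariate and replicate sample ids differ")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.covariates.index]

    @property
    def replicate_ids(self) -> list[str]:
        return [str(c) for c in self.replicates.columns]


def _read_table(path, sep):
    try:
        if sep is None:
            return pd.read_csv(path, sep=None, engine="python", index_col=0)
        return pd.read_csv(path, sep=sep, index_col=0)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ParseError(f"could not read table {path}: {exc}") from exc


def read_genotype_table(path, sep=None) -> GenotypeTable:
    """Parse a sample-major 0/1/2/NA genotype table (TSV or CSV).

    Any entry outside {0, 1, 2, NA} raises :class:`ParseError` naming the
    sample and SNP.  Missing entries stay NaN in ``data``; imputation happens
    lazily via :meth:`GenotypeTable.imputed` with a warning here if any calls
    are missing.
    """
    df = _read_table(path, sep)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric genotype entry in {path}: {exc}") from exc
    values = df.to_numpy()
    bad = ~(np.isnan(values) | np.isin(values, list(_ALLOWED)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"invalid genotype {values[i, j]!r} at sample {df.index[i]!r}, "
            f"SNP {df.columns[j]!r}"
        )
    table = GenotypeTable(data=df)
    if table.n_missing:
        rate = table.n_missing / values.size
        warnings.warn(
            f"{table.n_missing} missing genotype calls "
            f"({100 * rate:.2f}%) will be mean-imputed for fitting",
            UserWarning,
            stacklevel=2,
        )
    return table


def write_genotype_table(table: GenotypeTable, path, sep="\t") -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    # keep integers as integers in the text representation
    out.to_csv(path, sep=sep, na_rep="NA", float_format="%g")


def read_vcf_genotypes(path) -> GenotypeTable:
    """Read biallelic GT genotypes from a VCF into 0/1/2 dosages.

    Multiallelic records are skipped with a warning; missing genotypes become
    NA.  Record ids fall back to ``chrom:pos`` when the ID column is empty.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"could not open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        name = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        gt = np.asarray(variant.gt_types, dtype=float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        columns[name] = gt
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic VCF records", UserWarning, stacklevel=2)
    df = pd.DataFrame(columns, index=samples)
    return GenotypeTable(data=df)


def read_group_map(path, sep="\t") -> GroupMap:
    """Parse a ``snp_id, gene_id[, nonsynonymous]`` table (with header)."""
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"could not read group map {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError("group map needs at least snp_id and gene_id columns")
    snp_col, gene_col = df.columns[0], df.columns[1]
    if df[snp_col].duplicated().any():
        dup = df[snp_col][df[snp_col].duplicated()].iloc[0]
        raise ParseError(f"SNP {dup!r} mapped more than once")
    gene_of = dict(zip(df[snp_col], df[gene_col]))
    annotation = None
    if df.shape[1] >= 3:
        flag_col = df.columns[2]
        annotation = {
            s: str(v).strip() in ("1", "True", "true")
            for s, v in zip(df[snp_col], df[flag_col])
        }
    return GroupMap(gene_of=gene_of, annotation=annotation)


def write_group_map(gmap: GroupMap, path, sep="\t") -> None:
    rows = []
    for snp, gene in gmap.gene_of.items():
        row = {"snp_id": snp, "gene_id": gene}
        if gmap.annotation is not None:
            row["nonsynonymous"] = int(gmap.annotation.get(snp, False))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_phenotype_table(path, sep="\t") -> PhenotypeTable:
    """Parse ``sample_id, sex, age, smoking, Q.rep1, ...`` into a table."""
    df = _read_table(path, sep)
    needed = ["sex", "age", "smoking"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ParseError(f"phenotype table lacks covariate columns {missing}")
    rep_cols = [c for c in df.columns if c not in needed]
    if not rep_cols:
        raise ParseError("phenotype table has no replicate columns")
    return PhenotypeTable(
        covariates=df[needed].astype(float),
        replicates=df[rep_cols].astype(float),
    )


def write_phenotype_table(phen: PhenotypeTable, path, sep="\t") -> None:
    out = pd.concat([phen.covariates, phen.replicates], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# assembly, MAF, filtering
# ---------------------------------------------------------------------------

def build_design(
    genotypes: GenotypeTable,
    gmap: GroupMap,
    covariates: pd.DataFrame | None = None,
) -> GroupedDesign:
    """Assemble a :class:`GroupedDesign` from parsed tables.

    SNPs missing from the map are dropped with a warning; sample id
    mismatches between genotypes and covariates raise
    :class:`AlignmentError` naming the first offender.  Missing genotypes are
    mean-imputed here.
    """
    mapped = [s for s in genotypes.snp_ids if s in gmap.gene_of]
    unmapped = [s for s in genotypes.snp_ids if s not in gmap.gene_of]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} SNPs absent from the group map were dropped",
            UserWarning,
            stacklevel=2,
        )
    if not mapped:
        raise EmptyDesignError("no genotype column appears in the group map")
    X = genotypes.imputed()[mapped]
    sample_ids = genotypes.sample_ids
    cov_names: list[str] = []
    if covariates is not None:
        for sid in covariates.index:
            if str(sid) not in set(sample_ids):
                raise AlignmentError(f"covariate sample {sid!r} not in genotype table")
        for sid in sample_ids:
            if sid not in {str(s) for s in covariates.index}:
                raise AlignmentError(f"genotype sample {sid!r} lacks covariates")
        covariates = covariates.loc[[s for s in sample_ids]]
        cov_names = [str(c) for c in covariates.columns]
    # genes ordered by first appearance among mapped SNPs; columns gene-major
    gene_order = list(dict.fromkeys(gmap.gene_of[s] for s in mapped))
    by_gene: dict[str, list[str]] = {g: [] for g in gene_order}
    for s in mapped:
        by_gene[gmap.gene_of[s]].append(s)
    snp_order = [s for g in gene_order for s in by_gene[g]]
    mat = X[snp_order].to_numpy(dtype=float)
    if cov_names:
        mat = np.column_stack([mat, covariates.to_numpy(dtype=float)])
    group_of = {j: gmap.gene_of[s] for j, s in enumerate(snp_order)}
    return GroupedDesign(
        matrix=mat,
        column_ids=snp_order + cov_names,
        sample_ids=sample_ids,
        group_of=group_of,
        group_ids=gene_order,
        covariate_columns=list(range(len(snp_order), len(snp_order) + len(cov_names))),
    )


def compute_maf(column) -> float:
    """Folded minor allele frequency of a 0/1/2 dosage vector.

    Missing (NaN) entries are excluded from the allele counts; fractional
    (imputed) entries are excluded too, since they are not observed calls.
    """
    x = np.asarray(column, dtype=float).ravel()
    x = x[~np.isnan(x)]
    x = x[np.isin(x, list(_ALLOWED))]
    if x.size == 0:
        raise InputError("no observed genotype calls in column")
    f = float(x.sum()) / (2.0 * x.size)
    return min(f, 1.0 - f)


def filter_snps(
    design: GroupedDesign,
    gmap: GroupMap,
    maf_threshold: float | None = None,
    require_annotation: bool = False,
) -> GroupedDesign:
    """Pre-filter SNP columns by MAF and/or annotation flag.

    Retains SNPs with folded MAF strictly below ``maf_threshold`` (when
    given) and, if ``require_annotation``, only SNPs flagged in the map.
    Genes left without SNPs are dropped.  Raises
    :class:`EmptyDesignError` when nothing survives.
    """
    if maf_threshold is not None and not 0.0 < maf_threshold <= 0.5:
        raise InputError("maf_threshold must lie in (0, 0.5]")
    if require_annotation and gmap.annotation is None:
        raise InputError("group map carries no annotation flags")
    keep: list[int] = []
    for j in design.snp_columns:
        if maf_threshold is not None:
            if compute_maf(design.matrix[:, j]) >= maf_threshold:
                continue
        if require_annotation:
            if not gmap.annotation.get(design.column_ids[j], False):
                continue
        keep.append(j)
    if not keep:
        raise EmptyDesignError("every SNP was removed by the filter")
    cols = keep + list(design.covariate_columns)
    group_of = {i: design.group_of[j] for i, j in enumerate(keep)}
    genes = list(dict.fromkeys(group_of.values()))
    out = GroupedDesign(
        matrix=design.matrix[:, cols],
        column_ids=[design.column_ids[j] for j in cols],
        sample_ids=list(design.sample_ids),
        group_of=group_of,
        group_ids=genes,
        covariate_columns=list(range(len(keep), len(cols))),
    )
    log.info(
        "filter retained %d/%d SNPs in %d/%d genes",
        len(keep), len(design.snp_columns), len(genes), design.n_groups,
    )
    return out


@dataclass
class DuplicateClass:
    """Columns identical as vectors; cross-gene duplicates are the hazard."""

    column_ids: list[str]
    genes: list[str]
    cross_gene: bool


def find_duplicate_snps(design: GroupedDesign) -> list[DuplicateClass]:
    """Equivalence classes of identical SNP columns.

    Classes spanning two or more genes are flagged ``cross_gene``: such
    aliases make gene attribution non-identifiable (only one of the genes can
    be credited by any selection method).
    """
    buckets: dict[bytes, list[int]] = {}
    for j in design.snp_columns:
        buckets.setdefault(design.matrix[:, j].tobytes(), []).append(j)
    out = []
    for cols in buckets.values():
        if len(cols) < 2:
            continue
        genes = list(dict.fromkeys(design.group_of[j] for j in cols))
        out.append(
            DuplicateClass(
                column_ids=[design.column_ids[j] for j in cols],
                genes=genes,
                cross_gene=len(genes) > 1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# selection reports
# ---------------------------------------------------------------------------

def write_selection_report(result, path, metadata: dict | None = None) -> None:
    """Tab-delimited gene/SNP selection report with a metadata header."""
    lines = ["# grpisis selection report"]
    if metadata:
        lines.append("# " + json.dumps(metadata, sort_keys=True, default=str))
    lines.append("gene_id\tsnp_ids\tcoefficients\titeration_added")
    for gene in result.selected_genes:
        snps = result.selected_snps.get(gene, [])
        coefs = result.coefficients.get(gene, [])
        lines.append(
            "\t".join([
                gene,
                ",".join(snps),
                ",".join(f"{c:.6g}" for c in coefs),
                str(result.iteration_added.get(gene, "")),
            ])
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_selection_report(path) -> tuple[dict[str, list[str]], dict | None]:
    """Recover the gene -> SNP mapping (and metadata) from a report file."""
    genes: dict[str, list[str]] = {}
    metadata = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = []
    for ln in lines:
        if ln.startswith("# {"):
            metadata = json.loads(ln[2:])
        elif not ln.startswith("#") and ln:
            body.append(ln)
    if not body:
        raise ParseError(f"report {path} has no header row")
    header = body[0].split("\t")
    if header[0] != "gene_id":
        raise ParseError(f"unexpected report header in {path}")
    for ln in body[1:]:
        fields = ln.split("\t")
        genes[fields[0]] = [s for s in fields[1].split(",") if s]
    return genes, metadata
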