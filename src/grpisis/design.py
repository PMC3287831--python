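"""Grouped design matrices for gene-based SNP selection.

A :class:`GroupedDesign` holds an ``n x p`` predictor matrix in which most
columns are SNP genotype dosages (0/1/2, possibly fractional after
mean-imputation of missing calls) partitioned into genes, plus a small set of
ungrouped, forced-in covariate columns (sex, age, smoking).  The grouped
linear model behind everything in this package is

    y = X_1 beta_1 + ... + X_J beta_J + Z gamma + eps,

with bilevel sparsity: few genes carry nonzero coefficient blocks, and each
nonzero block is itself sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class Response:
    """A quantitative phenotype vector (possibly a replicate average)."""

    values: np.ndarray
    label: str = "y"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise InputError("response must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise InputError("response contains non-finite values")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class GroupedDesign:
    """Predictor matrix with a SNP -> gene partition and forced-in covariates.

    Parameters
    ----------
    matrix
        ``n x p`` float matrix; SNP columns hold dosages in ``[0, 2]``.
    column_ids
        ``p`` unique column labels (SNP ids, then covariate names).
    sample_ids
        ``n`` unique sample labels.
    group_of
        Mapping from SNP column index to gene identifier.  Every column not
        listed in ``covariate_columns`` must appear exactly once.
    group_ids
        Ordered gene identifiers; fixes tie-breaking order everywhere.
    covariate_columns
        Indices of the ungrouped, always-included covariate columns.
    """

    matrix: np.ndarray
    column_ids: list[str]
    sample_ids: list[str]
    group_of: dict[int, str]
    group_ids: list[str]
    covariate_columns: list[int]
    groups: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise InputError("design matrix must be 2-dimensional")
        n, p = self.matrix.shape
        if n < 1:
            raise InputError("design needs at least one sample")
        if len(self.column_ids) != p:
            raise InputError(f"{len(self.column_ids)} column ids for {p} columns")
        if len(set(self.column_ids)) != p:
            raise InputError("column ids are not unique")
        if len(self.sample_ids) != n:
            raise InputError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(set(self.sample_ids)) != n:
            raise InputError("sample ids are not unique")
        cov = set(self.covariate_columns)
        snp_cols = [j for j in range(p) if j not in cov]
        if set(self.group_of) != set(snp_cols):
            raise InputError("group_of must map every non-covariate column")
        if not self.group_ids:
            raise InputError("at least one group is required")
        known = set(self.group_ids)
        if len(known) != len(self.group_ids):
            raise InputError("group ids are not unique")
        for j, g in self.group_of.items():
            if g not in known:
                raise InputError(f"column {j} mapped to unknown group {g!r}")
        if not np.all(np.isfinite(self.matrix)):
            raise InputError("design matrix contains non-finite values")
        # dosage range {0,1,2} is enforced by the genotype readers; the design
        # itself accepts any finite reals so imputed / rescaled columns work
        self.groups = {g: [] for g in self.group_ids}
        for j in sorted(self.group_of):
            self.groups[self.group_of[j]].append(j)
        for g, cols in self.groups.items():
            if not cols:
                raise InputError(f"group {g!r} has no columns")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    @property
    def snp_columns(self) -> list[int]:
        cov = set(self.covariate_columns)
        return [j for j in range(self.p) if j not in cov]

    def group_size(self, gene: str) -> int:
        return len(self.groups[gene])

    def column_index(self, column_id: str) -> int:
        try:
            return self.column_ids.index(column_id)
        except ValueError:
            raise InputError(f"unknown column id {column_id!r}") from None

    # -- restriction ----------------------------------------------------
    def subset_groups(self, genes: list[str]) -> "GroupedDesign":
        """Design restricted to the given genes (covariates are kept).

        Gene order follows the ``genes`` argument; columns within a gene keep
        their original order, covariates come last.
        """
        known = set(self.group_ids)
        genes = list(dict.fromkeys(genes))
        for g in genes:
            if g not in known:
                raise InputError(f"unknown group {g!r}")
        if not genes:
            raise InputError("subset_groups needs at least one gene")
        cols: list[int] = []
        group_of: dict[int, str] = {}
        for g in genes:
            for j in self.groups[g]:
                group_of[len(cols)] = g
                cols.append(j)
        cov_start = len(cols)
        cols.extend(self.covariate_columns)
        return GroupedDesign(
            matrix=self.matrix[:, cols],
            column_ids=[self.column_ids[j] for j in cols],
            sample_ids=list(self.sample_ids),
            group_of=group_of,
            group_ids=genes,
            covariate_columns=list(range(cov_start, len(cols))),
        )
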