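"""Least-squares core: subset OLS, forward stepwise selection, RSS/df.

Everything the screening procedures do reduces to ordinary least squares on a
column subset with an always-estimated intercept, scored by the residual mean
square RSS/df with df = n - (number of estimated coefficients, intercept
included).  Rank-deficient subsets (frequent with singleton-heavy genotype
blocks) are fit by the minimum-norm solution and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import GroupedDesign, Response
from .errors import CollinearityWarning, DegenerateFitError, InputError

#: Relative RSS-reduction below which forward stepwise stops adding columns.
STEPWISE_RTOL = 1e-10


@dataclass
class OLSFit:
    """A least-squares fit on a column subset (intercept always included)."""

    support: list[int]
    coefficients: np.ndarray  # [intercept, coef for support[0], ...]
    rss: float
    residual_df: int
    rank_deficient: bool = False
    selected: list[int] = field(default_factory=list)  # stepwise additions only

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def score(self) -> float:
        """Residual mean square RSS/df; the screening score (smaller wins)."""
        if self.residual_df < 1:
            raise DegenerateFitError("fit has no residual degrees of freedom")
        return self.rss / self.residual_df


def _check_columns(design: GroupedDesign, columns) -> list[int]:
    cols = [int(c) for c in columns]
    if len(set(cols)) != len(cols):
        raise InputError("duplicate column indices in subset")
    for c in cols:
        if not 0 <= c < design.p:
            raise InputError(f"column index {c} outside design with p={design.p}")
    return cols


def fit_ols(design: GroupedDesign, columns, response: Response) -> OLSFit:
    """OLS of the response on the given design columns plus an intercept.

    The residual degrees of freedom follow the convention
    ``df = n - (len(columns) + 1)``; a subset leaving ``df < 1`` raises
    :class:`DegenerateFitError`.  Rank-deficient subsets are solved in the
    minimum-norm sense and flagged with a :class:`CollinearityWarning`.
    """
    cols = _check_columns(design, columns)
    y = response.values
    n = design.n
    if len(y) != n:
        raise InputError(f"response length {len(y)} != design n {n}")
    residual_df = n - (len(cols) + 1)
    if residual_df < 1:
        raise DegenerateFitError(
            f"{len(cols)} columns + intercept leave df={residual_df} < 1 at n={n}"
        )
    A = np.column_stack([np.ones(n)] + ([design.matrix[:, cols]] if cols else []))
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rss = float(resid @ resid)
    rank_def = rank < A.shape[1]
    if rank_def:
        warnings.warn(
            "rank-deficient OLS subset; minimum-norm solution used",
            CollinearityWarning,
            stacklevel=2,
        )
    return OLSFit(
        support=cols,
        coefficients=coef,
        rss=max(rss, 0.0),
        residual_df=residual_df,
        rank_deficient=rank_def,
    )


def _orthonormal_basis(A: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of A (rank-filtered SVD)."""
    if A.shape[1] == 0:
        return np.empty((A.shape[0], 0))
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    if s.size == 0 or s[0] <= 0:
        return np.empty((A.shape[0], 0))
    r = int(np.sum(s > tol * s[0]))
    return U[:, :r]


def forward_stepwise(
    design: GroupedDesign,
    candidates,
    forced,
    response: Response,
    max_new: int,
    rtol: float = STEPWISE_RTOL,
) -> OLSFit:
    """Greedy forward selection starting from the forced set plus intercept.

    At each step the candidate column giving the largest RSS reduction is
    added (ties broken by the smaller column index), until ``max_new`` columns
    have been added or the best relative reduction drops below ``rtol``.
    Columns that are numerically collinear with the current model are never
    added.  The returned fit is refit by :func:`fit_ols` on the final support
    (forced columns first, then additions in selection order).
    """
    forced = _check_columns(design, forced)
    cand = sorted(_check_columns(design, candidates))
    if set(forced) & set(cand):
        raise InputError("forced and candidate sets overlap")
    if max_new < 0:
        raise InputError("max_new must be nonnegative")
    y = response.values
    if len(y) != design.n:
        raise InputError("response length does not match design")
    n = design.n
    if len(forced) + max_new + 1 >= n:
        max_new = max(0, n - len(forced) - 2)

    X = design.matrix
    base = np.column_stack([np.ones(n)] + ([X[:, forced]] if forced else []))
    Q = _orthonormal_basis(base)
    r = y - Q @ (Q.T @ y)
    rss = float(r @ r)

    if cand and max_new > 0:
        Z = X[:, cand] - Q @ (Q.T @ X[:, cand])
        orig_norm2 = np.maximum((X[:, cand] ** 2).sum(axis=0), 1.0)
        norm2 = (Z**2).sum(axis=0)
    selected: list[int] = []
    for _ in range(max_new):
        if not cand or rss <= 0.0:
            break
        usable = norm2 > 1e-10 * orig_norm2
        if not usable.any():
            break
        proj = Z.T @ r
        with np.errstate(divide="ignore", invalid="ignore"):
            gains = np.where(usable, proj**2 / np.where(norm2 > 0, norm2, 1.0), -np.inf)
        j = int(np.argmax(gains))  # first max -> smallest column index
        gain = gains[j]
        if not np.isfinite(gain) or gain <= rtol * rss:
            break
        q = Z[:, j] / np.sqrt(norm2[j])
        selected.append(cand[j])
        r = r - q * (q @ r)
        rss = float(r @ r)
        qz = q @ Z
        Z = Z - np.outer(q, qz)
        norm2 = np.maximum(norm2 - qz**2, 0.0)
        norm2[j] = 0.0

    fit = fit_ols(design, forced + selected, response)
    fit.selected = selected
    return fit


def rss_per_df(fit: OLSFit) -> float:
    """RSS divided by residual degrees of freedom (the screening score)."""
    return fit.score
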