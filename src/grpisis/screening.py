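"""Group SIS marginal ranking and the two iterative (ISIS) procedures.

Group SIS ranks genes by the residual mean square (RSS/df) of a per-gene
regression that always includes the forced-in covariates.  Genes larger than
the per-group cap ``C`` contribute their best ``C`` SNPs by forward stepwise
selection, so no marginal model exceeds ``C + #covariates`` predictors.

Procedure 1 is the grouped analogue of forward stepwise selection: one gene
is added per iteration, chosen by re-running stepwise selection over the SNPs
of the already-selected genes plus each candidate gene (whole-model cap
``C*k + #covariates`` at iteration k), for exactly ``K`` iterations.

Procedure 2 adds ``k0`` genes per iteration by conditional ranking (cap ``C``
per candidate gene beyond the retained model) and immediately runs a
group-penalized fit (group LASSO or group MCP, lambda chosen by AIC or BIC)
on all SNPs of the retained + new genes; genes whose coefficient block is
entirely zero are deleted.  The loop stops when every newly added gene is
deleted in the same iteration ("stable") or after ``max_iter2`` iterations.
Covariates are never penalized and never deletable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import GroupedDesign, Response
from .errors import ConvergenceError, DegenerateFitError, InputError
from .penalized import PenaltySpec, select_by_information_criterion, solve_path
from .regression import OLSFit, _orthonormal_basis, fit_ols, forward_stepwise


@dataclass
class ScreeningConfig:
    """Constants of the screening procedures (defaults as used throughout)."""

    K: int = 12            # procedure-1 iterations (one gene each)
    C: int = 5             # per-gene SNP cap in screening fits
    k0: int = 5            # genes added per procedure-2 iteration
    max_iter2: int = 10    # procedure-2 iteration cap
    deletion_method: str = "group-mcp"
    criterion: str = "BIC"
    gamma: float = 3.0     # MCP concavity for the deletion step

    def __post_init__(self):
        for name in ("K", "C", "k0", "max_iter2"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be at least 1")
        if self.deletion_method not in ("group-lasso", "group-mcp"):
            raise InputError("deletion_method must be 'group-lasso' or 'group-mcp'")
        if self.criterion.upper() not in ("AIC", "BIC"):
            raise InputError("criterion must be 'AIC' or 'BIC'")


@dataclass
class ScreeningResult:
    """Genes ranked by ascending RSS/df with their marginal SNP supports."""

    ranked_groups: list[tuple[str, float]]
    per_group_support: dict[str, list[int]]
    degenerate: set[str] = field(default_factory=set)

    def top(self, k: int) -> list[str]:
        return [g for g, _ in self.ranked_groups[:k]]


@dataclass
class SelectionResult:
    """Final gene/SNP selection with its per-iteration trace."""

    selected_genes: list[str]
    selected_snps: dict[str, list[str]]
    coefficients: dict[str, list[float]]
    iteration_trace: list[dict]
    stopped_reason: str
    iteration_added: dict[str, int] = field(default_factory=dict)


def _marginal_fit(design: GroupedDesign, response: Response, gene: str, C: int) -> OLSFit:
    cols = design.groups[gene]
    cov = design.covariate_columns
    if len(cols) <= C:
        return fit_ols(design, cov + cols, response)
    return forward_stepwise(design, candidates=cols, forced=cov, response=response, max_new=C)


def rank_groups_marginal(
    design: GroupedDesign, response: Response, config: ScreeningConfig
) -> ScreeningResult:
    """Rank every gene by the RSS/df of its marginal (covariate-adjusted) fit.

    Genes whose fit is degenerate (no residual degrees of freedom) are ranked
    last and flagged.  Ties break toward the gene listed earlier in
    ``design.group_ids``.
    """
    cov = set(design.covariate_columns)
    scores: list[tuple[float, int, str]] = []
    support: dict[str, list[int]] = {}
    degenerate: set[str] = set()
    for idx, gene in enumerate(design.group_ids):
        try:
            fit = _marginal_fit(design, response, gene, config.C)
            score = fit.score
            support[gene] = [j for j in fit.support if j not in cov]
        except DegenerateFitError:
            score = np.inf
            support[gene] = []
            degenerate.add(gene)
        scores.append((score, idx, gene))
    scores.sort(key=lambda t: (t[0], t[1]))
    return ScreeningResult(
        ranked_groups=[(g, s) for s, _, g in scores],
        per_group_support=support,
        degenerate=degenerate,
    )


def group_sis(
    design: GroupedDesign, response: Response, k: int, config: ScreeningConfig | None = None
) -> list[str]:
    """The ``k`` genes with the smallest marginal RSS/df."""
    config = config or ScreeningConfig()
    if not 1 <= k <= design.n_groups:
        raise InputError(f"k must be in [1, {design.n_groups}]")
    return rank_groups_marginal(design, response, config).top(k)


def _fit_to_selection(
    design: GroupedDesign,
    fit: OLSFit,
    genes: list[str],
    trace: list[dict],
    reason: str,
    iteration_added: dict[str, int],
) -> SelectionResult:
    cov = set(design.covariate_columns)
    snps: dict[str, list[str]] = {g: [] for g in genes}
    coefs: dict[str, list[float]] = {g: [] for g in genes}
    for pos, col in enumerate(fit.support):
        if col in cov:
            continue
        gene = design.group_of[col]
        if gene in snps:
            snps[gene].append(design.column_ids[col])
            coefs[gene].append(float(fit.coefficients[pos + 1]))
    return SelectionResult(
        selected_genes=list(genes),
        selected_snps=snps,
        coefficients=coefs,
        iteration_trace=trace,
        stopped_reason=reason,
        iteration_added=dict(iteration_added),
    )


def group_isis_procedure1(
    design: GroupedDesign, response: Response, config: ScreeningConfig | None = None
) -> SelectionResult:
    """One-gene-per-iteration group ISIS (grouped forward selection).

    Iteration 1 takes the best marginally ranked gene; iteration k re-runs
    forward stepwise selection over the SNP union of the selected genes plus
    each candidate gene (covariates forced in, at most ``C*k`` SNPs) and adds
    the candidate with the smallest RSS/df.  Exactly ``min(K, J)`` genes are
    selected.
    """
    config = config or ScreeningConfig()
    cov = design.covariate_columns
    K = min(config.K, design.n_groups)
    trace: list[dict] = []
    iteration_added: dict[str, int] = {}

    marginal = rank_groups_marginal(design, response, config)
    first = marginal.ranked_groups[0][0]
    selected = [first]
    iteration_added[first] = 1
    union = list(design.groups[first])
    best_fit = _marginal_fit(design, response, first, config.C)
    trace.append({"iteration": 1, "added": [first], "score": best_fit.score})

    for k in range(2, K + 1):
        chosen = None
        chosen_fit = None
        chosen_score = np.inf
        for gene in design.group_ids:
            if gene in iteration_added:
                continue
            cand_cols = union + design.groups[gene]
            try:
                fit = forward_stepwise(
                    design,
                    candidates=cand_cols,
                    forced=cov,
                    response=response,
                    max_new=config.C * k,
                )
                score = fit.score
            except DegenerateFitError:
                continue
            if score < chosen_score:
                chosen, chosen_fit, chosen_score = gene, fit, score
        if chosen is None:
            return _fit_to_selection(
                design, best_fit, selected, trace, "stable", iteration_added
            )
        selected.append(chosen)
        iteration_added[chosen] = k
        union = union + design.groups[chosen]
        best_fit = chosen_fit
        trace.append({"iteration": k, "added": [chosen], "score": chosen_score})

    reason = "max-iterations" if K == config.K else "stable"
    return _fit_to_selection(design, best_fit, selected, trace, reason, iteration_added)


def _conditional_group_scores(
    design: GroupedDesign,
    response: Response,
    forced_cols: list[int],
    genes: list[str],
    C: int,
) -> dict[str, float]:
    """RSS/df of each candidate gene conditional on a forced column set.

    A gene with at most ``C`` SNPs enters with all of them; larger genes
    contribute up to ``C`` SNPs chosen greedily.  All fits share the
    orthonormal basis of [intercept, forced columns], so the whole candidate
    sweep costs one basis construction.
    """
    X = design.matrix
    y = response.values
    n = design.n
    base = np.column_stack([np.ones(n)] + ([X[:, forced_cols]] if forced_cols else []))
    Q = _orthonormal_basis(base)
    r0 = y - Q @ (Q.T @ y)
    rss0 = float(r0 @ r0)
    m = 1 + len(forced_cols)
    out: dict[str, float] = {}
    for gene in genes:
        cols = design.groups[gene]
        Z = X[:, cols] - Q @ (Q.T @ X[:, cols])
        if len(cols) <= C:
            b, *_ = np.linalg.lstsq(Z, r0, rcond=None)
            res = r0 - Z @ b
            rss = float(res @ res)
            used = len(cols)
        else:
            rss, used = _greedy_rss(Z, r0, rss0, C)
        df = n - (m + used)
        out[gene] = rss / df if df >= 1 else np.inf
    return out


def _greedy_rss(Z: np.ndarray, r: np.ndarray, rss: float, steps: int) -> tuple[float, int]:
    Z = Z.copy()
    r = r.copy()
    orig = np.maximum((Z**2).sum(axis=0), 1.0)
    norm2 = (Z**2).sum(axis=0)
    used = 0
    for _ in range(steps):
        usable = norm2 > 1e-10 * orig
        if not usable.any() or rss <= 0.0:
            break
        proj = Z.T @ r
        gains = np.where(usable, proj**2 / np.where(norm2 > 0, norm2, 1.0), -np.inf)
        j = int(np.argmax(gains))
        if not np.isfinite(gains[j]) or gains[j] <= 1e-10 * rss:
            break
        q = Z[:, j] / np.sqrt(norm2[j])
        r = r - q * (q @ r)
        rss = float(r @ r)
        qz = q @ Z
        Z -= np.outer(q, qz)
        norm2 = np.maximum(norm2 - qz**2, 0.0)
        norm2[j] = 0.0
        used += 1
    return rss, used


def group_isis_procedure2(
    design: GroupedDesign, response: Response, config: ScreeningConfig | None = None
) -> SelectionResult:
    """Multi-gene group ISIS with a penalized deletion step.

    Each iteration adds the ``k0`` best conditionally ranked genes, refits a
    group-penalized path (``deletion_method``) on all SNPs of the retained +
    new genes with covariates unpenalized, picks lambda by ``criterion`` and
    deletes every gene whose block is zero there.  Stops when all newly added
    genes are deleted ("stable") or after ``max_iter2`` iterations.
    """
    config = config or ScreeningConfig()
    spec = PenaltySpec(penalty=config.deletion_method, gamma=config.gamma)
    cov = design.covariate_columns
    id_to_col = {cid: j for j, cid in enumerate(design.column_ids)}

    retained: list[str] = []
    support_cols: list[int] = []
    trace: list[dict] = []
    iteration_added: dict[str, int] = {}
    last_point = None
    last_sub = None
    reason = "max-iterations"

    for it in range(1, config.max_iter2 + 1):
        in_model = set(retained)
        remaining = [g for g in design.group_ids if g not in in_model]
        if not remaining:
            reason = "stable"
            break
        scores = _conditional_group_scores(
            design, response, cov + support_cols, remaining, config.C
        )
        order = {g: i for i, g in enumerate(design.group_ids)}
        ranked = sorted(remaining, key=lambda g: (scores[g], order[g]))
        new = ranked[: config.k0]

        cand = retained + new
        sub = design.subset_groups(cand)
        try:
            path = solve_path(sub, response, spec)
        except DegenerateFitError:
            # nothing left to fit: response fully explained; stop as stable
            reason = "stable"
            trace.append({"iteration": it, "added": new, "deleted": new,
                          "n_selected": len(retained), "rss": 0.0,
                          "criterion_value": -np.inf})
            break
        if not path.converged:
            raise ConvergenceError(
                f"penalized deletion step did not converge at iteration {it}",
                trace=trace,
            )
        point = select_by_information_criterion(path, config.criterion, design.n)
        active = set(point.active_groups)
        deleted = [g for g in cand if g not in active]
        retained = [g for g in cand if g in active]
        for g in new:
            if g in active and g not in iteration_added:
                iteration_added[g] = it
        for g in deleted:
            iteration_added.pop(g, None)
        cov_ids = {design.column_ids[c] for c in cov}
        support_cols = [
            id_to_col[cid]
            for cid, coef in zip(sub.column_ids, point.coefficients)
            if coef != 0.0 and cid not in cov_ids
        ]
        crit_val = point.aic if config.criterion.upper() == "AIC" else point.bic
        trace.append({
            "iteration": it,
            "added": new,
            "deleted": deleted,
            "n_selected": len(retained),
            "rss": point.rss,
            "criterion_value": float(crit_val),
        })
        last_point, last_sub = point, sub
        if all(g in deleted for g in new):
            reason = "stable"
            break

    snps: dict[str, list[str]] = {g: [] for g in retained}
    coefs: dict[str, list[float]] = {g: [] for g in retained}
    if last_point is not None and last_sub is not None:
        cov_ids = {design.column_ids[c] for c in cov}
        for cid, coef in zip(last_sub.column_ids, last_point.coefficients):
            if coef == 0.0 or cid in cov_ids:
                continue
            gene = last_sub.group_of[last_sub.column_index(cid)]
            if gene in snps:
                snps[gene].append(cid)
                coefs[gene].append(float(coef))
    return SelectionResult(
        selected_genes=retained,
        selected_snps=snps,
        coefficients=coefs,
        iteration_trace=trace,
        stopped_reason=reason,
        iteration_added=iteration_added,
    )
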