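"""Synthetic mini-exome cohort generator.

Emulates the structure of a GAW17-style exome panel: ~700 unrelated samples,
genes of heterogeneous size (heavy-tailed, mean ~7.6 SNPs), a rare-variant
MAF spectrum with a large singleton mass (38.5% of SNPs have exactly one
heterozygous carrier), three forced-in covariates (sex, age, smoking), a
bilevel-sparse genetic architecture (few causal genes, 1-4 causal SNPs
each), and R independent phenotype replicates sharing the genetic/covariate
signal but with fresh Gaussian noise.  Averaging replicates lowers the noise
level: all replicates = low noise, blocks of 10 = medium, a single
replicate = high.

Genotypes are drawn under Hardy-Weinberg equilibrium (Binomial(2, q)); no
linkage disequilibrium is simulated.  An optional duplicate-column injector
reproduces the cross-gene aliasing hazard seen in real exome panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GroupedDesign, Response
from .errors import InputError
from .io import GenotypeTable, GroupMap, PhenotypeTable, build_design


@dataclass
class SimulationConfig:
    """Cohort, architecture and noise settings (defaults = study conditions).

    The default cohort echoes the printed GAW17 counts at reduced scale:
    n = 700 samples, 500 genes with geometric sizes of mean 7.6 clipped to
    [1, 40] (24,487/3,205 ~ 7.6 SNPs per gene), singleton fraction 0.385
    (9,433/24,487), remaining MAFs log-uniform on [1/(2n), 0.45].  Ten causal
    genes carry 1-4 causal SNPs each with per-dosage effects of 0.4-1.0;
    causal SNPs are drawn preferentially among variants with MAF >= 0.01 so
    that each causal gene has at least a handful of carriers.  Covariate
    effects and a per-replicate noise standard deviation of 1 complete the
    generating model.
    """

    n: int = 700
    n_genes: int = 500
    gene_size_mean: float = 7.6
    gene_size_max: int = 40
    singleton_fraction: float = 0.385
    maf_min: float | None = None  # default 1/(2n)
    maf_max: float = 0.45
    nonsyn_fraction: float = 0.55
    n_causal_genes: int = 10
    causal_snps_min: int = 1
    causal_snps_max: int = 4
    causal_maf_floor: float = 0.01
    beta_min: float = 0.4
    beta_max: float = 1.0
    sex_effect: float = 0.5
    age_effect: float = 0.01
    smoking_effect: float = 0.4
    noise_sd: float = 1.0
    n_replicates: int = 200
    n_duplicate_pairs: int = 0  # cross-gene duplicate-column injector
    seed: int = 0

    def __post_init__(self):
        for name in ("n", "n_genes", "n_replicates", "causal_snps_min", "causal_snps_max"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be at least 1")
        if self.n_causal_genes < 0 or self.n_causal_genes > self.n_genes:
            raise InputError("n_causal_genes must lie in [0, n_genes]")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise InputError("singleton_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")


@dataclass
class SimulationTruth:
    """The generating architecture, for scoring selections."""

    causal_genes: list[str]
    causal_snps: dict[str, dict[str, float]]  # gene -> {snp_id: beta}
    covariate_coefficients: dict[str, float]
    noise_sd: float

    def __post_init__(self):
        extra = set(self.causal_snps) - set(self.causal_genes)
        if extra:
            raise InputError(f"causal SNPs listed for non-causal genes {sorted(extra)}")


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, GroupMap]:
    """Draw the genotype panel and its gene partition.

    Gene sizes are geometric (mean ``gene_size_mean``) clipped to
    ``[1, gene_size_max]``.  Each SNP is a singleton with probability
    ``singleton_fraction`` (exactly one heterozygote, a random carrier);
    otherwise its MAF is log-uniform and genotypes are Binomial(2, q).
    Monomorphic draws are converted to singletons so every SNP is
    polymorphic.  Optionally, ``n_duplicate_pairs`` SNPs are overwritten
    with exact copies of SNPs from other genes.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, J = config.n, config.n_genes
    sizes = np.clip(
        rng.geometric(1.0 / config.gene_size_mean, size=J), 1, config.gene_size_max
    )
    width = len(str(J))
    gene_ids = [f"GENE{j + 1:0{width}d}" for j in range(J)]
    maf_lo = config.maf_min if config.maf_min is not None else 1.0 / (2 * n)
    snp_ids: list[str] = []
    gene_of: dict[str, str] = {}
    columns = []
    for g, size in zip(gene_ids, sizes):
        for k in range(size):
            sid = f"{g}.S{k + 1}"
            snp_ids.append(sid)
            gene_of[sid] = g
            if rng.random() < config.singleton_fraction:
                col = np.zeros(n)
                col[rng.integers(n)] = 1.0
            else:
                q = np.exp(rng.uniform(np.log(maf_lo), np.log(config.maf_max)))
                col = rng.binomial(2, q, size=n).astype(float)
                if col.sum() == 0:  # keep every SNP polymorphic
                    col[rng.integers(n)] = 1.0
            columns.append(col)
    if config.n_duplicate_pairs:
        p = len(snp_ids)
        for _ in range(config.n_duplicate_pairs):
            a, b = rng.choice(p, size=2, replace=False)
            if gene_of[snp_ids[a]] != gene_of[snp_ids[b]]:
                columns[b] = columns[a].copy()
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    data = pd.DataFrame(np.column_stack(columns), index=sample_ids, columns=snp_ids)
    annotation = {s: bool(rng.random() < config.nonsyn_fraction) for s in snp_ids}
    return GenotypeTable(data=data), GroupMap(gene_of=gene_of, annotation=annotation)


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Sex (0/1), age (years, 20-80) and smoking (0/1) per sample."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n
    return pd.DataFrame(
        {
            "sex": rng.integers(0, 2, size=n).astype(float),
            "age": rng.integers(20, 81, size=n).astype(float),
            "smoking": (rng.random(n) < 0.3).astype(float),
        },
        index=[f"S{i + 1:04d}" for i in range(n)],
    )


def simulate_truth(
    genotypes: GenotypeTable,
    gmap: GroupMap,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Pick causal genes/SNPs and draw effect sizes.

    Causal genes are sampled among genes carrying at least one SNP with
    folded MAF >= ``causal_maf_floor`` (so the signal is not purely
    singleton-borne); within each, 1-4 causal SNPs are drawn, preferring
    SNPs above the floor.  Effects are positive, uniform on
    [beta_min, beta_max].  Causal SNPs are flagged nonsynonymous in the map.
    """
    rng = rng or np.random.default_rng(config.seed)
    X = genotypes.data
    n_obs = X.shape[0]
    maf = X.sum(axis=0).to_numpy() / (2.0 * n_obs)
    maf = np.minimum(maf, 1.0 - maf)
    maf_of = dict(zip(genotypes.snp_ids, maf))
    by_gene: dict[str, list[str]] = {}
    for s in genotypes.snp_ids:
        by_gene.setdefault(gmap.gene_of[s], []).append(s)
    genes = list(by_gene)
    eligible = [g for g in genes if any(maf_of[s] >= config.causal_maf_floor for s in by_gene[g])]
    pool = eligible if len(eligible) >= config.n_causal_genes else genes
    causal_genes = sorted(
        rng.choice(pool, size=config.n_causal_genes, replace=False).tolist()
    ) if config.n_causal_genes else []
    causal_snps: dict[str, dict[str, float]] = {}
    for g in causal_genes:
        snps = by_gene[g]
        m = int(rng.integers(config.causal_snps_min, config.causal_snps_max + 1))
        m = min(m, len(snps))
        good = [s for s in snps if maf_of[s] >= config.causal_maf_floor]
        rest = [s for s in snps if s not in good]
        chosen = list(rng.choice(good, size=min(m, len(good)), replace=False))
        if len(chosen) < m:
            chosen += list(rng.choice(rest, size=m - len(chosen), replace=False))
        betas = rng.uniform(config.beta_min, config.beta_max, size=len(chosen))
        causal_snps[g] = {s: float(b) for s, b in zip(chosen, betas)}
        if gmap.annotation is not None:
            for s in chosen:
                gmap.annotation[s] = True
    return SimulationTruth(
        causal_genes=causal_genes,
        causal_snps=causal_snps,
        covariate_coefficients={
            "sex": config.sex_effect,
            "age": config.age_effect,
            "smoking": config.smoking_effect,
        },
        noise_sd=config.noise_sd,
    )


def simulate_replicates(
    genotypes: GenotypeTable,
    covariates: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PhenotypeTable:
    """Replicate phenotypes: fixed genetic + covariate signal, fresh noise."""
    rng = rng or np.random.default_rng(config.seed)
    X = genotypes.data
    n = X.shape[0]
    signal = np.zeros(n)
    for snp_betas in truth.causal_snps.values():
        for snp, beta in snp_betas.items():
            if snp not in X.columns:
                raise InputError(f"truth references unknown SNP {snp!r}")
            signal += beta * X[snp].to_numpy()
    for name, gamma in truth.covariate_coefficients.items():
        signal += gamma * covariates[name].to_numpy()
    noise = rng.normal(0.0, truth.noise_sd, size=(n, config.n_replicates))
    reps = signal[:, None] + noise
    rep_ids = [f"Q.rep{r + 1}" for r in range(config.n_replicates)]
    return PhenotypeTable(
        covariates=covariates,
        replicates=pd.DataFrame(reps, index=X.index, columns=rep_ids),
    )


def average_replicates(phenotypes: PhenotypeTable, replicate_ids) -> Response:
    """Samplewise mean of the chosen replicates (the noise-level dial)."""
    ids = list(replicate_ids)
    if not ids:
        raise InputError("replicate_ids must be non-empty")
    known = set(phenotypes.replicate_ids)
    for rid in ids:
        if rid not in known:
            raise InputError(f"unknown replicate id {rid!r}")
    values = phenotypes.replicates[ids].mean(axis=1).to_numpy()
    label = ids[0] if len(ids) == 1 else f"mean({len(ids)} replicates)"
    return Response(values=values, label=label)


def noise_level_responses(phenotypes: PhenotypeTable, level: str) -> list[Response]:
    """Preset responses: 'low' = mean of all replicates, 'medium' = means of
    consecutive blocks of 10, 'high' = each single replicate."""
    ids = phenotypes.replicate_ids
    if level == "low":
        return [average_replicates(phenotypes, ids)]
    if level == "medium":
        if len(ids) < 10:
            raise InputError("medium noise level needs at least 10 replicates")
        return [
            average_replicates(phenotypes, ids[i : i + 10])
            for i in range(0, len(ids) - len(ids) % 10, 10)
        ]
    if level == "high":
        return [average_replicates(phenotypes, [rid]) for rid in ids]
    raise InputError("noise level must be 'low', 'medium' or 'high'")


@dataclass
class SimulatedDataset:
    design: GroupedDesign
    genotypes: GenotypeTable
    group_map: GroupMap
    phenotypes: PhenotypeTable
    truth: SimulationTruth
    config: SimulationConfig = field(repr=False, default=None)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """One fully assembled cohort: design, phenotype replicates and truth.

    All randomness flows from ``config.seed`` through a single generator, so
    identical configs give bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    genotypes, gmap = simulate_genotypes(config, rng)
    covariates = simulate_covariates(config, rng)
    truth = simulate_truth(genotypes, gmap, config, rng)
    phenotypes = simulate_replicates(genotypes, covariates, truth, config, rng)
    design = build_design(genotypes, gmap, covariates)
    return SimulatedDataset(
        design=design,
        genotypes=genotypes,
        group_map=gmap,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )


def write_truth_table(truth: SimulationTruth, path, sep="\t") -> None:
    """Persist the causal architecture as a gene/snp/beta table."""
    rows = [
        {"gene_id": g, "snp_id": s, "beta": b}
        for g in truth.causal_genes
        for s, b in truth.causal_snps.get(g, {}).items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "snp_id", "beta"]).to_csv(
        path, sep=sep, index=False
    )


def read_truth_table(path, sep="\t") -> SimulationTruth:
    df = pd.read_csv(path, sep=sep, dtype={"gene_id": str, "snp_id": str})
    causal: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        causal.setdefault(row["gene_id"], {})[row["snp_id"]] = float(row["beta"])
    return SimulationTruth(
        causal_genes=list(causal),
        causal_snps=causal,
        covariate_coefficients={},
        noise_sd=float("nan"),
    )
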