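import numpy as np
import pytest

from grpisis.design import GroupedDesign, Response


def make_design(rng, n=40, group_sizes=(3, 4, 2), n_cov=2, maf=0.3):
    """Random genotype design with labelled genes and covariate columns."""
    p_snp = sum(group_sizes)
    X = rng.binomial(2, maf, size=(n, p_snp)).astype(float)
    cov = np.column_stack([
        rng.integers(0, 2, size=n).astype(float),
        rng.uniform(20, 80, size=n),
    ])[:, :n_cov]
    mat = np.column_stack([X, cov]) if n_cov else X
    group_of = {}
    gene_ids = []
    j = 0
    for gi, size in enumerate(group_sizes):
        gene = f"G{gi + 1}"
        gene_ids.append(gene)
        for _ in range(size):
            group_of[j] = gene
            j += 1
    return GroupedDesign(
        matrix=mat,
        column_ids=[f"snp{i}" for i in range(p_snp)] + [f"cov{i}" for i in range(n_cov)],
        sample_ids=[f"s{i}" for i in range(n)],
        group_of=group_of,
        group_ids=gene_ids,
        covariate_columns=list(range(p_snp, p_snp + n_cov)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_design(rng):
    return make_design(rng)


@pytest.fixture
def noiseless(rng):
    """Design whose response is generated exactly by gene G1's first SNP."""
    design = make_design(rng, n=50, group_sizes=(3, 4, 2, 5))
    y = Response(2.0 * design.matrix[:, 0] + 0.5 * design.matrix[:, -2], label="exact")
    return design, y
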