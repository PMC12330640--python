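import numpy as np
import pytest

from ithkit import ExpressionMatrix, SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Desk-scale cohort: 4 samples, 4 programs, quick to generate and factorise."""
    return SyntheticSpec(
        n_samples=4,
        n_genes=600,
        cells_per_sample=100,
        n_programs=4,
        genes_per_program=40,
        program_sharing=0.75,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_matrix(rng) -> ExpressionMatrix:
    """A 40-gene x 30-cell matrix of lognormal 'expression' over two samples."""
    values = rng.lognormal(0.0, 1.0, size=(40, 30))
    genes = [f"G{i:03d}" for i in range(40)]
    cells = [f"C{i:03d}" for i in range(30)]
    samples = ["A"] * 15 + ["B"] * 15
    return ExpressionMatrix(values, genes, cells, samples)
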