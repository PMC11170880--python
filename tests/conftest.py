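import numpy as np
import pytest
import scipy.sparse as sp

import caracal as cc


@pytest.fixture(scope="session")
def tiny():
    return cc.make_fixture("tiny")


@pytest.fixture(scope="session")
def benchmark():
    return cc.make_fixture("benchmark")


@pytest.fixture(scope="session")
def benchmark_normalized(benchmark):
    return cc.log_normalize(benchmark.activity)


@pytest.fixture(scope="session")
def benchmark_gene_sets(benchmark, benchmark_normalized):
    """Up/down sets built from the benchmark reference labels."""
    return cc.build_gene_sets_from_reference(
        benchmark_normalized, benchmark.truth_labels, n_genes=100
    )


def make_count_matrix(values, layer="raw", feature_kind="gene", prefix="G"):
    """A CountMatrix from a dense array with generated identifiers."""
    values = np.asarray(values)
    return cc.CountMatrix(
        features=[f"{prefix}{i}" for i in range(values.shape[0])],
        barcodes=[f"c{j}" for j in range(values.shape[1])],
        values=sp.csr_matrix(values),
        layer=layer,
        feature_kind=feature_kind,
    )
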