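import numpy as np
import pandas as pd
import pytest

from splitgene import FixtureConfig, generate_fixture
from splitgene.expression import ExonCountMatrix


@pytest.fixture(scope="session")
def toy_fixture():
    """Small study with known class counts: 10 one-to-one, 2 tandem,
    3 testable candidates (2 true_split + 1 true_merged), 1 strand-fail,
    1 overlap-fail."""
    cfg = FixtureConfig(
        n_one_to_one=10, n_tandem=2, n_true_split=2, n_true_merged=1,
        n_strand_fail=1, n_overlap_fail=1, sigma=1.5, seed=11,
    )
    return generate_fixture(cfg)


def make_library_sheet(n_tissues=2, n_replicates=1, genotype="A"):
    rows = [
        (f"{genotype}_T{t}_R{r}", genotype, f"tissue{t}", r)
        for t in range(1, n_tissues + 1)
        for r in range(1, n_replicates + 1)
    ]
    libs = pd.DataFrame(rows, columns=["library_id", "genotype", "tissue", "replicate"])
    return libs.set_index("library_id", drop=False)


def make_counts(counts, lengths, gene_ids=None, genotype="A"):
    """Build an ExonCountMatrix from a (n_exons, n_libraries) array."""
    counts = np.atleast_2d(np.asarray(counts))
    n_exons, n_libs = counts.shape
    libs = make_library_sheet(n_tissues=n_libs, genotype=genotype)
    idx = pd.Index([f"e{i}" for i in range(n_exons)], name="exon_id")
    meta = pd.DataFrame(
        {
            "gene_id": gene_ids or [f"g{i}" for i in range(n_exons)],
            "length": lengths,
        },
        index=idx,
    )
    cdf = pd.DataFrame(counts, index=idx, columns=list(libs["library_id"]))
    return ExonCountMatrix(cdf, meta, libs)
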