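import numpy as np
import pytest

from ribodelta.io import CountMatrix, SampleMeta


def make_samples(lines=("MCF10A", "MCF7"), replicates=2):
    samples = []
    for line in lines:
        for treatment in ("untreated", "treated"):
            for fraction in ("total", "polysome"):
                for rep in range(1, replicates + 1):
                    samples.append(
                        SampleMeta(
                            sample_id=f"{line}.{treatment}.{fraction}.r{rep}",
                            cell_line=line,
                            treatment=treatment,
                            fraction=fraction,
                            replicate=rep,
                            spike_mix="mix1",
                        )
                    )
    return samples


@pytest.fixture
def small_counts():
    """3 genes + 3 spikes x full two-line design, 2 replicates."""
    rng = np.random.default_rng(42)
    samples = make_samples()
    genes = ["geneA", "geneB", "geneC", "ERCC-1", "ERCC-2", "ERCC-3"]
    counts = rng.integers(50, 500, size=(len(genes), len(samples)))
    return CountMatrix(
        gene_ids=genes,
        samples=samples,
        counts=counts,
        spike_ids=frozenset({"ERCC-1", "ERCC-2", "ERCC-3"}),
    )
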