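import numpy as np
import pandas as pd
import pytest

import scmra


@pytest.fixture(scope="session")
def default_truth():
    """Gene architecture at the default study conditions (seed 1)."""
    return scmra.make_truth(scmra.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_dataset(default_truth):
    """Counts + annotation simulated at the default study conditions."""
    counts, annotation = scmra.simulate_counts(default_truth)
    return default_truth, counts, annotation


@pytest.fixture(scope="session")
def default_normalized(default_dataset):
    """Filtered counts and the three normalized matrices."""
    truth, counts, annotation = default_dataset
    counts_f = scmra.filter_genes(counts)
    x_tpm = scmra.tpm(counts_f, truth.gene_lengths)
    return {
        "truth": truth,
        "annotation": annotation,
        "counts": counts_f,
        "tpm": x_tpm,
        "log10tpm": scmra.log10_with_pseudo(x_tpm),
        "lognorm": scmra.lognormalize(counts_f),
    }


@pytest.fixture
def random_signature():
    rng = np.random.default_rng(42)
    genes = pd.Index([f"g{i:03d}" for i in range(200)], name="gene")
    return pd.Series(rng.normal(size=len(genes)), index=genes, name="score")
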