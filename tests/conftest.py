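import numpy as np
import pytest

from pairsplice import as_caller, io, pair_align, pipeline
from pairsplice.synthetic_data import GeneratorConfig, generate_dataset

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-gene default-parameter dataset shared across tests."""
    cfg = GeneratorConfig(n_genes=60, seed=3)
    models, records, truths = generate_dataset(cfg)
    return cfg, models, records, truths


@pytest.fixture(scope="session")
def small_detection(small_dataset):
    """Alignment + event calling on the shared dataset."""
    _cfg, _models, records, truths = small_dataset
    clusters = io.clusters_from_records(records)
    chains_by_gene, events, sequences = pipeline.detect_events(
        clusters, pair_align.AlignParams(), as_caller.CallerOptions()
    )
    return clusters, chains_by_gene, events, sequences, truths
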