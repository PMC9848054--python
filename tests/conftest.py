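import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hicsaga.core import make_binned_genome
from hicsaga.pipeline import run_pipeline
from hicsaga.simulate import simulate_dataset

RES = 100_000


@pytest.fixture
def small_genome():
    """Two chromosomes, 3 + 2 bins of 100 kb (second chrom has a short
    last bin)."""
    return make_binned_genome([("chr1", 300_000), ("chr2", 150_000)], RES)


@pytest.fixture(scope="session")
def integration_runs():
    """Full pipeline (graph -> embedding -> HMM in all three modes) on
    the default factorized simulation (3 functional x 2 structural
    states, 1000 bins), five seeds. Shared across the integration and
    acceptance tests because each run trains an embedding."""
    runs = []
    for seed in range(5):
        ds = simulate_dataset(seed=seed)
        res = run_pipeline(
            ds.truth.genome,
            ds.contacts,
            ds.signals,
            K=6,
            seed=seed,
            modes=("combined", "functional", "structural"),
        )
        m = res.bin_mask
        truth = ds.truth.combined_states
        aris = {
            mode: adjusted_rand_score(truth[m], ann.labels[m])
            for mode, ann in res.annotations.items()
        }
        runs.append({"dataset": ds, "result": res, "aris": aris})
    return runs
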