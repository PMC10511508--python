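import numpy as np
import pytest

from cnatac import simulate as sim
from cnatac.pipeline import call_cnas


@pytest.fixture(scope="session")
def reference_run():
    """One shared end-to-end run of the reference synthetic configuration.

    200 cells, two 500-bin chromosomes, lambda 10, two clones with 100-bin
    gains and losses; called with the default caller parameters.
    """
    cfg = sim.SimConfig(seed=1)
    counts, truth, clones = sim.simulate_counts(cfg)
    result = call_cnas(counts, min_frags=2000, n_clusters=2)
    return cfg, counts, truth, clones, result


def align_truth(truth, karyotype) -> np.ndarray:
    """Truth states re-ordered to the called karyotype's cells and bins."""
    return (
        truth.to_frame()
        .loc[list(karyotype.cell_ids), list(karyotype.bin_ids)]
        .to_numpy()
    )
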