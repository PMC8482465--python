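import numpy as np
import pandas as pd
import pytest

from apmsmist.io_quant import CollapsedMatrix


def make_matrix(arr, preys, baits, n_bio, control="IgG"):
    """Build a CollapsedMatrix from a preys x (baits*n_bio) array (NaN = missing)."""
    cols = pd.MultiIndex.from_tuples(
        [(b, r) for b in baits for r in range(1, n_bio + 1)], names=["bait", "bio_rep"]
    )
    df = pd.DataFrame(np.asarray(arr, dtype=float), index=list(preys), columns=cols)
    return CollapsedMatrix(
        values=df,
        control=control,
        gene_names=pd.Series("", index=list(preys)),
        baits=list(baits),
    )


@pytest.fixture
def small_synth():
    """A small synthetic dataset shared across tests (fast to generate)."""
    from apmsmist.synthetic_data import SynthConfig, generate_apms_dataset

    cfg = SynthConfig(
        n_preys=60,
        n_true_per_bait=8,
        n_shared_true=3,
        n_frequent_background=10,
        seed=11,
    )
    return generate_apms_dataset(cfg)
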