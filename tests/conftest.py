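import numpy as np
import pandas as pd
import pytest

import tissueatlas as ta


@pytest.fixture(scope="session")
def zero_noise_sim():
    """Small noise-free atlas with planted roles; detection/tau/bias are exact."""
    cfg = ta.SimConfig(n_genes=300, noise_sd=0.0, seed=1)
    atlas, signals, truth = ta.simulate_atlas(cfg)
    return cfg, atlas, signals, truth


@pytest.fixture(scope="session")
def zero_noise_detection(zero_noise_sim):
    _, _, signals, _ = zero_noise_sim
    return ta.build_detection_table(signals)


def make_atlas(values, tissues, sexes=("male", "female"), n_reps=2, genes=None, arms=None):
    """Build a toy ExpressionAtlas from a genes x cells array.

    ``values`` is (n_probes, len(tissues) * len(sexes)); every cell value is
    replicated ``n_reps`` times.
    """
    values = np.asarray(values, dtype=float)
    cols = [(t, s, r) for t in tissues for s in sexes for r in range(1, n_reps + 1)]
    data = np.repeat(values, n_reps, axis=1)
    probes = [f"p{i}" for i in range(values.shape[0])]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(
        data,
        index=probes,
        columns=pd.MultiIndex.from_tuples(cols, names=["tissue", "sex", "replicate"]),
    )
    probe_to_gene = pd.Series(genes, index=probes)
    gene_to_arm = pd.Series(arms or ["2R"] * len(set(genes)), index=sorted(set(genes)))
    return ta.ExpressionAtlas(df, probe_to_gene, gene_to_arm)
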