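import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small planted-structure dataset shared across tests (seed-fixed)."""
    from thermomem.simulate import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_genes=1200,
        module_sizes=(120, 100, 80, 60),
        samples_per_cell=6,
        n_hub_candidates=8,
        seed=3,
    )
    counts, design, truth = simulate_dataset(cfg)
    return cfg, counts, design, truth


@pytest.fixture(scope="session")
def family_expression(small_sim):
    """Preprocessed per-family expression matrices for the small dataset."""
    from thermomem import preprocessing as pp

    _, counts, design, _ = small_sim
    out = {}
    for fam in ("A", "B"):
        cols = [c for c in counts.columns if design.loc[c, "family"] == fam]
        expr, _ = pp.preprocess(counts[cols])
        out[fam] = expr
    return out


@pytest.fixture
def toy_counts():
    """6-sample toy count matrix with equal library sizes of 1e6."""
    genes = ["kept", "dropped", "zero"]
    data = np.array(
        [
            [2, 2, 2, 2, 0, 0],
            [2, 2, 2, 0, 0, 0],
            [0, 0, 0, 0, 0, 0],
        ]
    )
    filler = np.full((1, 6), 10**6) - data.sum(axis=0)
    mat = np.vstack([data, filler])
    return pd.DataFrame(
        mat, index=genes + ["filler"], columns=[f"s{i}" for i in range(6)]
    )


def block_expression(sizes, cors, n_samples=40, seed=0, noise_index=None, n_noise=0):
    """Expression with planted correlation blocks: gene = sqrt(c)*factor + sqrt(1-c)*noise."""
    rng = np.random.default_rng(seed)
    rows = []
    ids = []
    for b, (m, c) in enumerate(zip(sizes, cors)):
        f = rng.standard_normal(n_samples)
        lam = np.sqrt(c)
        for i in range(m):
            rows.append(lam * f + np.sqrt(1 - c) * rng.standard_normal(n_samples))
            ids.append(f"b{b}_g{i}")
    for i in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        ids.append(f"noise_g{i}")
    return pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n_samples)])
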