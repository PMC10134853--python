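import numpy as np
import pandas as pd
import pytest

from phycoactivity import (
    CountTable,
    EnvTable,
    SampleMetadata,
    SimConfig,
    compute_activity,
    pair_samples,
    relative_abundance,
    simulate_paired_dataset,
    tree_from_newick,
)


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(pd.DataFrame(
        {"s1": [10, 5, 0], "s2": [2, 2, 4]},
        index=["t1", "t2", "t3"],
    ))


@pytest.fixture
def three_taxon_tree():
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def paired_meta() -> SampleMetadata:
    rows = []
    for k, (date, cond) in enumerate([("2021-05-04", "daytime"),
                                      ("2021-05-04", "nighttime")]):
        for mol in ("rDNA", "rRNA"):
            rows.append({"sample_id": f"p{k}_{mol}", "date": date,
                         "condition": cond, "molecule": mol, "pair_key": f"p{k}"})
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_dataset():
    """A complete simulated paired dataset at a small, fast scale."""
    cfg = SimConfig(n_taxa=80, n_dates=8, depth=3000, seed=11)
    return simulate_paired_dataset(cfg)


@pytest.fixture(scope="session")
def small_records(small_dataset):
    rdna, rrna, meta, env, tree, truth = small_dataset
    pairs = pair_samples(meta)
    records = compute_activity(
        relative_abundance(rdna), relative_abundance(rrna), pairs)
    return records, truth, env


@pytest.fixture
def env_table() -> EnvTable:
    rng = np.random.default_rng(0)
    rows = []
    for i in range(10):
        rows.append({
            "date": f"2021-06-{i + 1:02d}", "condition": "daytime",
            "WT": 20 + rng.normal(), "pH": 8 + 0.1 * rng.normal(),
            "Tur": 30 + rng.normal(), "EC": 300 + rng.normal(),
            "DO": 8 + rng.normal(), "NO3_N": 0.5 + 0.1 * rng.normal(),
            "NO2_N": 0.05, "NH4_N": 0.3, "DIN": 0.85, "DIP": 0.05,
        })
    return EnvTable(pd.DataFrame(rows))
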