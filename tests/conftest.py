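import numpy as np
import pandas as pd
import pytest

import forecasd as f


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study reused across modules (read-only)."""
    cfg = f.SimulationConfig(seed=11, n_genes=400, n_positive=30, n_candidate=30, n_negative=150)
    return f.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    """One reduced end-to-end pipeline run (read-only)."""
    cfg = f.PipelineConfig(seed=5, n_negative=150, n_trees=120, per_class=25)
    res = f.run_pipeline(
        small_study.bundle,
        small_study.network,
        small_study.eval_data.priors,
        small_study.positives,
        small_study.exclusion,
        cfg,
    )
    return cfg, res


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_bundle(n_genes=6, regions=("A", "B"), samples_per_region=4, seed=0):
    """Tiny hand-rolled expression bundle for format-level tests."""
    g = np.random.default_rng(seed)
    rows = []
    for r in regions:
        for i in range(samples_per_region):
            rows.append((f"d{i}", r, 8.0 + 10.0 * i))
    meta = pd.DataFrame(rows, columns=["donor", "region", "age_pcw"])
    meta.index = pd.Index([f"s{i}" for i in range(len(meta))], name="sample")
    values = pd.DataFrame(
        g.uniform(0.0, 10.0, size=(n_genes, len(meta))),
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
        columns=meta.index,
    )
    return f.ExpressionBundle(values=values, sample_meta=meta)
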