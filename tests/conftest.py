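import numpy as np
import pytest

from sadln import SimulationConfig, simulate_multiomics, zscore_blocks


@pytest.fixture(scope="session")
def small_sim():
    """Compact 4-block dataset with strong cluster structure (N=120, K=4)."""
    cfg = SimulationConfig(n_samples=120, block_widths=(30, 30, 10, 30), seed=2)
    dataset, truth, clinical = simulate_multiomics(cfg)
    return zscore_blocks(dataset), truth, clinical


@pytest.fixture(scope="session")
def benchmark_sim():
    """The full synthetic benchmark: N=400, blocks 200/200/50/200, K=4, seed 2."""
    cfg = SimulationConfig(seed=2)
    dataset, truth, clinical = simulate_multiomics(cfg)
    return zscore_blocks(dataset), truth, clinical


@pytest.fixture(scope="session")
def benchmark_runs(benchmark_sim):
    """Trained latent representations on the benchmark: full model and the
    reconstruction-ablated (lambda1 = 0) variant, for seeds 0, 1, 2."""
    from sadln import SADLN

    dataset, truth, clinical = benchmark_sim
    runs = {}
    for seed in (0, 1, 2):
        for lam1, tag in ((1.0, "full"), (0.0, "lambda1_zero")):
            res = SADLN(dataset, epochs=200, seed=seed, lambda1=lam1).fit()
            runs[(tag, seed)] = res
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
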