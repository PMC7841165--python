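import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def small_cohort():
    """A small simulated cohort with planted DE genes, shared across tests."""
    from permde import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(
        n_genes=400, de_fraction=0.1, effect_log2fc=1.5, seed=11
    )
    counts, fpkm, truth = simulate_cohort(cfg)
    return cfg, counts, fpkm, truth


def make_normalized(values, groups=None):
    """Wrap a plain array as a NormalizedMatrix with case/control labels."""
    from permde import NormalizedMatrix

    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    sample_ids = [f"s{j}" for j in range(n_samples)]
    m = NormalizedMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        sample_ids=sample_ids,
        values=values,
    )
    if groups is None:
        half = n_samples // 2
        groups = {
            s: ("case" if j < half else "control")
            for j, s in enumerate(sample_ids)
        }
    return m, groups
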