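import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import slconnect as sl

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bench_default():
    """The generator's default study conditions (n=500, signal 0.7, rewire 0.2)."""
    return sl.make_benchmark(sl.SimConfig())


@pytest.fixture(scope="session")
def bench_strong_small():
    """Strong-signal benchmark at reduced size for fast training tests."""
    cfg = sl.SimConfig(n_genes=200, feature_signal=0.9,
                       network_rewire_prob=0.1, seed=0)
    return sl.make_benchmark(cfg)


@pytest.fixture(scope="session")
def small_model_config():
    return sl.ModelConfig.small(max_epochs=100, early_stop_patience_epochs=30)


@pytest.fixture
def toy_screen():
    """Labeled 4-gene screen with SL pairs (A,B) and (A,C)."""
    records = (
        sl.GenePairRecord("A", "B", -3.5),
        sl.GenePairRecord("A", "C", -4.0),
        sl.GenePairRecord("B", "C", 0.2),
        sl.GenePairRecord("A", "D", -1.0),
    )
    return sl.label_pairs(sl.SLScreen("toy", records, ("A", "B", "C", "D")))


def random_screen(rng: np.random.Generator, n_genes: int = 8,
                  sl_prob: float = 0.3) -> "sl.SLScreen":
    """Random complete-pair labeled screen for property tests."""
    import itertools

    genes = tuple(f"g{i}" for i in range(n_genes))
    records = tuple(
        sl.GenePairRecord(a, b, float(rng.normal(-5 if rng.random() < sl_prob
                                                 else 0, 0.5)))
        for a, b in itertools.combinations(genes, 2)
    )
    return sl.label_pairs(sl.SLScreen("rand", records, genes))
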