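import numpy as np
import pytest

from stagkit import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_contacts():
    """Contact list with one planted 150-contact cluster over a light
    background."""
    config = sim.SimConfig(
        seed=11,
        chrom_length=50e6,
        n_background_contacts=20_000,
        background_score_sd=20.0,
        hotspot_specs=((5e6, 20e6, 150, 20e3),),
    )
    return sim.gen_contacts(config)


def planted_cluster_specs(seed: int, n_clusters: int = 20,
                          chrom_length: float = 50e6):
    """Well-separated planted hotspot specs inside the separation band."""
    rng = np.random.default_rng(seed)
    specs = []
    while len(specs) < n_clusters:
        c1 = rng.uniform(1e6, 0.9 * chrom_length)
        c2 = rng.uniform(c1 + 1e6, min(c1 + 40e6, chrom_length - 1e6))
        if all(max(abs(c1 - a), abs(c2 - b)) > 2e6 for a, b, _, _ in specs):
            specs.append((c1, c2, int(rng.integers(120, 201)), 20e3))
    return tuple(specs)
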