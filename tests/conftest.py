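import numpy as np
import pytest

from vinepop import synthpop
from vinepop.containers import Genotypes


@pytest.fixture(scope="session")
def small_cfg():
    """A fast synthetic study: 20 mothers x 4 offspring, 400 SNPs."""
    return synthpop.SimConfig(
        seed=11, n_mothers=20, offspring_per_mother=4, n_selected=72,
        n_snps=400, n_env_loci=4, missing_rate=0.15,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    meta = synthpop.make_landscape(small_cfg)
    gt, vt, truth = synthpop.simulate_genotypes(meta, small_cfg)
    return meta, gt, vt, truth


@pytest.fixture(scope="session")
def small_climate(small_cfg, small_study):
    meta = small_study[0]
    return synthpop.make_climate(meta, small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_genotypes(g, depth=None, samples=None):
    return Genotypes(np.asarray(g, dtype=np.int8), samples or [], depth)


@pytest.fixture(scope="session")
def two_deme_strong():
    """Two well-separated demes (F about 0.1), no admixture, no missing."""
    rng = np.random.default_rng(7)
    n_per, L, F = 40, 800, 0.1
    p = rng.uniform(0.1, 0.9, L)
    a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
    p1, p2 = rng.beta(a, b), rng.beta(a, b)
    g1 = rng.binomial(2, p1, (n_per, L)).astype(np.int8)
    g2 = rng.binomial(2, p2, (n_per, L)).astype(np.int8)
    g = np.vstack([g1, g2])
    labels = np.array(["deme1"] * n_per + ["deme2"] * n_per, dtype=object)
    return Genotypes(g), labels
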