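import dendropy
import pytest
from hypothesis import HealthCheck, settings

from beeallometry import morphodata as md
from beeallometry import synthdata as sd

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture
def six_family_means():
    """Zero-noise species means covering all six families (deterministic)."""
    cfg = sd.SynthConfig(seed=0, noise_sd=0.0, n_specimens=2,
                         n_species={f: 5 for f in md.FAMILIES})
    return md.aggregate_species_means(sd.gen_specimens(cfg))


@pytest.fixture
def noisy_means():
    """Species means at the default study conditions (110 species, noise 0.1)."""
    cfg = sd.SynthConfig(seed=42)
    return md.aggregate_species_means(sd.gen_specimens(cfg))


@pytest.fixture
def worked_tree():
    """Three-tip tree with hand-computable depths and Brownian covariance."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


@pytest.fixture
def star_tree():
    return dendropy.Tree.get(
        data="(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);", schema="newick"
    )
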