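import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_alignment():
    """8 taxa x 30 sites with gaps and ambiguity codes."""
    from ratepart.msa_io import Alignment

    rs = np.random.default_rng(7)
    mat = rs.choice(list("ACGT-N"), size=(8, 30), p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06])
    return Alignment(tuple(f"s{i}" for i in range(8)), mat)


@pytest.fixture(scope="session")
def sim_alignment_tree():
    """A simulated 12-taxon alignment with its generating tree (session-wide)."""
    from ratepart.simulate import scale_tree_depth, simulate_alignment, yule_tree

    tree = scale_tree_depth(yule_tree(12, 1.0, rng=np.random.default_rng(11)), 0.6)
    aln = simulate_alignment(tree, 800, rng=np.random.default_rng(12))
    return aln, tree
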