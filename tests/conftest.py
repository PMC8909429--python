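import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phagefunnel import CountsTable, build_library, run_selection
from phagefunnel.simulate import CORE_AA, FR1_AA, FR4_AA

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def valid_vh_aa() -> str:
    """A complete, valid VH amino-acid sequence on the simulator scaffold."""
    return FR1_AA + CORE_AA + "ARDRSTGYFDY" + FR4_AA


@pytest.fixture
def small_table() -> CountsTable:
    """Tiny counts table with known trajectories."""
    return CountsTable(
        sequences=["AAA", "CCC", "GGG"],
        counts=np.array([[2, 5, 20], [1, 0, 0], [7, 5, 5]]),
        cycle_totals=np.array([10, 10, 25]),
    )


@pytest.fixture(scope="session")
def small_screen():
    """Session-scoped small simulated screen (1000 clones, 2e4 reads/cycle)."""
    library = build_library(n_clones=1000, seed=11)
    return run_selection(library, depth=20_000, seed=12, screen_id="small")
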