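import numpy as np
import pytest

from filacover import CoverOptions, contrived_scene, solve_fcp


@pytest.fixture(scope="session")
def scene():
    """The deterministic planted scene: crossings, one overlap, one loop."""
    return contrived_scene(seed=0)


@pytest.fixture(scope="session")
def scene_cover(scene):
    """Default-options decomposition of the planted scene (BFS/over/pair/total)."""
    graph, _ = scene
    return solve_fcp(graph, CoverOptions())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
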