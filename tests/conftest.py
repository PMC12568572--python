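import numpy as np
import pytest

from retinavasc.graph import build_graph, skeletonize
from retinavasc.simulate import default_scene


@pytest.fixture(scope="session")
def scene0():
    """The default synthetic scene, fixed seed 0: (FundusImage, GroundTruth)."""
    return default_scene(seed=0)


@pytest.fixture(scope="session")
def scene0_graph(scene0):
    """Measured centerline graph built from the scene's ground-truth mask."""
    _, truth = scene0
    skel = skeletonize(truth.vessel_mask, spur_length=5)
    return build_graph(skel, truth.vessel_mask, truth.artery_mask, truth.vein_mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full synthetic pipeline run (2 subjects/group, both eyes)."""
    from retinavasc.pipeline import RunConfig, run_pipeline

    cfg = RunConfig(seed=5, n_per_group=2, save_images=True)
    out = run_pipeline(cfg, tmp_path_factory.mktemp("run"))
    return cfg, out
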