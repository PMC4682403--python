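import numpy as np
import pytest

from copepodid.cli_app import RunConfig, run_pipeline
from copepodid.shape_features import PipelineConfig
from copepodid.synthetic_copepods import SceneParams

#: Printed species-level confusion matrix from the published evaluation
#: of the 8-species test set (20 specimens per species); rows = true
#: class As..Tf, columns = predicted.  Used as input data for the
#: accuracy-recomputation checks.
PUBLISHED_SPECIES_CONFUSION = np.array([
    [20, 0, 0, 0, 0, 0, 0, 0],
    [0, 20, 0, 0, 0, 0, 0, 0],
    [0, 0, 20, 0, 0, 0, 0, 0],
    [0, 0, 0, 18, 2, 0, 0, 0],
    [0, 0, 0, 2, 17, 1, 0, 0],
    [0, 0, 1, 0, 1, 18, 0, 0],
    [0, 0, 0, 0, 0, 0, 19, 1],
    [0, 0, 0, 0, 0, 0, 3, 17],
])
SPECIES_ORDER = ["As", "Bs", "Oa", "Od", "Os", "Pc", "Tb", "Tf"]


@pytest.fixture(scope="session")
def desk_pipeline_config() -> PipelineConfig:
    """Pipeline settings matched to the synthetic canvas scale."""
    return PipelineConfig().with_min_area(SceneParams().min_area_scaled)


@pytest.fixture(scope="session")
def study_reports() -> dict[int, dict]:
    """Full synthetic-study pipeline reports for three master seeds.

    This is the expensive shared fixture (a few minutes): 8 classes x
    (30 train + 20 test) images per seed, full feature extraction,
    selection, training and evaluation.  Feature tables are attached
    so other tests can reuse them without re-extracting.
    """
    return {
        seed: run_pipeline(RunConfig(seed=seed), return_tables=True)
        for seed in (1, 2, 3)
    }


@pytest.fixture(scope="session")
def study_train_table(study_reports):
    """Training-pool feature table (240 rows) of the seed-1 study."""
    return study_reports[1]["tables"]["train"]
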