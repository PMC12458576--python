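import numpy as np
import pandas as pd
import pytest

from rvindex.io_formats import EffectSizeBlueprint, PhenotypeTable, StatusPanel
from rvindex.synthetic_cohort import bundled_ad_blueprint


@pytest.fixture(scope="session")
def ad_blueprint():
    """The packaged synthetic 64-region blueprint (33/7/24)."""
    return bundled_ad_blueprint()


@pytest.fixture
def small_blueprint():
    return EffectSizeBlueprint(pd.DataFrame({
        "region_id": ["hippocampus", "entorhinal", "precuneus", "fx", "amygdala"],
        "modality": ["subcortical_volume", "cortical_thickness",
                     "cortical_thickness", "white_matter", "subcortical_volume"],
        "d": [-1.2, -1.1, -0.6, -0.8, -1.0],
    }))


@pytest.fixture
def toy_phenotypes():
    """Five subjects, five already-averaged regions, full covariates."""
    rng = np.random.default_rng(42)
    ids = [f"S{i}" for i in range(5)]
    data = pd.DataFrame(
        rng.normal(
            loc=[3700.0, 3.2, 2.3, 0.45, 1600.0],
            scale=[300.0, 0.2, 0.15, 0.02, 150.0],
            size=(5, 5),
        ),
        index=pd.Index(ids, name="subject_id"),
        columns=["hippocampus", "entorhinal", "precuneus", "fx", "amygdala"],
    )
    data["age"] = [55.0, 62.0, 70.0, 48.0, 66.0]
    data["sex"] = [0, 1, 1, 0, 1]
    data["icv"] = rng.normal(1.5e6, 1e5, 5)
    data["apoe4_carrier"] = [0, 1, 0, 1, 0]
    return PhenotypeTable(
        data=data,
        regions=["hippocampus", "entorhinal", "precuneus", "fx", "amygdala"],
        covariates=["age", "sex", "icv", "apoe4_carrier"],
    )


@pytest.fixture
def toy_panel():
    """Hand-enumerated three-subject panel: one converts at year 2, one
    stays MCI for 12 years, one drops out after year 1."""
    rows = []
    rows += [{"subject_id": "conv", "visit_year": 0, "status": "MCI"},
             {"subject_id": "conv", "visit_year": 1, "status": "MCI"},
             {"subject_id": "conv", "visit_year": 2, "status": "dementia"}]
    for y in range(13):
        rows.append({"subject_id": "stable", "visit_year": y, "status": "MCI"})
    rows += [{"subject_id": "drop", "visit_year": 0, "status": "MCI"},
             {"subject_id": "drop", "visit_year": 1, "status": "MCI"}]
    return StatusPanel(pd.DataFrame(rows))
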