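import numpy as np
import pandas as pd
import pytest

from nanosip.organelles import OrganelleClass
from nanosip.phantom import (
    AcquisitionSpec,
    ClassTruth,
    PhantomConfig,
    PhantomTruth,
    build_label_map,
    simulate_session,
)
from nanosip.stack_io import ROILabelMap


#: Reduced organelle load that fits comfortably in a small field.
SMALL_COUNTS = {
    OrganelleClass.VACUOLE: 1,
    OrganelleClass.MITOCHONDRION: 2,
    OrganelleClass.LIPID_DROPLET: 1,
    OrganelleClass.POSSIBLE_ENDOBIONT: 1,
    OrganelleClass.ELECTRON_DENSE_BODY: 3,
}


def small_config(**overrides) -> PhantomConfig:
    kwargs = dict(
        rows=96,
        cols=96,
        pixel_size_nm=10000.0 / 96.0,
        organelle_counts=dict(SMALL_COUNTS),
        seed=11,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture
def small_truth():
    return build_label_map(small_config())


@pytest.fixture
def small_session(small_truth):
    return simulate_session(small_truth, AcquisitionSpec(planes=50, raster=96), seed=7)


def uniform_truth(rows=32, cols=32, organelle=OrganelleClass.CYTOSOME,
                  f15=0.01, f34=0.05, lambda_cn=40.0, lambda_s=3.0,
                  seed=0) -> PhantomTruth:
    """A single-class field with hand-set truth, for closed-form checks."""
    pixel_size = 10000.0 / rows  # keep a 10 um field regardless of raster
    labels = np.ones((rows, cols), dtype=np.int32)
    table = pd.DataFrame(
        [{"label": 1, "roi_id": 1, "class": organelle.value,
          "condition": "dysoxic", "chamber": ""}]
    )
    truth_tbl = pd.DataFrame(
        [{"label": 1, "class": organelle.value, "f15_true": f15, "f34_true": f34,
          "lambda_cn": lambda_cn, "lambda_s": lambda_s}]
    )
    cfg = PhantomConfig(rows=rows, cols=cols, pixel_size_nm=pixel_size,
                        condition="dysoxic", seed=seed, organelle_counts={})
    truths = [ClassTruth(organelle=organelle, f15=f15, f34=f34,
                         lambda_cn=lambda_cn, lambda_s=lambda_s)]
    return PhantomTruth(label_map=ROILabelMap(labels, table), truths=truths,
                        roi_truth=truth_tbl, seed=seed, config=cfg)
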