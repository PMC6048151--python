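import numpy as np
import pandas as pd
import pytest

from panelqc import build_default_layout, Config
from panelqc.chipio import Cluster, ChipLayout, CqTable
from panelqc.synthdata import AssayTruth, SimConfig


@pytest.fixture(scope="session")
def layout():
    """Emulated full panel: 164 targets + 7 controls, 9 wells each."""
    return build_default_layout()


@pytest.fixture(scope="session")
def small_layout():
    """4 targets + 7 controls on a small grid, for fast chip runs."""
    return build_default_layout(n_targets=4, wells_total=99)


@pytest.fixture
def config():
    return Config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cluster_table(cqs, assay_id="mir-001", sample_id="s1", chip_id="chip-1",
                       well_start=0):
    """Single-cluster CqTable from a list of Cq values (None = no amp)."""
    data = pd.DataFrame(
        {
            "well_id": range(well_start, well_start + len(cqs)),
            "assay_id": assay_id,
            "cq": [np.nan if c is None else float(c) for c in cqs],
        }
    )
    return CqTable(sample_id=sample_id, chip_id=chip_id, data=data)


def make_truth(assay_id="mir-001", copies_A=1e4, copies_B=1e3, efficiency=1.0,
               intercept=36.0):
    return AssayTruth(assay_id, copies_A, copies_B, efficiency, intercept)


@pytest.fixture
def noise_free_sim():
    """Deterministic generator settings: no Cq noise, no dropout
    (detection knee far below any used copy number)."""
    return SimConfig(cq_noise_sd=0.0, detection_scale_phi=1e-9, p_ntc=0.0)
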