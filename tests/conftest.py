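import pytest

from ssikit.coronary_model import CoronaryTree, Segment
from ssikit.lpm_boundary import PerfusionParams
from ssikit.synthetic_fixtures import TreeGenParams, generate_tree


@pytest.fixture
def params():
    return PerfusionParams()


@pytest.fixture
def single_lad_tree():
    """One LAD segment: length 100 mm, 3.0 -> 2.5 mm taper."""
    return CoronaryTree(
        patient_id="single",
        segments=[
            Segment(
                id="LAD_0",
                artery="LAD",
                parent_id=None,
                length_mm=100.0,
                d_prox_mm=3.0,
                d_dist_mm=2.5,
            )
        ],
    )


@pytest.fixture
def three_artery_tree():
    """Hand-built 3-artery tree with a bifurcating LAD and a split-territory RCA."""
    return CoronaryTree(
        patient_id="hand",
        segments=[
            Segment("RCA_0", "RCA", None, 60.0, 3.5, 3.0, "RV"),
            Segment("RCA_1", "RCA", "RCA_0", 50.0, 2.8, 2.2, "LV"),
            Segment("LAD_0", "LAD", None, 80.0, 3.8, 3.0),
            Segment("LAD_1", "LAD", "LAD_0", 40.0, 2.8, 2.2),
            Segment("LAD_2", "LAD", "LAD_0", 30.0, 2.6, 2.0),
            Segment("LCX_0", "LCX", None, 70.0, 3.2, 2.6),
        ],
    )


@pytest.fixture
def synthetic_tree():
    return generate_tree(TreeGenParams(seed=7))
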