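import pytest
from hypothesis import HealthCheck, settings

from spinegrader import phantom
from spinegrader.phantom import PhantomSpec, SegmentPathology

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: Published confusion counts (TP, TN, FP, FN) per pathology; n = 888
#: segments (1036 for nerve-root compression).
TABLE1_COUNTS = {
    "herniation": (58, 713, 98, 19),
    "extrusion": (41, 727, 115, 5),
    "stenosis": (27, 844, 9, 8),
    "bulging": (69, 602, 153, 64),
    "nerve_root_compression": (42, 896, 81, 17),
    "spondylolisthesis": (16, 762, 106, 4),
}


def worked_example_spec(segment: str = "L5/S1") -> PhantomSpec:
    """The published worked example: a 6.5 mm focal herniation (extrusion),
    a broad 4 mm bulge, a 201 mm^2 dural sac and non-displaced nerve roots
    on one disc."""
    return PhantomSpec(
        study_id="worked-example",
        segments={
            segment: SegmentPathology(
                herniation_depth_mm=6.5,
                dome_base_ratio=1.5,
                bulge_depth_mm=4.0,
                bulge_width_deg=150.0,
                dural_sac_area_mm2=201.0,
            )
        },
    )


@pytest.fixture(scope="session")
def healthy_study():
    study, truth = phantom.generate_study(PhantomSpec(study_id="healthy"))
    return study, truth


@pytest.fixture(scope="session")
def worked_example_study():
    study, truth = phantom.generate_study(worked_example_spec())
    return study, truth
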