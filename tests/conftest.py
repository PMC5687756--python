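import pytest
from hypothesis import settings

import oystervid as ov

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def ref_design() -> ov.SurveyDesign:
    return ov.reference_design()


@pytest.fixture(scope="session")
def ref_vc() -> ov.VarianceComponents:
    return ov.reference_variance_components()


@pytest.fixture(scope="session")
def gaussian_readings(ref_design, ref_vc):
    """One gaussian-vc dataset at the reference design, fixed seed."""
    cfg = ov.GeneratorConfig(
        mode="gaussian-vc", grand_mean=10.0, vc=ref_vc, seed=20240101
    )
    return ov.generate_vc_dataset(ref_design, cfg)


@pytest.fixture(scope="session")
def mechanistic_survey(ref_design):
    """One mechanistic survey (truth, readings, matched oysters) from the
    study-emulation preset, fixed seed."""
    cfg = ov.reference_generator_config(seed=77)
    truth = ov.generate_field_truth(ref_design, cfg)
    readings, oysters = ov.generate_video_observations(truth, ref_design, cfg)
    return truth, readings, oysters
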