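"""Shared fixtures: one default synthetic cohort run through the pipeline stages."""

import pytest

import trajdope as td
from trajdope.fusion import block_to_matrix, fuse


@pytest.fixture(scope="session")
def default_panel():
    """Default study-emulating cohort (2x7 subjects, 4 days, 68 analytes)."""
    return td.generate_cohort(td.default_design(seed=1))


@pytest.fixture(scope="session")
def filtered_panel(default_panel):
    panel, dropped = td.lod_filter(default_panel, 0.5)
    assert len(dropped) == 5
    return panel


@pytest.fixture(scope="session")
def gta_panel(filtered_panel):
    return td.GtaTransformer().fit_transform(filtered_panel)


@pytest.fixture(scope="session")
def fused_all(gta_panel):
    return fuse(
        [block_to_matrix(gta_panel, b) for b in ("CBC", "STEROID", "ENDOCRINE")]
    )


def fused_for(seed: int, effect_scale: float, n_per_arm: int = 7,
              blocks=("CBC", "STEROID", "ENDOCRINE")):
    """Generate -> LOD filter -> GTA -> fuse, for one seeded cohort."""
    design = td.default_design(seed=seed, effect_scale=effect_scale)
    design.n_subjects_per_arm = n_per_arm
    panel, _ = td.lod_filter(td.generate_cohort(design))
    gta = td.GtaTransformer().fit_transform(panel)
    return fuse([block_to_matrix(gta, b) for b in blocks])
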