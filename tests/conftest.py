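import pytest

from chronet import (
    CohortSpec,
    ClassifierConfig,
    Contrast,
    generate_edge_level_cohort,
    random_planted_edges,
)


@pytest.fixture
def small_edge_cohort():
    """11-subject, 8-ROI edge-level cohort with a moderate planted effect."""
    spec = CohortSpec(
        n_ecp=5, n_lcp=6, n_rois=8,
        planted_edges=random_planted_edges(8, 5, seed=1),
        effect_size=0.4, subject_sd=0.12, seed=2,
    )
    return generate_edge_level_cohort(spec)


@pytest.fixture
def null_edge_cohort():
    """13-subject, 8-ROI edge-level cohort with no group difference."""
    spec = CohortSpec(
        n_ecp=6, n_lcp=7, n_rois=8,
        planted_edges=frozenset(), effect_size=0.0, subject_sd=0.15, seed=9,
    )
    return generate_edge_level_cohort(spec)


@pytest.fixture
def fast_cfg():
    return ClassifierConfig(contrast=Contrast.ECP_GT_LCP, n_perm=100, seed=3)
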