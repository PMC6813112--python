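"""Shared fixtures: a synthetic cell-type reference and paired cohorts."""

import pytest

from tnfblood import celltype, diffexpr, reference, simulate


@pytest.fixture(scope="session")
def ref600():
    """Reference with 600 genes, half of them designed markers (50/cell type)."""
    return reference.generate_reference(600, marker_fraction=0.5, seed=1)


@pytest.fixture(scope="session")
def scores600(ref600):
    return celltype.specificity_scores(ref600)


@pytest.fixture(scope="session")
def marker_sets600(scores600):
    return celltype.build_marker_sets(scores600)


@pytest.fixture(scope="session")
def cohort_pair(ref600):
    """Two default-condition cohorts matching the study's sample sizes."""
    p1 = simulate.GeneratorParams(
        n_subjects_gr=19, n_subjects_nr=21, cohort="C1", seed=41
    )
    p2 = simulate.GeneratorParams(
        n_subjects_gr=21, n_subjects_nr=15, cohort="C2", seed=42
    )
    return simulate.generate_cohort(p1, ref600), simulate.generate_cohort(p2, ref600)


@pytest.fixture(scope="session")
def mo3_spec():
    return diffexpr.DesignSpec(contrast="MO3-BL", paired=True)


@pytest.fixture(scope="session")
def gr_spec():
    return diffexpr.DesignSpec(contrast="GR-NR", paired=False)
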