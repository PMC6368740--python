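import pytest

from oncoamp.synthetic_data import CohortSpec, generate_cohort, toy_panel
from oncoamp.variant_io import attach_annotations


@pytest.fixture(scope="session")
def panel():
    return toy_panel()


@pytest.fixture(scope="session")
def solid_cohort():
    """46-sample solid-tumor cohort with planted truth classes."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def solid_calls(solid_cohort):
    """The cohort's calls with annotations attached (cascade-ready)."""
    return attach_annotations(solid_cohort.calls, solid_cohort.annotations)


@pytest.fixture(scope="session")
def ctdna_cohort():
    """14-draw ctDNA cohort (7 patients x 2 draws) with matched germline."""
    return generate_cohort(
        CohortSpec(
            n_samples=14,
            cohort="ctdna",
            recurrence_threshold=4,
            n_germline_shared=3,
            n_hypermutated=1,
            hypermutated_burden=13.0,
            mean_somatic_per_sample=1.5,
            somatic_af_range=(0.01, 0.90),
            seed=23,
        )
    )


@pytest.fixture(scope="session")
def ctdna_calls(ctdna_cohort):
    return attach_annotations(ctdna_cohort.calls, ctdna_cohort.annotations)
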