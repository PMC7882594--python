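import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from famseq.model import AnnotationProfile, Individual, Pedigree
from famseq.pipeline import RunConfig, run_cascade
from famseq.synthetic_cohort import CohortSpec, generate_cohort


def make_trio(family_id: str = "FAM1", child_affected: bool = True,
              parents_affected=(True, False)) -> Pedigree:
    """Founder couple + one child."""
    return Pedigree([
        Individual("DAD", family_id, None, None, "male",
                   "affected" if parents_affected[0] else "unaffected"),
        Individual("MOM", family_id, None, None, "female",
                   "affected" if parents_affected[1] else "unaffected"),
        Individual("KID", family_id, "DAD", "MOM", "male",
                   "affected" if child_affected else "unaffected"),
    ])


def profile(**kwargs) -> AnnotationProfile:
    return AnnotationProfile(**kwargs)


@pytest.fixture(scope="session")
def cohort1():
    """Default study-scale cohort, seed 1 (shared across tests)."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def result1(cohort1):
    """Default cascade run on the seed-1 cohort."""
    return run_cascade(cohort1.variants, cohort1.pedigree,
                       cohort1.cnv_segments, cohort1.gene_models, RunConfig())
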