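import pytest

from vkorcall.pipeline import run_pipeline_files
from vkorcall.references import load_catalogue
from vkorcall.synth import build_fixture_spec, generate_cohort, make_pseudo_references


@pytest.fixture(scope="session")
def catalogue():
    return load_catalogue()


@pytest.fixture(scope="session")
def references(catalogue):
    return make_pseudo_references(catalogue)


@pytest.fixture(scope="session")
def fixture_cohort(tmp_path_factory, catalogue, references):
    """The study-shaped 67-animal cohort, materialised once per session."""
    spec = build_fixture_spec(seed=7)
    return generate_cohort(spec, references, catalogue, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def fixture_result(fixture_cohort, references, catalogue):
    """Full pipeline run (with COI species identification) on the fixture."""
    return run_pipeline_files(
        sorted(fixture_cohort.exon_fastas.values()),
        references,
        catalogue,
        coi_fasta=fixture_cohort.coi_fasta,
        panel_fasta=fixture_cohort.panel_fasta,
    )
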