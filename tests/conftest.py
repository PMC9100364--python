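import pytest

from cypmine import bgc, ferredoxin, mining, nomenclature, synth


@pytest.fixture(scope="session")
def references():
    return synth.builtin_references()


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort (seeded; shared across the session)."""
    return synth.generate_cohort()


@pytest.fixture(scope="session")
def pipeline(cohort):
    """Full pipeline outputs on the default cohort."""
    proteins = cohort.all_proteins()
    candidates = mining.screen_proteome(proteins)
    annotations = nomenclature.annotate(candidates, cohort.references)
    fdx_annotations, ambiguous = ferredoxin.annotate_ferredoxins(proteins)
    links = bgc.find_p450s_in_clusters(cohort.clusters, cohort.references)
    return {
        "proteins": proteins,
        "candidates": candidates,
        "annotations": annotations,
        "fdx_annotations": fdx_annotations,
        "fdx_ambiguous": ambiguous,
        "links": links,
    }
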