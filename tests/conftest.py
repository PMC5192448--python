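import numpy as np
import pytest

from fatlabel import (
    EnrichmentModel,
    FattyAcidSpec,
    IsotopeTable,
    SimScenario,
    build_correction_matrix,
    carboxylate_anion_formula,
    make_fixture_suite,
    parse_fatty_acid_name,
)


@pytest.fixture(scope="session")
def fa_183():
    return parse_fatty_acid_name("C18:3n3")


@pytest.fixture(scope="session")
def natural_table():
    return IsotopeTable.natural()


@pytest.fixture(scope="session")
def mono_table():
    return IsotopeTable.monoisotopic()


@pytest.fixture(scope="session")
def cm_183(fa_183, natural_table):
    return build_correction_matrix(carboxylate_anion_formula(fa_183), natural_table)


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The canonical simulated chromatogram fixtures plus their manifest."""
    outdir = tmp_path_factory.mktemp("fixtures")
    manifest = make_fixture_suite(outdir, seed=0)
    return outdir, manifest


def shift_scenario(fa, labeling=0.5, shift_s_per_label=4.2 / 18.0, **kwargs):
    """A single-fatty-acid scenario used across integration tests."""
    em = EnrichmentModel(
        kind="two_pool", labeled_fraction=labeling / 0.95, p_per_carbon=0.95
    )
    spec = FattyAcidSpec(
        fatty_acid=fa, enrichment=em, abundance=1.0e6, apex_rt_min=30.0
    )
    return SimScenario(
        fatty_acids=[spec], rt_shift_s_per_label=shift_s_per_label, **kwargs
    )
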