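import pytest

from comorbex.kb import build_enriched_kb
from comorbex.synthetic import build_paper_fixture, fixture_objects


@pytest.fixture(scope="session")
def ent():
    return fixture_objects("ent")


@pytest.fixture(scope="session")
def general():
    return fixture_objects("general")


@pytest.fixture(scope="session")
def hyperkalemia():
    return fixture_objects("hyperkalemia")


@pytest.fixture(scope="session")
def kb_paper():
    return fixture_objects("kb_paper")


@pytest.fixture(scope="session")
def ent_ekb(ent):
    return build_enriched_kb(ent["drugs"], ent["comorbidity_list"])


@pytest.fixture(scope="session")
def general_ekb(general):
    return build_enriched_kb(general["drugs"], general["comorbidity_list"])


@pytest.fixture(scope="session")
def hyperkalemia_ekb(hyperkalemia):
    return build_enriched_kb(hyperkalemia["drugs"], hyperkalemia["comorbidity_list"])


@pytest.fixture(scope="session")
def ent_dir(tmp_path_factory):
    return build_paper_fixture("ent", tmp_path_factory.mktemp("ent"))
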