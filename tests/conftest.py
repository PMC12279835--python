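import pytest

import fishrisk as fr

NJ = "Nemipterus japonicus"
OM = "Oreochromis mossambicus"
LN = "Lates niloticus"


@pytest.fixture(scope="session")
def fixture_ds() -> fr.StudyDataset:
    return fr.load_fixture()


@pytest.fixture(scope="session")
def refs() -> fr.ReferenceValueSet:
    return fr.ReferenceValueSet.defaults()


@pytest.fixture(scope="session")
def published() -> dict:
    return {name: fr.load_published_table(name)
            for name in ("exposure", "limits", "risk", "hazard_index")}
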