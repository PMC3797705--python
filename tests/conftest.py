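import pytest

from methyltext.extract import annotate_document
from methyltext.synth import toy_dictionaries

# The canonical worked scoring example: one pattern (MIR203, methylated,
# multiple myeloma) occurring in two orders.
MIR203_TEXT = (
    "Promoter of MIR203 was found methylated in approximately 25% "
    "multiple myeloma cell lines but not methylated in normal controls"
)


@pytest.fixture(scope="session")
def toy_dicts():
    return toy_dictionaries()


@pytest.fixture()
def mir203_sentence(toy_dicts):
    sentences, _ = annotate_document("pm0", MIR203_TEXT, toy_dicts)
    assert len(sentences) == 1
    return sentences[0]
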