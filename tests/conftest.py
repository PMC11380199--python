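import pytest
from hypothesis import settings

from maveinfo import EvidenceOddsTable, FunctionalClassMap, VariantEvidenceRecord

settings.register_profile("repro", derandomize=True, max_examples=60)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def table():
    return EvidenceOddsTable()


@pytest.fixture()
def brca1_records():
    """The two worked BRCA1 examples: both absent from population databases
    (PM2_supporting baseline), one functionally normal (BS3), one loss of
    function (PS3)."""
    return [
        VariantEvidenceRecord(
            "BRCA1 c.5120T>C",
            gene="BRCA1",
            prior=0.1,
            baseline_codes=("PM2_supporting",),
            mave_code="BS3",
            is_vus=True,
        ),
        VariantEvidenceRecord(
            "BRCA1 c.5288G>T",
            gene="BRCA1",
            prior=0.1,
            baseline_codes=("PM2_supporting",),
            mave_code="PS3",
            is_vus=True,
        ),
    ]


@pytest.fixture(scope="session")
def tp53_class_map():
    """Functional-class weights used for the TP53 classifier output."""
    return FunctionalClassMap(normal="BM", abnormal="PS")
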