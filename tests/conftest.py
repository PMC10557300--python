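import pytest

from latentneeds.corpus import Corpus, Record
from latentneeds.morphology import FixtureTokenizer


@pytest.fixture
def analyzer():
    return FixtureTokenizer()


def make_record(record_id, text="", role="caregiver", **kw):
    return Record(record_id=record_id, role=role, text=text, **kw)


@pytest.fixture
def tagged_corpus():
    """Six labelled records in fixture (surface/POS) format."""
    recs = [
        make_record("r1", "犬/名詞 が/助詞 走る/動詞 公園/名詞", label="yes"),
        make_record("r2", "犬/名詞 猫/名詞 いい/形容詞", label="yes"),
        make_record("r3", "公園/名詞 散歩/名詞", label="yes"),
        make_record("r4", "猫/名詞 が/助詞 鳴く/動詞", label="no"),
        make_record("r5", "天気/名詞 雨/名詞 雨/名詞", label="no"),
        make_record("r6", "散歩/名詞 天気/名詞", label="no"),
    ]
    return Corpus(records=recs)
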