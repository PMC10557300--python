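"""Record/corpus I-O, marker annotation and label reconciliation."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentneeds.corpus import (
    Corpus,
    CorpusError,
    MarkerLexicon,
    Record,
    annotate_markers,
    read_corpus,
    reconcile_labels,
    write_corpus,
)

from conftest import make_record


# -- construction invariants -------------------------------------------------

def test_duplicate_record_id_rejected():
    with pytest.raises(CorpusError, match="dup-1"):
        Corpus(records=[make_record("dup-1"), make_record("dup-1")])


def test_unknown_role_rejected():
    with pytest.raises(CorpusError, match="role"):
        Record(record_id="x", role="doctor", text="t")


def test_label_must_be_yes_or_no():
    with pytest.raises(CorpusError, match="label"):
        Record(record_id="x", role="patient", text="t", label="maybe")


# -- file I/O ---------------------------------------------------------------

def test_read_jsonl_two_lines(tmp_path):
    p = tmp_path / "c.jsonl"
    p.write_text(
        json.dumps({"record_id": "a", "role": "patient", "text": "こんにちは"})
        + "\n"
        + json.dumps({"record_id": "b", "role": "caregiver", "text": "はい", "label": "yes"})
        + "\n",
        encoding="utf-8",
    )
    corpus = read_corpus(p)
    assert [r.record_id for r in corpus] == ["a", "b"]
    assert corpus["a"].label is None
    assert corpus["b"].label == "yes"


def test_malformed_jsonl_names_line(tmp_path):
    p = tmp_path / "c.jsonl"
    p.write_text('{"record_id": "a", "role": "patient", "text": "x"}\n{broken\n')
    with pytest.raises(CorpusError, match="line 2"):
        read_corpus(p)


def test_duplicate_id_in_file_names_id(tmp_path):
    p = tmp_path / "c.jsonl"
    line = json.dumps({"record_id": "same", "role": "patient", "text": "x"})
    p.write_text(line + "\n" + line + "\n")
    with pytest.raises(CorpusError, match="same"):
        read_corpus(p)


def test_unset_label_not_serialized_as_no(tmp_path):
    corpus = Corpus(records=[make_record("a")])
    p = tmp_path / "c.csv"
    write_corpus(corpus, p)
    raw = p.read_text(encoding="utf-8")
    assert '"no"' not in raw
    assert read_corpus(p)["a"].label is None


records_strategy = st.lists(
    st.builds(
        Record,
        record_id=st.uuids().map(str),
        role=st.sampled_from(["patient", "caregiver"]),
        text=st.text(
            alphabet=st.characters(
                codec="utf-8", exclude_characters="\r\n\x00", exclude_categories=("Cs",)
            ),
            max_size=40,
        ),
        marker_flag=st.one_of(st.none(), st.booleans()),
        label=st.one_of(st.none(), st.sampled_from(["yes", "no"])),
    ),
    min_size=1,
    max_size=8,
    unique_by=lambda r: r.record_id,
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(records=records_strategy, fmt=st.sampled_from(["jsonl", "csv"]))
def test_round_trip_is_identity(tmp_path_factory, records, fmt):
    """write_corpus then read_corpus preserves every field in both formats."""
    corpus = Corpus(records=records)
    path = tmp_path_factory.mktemp("rt") / f"c.{fmt}"
    write_corpus(corpus, path)
    back = read_corpus(path)
    assert [
        (r.record_id, r.role, r.text, r.marker_flag, r.label) for r in back
    ] == [(r.record_id, r.role, r.text, r.marker_flag, r.label) for r in corpus]


# -- marker lexicon and annotation ------------------------------------------

def test_lexicon_from_file_skips_comments(tmp_path):
    p = tmp_path / "lex.txt"
    p.write_text("やっぱり\n# comment\nいい  # trailing\n\n", encoding="utf-8")
    assert MarkerLexicon.from_file(p).markers == ("やっぱり", "いい")


def test_lexicon_rejects_duplicates():
    with pytest.raises(CorpusError):
        MarkerLexicon(markers=("いい", "いい"))


@pytest.mark.parametrize(
    "text,expected",
    [
        ("やっぱり それ が ほしい", True),   # expectation adverb present
        ("", False),                          # empty text never flags
        ("あるといい と 思う", True),         # contains 'いい' inside a longer marker
        ("ただ の 文", False),
    ],
)
def test_marker_flagging(text, expected):
    corpus = Corpus(records=[make_record("a", text)])
    out = annotate_markers(corpus)
    assert out["a"].marker_flag is expected
    assert out["a"].text == text  # text unmodified


def test_annotation_idempotent_and_monotone():
    corpus = Corpus(records=[make_record("a", "やはり そう"), make_record("b", "別 の 話")])
    once = annotate_markers(corpus)
    twice = annotate_markers(once)
    assert [r.marker_flag for r in once] == [r.marker_flag for r in twice]
    # adding a marker to the lexicon never unsets a flag
    bigger = MarkerLexicon(markers=MarkerLexicon().markers + ("別",))
    out = annotate_markers(corpus, bigger)
    for r_small, r_big in zip(once, out):
        assert not (r_small.marker_flag and not r_big.marker_flag)


# -- reconciliation ----------------------------------------------------------

def test_reconcile_agreement_and_disagreement():
    recs = [
        make_record("agree", annotator_labels=(("a1", "yes"), ("a2", "yes"))),
        make_record("clash", annotator_labels=(("a1", "yes"), ("a2", "no"))),
        make_record("blank"),
    ]
    out, report = reconcile_labels(Corpus(records=recs))
    assert out["agree"].label == "yes"
    assert out["clash"].label is None
    assert [d["record_id"] for d in report.disagreements] == ["clash"]
    assert report.unlabelled == ["blank"]


def test_reconcile_counts_planted_disagreements():
    recs = []
    for i in range(10):
        labels = (("a1", "yes"), ("a2", "no" if i in (2, 5, 7) else "yes"))
        recs.append(make_record(f"r{i}", annotator_labels=labels))
    _out, report = reconcile_labels(Corpus(records=recs))
    assert len(report) == 3
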