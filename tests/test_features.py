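"""TF-IDF dialects, balanced undersampling and the 70/30 split."""

import math
from collections import namedtuple

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentneeds.features import (
    DataSplit,
    TfidfModel,
    count_matrix,
    read_matrix,
    split,
    tfidf,
    undersample,
    write_matrix,
)

from conftest import make_record

Row = namedtuple("Row", ["record_id", "label"])


def rows(n_yes, n_no):
    return [Row(f"y{i}", "yes") for i in range(n_yes)] + [
        Row(f"n{i}", "no") for i in range(n_no)
    ]


# -- TF-IDF ------------------------------------------------------------------

def test_smooth_variant_matches_hand_computation(analyzer):
    """d1=[a,a,b], d2=[b]: unnormalized d1 = (2*(ln(3/2)+1), 1), L2-normalized."""
    recs = [
        make_record("d1", "a/名詞 a/名詞 b/名詞", label="yes"),
        make_record("d2", "b/名詞", label="no"),
    ]
    m = tfidf(recs, ["a", "b"], analyzer, variant="smooth")
    w_a = 2 * (math.log(3 / 2) + 1)  # idf(a): df=1, N=2
    w_b = 1.0                        # idf(b): df=2 -> ln(3/3)+1 = 1
    norm = math.hypot(w_a, w_b)
    d1 = m.weights.toarray()[m.record_ids.index("d1")]
    assert d1[m.vocabulary.index("a")] == pytest.approx(w_a / norm)
    assert d1[m.vocabulary.index("b")] == pytest.approx(w_b / norm)
    assert np.linalg.norm(d1) == pytest.approx(1.0)


def test_raw_variant_ubiquitous_term_weighs_zero(analyzer):
    recs = [
        make_record("d1", "a/名詞 b/名詞", label="yes"),
        make_record("d2", "a/名詞", label="no"),
    ]
    m = tfidf(recs, ["a", "b"], analyzer, variant="raw")
    col_a = m.vocabulary.index("a")
    assert m.weights.toarray()[:, col_a] == pytest.approx([0.0, 0.0])
    # b: tf 1 in d1 only, idf = ln(2/1)
    assert m.weights.toarray()[0, m.vocabulary.index("b")] == pytest.approx(math.log(2))


def test_out_of_vocabulary_record_gets_zero_row(analyzer):
    recs = [
        make_record("d1", "a/名詞", label="yes"),
        make_record("d2", "zzz/名詞", label="no"),
        make_record("d3", "", label="no"),
    ]
    m = tfidf(recs, ["a"], analyzer)
    arr = m.weights.toarray()
    assert arr[1].sum() == 0 and arr[2].sum() == 0


def test_tfidf_monotone_in_term_count(analyzer):
    base = [
        make_record("d1", "a/名詞 b/名詞", label="yes"),
        make_record("d2", "b/名詞", label="no"),
    ]
    more = [
        make_record("d1", "a/名詞 a/名詞 b/名詞", label="yes"),
        make_record("d2", "b/名詞", label="no"),
    ]
    vocab = ["a", "b"]
    for variant in ("smooth", "raw"):
        model = TfidfModel(vocabulary=vocab, variant=variant, unit="nouns").fit(
            base, analyzer
        )
        # unnormalized weights: counts x idf (df unchanged between corpora)
        c1 = count_matrix(base, vocab, analyzer)
        c2 = count_matrix(more, vocab, analyzer)
        w1 = c1.multiply(model.idf_).toarray()
        w2 = c2.multiply(model.idf_).toarray()
        assert w2[0, 0] >= w1[0, 0]


def test_empty_vocabulary_rejected(analyzer):
    with pytest.raises(ValueError, match="vocabulary"):
        tfidf([make_record("d1", "a/名詞", label="yes")], [], analyzer)


def test_strict_fit_transform_reuses_training_idf(analyzer):
    train = [
        make_record("t1", "a/名詞 b/名詞", label="yes"),
        make_record("t2", "b/名詞", label="no"),
    ]
    test = [make_record("u1", "a/名詞 a/名詞", label="yes")]
    model = TfidfModel(vocabulary=["a", "b"], variant="raw", unit="nouns").fit(
        train, analyzer
    )
    out = model.transform(test, analyzer)
    # idf of 'a' from the training fold: ln(2/1)
    assert out.weights.toarray()[0, 0] == pytest.approx(2 * math.log(2))


# -- undersampling -----------------------------------------------------------

@pytest.mark.parametrize(
    "n_yes,n_no,expected",
    [(343, 7231, 686), (63, 2010, 126), (5, 5, 10)],
)
def test_undersample_sizes_match_study_strata(n_yes, n_no, expected):
    out = undersample(rows(n_yes, n_no), seed=0)
    assert len(out) == expected
    assert sum(r.label == "yes" for r in out) == sum(r.label == "no" for r in out)


def test_undersample_keeps_every_minority_record():
    data = rows(4, 30)
    out = undersample(data, seed=11)
    assert {r.record_id for r in out if r.label == "yes"} == {f"y{i}" for i in range(4)}
    assert len({r.record_id for r in out}) == len(out)  # no duplicates


def test_undersample_deterministic_and_seed_sensitive():
    data = rows(10, 200)
    a = [r.record_id for r in undersample(data, seed=5)]
    b = [r.record_id for r in undersample(data, seed=5)]
    c = [r.record_id for r in undersample(data, seed=6)]
    assert a == b
    assert a != c


def test_undersample_requires_both_classes():
    with pytest.raises(ValueError):
        undersample(rows(5, 0), seed=0)


# -- splitting ---------------------------------------------------------------

@pytest.mark.parametrize(
    "n_per_class,expected_train,expected_test",
    [(343, 480, 206), (63, 88, 38), (5, 6, 4)],
)
def test_split_counts_follow_ceiling_rule(n_per_class, expected_train, expected_test):
    data = rows(n_per_class, n_per_class)
    ds = split(data, train_fraction=0.7, seed=0)
    assert (len(ds.train), len(ds.test)) == (expected_train, expected_test)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n_yes=st.integers(min_value=2, max_value=40),
    n_no=st.integers(min_value=2, max_value=40),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
    frac=st.sampled_from([0.5, 0.6, 0.7, 0.8]),
)
def test_split_partition_invariants(n_yes, n_no, seed, frac):
    """Split partitions the input with per-class ceiling test counts."""
    data = rows(n_yes, n_no)
    ds = split(data, train_fraction=frac, seed=seed)
    assert set(ds.train) | set(ds.test) == {r.record_id for r in data}
    assert not (set(ds.train) & set(ds.test))
    by_label = {r.record_id: r.label for r in data}
    for label, n in (("yes", n_yes), ("no", n_no)):
        n_test = sum(by_label[i] == label for i in ds.test)
        assert n_test == math.ceil((1 - frac) * n)
    # a different seed permutes membership, never the counts
    other = split(data, train_fraction=frac, seed=seed + 1)
    assert (len(other.train), len(other.test)) == (len(ds.train), len(ds.test))


def test_split_rejects_tiny_class():
    with pytest.raises(ValueError, match="fewer than 2"):
        split(rows(1, 10), seed=0)


def test_split_overlap_rejected():
    with pytest.raises(ValueError):
        DataSplit(train=["a"], test=["a"], train_fraction=0.7, seed=0)


# -- serialization -----------------------------------------------------------

def test_matrix_mtx_round_trip(tmp_path, analyzer):
    recs = [
        make_record("d1", "a/名詞 a/名詞 b/名詞", label="yes"),
        make_record("d2", "b/名詞", label="no"),
    ]
    m = tfidf(recs, ["a", "b"], analyzer)
    write_matrix(m, tmp_path / "mat")
    back = read_matrix(tmp_path / "mat")
    assert back.record_ids == m.record_ids
    assert back.vocabulary == m.vocabulary
    assert back.labels == m.labels
    assert np.allclose(back.weights.toarray(), m.weights.toarray())
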