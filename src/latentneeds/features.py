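"""TF-IDF vectorization, balanced undersampling and the train/test split.

The vectorizer supports two dialects.  ``smooth`` (default) is the
de-facto standard used by common ML libraries:

    w(t, d) = tf(t, d) * ( ln((1 + N) / (1 + df(t))) + 1 ),  rows L2-normalized

``raw`` is the literal "term frequency times inverse document frequency"
reading: w = tf * ln(N / df), no normalization, and a term absent from
every document gets idf 0 (its tf is 0 everywhere anyway).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer

from .corpus import Record
from .morphology import morpheme_keys, tokenize

logger = logging.getLogger(__name__)

TFIDF_VARIANTS = ("smooth", "raw")


@dataclass
class DocTermMatrix:
    """Records x selected-vocabulary weight matrix with aligned labels."""

    record_ids: list[str]
    vocabulary: list[str]
    weights: sp.csr_matrix
    labels: list[Optional[str]]

    def __post_init__(self) -> None:
        if self.weights.shape != (len(self.record_ids), len(self.vocabulary)):
            raise ValueError("weight matrix shape does not match ids/vocabulary")
        if len(self.labels) != len(self.record_ids):
            raise ValueError("labels misaligned with record ids")
        if (self.weights.data < 0).any():
            raise ValueError("weights must be nonnegative")

    @property
    def vocabulary_fingerprint(self) -> str:
        joined = "\x1f".join(self.vocabulary).encode("utf-8")
        return hashlib.sha256(joined).hexdigest()

    def restrict(self, record_ids: Sequence[str]) -> "DocTermMatrix":
        """Row-subset the matrix to the given record ids, in their order."""
        index = {rid: i for i, rid in enumerate(self.record_ids)}
        rows = [index[r] for r in record_ids]
        return DocTermMatrix(
            record_ids=list(record_ids),
            vocabulary=list(self.vocabulary),
            weights=self.weights[rows],
            labels=[self.labels[i] for i in rows],
        )


def count_matrix(
    records: Sequence[Record], vocabulary: Sequence[str], analyzer, unit: str = "nouns"
) -> sp.csr_matrix:
    """Token counts per record over a fixed, ordered vocabulary."""
    col = {t: j for j, t in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for i, rec in enumerate(records):
        seen: dict[int, int] = {}
        for key in morpheme_keys(tokenize(rec.text, analyzer), unit=unit):
            j = col.get(key)
            if j is not None:
                seen[j] = seen.get(j, 0) + 1
        for j, c in seen.items():
            rows.append(i)
            cols.append(j)
            data.append(c)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(records), len(vocabulary)), dtype=float
    )


@dataclass
class TfidfModel:
    """A fitted idf, reusable to transform held-out records.

    Fitting on the full corpus before splitting mirrors the original
    method order ("faithful" mode); fitting on the training fold
    only and transforming the test fold is the leakage-free alternative.
    """

    vocabulary: list[str]
    variant: str
    unit: str
    _transformer: Optional[TfidfTransformer] = field(default=None, repr=False)
    idf_: Optional[np.ndarray] = field(default=None, repr=False)

    def fit(self, records: Sequence[Record], analyzer) -> "TfidfModel":
        if not self.vocabulary:
            raise ValueError("kept vocabulary is empty")
        if self.variant not in TFIDF_VARIANTS:
            raise ValueError(f"unknown tfidf variant {self.variant!r}")
        counts = count_matrix(records, self.vocabulary, analyzer, self.unit)
        if self.variant == "smooth":
            self._transformer = TfidfTransformer(
                norm="l2", smooth_idf=True, sublinear_tf=False
            ).fit(counts)
            self.idf_ = self._transformer.idf_
        else:
            n = counts.shape[0]
            df = np.asarray((counts > 0).sum(axis=0)).ravel()
            with np.errstate(divide="ignore"):
                idf = np.log(n / df)
            idf[df == 0] = 0.0
            self.idf_ = idf
        return self

    def transform(self, records: Sequence[Record], analyzer) -> DocTermMatrix:
        if self.idf_ is None:
            raise ValueError("TfidfModel is not fitted")
        counts = count_matrix(records, self.vocabulary, analyzer, self.unit)
        if self.variant == "smooth":
            weights = self._transformer.transform(counts)
        else:
            weights = counts.multiply(self.idf_)
        weights = sp.csr_matrix(weights)
        zero_rows = int((abs(weights).sum(axis=1) == 0).sum())
        if zero_rows:
            logger.info(
                "%d record(s) share no term with the vocabulary (zero rows)",
                zero_rows,
            )
        return DocTermMatrix(
            record_ids=[r.record_id for r in records],
            vocabulary=list(self.vocabulary),
            weights=weights,
            labels=[r.label for r in records],
        )


def tfidf(
    records: Sequence[Record],
    kept_vocabulary: Sequence[str],
    analyzer,
    variant: str = "smooth",
    unit: str = "nouns",
) -> DocTermMatrix:
    """Fit-and-transform TF-IDF on one record set (see module docstring)."""
    vocab = sorted(kept_vocabulary)
    model = TfidfModel(vocabulary=vocab, variant=variant, unit=unit)
    return model.fit(records, analyzer).transform(records, analyzer)


# ---------------------------------------------------------------------------
# Sampling and splitting

def undersample(records: Sequence[Record], seed: int) -> list[Record]:
    """Balance classes by random undersampling of the majority class.

    Every minority-class record is kept; an equal-size uniform random
    subset (without replacement) of the majority class is kept.  Output
    preserves the original record order and has size 2 x minority count.
    """
    yes = [r for r in records if r.label == "yes"]
    no = [r for r in records if r.label == "no"]
    if not yes or not no:
        raise ValueError("undersampling requires both classes to be present")
    minority, majority = (yes, no) if len(yes) <= len(no) else (no, yes)
    rng = np.random.default_rng(seed)
    chosen_idx = rng.choice(len(majority), size=len(minority), replace=False)
    chosen = {majority[i].record_id for i in chosen_idx}
    keep = {r.record_id for r in minority} | chosen
    return [r for r in records if r.record_id in keep]


@dataclass
class DataSplit:
    """Disjoint train/test record-id partition."""

    train: list[str]
    test: list[str]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test overlap")


def split(
    records: Sequence[Record],
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> DataSplit:
    """Seeded train/test split with per-class ceiling rounding.

    Per class (when stratified), the test fold receives
    ``ceil((1 - train_fraction) * class_size)`` records chosen uniformly
    at random; the remainder trains.  This rounding reproduces a 70/30
    split of 686 balanced records as 480/206 and of 126 as 88/38.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    groups: dict[Optional[str], list[str]]
    if stratified:
        groups = {}
        for r in records:
            groups.setdefault(r.label, []).append(r.record_id)
    else:
        groups = {None: [r.record_id for r in records]}
    train: list[str] = []
    test: list[str] = []
    for label, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(
                f"class {label!r} has fewer than 2 records; cannot split"
            )
        # round at 9 dp before the ceiling so 0.3 * 10 is 3, not ceil(3.0000000004)
        n_test = math.ceil(round((1.0 - train_fraction) * len(ids), 9))
        perm = rng.permutation(len(ids))
        test.extend(ids[i] for i in sorted(perm[:n_test]))
        train.extend(ids[i] for i in sorted(perm[n_test:]))
    order = {r.record_id: i for i, r in enumerate(records)}
    train.sort(key=order.__getitem__)
    test.sort(key=order.__getitem__)
    return DataSplit(train=train, test=test, train_fraction=train_fraction, seed=seed)


# ---------------------------------------------------------------------------
# Serialization: Matrix Market plus sidecar TSVs

def write_matrix(matrix: DocTermMatrix, prefix: str | Path) -> None:
    """Write weights as MTX with ``.rows.tsv`` / ``.vocab.tsv`` sidecars."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), matrix.weights)
    with prefix.with_suffix(".rows.tsv").open("w", encoding="utf-8") as fh:
        fh.write("record_id\tlabel\n")
        for rid, lab in zip(matrix.record_ids, matrix.labels):
            fh.write(f"{rid}\t{lab or ''}\n")
    with prefix.with_suffix(".vocab.tsv").open("w", encoding="utf-8") as fh:
        for term in matrix.vocabulary:
            fh.write(term + "\n")


def read_matrix(prefix: str | Path) -> DocTermMatrix:
    prefix = Path(prefix)
    weights = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    record_ids, labels = [], []
    with prefix.with_suffix(".rows.tsv").open(encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            rid, lab = line.rstrip("\n").split("\t")
            record_ids.append(rid)
            labels.append(lab or None)
    vocabulary = prefix.with_suffix(".vocab.tsv").read_text(encoding="utf-8").splitlines()
    return DocTermMatrix(
        record_ids=record_ids, vocabulary=vocabulary, weights=weights, labels=labels
    )
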