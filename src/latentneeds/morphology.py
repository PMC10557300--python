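"""Morphological tokenization, noun extraction and per-class count tables.

Two tokenizer backends satisfy one contract (text in, ``MorphemeToken``
list out): an adapter for a real Japanese morphological analyzer (MeCab
via fugashi or mecab-python3, when installed), and a fixture tokenizer
that reads pre-tagged text of the form ``surface/POS`` or
``surface/POS/base`` separated by whitespace.  The fixture backend is
what the synthetic corpus generator emits, so the whole pipeline runs
without an installed analyzer.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NOUN_TAG = "名詞"
CLASS_TAGS = ("needs_yes", "needs_no")


class TokenizerUnavailableError(RuntimeError):
    """Requested tokenizer backend cannot be constructed."""


@dataclass(frozen=True)
class MorphemeToken:
    surface: str
    pos: str
    base: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("token surface must be non-empty")

    @property
    def key(self) -> str:
        """Morpheme key: dictionary (base) form when known, else surface.

        NFC-normalized so that width/composition variants count together.
        """
        return unicodedata.normalize("NFC", self.base or self.surface)


class FixtureTokenizer:
    """Tokenizer for pre-tagged text: whitespace-split ``surface/POS[/base]``.

    Tokens without a ``/`` are given the empty POS tag and kept, so plain
    untagged words pass through rather than erroring.
    """

    name = "fixture"

    def tokenize(self, text: str) -> list[MorphemeToken]:
        tokens = []
        for chunk in text.split():
            parts = chunk.split("/")
            if len(parts) == 1:
                tokens.append(MorphemeToken(surface=parts[0], pos=""))
            elif len(parts) == 2:
                tokens.append(MorphemeToken(surface=parts[0], pos=parts[1]))
            else:
                tokens.append(
                    MorphemeToken(surface=parts[0], pos=parts[1], base=parts[2] or None)
                )
        return tokens


class MecabTokenizer:
    """Adapter for a MeCab-based analyzer (fugashi or mecab-python3)."""

    name = "mecab"

    def __init__(self) -> None:
        try:
            import fugashi  # type: ignore

            self._tagger = fugashi.Tagger()
            self._backend = "fugashi"
        except ImportError:
            try:
                import MeCab  # type: ignore

                self._tagger = MeCab.Tagger()
                self._backend = "mecab-python3"
            except ImportError as exc:
                raise TokenizerUnavailableError(
                    "no MeCab backend installed (fugashi or mecab-python3); "
                    "use the fixture tokenizer (tokenizer='fixture') with "
                    "pre-tagged surface/POS text"
                ) from exc

    def tokenize(self, text: str) -> list[MorphemeToken]:
        tokens = []
        if self._backend == "fugashi":
            for word in self._tagger(text):
                feat = word.feature
                base = getattr(feat, "lemma", None) or None
                tokens.append(
                    MorphemeToken(surface=word.surface, pos=feat[0], base=base)
                )
        else:
            node = self._tagger.parseToNode(text)
            while node:
                if node.surface:
                    feats = node.feature.split(",")
                    base = feats[6] if len(feats) > 6 and feats[6] != "*" else None
                    tokens.append(
                        MorphemeToken(surface=node.surface, pos=feats[0], base=base)
                    )
                node = node.next
        return tokens


def get_tokenizer(name: str = "fixture"):
    """Construct a tokenizer backend by name (``fixture`` or ``mecab``)."""
    if name == "fixture":
        return FixtureTokenizer()
    if name == "mecab":
        return MecabTokenizer()
    raise ValueError(f"unknown tokenizer backend {name!r}")


def tokenize(text: str, analyzer) -> list[MorphemeToken]:
    """Tokenize text with the given backend; deterministic, '' -> []."""
    if not text:
        return []
    return analyzer.tokenize(text)


def extract_nouns(
    tokens: Sequence[MorphemeToken], noun_tag: str = NOUN_TAG
) -> list[str]:
    """Keep noun tokens (first POS field equals ``noun_tag``), in order.

    Returns morpheme keys: base form when available, else surface.
    """
    return [t.key for t in tokens if t.pos.split("-")[0].split(",")[0] == noun_tag]


def morpheme_keys(
    tokens: Sequence[MorphemeToken], unit: str = "nouns", noun_tag: str = NOUN_TAG
) -> list[str]:
    """Reduce tokens to counting keys under the configured unit."""
    if unit == "nouns":
        return extract_nouns(tokens, noun_tag)
    if unit == "all_morphemes":
        return [t.key for t in tokens]
    raise ValueError(f"unknown counting unit {unit!r}")


@dataclass
class CountTable:
    """Morpheme occurrence counts for one class of records.

    ``mu`` and ``sigma`` are the mean and standard deviation of the count
    values over the table's vocabulary — the standardization constants of
    the per-class Z-score.  ``sigma`` is the population standard deviation
    by default (``ddof=0``): the vocabulary is the complete observed
    distribution being standardized, not a sample from a larger one.
    """

    class_tag: str
    counts: dict[str, int]
    ddof: int = 0

    def __post_init__(self) -> None:
        if self.class_tag not in CLASS_TAGS:
            raise ValueError(f"class_tag must be one of {CLASS_TAGS}")
        if not self.counts:
            raise ValueError("count table has empty vocabulary")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")

    @property
    def mu(self) -> float:
        return float(np.mean(list(self.counts.values())))

    @property
    def sigma(self) -> float:
        return float(np.std(list(self.counts.values()), ddof=self.ddof))

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def merge(self, other: "CountTable") -> "CountTable":
        """Additively combine two tables of the same class."""
        if other.class_tag != self.class_tag:
            raise ValueError("cannot merge tables of different classes")
        merged = dict(self.counts)
        for k, v in other.counts.items():
            merged[k] = merged.get(k, 0) + v
        return CountTable(class_tag=self.class_tag, counts=merged, ddof=self.ddof)


_TAG_TO_LABEL = {"needs_yes": "yes", "needs_no": "no"}


def build_count_table(
    records: Iterable,
    class_tag: str,
    analyzer,
    unit: str = "nouns",
    ddof: int = 0,
) -> CountTable:
    """Aggregate morpheme occurrences over all records of one class.

    Every record must carry the label matching ``class_tag``; total counts
    equal the number of kept tokens ingested.
    """
    if class_tag not in CLASS_TAGS:
        raise ValueError(f"class_tag must be one of {CLASS_TAGS}")
    want = _TAG_TO_LABEL[class_tag]
    counts: dict[str, int] = {}
    n = 0
    for rec in records:
        n += 1
        if rec.label != want:
            raise ValueError(
                f"record {rec.record_id!r} has label {rec.label!r}, "
                f"expected {want!r} for {class_tag}"
            )
        for key in morpheme_keys(tokenize(rec.text, analyzer), unit=unit):
            counts[key] = counts.get(key, 0) + 1
    if n == 0:
        raise ValueError("no records supplied")
    if not counts:
        raise ValueError("records yielded an empty vocabulary")
    return CountTable(class_tag=class_tag, counts=counts, ddof=ddof)
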