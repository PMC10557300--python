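"""Synthetic interview corpora with the structure the pipeline assumes.

The real interview transcripts behind the original study are
access-restricted, so this generator produces corpora with the same
statistical shape: heavy class imbalance, a heavy-tailed (Zipf-like)
shared background vocabulary, a small set of class-discriminative words
whose rate is multiplied by ``effect`` in the needs class, and a large
pool of idiosyncratic words each confined to a single record — the
one-off personal expressions that motivate Z-score selection in the
first place.  Tokens are symbolic (``w00042/名詞``) in the fixture
tokenizer's tagged format; no attempt is made to model Japanese grammar.

Yes-class records additionally embed a marker adverb (tagged 副詞, so it
never enters the noun vocabulary) with configurable probability, and
no-class records with a smaller probability, so marker annotation is
exercisable end to end and imperfect as a label proxy, as in real data.

Defaults reproduce the caregiver stratum of the original study's corpus
(343 needs / 7231 no-needs records); ``patient_stratum()`` gives the
63 / 2010 counterpart.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Corpus, Record

_MARKERS = ("やっぱり", "やっぱ", "やはり", "あるといい")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate the caregiver stratum."""

    n_yes: int = 343
    n_no: int = 7231
    vocab_background: int = 1500
    vocab_discriminative: int = 20
    vocab_idiosyncratic: int = 2000
    #: relative frequency multiplier of discriminative words in the yes class
    effect: float = 3.0
    record_length_mean: float = 25.0
    record_length_dispersion: float = 5.0
    #: fraction of records given the patient role (the rest are caregivers)
    role_mix: float = 0.0
    marker_prob_yes: float = 0.9
    marker_prob_no: float = 0.05
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_yes < 1 or self.n_no < 1:
            raise ValueError("n_yes and n_no must be >= 1")
        if self.effect < 1.0:
            raise ValueError("effect must be >= 1 (multiplier on the yes class)")
        if min(self.vocab_background, self.vocab_discriminative, self.vocab_idiosyncratic) < 0:
            raise ValueError("vocabulary sizes must be >= 0")
        if self.vocab_background + self.vocab_discriminative == 0:
            raise ValueError("background and discriminative vocabularies are both empty")
        if not 0.0 <= self.role_mix <= 1.0:
            raise ValueError("role_mix must lie in [0, 1]")


def patient_stratum(**overrides) -> SynthConfig:
    """Config matching the original study's patient stratum (63 / 2010)."""
    base = dict(n_yes=63, n_no=2010, role_mix=1.0)
    base.update(overrides)
    return SynthConfig(**base)


def planted_truth(config: SynthConfig) -> list[str]:
    """The exact discriminative vocabulary planted by ``generate_corpus``.

    Deterministic from the config alone (the names do not depend on the
    random stream), so recovery tests can call it independently.
    """
    return [f"d{i:03d}" for i in range(config.vocab_discriminative)]


def _background_vocab(config: SynthConfig) -> list[str]:
    return [f"w{i:05d}" for i in range(config.vocab_background)]


def _class_distributions(config: SynthConfig):
    """Per-class token probabilities over background + discriminative words."""
    bg = np.arange(1, config.vocab_background + 1, dtype=float)
    bg_w = 1.0 / bg ** config.zipf_exponent if len(bg) else np.array([])
    # each planted word sits at twice the mean background weight so that
    # even the no-needs class sees it often enough to count reliably
    base_d = 2.0 * (bg_w.mean() if len(bg_w) else 1.0)
    d_w = np.full(config.vocab_discriminative, base_d)
    w_no = np.concatenate([bg_w, d_w])
    w_yes = np.concatenate([bg_w, d_w * config.effect])
    return w_no / w_no.sum(), w_yes / w_yes.sum()


def generate_corpus(config: SynthConfig) -> Corpus:
    """Draw a labelled, role-tagged corpus; byte-identical for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    vocab = _background_vocab(config) + planted_truth(config)
    p_no, p_yes = _class_distributions(config)

    n_total = config.n_yes + config.n_no
    labels = ["yes"] * config.n_yes + ["no"] * config.n_no
    rng.shuffle(labels)

    m, r = config.record_length_mean, config.record_length_dispersion
    lengths = np.maximum(1, rng.negative_binomial(r, r / (r + m), size=n_total))
    roles = np.where(rng.random(n_total) < config.role_mix, "patient", "caregiver")

    token_lists: list[list[str]] = []
    for i in range(n_total):
        p = p_yes if labels[i] == "yes" else p_no
        draws = rng.choice(len(vocab), size=int(lengths[i]), p=p)
        token_lists.append([f"{vocab[j]}/名詞" for j in draws])

    # idiosyncratic words: each lives in exactly one record, 1-3 occurrences
    for k in range(config.vocab_idiosyncratic):
        i = int(rng.integers(n_total))
        reps = int(rng.integers(1, 4))
        token_lists[i].extend([f"u{k:05d}/名詞"] * reps)

    records = []
    for i in range(n_total):
        toks = token_lists[i]
        prob = config.marker_prob_yes if labels[i] == "yes" else config.marker_prob_no
        if rng.random() < prob:
            marker = _MARKERS[int(rng.integers(len(_MARKERS)))]
            pos = int(rng.integers(len(toks) + 1))
            toks = toks[:pos] + [f"{marker}/副詞"] + toks[pos:]
        records.append(
            Record(
                record_id=f"syn-{i:06d}",
                role=str(roles[i]),
                text=" ".join(toks),
                label=labels[i],
            )
        )
    return Corpus(
        records=records,
        metadata={"source": "synthetic", "seed": config.seed,
                  "config": dataclasses.asdict(config)},
    )


def write_truth(config: SynthConfig, path: str | Path) -> None:
    """Sidecar file: planted vocabulary plus a config echo."""
    Path(path).write_text(
        json.dumps(
            {"planted": planted_truth(config), "config": dataclasses.asdict(config)},
            indent=2,
        ),
        encoding="utf-8",
    )
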