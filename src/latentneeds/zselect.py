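"""Class-conditional Z-score morpheme selection.

The selection statistic for a morpheme is the magnitude of the difference
between its within-class Z-scores:

    Z_c(m)  = (x_c(m) - mu_c) / sigma_c          (per class c)
    score(m) = sqrt( (Z_A(m) - Z_B(m))^2 )  =  |Z_A(m) - Z_B(m)|

where x_c(m) is the occurrence count of m in class c, and mu_c / sigma_c
are the mean and standard deviation of counts over class c's vocabulary.
Class A is the needs class, B the no-needs class.  Morphemes whose score
falls below a threshold are excluded from the learning vocabulary; the
rationale is that interview transcripts carry many idiosyncratic
one-off expressions that are noise for class prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .morphology import CountTable

logger = logging.getLogger(__name__)

STRATEGIES = ("fraction_of_max", "quantile", "absolute")


@dataclass
class ZTable:
    """Per-class Z-scores over the class vocabulary.

    Carries mu/sigma so a morpheme absent from this class can be assigned
    the Z-score of a zero count, (0 - mu)/sigma.  ``degenerate`` marks a
    table whose sigma was zero (all counts equal); its z-scores are all 0.
    """

    class_tag: str
    z: dict[str, float]
    mu: float
    sigma: float
    degenerate: bool = False

    def z_of(self, morpheme: str) -> float:
        """Z-score of a morpheme, using the zero-count score if absent."""
        if morpheme in self.z:
            return self.z[morpheme]
        if self.degenerate:
            return 0.0
        return (0.0 - self.mu) / self.sigma


def zscores(table: CountTable) -> ZTable:
    """Standardize a count table: z[m] = (counts[m] - mu) / sigma.

    When sigma is 0 (all counts identical) every z is 0 and the table is
    flagged degenerate with a logged warning rather than raising, so a
    single pathological class does not abort the run.
    """
    mu, sigma = table.mu, table.sigma
    if sigma == 0.0:
        logger.warning(
            "count table %s has zero variance; all z-scores set to 0",
            table.class_tag,
        )
        return ZTable(
            class_tag=table.class_tag,
            z={m: 0.0 for m in table.counts},
            mu=mu,
            sigma=0.0,
            degenerate=True,
        )
    z = {m: (c - mu) / sigma for m, c in table.counts.items()}
    return ZTable(class_tag=table.class_tag, z=z, mu=mu, sigma=sigma)


@dataclass
class DiffScoreTable:
    """Nonnegative Z-difference scores over the union vocabulary."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.scores.values()):
            raise ValueError("difference scores must be nonnegative")

    def __len__(self) -> int:
        return len(self.scores)


def z_difference(zA: ZTable, zB: ZTable) -> DiffScoreTable:
    """Score every morpheme in the union vocabulary by sqrt((zA - zB)^2).

    A morpheme absent from one class gets that class's zero-count
    Z-score — class-exclusive words are maximally discriminative and must
    remain scoreable, not be dropped.
    """
    if zA.class_tag != "needs_yes" or zB.class_tag != "needs_no":
        raise ValueError("z_difference expects (needs_yes, needs_no) tables")
    if zA.degenerate and zB.degenerate:
        raise ValueError(
            "both classes are degenerate (zero variance); "
            "no discriminative signal is computable"
        )
    vocab = set(zA.z) | set(zB.z)
    scores = {m: math.sqrt((zA.z_of(m) - zB.z_of(m)) ** 2) for m in vocab}
    return DiffScoreTable(scores=scores)


@dataclass
class SelectionResult:
    """Partition of the vocabulary into kept and excluded morphemes."""

    kept: set[str]
    excluded: set[str]
    threshold_value: float
    strategy: str
    fraction: float

    def __post_init__(self) -> None:
        if self.kept & self.excluded:
            raise ValueError("kept and excluded must be disjoint")


def select_morphemes(
    scores: DiffScoreTable,
    strategy: str = "fraction_of_max",
    fraction: float = 0.25,
) -> SelectionResult:
    """Exclude morphemes whose score falls strictly below a threshold.

    Strategies for resolving the threshold from ``fraction``:

    - ``fraction_of_max`` (default): threshold = fraction * max(score).
    - ``quantile``: threshold = the nearest-rank fraction-quantile of the
      scores; excludes (roughly) the bottom ``fraction`` of morphemes.
    - ``absolute``: threshold = fraction itself, on the score scale.

    Ties at the threshold are kept: exclusion is strict ``<``.
    ``fraction=0`` keeps everything under every strategy.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected {STRATEGIES}")
    if not scores.scores:
        raise ValueError("empty score table")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")

    values = np.array(sorted(scores.scores.values()))
    if strategy == "fraction_of_max":
        threshold = fraction * float(values[-1])
    elif strategy == "quantile":
        rank = math.ceil(fraction * len(values))  # nearest-rank
        threshold = float(values[rank - 1]) if rank >= 1 else float(values[0])
    else:  # absolute
        threshold = fraction

    kept = {m for m, s in scores.scores.items() if s >= threshold}
    excluded = set(scores.scores) - kept
    return SelectionResult(
        kept=kept,
        excluded=excluded,
        threshold_value=threshold,
        strategy=strategy,
        fraction=fraction,
    )


def write_selection_tsv(
    path: str | Path,
    zA: ZTable,
    zB: ZTable,
    scores: DiffScoreTable,
    selection: SelectionResult,
) -> None:
    """Audit export: morpheme, zA, zB, score, kept — one row per morpheme."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("morpheme\tz_yes\tz_no\tscore\tkept\n")
        for m in sorted(scores.scores, key=lambda k: (-scores.scores[k], k)):
            fh.write(
                f"{m}\t{zA.z_of(m):.6g}\t{zB.z_of(m):.6g}\t"
                f"{scores.scores[m]:.6g}\t{str(m in selection.kept).lower()}\n"
            )


def read_selection_tsv(path: str | Path) -> SelectionResult:
    """Read back a selection audit file (kept/excluded sets only)."""
    kept: set[str] = set()
    excluded: set[str] = set()
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("morpheme\t"):
            raise ValueError(f"{path}: not a selection TSV")
        for line in fh:
            m, _za, _zb, _s, k = line.rstrip("\n").split("\t")
            (kept if k == "true" else excluded).add(m)
    return SelectionResult(
        kept=kept, excluded=excluded, threshold_value=float("nan"),
        strategy="loaded", fraction=float("nan"),
    )
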