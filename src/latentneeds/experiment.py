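"""End-to-end experiment: selection -> vectorize -> balance -> split -> models.

The modelling surface follows the Model/Results convention: a
:class:`LatentNeedsExperiment` is built from a :class:`~latentneeds.corpus.Corpus`
plus a :class:`PipelineConfig`; ``fit()`` executes both arms of the
comparison (with and without Z-score morpheme selection) across the three
classifier families and returns an :class:`ExperimentResults` carrying
confusion matrices, metrics, the selection audit, stage counts and a
``summary()`` table.

Two fitting modes exist because the original method order computes
morpheme selection and idf on the whole corpus *before* balancing and
splitting:

- ``faithful`` (default): selection and idf fitted on all labelled
  records, then balance, split, train.  Reproduces the original order;
  the test fold influences feature fitting (label-independent leakage).
- ``strict``: balance and split first; selection and idf fitted on the
  training fold only, the test fold merely transformed.

All randomness flows from one top-level seed; per-stage seeds are derived
as ``(seed * 1000003 + crc32(stage)) mod 2^31``.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import evaluate, features, modelkit, morphology, zselect
from .corpus import Corpus, MarkerLexicon, annotate_markers
from .modelkit import FAMILIES, ModelSpec
from .morphology import build_count_table, get_tokenizer

CONDITIONS = ("with_z", "without_z")
MODES = ("faithful", "strict")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed from the single top-level seed."""
    return (seed * 1000003 + zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration for one experiment; every field has a default.

    The resolved config is embedded verbatim in every report so a run can
    be audited and replayed.
    """

    role: Optional[str] = None          # filter to one speaker role; None = all
    tokenizer: str = "fixture"          # "fixture" or "mecab"
    unit: str = "nouns"                 # counting unit: "nouns" or "all_morphemes"
    selection_strategy: str = "fraction_of_max"
    selection_fraction: float = 0.25
    tfidf_variant: str = "smooth"
    mode: str = "faithful"
    train_fraction: float = 0.7
    families: tuple[str, ...] = FAMILIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown model family {fam!r}")
        object.__setattr__(self, "families", tuple(self.families))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping; keyword overrides win over the file."""
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)

    def asdict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(d["families"])
        return d


@dataclass
class ExperimentResults:
    """Fitted results: metrics per (condition, family), plus diagnostics."""

    config: PipelineConfig
    role: str
    cells: dict[tuple[str, str, str], evaluate.CellResult]
    selections: dict[str, Optional[zselect.SelectionResult]]
    stage_counts: dict
    predictions: dict[tuple[str, str], tuple[list, list, list]] = field(
        default_factory=dict, repr=False
    )

    def summary(self) -> pd.DataFrame:
        """One row per (condition, family): the four metrics and the 2x2 counts."""
        rows = []
        for (cond, role, fam), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "condition": cond,
                    "role": role,
                    "family": fam,
                    **cell.report.rounded,
                    "TN": cell.cm.tn,
                    "FP": cell.cm.fp,
                    "FN": cell.cm.fn,
                    "TP": cell.cm.tp,
                }
            )
        return pd.DataFrame(rows)

    def report(self) -> dict:
        cfg = {**self.config.asdict(), "stage_counts": self.stage_counts}
        return evaluate.compare_report(self.cells, config=cfg)

    def save(self, outdir: str | Path) -> None:
        """Write report.json / report.md / predictions TSVs under a run dir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rep = self.report()
        evaluate.write_report(rep, outdir / "report.json", outdir / "report.md")
        for (cond, fam), (ids, true, pred) in self.predictions.items():
            modelkit.write_predictions_tsv(
                outdir / f"predictions_{cond}_{fam}.tsv", ids, true, pred
            )
        (outdir / "manifest.json").write_text(
            json.dumps(
                {
                    "config": self.config.asdict(),
                    "role": self.role,
                    "stage_counts": self.stage_counts,
                    "files": sorted(p.name for p in outdir.iterdir()),
                },
                indent=2,
            ),
            encoding="utf-8",
        )


class LatentNeedsExperiment:
    """The with/without-selection comparison, built from a labelled corpus.

    Parameters
    ----------
    corpus : Corpus
        Records with gold ``label`` fields ("yes"/"no").  The marker flag
        is a candidate indicator only and is never trained on.
    config : PipelineConfig, optional
        Resolved settings; defaults reproduce the original method order.
    """

    def __init__(self, corpus: Corpus, config: Optional[PipelineConfig] = None):
        self.config = config or PipelineConfig()
        self.role = self.config.role or "all"
        working = corpus.filter(role=self.config.role)
        self._all_records = list(working)
        self.records = [r for r in working if r.label is not None]
        if not self.records:
            raise ValueError(
                "corpus has no records with a gold 'label' field "
                "(set label to 'yes'/'no' before fitting; marker_flag is "
                "only a candidate indicator)"
            )
        self.analyzer = get_tokenizer(self.config.tokenizer)

    # -- vocabulary and selection ------------------------------------------

    def _union_vocabulary(self, records: Sequence) -> list[str]:
        vocab: set[str] = set()
        for rec in records:
            vocab.update(
                morphology.morpheme_keys(
                    morphology.tokenize(rec.text, self.analyzer), unit=self.config.unit
                )
            )
        return sorted(vocab)

    def _select(self, records: Sequence) -> zselect.SelectionResult:
        yes = [r for r in records if r.label == "yes"]
        no = [r for r in records if r.label == "no"]
        tab_yes = build_count_table(yes, "needs_yes", self.analyzer, unit=self.config.unit)
        tab_no = build_count_table(no, "needs_no", self.analyzer, unit=self.config.unit)
        z_yes, z_no = zselect.zscores(tab_yes), zselect.zscores(tab_no)
        diff = zselect.z_difference(z_yes, z_no)
        selection = zselect.select_morphemes(
            diff,
            strategy=self.config.selection_strategy,
            fraction=self.config.selection_fraction,
        )
        self._audit = (z_yes, z_no, diff, selection)
        return selection

    # -- fitting ------------------------------------------------------------

    def fit(self) -> ExperimentResults:
        cfg = self.config
        counts: dict = {
            "records_in": len(self._all_records),
            "labelled": len(self.records),
            "label_yes": sum(r.label == "yes" for r in self.records),
            "label_no": sum(r.label == "no" for r in self.records),
            "marker_flagged": sum(bool(r.marker_flag) for r in self._all_records),
        }
        seed_sample = derive_seed(cfg.seed, "undersample")
        seed_split = derive_seed(cfg.seed, "split")

        cells: dict = {}
        selections: dict = {}
        predictions: dict = {}

        sampled = features.undersample(self.records, seed_sample)
        dsplit = features.split(
            sampled, train_fraction=cfg.train_fraction, seed=seed_split
        )
        counts["sampled"] = len(sampled)
        counts["train"] = len(dsplit.train)
        counts["test"] = len(dsplit.test)

        by_id = {r.record_id: r for r in sampled}
        train_records = [by_id[rid] for rid in dsplit.train]
        test_records = [by_id[rid] for rid in dsplit.test]
        fit_records = self.records if cfg.mode == "faithful" else train_records

        for cond in CONDITIONS:
            if cond == "with_z":
                selection = self._select(fit_records)
                kept = sorted(selection.kept)
                selections[cond] = selection
            else:
                kept = self._union_vocabulary(fit_records)
                selections[cond] = None
            counts[f"vocabulary_{cond}"] = len(kept)

            tf = features.TfidfModel(
                vocabulary=kept, variant=cfg.tfidf_variant, unit=cfg.unit
            ).fit(fit_records, self.analyzer)
            train_matrix = tf.transform(train_records, self.analyzer)
            test_matrix = tf.transform(test_records, self.analyzer)

            for fam in cfg.families:
                spec = ModelSpec(family=fam, seed=derive_seed(cfg.seed, f"model:{fam}"))
                model = modelkit.train(train_matrix, spec)
                pred = modelkit.predict(model, test_matrix)
                true = [r.label for r in test_records]
                cm = evaluate.confusion(true, pred)
                cells[(cond, self.role, fam)] = evaluate.CellResult(
                    cm=cm, report=evaluate.metrics(cm)
                )
                predictions[(cond, fam)] = (
                    [r.record_id for r in test_records],
                    true,
                    pred,
                )

        return ExperimentResults(
            config=cfg,
            role=self.role,
            cells=cells,
            selections=selections,
            stage_counts=counts,
            predictions=predictions,
        )


def run_pipeline(
    corpus: Corpus,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[str | Path] = None,
    lexicon: Optional[MarkerLexicon] = None,
) -> ExperimentResults:
    """Annotate markers, fit the full comparison, optionally write artifacts."""
    corpus = annotate_markers(corpus, lexicon or MarkerLexicon())
    exp = LatentNeedsExperiment(corpus, config)
    results = exp.fit()
    if outdir is not None:
        results.save(outdir)
        if getattr(exp, "_audit", None) is not None:
            z_yes, z_no, diff, selection = exp._audit
            zselect.write_selection_tsv(
                Path(outdir) / "selection_with_z.tsv", z_yes, z_no, diff, selection
            )
    return results
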