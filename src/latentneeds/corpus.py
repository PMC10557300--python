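"""Data model and I/O for interview records, labels and marker lexica.

The unit of analysis is the *record*: everything a subject says in answer
to one interviewer question.  Records carry a speaker role (patient or
caregiver), an optional marker flag (a candidate indicator set by lexicon
matching) and an optional gold label for the latent need, which comes from
human review and is the only field the pipeline ever trains on.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

ROLES = ("patient", "caregiver")
LABELS = ("yes", "no")

#: Expectation-adverb surface forms used as candidate indicators of a
#: latent need: "it would be good to have", "good", "after all", "still".
DEFAULT_MARKERS = ("あるといい", "いい", "やっぱり", "やっぱ", "やはり")


class CorpusError(ValueError):
    """Malformed corpus input (bad line, duplicate id, unknown role...)."""


@dataclass(frozen=True)
class Record:
    """One answer-unit of transcript text.

    Parameters
    ----------
    record_id : str
        Unique identifier within a corpus.
    role : str
        ``"patient"`` or ``"caregiver"``.
    text : str
        The transcribed answer (UTF-8).
    marker_flag : bool, optional
        Whether a marker adverb occurs in the text.  Unset until
        :func:`annotate_markers` runs.
    label : str, optional
        Gold latent-need label, ``"yes"`` or ``"no"``; unset when the
        record has not been reviewed.  Unset is distinct from ``"no"``.
    annotator_labels : tuple of (annotator_id, label), optional
        Raw per-annotator judgements prior to reconciliation.
    """

    record_id: str
    role: str
    text: str
    marker_flag: Optional[bool] = None
    label: Optional[str] = None
    annotator_labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise CorpusError("record_id must be non-empty")
        if self.role not in ROLES:
            raise CorpusError(
                f"record {self.record_id!r}: unknown role {self.role!r} "
                f"(expected one of {ROLES})"
            )
        if self.label is not None and self.label not in LABELS:
            raise CorpusError(
                f"record {self.record_id!r}: label must be 'yes' or 'no', "
                f"got {self.label!r}"
            )
        if self.annotator_labels is not None:
            object.__setattr__(
                self, "annotator_labels", tuple(tuple(a) for a in self.annotator_labels)
            )
            for _aid, lab in self.annotator_labels:
                if lab not in LABELS:
                    raise CorpusError(
                        f"record {self.record_id!r}: annotator label {lab!r} invalid"
                    )


@dataclass
class Corpus:
    """An ordered collection of records with stable iteration order."""

    records: list[Record] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise CorpusError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> Record:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def filter(self, *, role: Optional[str] = None, labelled: bool = False) -> "Corpus":
        recs = self.records
        if role is not None:
            recs = [r for r in recs if r.role == role]
        if labelled:
            recs = [r for r in recs if r.label is not None]
        return Corpus(records=list(recs), metadata=dict(self.metadata))


@dataclass(frozen=True)
class MarkerLexicon:
    """Ordered list of marker strings matched against record text."""

    markers: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if not self.markers:
            raise CorpusError("marker lexicon must be non-empty")
        seen: set[str] = set()
        for m in self.markers:
            if not m:
                raise CorpusError("marker lexicon contains an empty string")
            if m in seen:
                raise CorpusError(f"duplicate marker {m!r}")
            seen.add(m)
        object.__setattr__(self, "markers", tuple(self.markers))

    @classmethod
    def from_file(cls, path: str | Path) -> "MarkerLexicon":
        """Load a lexicon: UTF-8 text, one marker per line, '#' comments."""
        markers = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                markers.append(line)
        return cls(markers=tuple(markers))


# ---------------------------------------------------------------------------
# I/O

_CSV_FIELDS = ["record_id", "role", "text", "marker_flag", "label"]
_BOOL = {"true": True, "false": False, "": None}


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("jsonl", "csv"):
        return suffix
    raise CorpusError(f"cannot infer format from {path.name!r}; pass format=")


def read_corpus(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a corpus from JSONL or CSV.

    Raises :class:`CorpusError` naming the offending line for malformed
    input, duplicate record ids or unknown role values.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[Record] = []
    if fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"{path.name} line {lineno}: invalid JSON ({exc})")
                try:
                    records.append(_record_from_obj(obj))
                except CorpusError as exc:
                    raise CorpusError(f"{path.name} line {lineno}: {exc}")
    elif fmt == "csv":
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "record_id" not in reader.fieldnames:
                raise CorpusError(f"{path.name}: missing CSV header with record_id")
            for lineno, row in enumerate(reader, start=2):
                try:
                    records.append(_record_from_obj(row))
                except CorpusError as exc:
                    raise CorpusError(f"{path.name} line {lineno}: {exc}")
    else:
        raise CorpusError(f"unknown format {fmt!r}")
    corpus = Corpus(records=records, metadata={"source": str(path)})
    logger.info("read %d records from %s", len(records), path)
    return corpus


def _record_from_obj(obj: dict) -> Record:
    for key in ("record_id", "role"):
        if obj.get(key) in (None, ""):
            raise CorpusError(f"missing required field {key!r}")
    if obj.get("text") is None:
        raise CorpusError("missing required field 'text'")
    marker = obj.get("marker_flag")
    if isinstance(marker, str):
        if marker.lower() not in _BOOL:
            raise CorpusError(f"bad marker_flag {marker!r}")
        marker = _BOOL[marker.lower()]
    label = obj.get("label") or None
    ann = obj.get("annotator_labels")
    if isinstance(ann, list):
        ann = tuple(
            (a["annotator_id"], a["label"]) if isinstance(a, dict) else tuple(a)
            for a in ann
        )
    return Record(
        record_id=str(obj["record_id"]),
        role=obj["role"],
        text=obj["text"],
        marker_flag=marker,
        label=label,
        annotator_labels=ann,
    )


def write_corpus(corpus: Corpus, path: str | Path, format: Optional[str] = None) -> None:
    """Write a corpus so that :func:`read_corpus` round-trips it exactly.

    Unset optional fields serialize as null/empty, never as ``"no"``.
    """
    if not corpus.records:
        raise CorpusError("refusing to write an empty corpus")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in corpus:
                obj = {
                    "record_id": rec.record_id,
                    "role": rec.role,
                    "text": rec.text,
                    "marker_flag": rec.marker_flag,
                    "label": rec.label,
                }
                if rec.annotator_labels is not None:
                    obj["annotator_labels"] = [
                        {"annotator_id": a, "label": l} for a, l in rec.annotator_labels
                    ]
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS, quoting=csv.QUOTE_ALL)
            writer.writeheader()
            for rec in corpus:
                writer.writerow(
                    {
                        "record_id": rec.record_id,
                        "role": rec.role,
                        "text": rec.text,
                        "marker_flag": ""
                        if rec.marker_flag is None
                        else str(rec.marker_flag).lower(),
                        "label": rec.label or "",
                    }
                )
    else:
        raise CorpusError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Annotation

def annotate_markers(
    corpus: Corpus,
    lexicon: MarkerLexicon | None = None,
    *,
    mode: str = "substring",
    analyzer=None,
) -> Corpus:
    """Flag records that contain at least one marker expression.

    Default matching is a plain substring test on the raw text (the marker
    inventory is given as surface strings, and a short marker contained in
    a longer one must still flag).  ``mode="token"`` instead matches whole
    token surfaces, which requires an ``analyzer``.  Idempotent; the flag
    is boolean, so multiple hits count once.
    """
    lexicon = lexicon or MarkerLexicon()
    if mode not in ("substring", "token"):
        raise ValueError(f"unknown marker matching mode {mode!r}")
    if mode == "token" and analyzer is None:
        raise ValueError("token mode requires an analyzer")
    out = []
    for rec in corpus:
        if mode == "substring":
            flag = any(m in rec.text for m in lexicon.markers)
        else:
            surfaces = {t.surface for t in analyzer.tokenize(rec.text)}
            flag = any(m in surfaces for m in lexicon.markers)
        out.append(replace(rec, marker_flag=flag))
    return Corpus(records=out, metadata=dict(corpus.metadata))


@dataclass
class DisagreementReport:
    """Outcome of reconciling independent annotator judgements."""

    disagreements: list[dict] = field(default_factory=list)
    unlabelled: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.disagreements)


def reconcile_labels(corpus: Corpus) -> tuple[Corpus, DisagreementReport]:
    """Set ``label`` where all annotators agree; report the rest.

    Records whose annotators disagree are left unlabelled and listed in
    the report with every judgement — resolving them is a human step.
    Records with no annotator labels at all are listed as unlabelled.
    """
    report = DisagreementReport()
    out = []
    for rec in corpus:
        labels = [lab for _a, lab in (rec.annotator_labels or ())]
        if not labels:
            report.unlabelled.append(rec.record_id)
            out.append(rec)
        elif len(set(labels)) == 1:
            out.append(replace(rec, label=labels[0]))
        else:
            report.disagreements.append(
                {
                    "record_id": rec.record_id,
                    "labels": [
                        {"annotator_id": a, "label": l}
                        for a, l in rec.annotator_labels
                    ],
                }
            )
            out.append(replace(rec, label=None))
    return Corpus(records=out, metadata=dict(corpus.metadata)), report
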