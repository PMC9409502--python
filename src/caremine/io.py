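"""Reading and writing transcripts, annotation surveys, and tabular outputs.

Two on-disk dialects are supported for transcripts: JSON-lines (one
utterance object per line, UTF-8; the canonical format) and tab-separated
values with a header row.  Annotation surveys are tab-separated.  Loading
validates every record and reports the offending line number on failure;
it never mutates text content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

GROUPS = ("resident", "family", "professional")
SPEAKERS = ("interviewer", "interviewee")
LABELS = ("positive", "neutral", "negative")

TRANSCRIPT_FIELDS = ("interview_id", "group", "speaker", "position", "text")
ANNOTATION_FIELDS = (
    "sentence_id",
    "text",
    "label",
    "annotator_id",
    "age",
    "gender",
    "education",
    "region",
)


class ValidationError(ValueError):
    """A record failed schema validation; the message names the line."""


@dataclass(frozen=True, slots=True)
class Utterance:
    """One speaker turn in one interview."""

    interview_id: str
    group: str  # resident | family | professional
    speaker: str  # interviewer | interviewee
    position: int
    text: str

    def validate(self, where: str = "") -> None:
        ctx = f" at {where}" if where else ""
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}{ctx}")
        if self.speaker not in SPEAKERS:
            raise ValidationError(f"unknown speaker {self.speaker!r}{ctx}")
        if self.position < 0:
            raise ValidationError(f"negative position {self.position}{ctx}")


@dataclass(frozen=True, slots=True)
class AnnotatedSentence:
    """One (sentence, annotator) judgement from the sentiment survey."""

    sentence_id: str
    text: str
    label: str  # positive | neutral | negative
    annotator_id: str
    age: str = ""
    gender: str = ""
    education: str = ""
    region: str = ""

    def validate(self, where: str = "") -> None:
        ctx = f" at {where}" if where else ""
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}{ctx}")


def _check_transcript_collection(utterances: Sequence[Utterance]) -> None:
    """Cross-record invariants: unique, increasing positions; constant group."""
    seen: dict[tuple[str, int], bool] = {}
    group_of: dict[str, str] = {}
    for u in utterances:
        key = (u.interview_id, u.position)
        if key in seen:
            raise ValidationError(
                f"duplicate (interview_id, position) = {key!r}"
            )
        seen[key] = True
        prev = group_of.setdefault(u.interview_id, u.group)
        if prev != u.group:
            raise ValidationError(
                f"interview {u.interview_id!r} has conflicting groups "
                f"{prev!r} and {u.group!r}"
            )


def load_transcripts(path: str | Path) -> list[Utterance]:
    """Load a transcript file (``.jsonl`` or ``.tsv`` by extension).

    Returns utterances sorted by (interview_id, position).  Raises
    :class:`ValidationError` naming the line number for malformed records.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        utterances = _load_transcripts_tsv(path)
    else:
        utterances = _load_transcripts_jsonl(path)
    _check_transcript_collection(utterances)
    utterances.sort(key=lambda u: (u.interview_id, u.position))
    return utterances


def _load_transcripts_jsonl(path: Path) -> list[Utterance]:
    out: list[Utterance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"bad JSON at {path}:{lineno}: {exc}") from exc
            try:
                u = Utterance(
                    interview_id=str(rec["interview_id"]),
                    group=rec["group"],
                    speaker=rec["speaker"],
                    position=int(rec["position"]),
                    text=rec["text"],
                )
            except KeyError as exc:
                raise ValidationError(
                    f"missing field {exc} at {path}:{lineno}"
                ) from exc
            u.validate(where=f"{path}:{lineno}")
            out.append(u)
    return out


def _load_transcripts_tsv(path: Path) -> list[Utterance]:
    out: list[Utterance] = []
    with open(path, encoding="utf-8", newline="") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            row = line.rstrip("\n").split("\t")
            if header is None:
                header = row
                if header[: len(TRANSCRIPT_FIELDS)] != list(TRANSCRIPT_FIELDS):
                    raise ValidationError(
                        f"bad transcript header at {path}:{lineno}: {header!r}"
                    )
                continue
            if row == [""]:
                continue
            if len(row) != len(TRANSCRIPT_FIELDS):
                raise ValidationError(
                    f"expected {len(TRANSCRIPT_FIELDS)} columns at {path}:{lineno}"
                )
            u = Utterance(
                interview_id=row[0],
                group=row[1],
                speaker=row[2],
                position=int(row[3]),
                text=_tsv_unescape(row[4]),
            )
            u.validate(where=f"{path}:{lineno}")
            out.append(u)
    if header is None:
        raise ValidationError(f"empty transcript file {path} (no header)")
    return out


def write_transcripts(
    utterances: Iterable[Utterance],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write utterances in the dialect implied by the extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header_lines = [f"# {k}={v}" for k, v in (metadata or {}).items()]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        if path.suffix == ".tsv":
            fh.write("\t".join(TRANSCRIPT_FIELDS) + "\n")
            for u in utterances:
                fh.write(
                    "\t".join(
                        (
                            u.interview_id,
                            u.group,
                            u.speaker,
                            str(u.position),
                            _tsv_escape(u.text),
                        )
                    )
                    + "\n"
                )
        else:
            for u in utterances:
                fh.write(json.dumps(asdict(u), ensure_ascii=False) + "\n")


def load_annotations(path: str | Path) -> list[AnnotatedSentence]:
    """Load an annotation survey TSV; validates labels per line."""
    path = Path(path)
    out: list[AnnotatedSentence] = []
    with open(path, encoding="utf-8", newline="") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            row = line.rstrip("\n").split("\t")
            if header is None:
                header = row
                if header[:4] != list(ANNOTATION_FIELDS[:4]):
                    raise ValidationError(
                        f"bad annotation header at {path}:{lineno}: {header!r}"
                    )
                continue
            if row == [""]:
                continue
            if len(row) < 4:
                raise ValidationError(f"expected ≥4 columns at {path}:{lineno}")
            row = row + [""] * (len(ANNOTATION_FIELDS) - len(row))
            a = AnnotatedSentence(
                sentence_id=row[0],
                text=_tsv_unescape(row[1]),
                label=row[2],
                annotator_id=row[3],
                age=row[4],
                gender=row[5],
                education=row[6],
                region=row[7],
            )
            a.validate(where=f"{path}:{lineno}")
            out.append(a)
    if header is None:
        raise ValidationError(f"empty annotation file {path} (no header)")
    return out


def write_annotations(
    annotations: Iterable[AnnotatedSentence],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("\t".join(ANNOTATION_FIELDS) + "\n")
        for a in annotations:
            fh.write(
                "\t".join(
                    (
                        a.sentence_id,
                        _tsv_escape(a.text),
                        a.label,
                        a.annotator_id,
                        a.age,
                        a.gender,
                        a.education,
                        a.region,
                    )
                )
                + "\n"
            )


def _tsv_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _tsv_unescape(text: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            if nxt == "t":
                out.append("\t")
                i += 2
                continue
            if nxt == "n":
                out.append("\n")
                i += 2
                continue
            if nxt == "\\":
                out.append("\\")
                i += 2
                continue
        out.append(c)
        i += 1
    return "".join(out)


def write_table(
    df, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a pandas DataFrame as TSV with ``# key=value`` comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_json(obj, path: str | Path, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"metadata": metadata or {}, "data": obj} if metadata else obj
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1, sort_keys=True)
        fh.write("\n")
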