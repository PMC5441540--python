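"""Verbal-report transcripts and tokenization.

A transcript is the pipeline's atomic input: an ordered sequence of word
tokens produced by one subject for one report type (a dream report, a
short story told about an affective image, ...), usually elicited under a
30-second time limit so that verbosity itself carries signal.

Tokenization is deliberately simple and fully configurable: the structural
graph analysis downstream treats every token as an opaque word, so no
part-of-speech tagging, lemmatization, or stop-word removal is performed.
Fillers and disfluencies, if present in the transcription, are ordinary
tokens.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "REPORT_TYPES",
    "EmptyTranscriptError",
    "Transcript",
    "tokenize",
    "read_transcripts_tsv",
    "read_transcript_file",
]

#: Recognized report types. ``dream`` and the affective-image stories are
#: the informative ones for psychosis screening; the long-term memory
#: reports are kept for completeness.
REPORT_TYPES = (
    "dream",
    "yesterday",
    "oldest",
    "image_negative",
    "image_neutral",
    "image_positive",
    "other",
)

#: Short attribute-column suffix per report type (``LSC_negative`` etc.).
REPORT_SUFFIX = {
    "dream": "dream",
    "yesterday": "yesterday",
    "oldest": "oldest",
    "image_negative": "negative",
    "image_neutral": "neutral",
    "image_positive": "positive",
    "other": "other",
}


class EmptyTranscriptError(ValueError):
    """Raised when a whitespace-only or token-free report enters the pipeline."""


# Punctuation stripped from token edges; internal hyphens/apostrophes are kept
# so "didn't" and "well-being" stay single words.
_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$", flags=re.UNICODE)


def tokenize(
    raw_text: str,
    *,
    lowercase: bool = True,
    strip_punctuation: bool = True,
) -> list[str]:
    """Split raw UTF-8 text into word tokens.

    Tokens are maximal non-whitespace runs. With ``strip_punctuation``
    (default) leading/trailing punctuation is removed from each run while
    intra-word hyphens and apostrophes survive; runs that were punctuation
    only are dropped. Returns an empty list only for whitespace-only input.
    """
    tokens: list[str] = []
    for run in raw_text.split():
        if strip_punctuation:
            run = _EDGE_PUNCT.sub("", run)
        if lowercase:
            run = run.lower()
        if run:
            tokens.append(run)
    return tokens


@dataclass
class Transcript:
    """One verbal report: subject metadata plus the ordered token sequence.

    Token order is meaningful and preserved; every token must be a
    non-empty string with no internal whitespace. ``duration_s`` is 30 for
    the time-limited protocol and ``None`` when unknown/not limited.
    """

    subject_id: str
    report_type: str
    tokens: list[str] = field(default_factory=list)
    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.report_type not in REPORT_TYPES:
            raise ValueError(
                f"unknown report_type {self.report_type!r}; expected one of {REPORT_TYPES}"
            )
        if not self.tokens:
            raise EmptyTranscriptError(
                f"transcript {self.subject_id}/{self.report_type} has no tokens"
            )
        for t in self.tokens:
            if not t or any(c.isspace() for c in t):
                raise ValueError(f"invalid token {t!r}: empty or contains whitespace")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ValueError("duration_s must be positive when given")

    @classmethod
    def from_text(
        cls,
        subject_id: str,
        report_type: str,
        raw_text: str,
        duration_s: float | None = None,
        **tokenizer_options,
    ) -> "Transcript":
        tokens = tokenize(raw_text, **tokenizer_options)
        if not tokens:
            raise EmptyTranscriptError(
                f"report {subject_id}/{report_type}: input is whitespace-only"
            )
        return cls(subject_id, report_type, tokens, duration_s)

    @property
    def word_rate(self) -> int:
        """Number of words produced in the (time-limited) report."""
        return len(self.tokens)

    @property
    def suffix(self) -> str:
        return REPORT_SUFFIX[self.report_type]


def read_transcripts_tsv(path: str | Path, **tokenizer_options) -> list[Transcript]:
    """Read a TSV with columns ``subject_id``, ``report_type``, ``text``.

    An optional ``duration_s`` column is honored. Rows with whitespace-only
    text raise :class:`EmptyTranscriptError` naming the row.
    """
    out: list[Transcript] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"subject_id", "report_type", "text"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: TSV must have columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            try:
                dur = float(row["duration_s"]) if row.get("duration_s") else None
                out.append(
                    Transcript.from_text(
                        row["subject_id"], row["report_type"], row["text"], dur,
                        **tokenizer_options,
                    )
                )
            except (EmptyTranscriptError, ValueError) as exc:
                raise type(exc)(f"{path} line {i}: {exc}") from exc
    return out


def read_transcript_file(
    path: str | Path,
    subject_id: str,
    report_type: str,
    duration_s: float | None = None,
    **tokenizer_options,
) -> Transcript:
    """Read one plain-text report file (UTF-8) into a :class:`Transcript`."""
    raw = Path(path).read_text(encoding="utf-8")
    return Transcript.from_text(subject_id, report_type, raw, duration_s, **tokenizer_options)


def write_transcripts_tsv(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts to the TSV layout accepted by :func:`read_transcripts_tsv`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "report_type", "text", "duration_s"])
        for t in transcripts:
            writer.writerow(
                [t.subject_id, t.report_type, " ".join(t.tokens),
                 "" if t.duration_s is None else t.duration_s]
            )
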