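"""Reading and writing interview transcripts in the Q/A plain-text dialect.

A transcript is a plain UTF-8 text file in which every interviewer utterance
starts on a line whose first non-whitespace character is ``Q`` and every
participant utterance on a line starting with ``A``; the marker is followed by
whitespace, ``:`` or ``.``.  Unmarked lines continue the current turn.  One
file per participant; the file stem is the participant id.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, List, Tuple


class Speaker(str, enum.Enum):
    INTERVIEWER = "interviewer"
    PARTICIPANT = "participant"


class MalformedTranscriptError(ValueError):
    """Raised when a text does not conform to the Q/A dialect."""


@dataclass(frozen=True)
class Turn:
    """One uninterrupted utterance by a single speaker.

    ``line_span`` is the pair of 1-based line numbers (first, last) the turn
    occupied in the source file; internal whitespace is collapsed to single
    spaces and case is preserved (the POS tagger and sentiment scorer
    downstream are case-sensitive).
    """

    speaker: Speaker
    text: str
    line_span: Tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise MalformedTranscriptError("turn text is empty")
        if self.line_span[0] > self.line_span[1]:
            raise MalformedTranscriptError(
                f"invalid line span {self.line_span}"
            )


@dataclass
class Transcript:
    """Ordered speaker turns for a single participant interview."""

    participant_id: str
    turns: List[Turn] = field(default_factory=list)

    def interviewer_indices(self) -> List[int]:
        return [i for i, t in enumerate(self.turns)
                if t.speaker is Speaker.INTERVIEWER]

    def participant_text(self) -> str:
        """All participant speech, concatenated in file order."""
        return " ".join(t.text for t in self.turns
                        if t.speaker is Speaker.PARTICIPANT)

    def is_valid_interview(self) -> bool:
        speakers = {t.speaker for t in self.turns}
        return speakers == {Speaker.INTERVIEWER, Speaker.PARTICIPANT}


# A marker line: first non-whitespace char is Q or A, then whitespace, ':' or
# '.', then the utterance (possibly empty, continued on following lines).
_MARKER_RE = re.compile(r"^\s*([QA])(?:[ \t:.]+(.*))?$")

_SPEAKER_FOR_MARKER = {"Q": Speaker.INTERVIEWER, "A": Speaker.PARTICIPANT}


def _collapse(parts: Iterable[str]) -> str:
    return " ".join(" ".join(parts).split())


def parse_transcript(raw_text: str, participant_id: str) -> Transcript:
    """Parse Q/A dialect text into an ordered-turn :class:`Transcript`.

    Raises
    ------
    MalformedTranscriptError
        If the text is empty, contains no marker lines, has content before
        the first marker, or a marked turn ends up with no text at all.
    """
    if not raw_text or not raw_text.strip():
        raise MalformedTranscriptError("empty transcript text")

    turns: List[Turn] = []
    current: List[str] = []
    current_speaker: Speaker | None = None
    span_start = 0
    span_end = 0
    first_offending: Tuple[int, str] | None = None

    def flush() -> None:
        if current_speaker is None:
            return
        text = _collapse(current)
        if not text:
            raise MalformedTranscriptError(
                f"turn starting at line {span_start} has no text"
            )
        turns.append(Turn(current_speaker, text, (span_start, span_end)))

    for lineno, line in enumerate(raw_text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _MARKER_RE.match(line)
        if m:
            flush()
            current_speaker = _SPEAKER_FOR_MARKER[m.group(1)]
            current = [m.group(2) or ""]
            span_start = span_end = lineno
        else:
            if current_speaker is None:
                if first_offending is None:
                    first_offending = (lineno, line.strip())
                continue
            current.append(line)
            span_end = lineno

    if current_speaker is None:
        lineno, text = first_offending  # type: ignore[misc]
        raise MalformedTranscriptError(
            f"no Q/A marker lines found; first line (line {lineno}): {text!r}"
        )
    if first_offending is not None:
        lineno, text = first_offending
        raise MalformedTranscriptError(
            f"text before first marker at line {lineno}: {text!r}"
        )
    flush()
    return Transcript(participant_id=participant_id, turns=turns)


def write_transcript(transcript: Transcript) -> str:
    """Serialize a transcript back to the Q/A dialect (one line per turn)."""
    marker = {Speaker.INTERVIEWER: "Q", Speaker.PARTICIPANT: "A"}
    return "\n".join(f"{marker[t.speaker]}: {t.text}"
                     for t in transcript.turns) + "\n"


def read_transcript_file(path: str | Path) -> Transcript:
    path = Path(path)
    return parse_transcript(path.read_text(encoding="utf-8"), path.stem)


def write_transcript_file(transcript: Transcript, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{transcript.participant_id}.txt"
    path.write_text(write_transcript(transcript), encoding="utf-8")
    return path


def read_transcript_dir(directory: str | Path) -> Iterator[Transcript]:
    """Yield transcripts for every ``*.txt`` file in a directory, sorted by id."""
    for path in sorted(Path(directory).glob("*.txt")):
        yield read_transcript_file(path)
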