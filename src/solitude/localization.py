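"""Locate template interview questions in a transcript by TF-IDF retrieval.

Within one interview, every interviewer turn is a "document"; a template
question is a "query".  Both are vectorized with raw term frequency weighted
by smoothed inverse document frequency, idf(t) = ln((1+N)/(1+df(t))) + 1, and
matched by cosine similarity.  The participant response is then recovered
positionally: all participant turns between the matched interviewer turn and
the next interviewer turn.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import scipy.sparse as sp
import yaml
from sklearn.feature_extraction.text import TfidfVectorizer

from .transcripts import Speaker, Transcript

#: Similarity below which a match is reported as low-confidence.
LOW_CONFIDENCE_THRESHOLD = 0.2

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize_for_retrieval(text: str) -> List[str]:
    """Lowercase word tokenizer for retrieval: no stemming, no stop words.

    The templates are short, so function words carry matching signal.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class QueryTemplate:
    label: str  # "Q1".."Q6"
    template_text: str


@dataclass
class DocumentVectors:
    """TF-IDF vectors for the interviewer turns of one transcript."""

    vocabulary: List[str]
    idf: np.ndarray
    doc_vectors: sp.spmatrix  # one row per document, columns = vocabulary
    turn_indices: List[int]  # document row -> index into transcript.turns
    _vectorizer: TfidfVectorizer

    def vectorize_query(self, tokens: Sequence[str]) -> sp.spmatrix:
        return self._vectorizer.transform([list(tokens)])


@dataclass
class LocatedResponse:
    label: str
    matched_turn_index: int
    similarity: float
    response_text: str
    low_confidence: bool = False


def load_templates(path: str | Path | None = None) -> List[QueryTemplate]:
    """Load the question template set (packaged default: the six
    relationship-section questions, verbatim)."""
    if path is None:
        text = (resources.files("solitude.data") / "questions.yaml").read_text(
            encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    templates = [QueryTemplate(label=k, template_text=v)
                 for k, v in raw.items()]
    labels = [t.label for t in templates]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate template labels")
    return templates


def build_tfidf(documents: Sequence[Sequence[str]]) -> DocumentVectors:
    """Vectorize pre-tokenized documents with raw-tf x smoothed-idf weights.

    Vectors are deliberately NOT length-normalized; cosine similarity
    normalizes at match time.  Empty documents yield zero vectors; if every
    document is empty a ValueError is raised.
    """
    if not documents:
        raise ValueError("no documents")
    vectorizer = TfidfVectorizer(
        analyzer=lambda doc: doc, norm=None, smooth_idf=True,
        sublinear_tf=False, lowercase=False)
    try:
        matrix = vectorizer.fit_transform([list(d) for d in documents])
    except ValueError as exc:  # empty vocabulary
        raise ValueError("all documents are empty") from exc
    vocab = vectorizer.get_feature_names_out().tolist()
    return DocumentVectors(
        vocabulary=vocab,
        idf=vectorizer.idf_,
        doc_vectors=matrix,
        turn_indices=list(range(len(documents))),
        _vectorizer=vectorizer,
    )


def build_transcript_vectors(transcript: Transcript) -> DocumentVectors:
    """TF-IDF vectors over the interviewer turns of a transcript."""
    idx = transcript.interviewer_indices()
    if not idx:
        raise ValueError(
            f"transcript {transcript.participant_id!r} has no interviewer turns")
    docs = [tokenize_for_retrieval(transcript.turns[i].text) for i in idx]
    vectors = build_tfidf(docs)
    vectors.turn_indices = idx
    return vectors


def _cosine_rows(query: sp.spmatrix, docs: sp.spmatrix) -> np.ndarray:
    """Cosine similarity of one query row against each document row; any
    zero vector yields similarity 0."""
    dots = (docs @ query.T).toarray().ravel()
    qn = float(np.sqrt(query.multiply(query).sum()))
    dn = np.sqrt(np.asarray(docs.multiply(docs).sum(axis=1)).ravel())
    denom = qn * dn
    out = np.zeros(docs.shape[0])
    nz = denom > 0
    out[nz] = dots[nz] / denom[nz]
    return np.clip(out, 0.0, 1.0)


def extract_response(transcript: Transcript, matched_turn_index: int) -> str:
    """Concatenate participant turns strictly after the matched interviewer
    turn, up to (not including) the next interviewer turn."""
    if not 0 <= matched_turn_index < len(transcript.turns):
        raise IndexError(f"turn index {matched_turn_index} out of range")
    if transcript.turns[matched_turn_index].speaker is not Speaker.INTERVIEWER:
        raise ValueError("matched turn is not an interviewer turn")
    parts: List[str] = []
    for turn in transcript.turns[matched_turn_index + 1:]:
        if turn.speaker is Speaker.INTERVIEWER:
            break
        parts.append(turn.text)
    return " ".join(parts)


def locate_question(
    transcript: Transcript,
    query: QueryTemplate,
    vectors: DocumentVectors | None = None,
) -> LocatedResponse:
    """Return the interviewer turn most similar to the query template.

    Ties break toward the earliest turn; a query sharing no vocabulary with
    any turn matches the earliest interviewer turn with similarity 0 and is
    flagged low-confidence.
    """
    if vectors is None:
        vectors = build_transcript_vectors(transcript)
    qvec = vectors.vectorize_query(tokenize_for_retrieval(query.template_text))
    sims = _cosine_rows(qvec, vectors.doc_vectors)
    best = int(np.argmax(sims))  # argmax returns the first maximum
    turn_index = vectors.turn_indices[best]
    similarity = float(sims[best])
    return LocatedResponse(
        label=query.label,
        matched_turn_index=turn_index,
        similarity=similarity,
        response_text=extract_response(transcript, turn_index),
        low_confidence=similarity < LOW_CONFIDENCE_THRESHOLD,
    )


def localize_all(
    transcript: Transcript, templates: Sequence[QueryTemplate]
) -> Dict[str, LocatedResponse]:
    """Locate every template question in one transcript (vectors built once)."""
    vectors = build_transcript_vectors(transcript)
    return {t.label: locate_question(transcript, t, vectors)
            for t in templates}


def write_localization_report(
    rows: Dict[str, Dict[str, LocatedResponse]], path: str | Path
) -> None:
    """Write a per-transcript localization report (CSV: participant, label,
    turn index, similarity, low-confidence flag)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "label", "matched_turn_index",
                         "similarity", "low_confidence"])
        for pid, located in rows.items():
            for label in sorted(located):
                loc = located[label]
                writer.writerow([pid, label, loc.matched_turn_index,
                                 f"{loc.similarity:.4f}",
                                 int(loc.low_confidence)])
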