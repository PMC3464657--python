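"""Cue-word lexicon induction (PMI), cue matching and citation detection.

A cue entry associates a lemma (or a contiguous multiword lemma sequence)
with one (dimension, value) pair and its pointwise-mutual-information score.
Counting is over events: a cue word co-occurs with an event when the word is
annotated as a cue mention in the event's sentence.  Entries at or above the
threshold survive; the default threshold of -1.5 is interpreted in log base
2 (any base merely rescales the threshold).
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import AnnotatedDocument, Sentence, Span
from .scheme import DIMENSIONS, is_legal

logger = logging.getLogger(__name__)

DEFAULT_PMI_THRESHOLD = -1.5


def compute_pmi(joint: int, word: int, value: int, total: int, base: float = 2.0) -> float:
    """log( (joint/total) / ((word/total)(value/total)) ) in ``base``.

    A zero joint count yields ``-inf`` so the entry can never pass a finite
    threshold.
    """
    if total <= 0:
        raise ValueError("total event count must be positive")
    if not (0 <= joint <= total and 0 < word <= total and 0 < value <= total):
        raise ValueError("counts must lie in (0, total]")
    if joint == 0:
        return float("-inf")
    return math.log((joint * total) / (word * value), base)


@dataclass(frozen=True, order=True)
class CueEntry:
    word: str  # lower-cased lemma, multiword joined by single spaces
    dimension: str
    value: str
    pmi: float

    def __post_init__(self) -> None:
        if not is_legal(self.dimension, self.value):
            raise ValueError(f"illegal pair ({self.dimension}, {self.value})")


@dataclass
class CueLexicon:
    entries: list[CueEntry] = field(default_factory=list)
    threshold: float = DEFAULT_PMI_THRESHOLD
    log_base: float = 2.0

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.word, e.dimension, e.value)
            if key in seen:
                raise ValueError(f"duplicate lexicon entry {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def words(self) -> set[str]:
        return {e.word for e in self.entries}

    def by_word(self) -> dict[str, list[CueEntry]]:
        out: dict[str, list[CueEntry]] = {}
        for e in self.entries:
            out.setdefault(e.word, []).append(e)
        return out

    def checksum(self) -> str:
        """Stable digest over entry identities and scores (for model binding)."""
        h = hashlib.sha256()
        for e in sorted(self.entries):
            h.update(f"{e.word}\t{e.dimension}\t{e.value}\t{e.pmi:.6f}\n".encode())
        return h.hexdigest()

    # -- serialisation ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        lines = []
        for e in sorted(self.entries, key=lambda e: (DIMENSIONS.index(e.dimension), -e.pmi, e.value, e.word)):
            lines.append(f"{e.word}\t{e.dimension}\t{e.value}\t{e.pmi:.6f}")
        Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, threshold: float = DEFAULT_PMI_THRESHOLD) -> "CueLexicon":
        entries = []
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            if not raw.strip():
                continue
            word, dim, value, pmi = raw.split("\t")
            entries.append(CueEntry(word, dim, value, float(pmi)))
        return cls(entries=entries, threshold=threshold)


@dataclass
class CueMention:
    span: Span
    word: str
    entries: list[CueEntry]


# ---------------------------------------------------------------------------
# induction


def _cue_words_of_sentence(doc: AnnotatedDocument, sent: Sentence) -> set[tuple[str, str]]:
    """(dimension, lemma-phrase) pairs annotated as cues inside ``sent``."""
    out: set[tuple[str, str]] = set()
    for tb in doc.cue_text_bounds():
        if not sent.span.contains(tb.span):
            continue
        toks = [t for frag in tb.fragments for t in sent.tokens_in(frag)]
        if not toks:
            continue
        phrase = " ".join(t.lemma.lower() for t in toks)
        out.add((tb.cue_dimension, phrase))
    return out


def build_cue_lexicon(
    corpus: Iterable[AnnotatedDocument],
    threshold: float = DEFAULT_PMI_THRESHOLD,
    external: Iterable[tuple[str, str, str]] | None = None,
    log_base: float = 2.0,
) -> CueLexicon:
    """Induce a lexicon from gold cue annotations by per-triple PMI.

    ``external`` optionally seeds extra (word, dimension, value) candidates
    (e.g. a BioScope-style list); candidates are still scored and thresholded
    on the training corpus.  Events are the counting unit: an event
    co-occurs with a cue word at most once per sentence.
    """
    total = 0
    word_count: dict[tuple[str, str], int] = {}  # (dim, word) -> events co-occurring
    value_count: dict[tuple[str, str], int] = {}  # (dim, value) -> events
    joint_count: dict[tuple[str, str, str], int] = {}

    candidates: set[tuple[str, str, str]] = set()
    if external is not None:
        for word, dim, value in external:
            candidates.add((word.lower(), dim, value))

    saw_cues = False
    for doc in corpus:
        sent_cues = {s.index: _cue_words_of_sentence(doc, s) for s in doc.sentences}
        if any(sent_cues.values()):
            saw_cues = True
        for ev in doc.events.values():
            mk = doc.mk.get(ev.id)
            if mk is None:
                continue
            sent = doc.sentence_of_event(ev)
            if sent is None:
                continue
            total += 1
            cues_here = sent_cues.get(sent.index, set())
            for dim in DIMENSIONS:
                value = mk.value(dim)
                value_count[(dim, value)] = value_count.get((dim, value), 0) + 1
            seen_words = {(dim, word) for dim, word in cues_here}
            for dim, word in seen_words:
                word_count[(dim, word)] = word_count.get((dim, word), 0) + 1
                value = mk.value(dim)
                joint_count[(word, dim, value)] = joint_count.get((word, dim, value), 0) + 1
                candidates.add((word, dim, value))

    if not saw_cues and external is None:
        logger.warning("corpus carries no cue annotations; returning empty lexicon")
        return CueLexicon(entries=[], threshold=threshold, log_base=log_base)

    entries = []
    for word, dim, value in sorted(candidates):
        joint = joint_count.get((word, dim, value), 0)
        word_n = word_count.get((dim, word), 0)
        value_n = value_count.get((dim, value), 0)
        if joint == 0 or word_n == 0 or value_n == 0 or total == 0:
            continue
        pmi = compute_pmi(joint, word_n, value_n, total, base=log_base)
        if pmi >= threshold:
            entries.append(CueEntry(word, dim, value, pmi))
    return CueLexicon(entries=entries, threshold=threshold, log_base=log_base)


# ---------------------------------------------------------------------------
# matching


def match_cues(sentence: Sentence, lexicon: CueLexicon) -> list[CueMention]:
    """Lemma-based, case-insensitive cue matching.

    Multiword entries match contiguous lemma sequences; matching is
    longest-first and greedy, so a token inside a matched multiword cue is
    not matched again on its own.
    """
    by_word = lexicon.by_word()
    max_len = max((w.count(" ") + 1 for w in by_word), default=1)
    lemmas = [t.lemma.lower() for t in sentence.tokens]
    mentions: list[CueMention] = []
    i = 0
    while i < len(lemmas):
        matched = False
        for n in range(min(max_len, len(lemmas) - i), 0, -1):
            phrase = " ".join(lemmas[i : i + n])
            entries = by_word.get(phrase)
            if entries:
                span = Span(
                    sentence.tokens[i].span.start, sentence.tokens[i + n - 1].span.end
                )
                mentions.append(CueMention(span=span, word=phrase, entries=sorted(entries)))
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return mentions


# ---------------------------------------------------------------------------
# citations

import re  # noqa: E402

#: bracketed number(s) like [108] or [3,5] / [1-4]
_BRACKET_NUM = re.compile(r"\[\s*\d+(?:\s*[,;–-]\s*\d+)*\s*\]")
#: parenthesised sequence ending in 4 digits, e.g. (Smith et al., 1998)
_PAREN_YEAR = re.compile(r"\([^()]*\d{4}\)")


def detect_citations(text: str) -> tuple[bool, list[Span]]:
    """Flag citation-like strings: bracketed numbers or parenthesised
    sequences ending in 4 digits."""
    spans = []
    for m in _BRACKET_NUM.finditer(text):
        spans.append(Span(m.start(), m.end()))
    for m in _PAREN_YEAR.finditer(text):
        inner = m.group(0)[1:-1]
        if inner[-4:].isdigit():
            spans.append(Span(m.start(), m.end()))
    spans.sort()
    return bool(spans), spans
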