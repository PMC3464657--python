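"""Standoff annotation and dependency-parse I/O.

The dialect is BioNLP-ST flavoured, tab-separated, UTF-8, ``\\n`` newlines:

``<doc>.txt``
    raw document text.
``<doc>.a1``
    entity text-bounds, one per line: ``T1<TAB>Protein 0 3<TAB>p53``.
``<doc>.a2``
    trigger and cue text-bounds (cue kinds have the form ``<Dim>-cue``),
    event lines ``E1<TAB>Type:T2 Theme:T1 Cause:E2`` (a trigger-less event
    omits the ``:T`` part of the type token), attribute lines
    ``A1<TAB><Dim> <EventId> <Value>`` (one per event and dimension) and cue
    linkage notes ``#1<TAB>CueLink <EventId> <Dim> <CueId>``.
    Discontinuous text-bounds carry ``;``-separated fragments
    (``T3<TAB>Kind 0 3;10 15<TAB>frag1 frag2``).
``<doc>.conll``
    one block per (sentence, parser), blank-line separated, with comments
    ``# sent_id = <n>``, ``# span = <start> <end>``, ``# parser = <name>``
    followed by token rows ``INDEX FORM LEMMA POS HEAD DEPREL`` (HEAD 0 is
    the root).  Token character spans are recovered by left-to-right exact
    matching of forms inside the sentence span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .scheme import DIMENSIONS, MetaKnowledge, is_legal

logger = logging.getLogger(__name__)

CUE_KIND_SUFFIX = "-cue"


class CorpusError(Exception):
    """Base class for corpus reading/validation failures."""


class MalformedAnnotationError(CorpusError):
    """A standoff or parse line violates the dialect or the text offsets."""


class UnresolvedReferenceError(CorpusError):
    """An annotation refers to an identifier that does not exist."""


class AlignmentError(CorpusError):
    """Parse tokens cannot be aligned to the document text."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class Span:
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


def resolve_discontinuous_span(fragments: list[Span]) -> Span:
    """Smallest continuous span covering every fragment."""
    if not fragments:
        raise ValueError("resolve_discontinuous_span: empty fragment list")
    return Span(min(f.start for f in fragments), max(f.end for f in fragments))


@dataclass
class TextBound:
    id: str
    kind: str
    fragments: list[Span]
    surface: str

    @property
    def span(self) -> Span:
        return resolve_discontinuous_span(self.fragments)

    @property
    def is_cue(self) -> bool:
        return self.kind.endswith(CUE_KIND_SUFFIX)

    @property
    def cue_dimension(self) -> str | None:
        return self.kind[: -len(CUE_KIND_SUFFIX)] if self.is_cue else None


@dataclass
class Event:
    id: str
    type: str
    trigger: str | None
    args: list[tuple[str, str]] = field(default_factory=list)

    def arg_ids(self) -> list[str]:
        return [target for _, target in self.args]


@dataclass
class Token:
    index: int
    surface: str
    lemma: str
    pos: str
    span: Span


@dataclass
class DependencyGraph:
    parser: str
    tokens: list[Token]
    edges: list[tuple[int, int, str]]  # (head index, dependent index, relation)

    def head_of(self, index: int) -> tuple[int, str] | None:
        for head, dep, rel in self.edges:
            if dep == index:
                return head, rel
        return None

    def neighbours(self, index: int) -> list[tuple[int, str, bool]]:
        """Adjacent token indices as ``(other, relation, other_is_head)``."""
        out = []
        for head, dep, rel in self.edges:
            if dep == index:
                out.append((head, rel, True))
            elif head == index:
                out.append((dep, rel, False))
        return out


@dataclass
class Sentence:
    index: int  # 1-based position in document
    span: Span
    tokens: list[Token]
    graphs: dict[str, DependencyGraph] = field(default_factory=dict)

    @property
    def text_token_count(self) -> int:
        return len(self.tokens)

    def token_at(self, offset: int) -> Token | None:
        for tok in self.tokens:
            if tok.span.start <= offset < tok.span.end:
                return tok
        return None

    def tokens_in(self, span: Span) -> list[Token]:
        return [t for t in self.tokens if t.span.overlaps(span)]


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    text_bounds: dict[str, TextBound] = field(default_factory=dict)
    events: dict[str, Event] = field(default_factory=dict)
    mk: dict[str, MetaKnowledge] = field(default_factory=dict)
    sentences: list[Sentence] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    # -- resolution helpers -------------------------------------------------

    def entities(self) -> list[TextBound]:
        return [tb for tb in self.text_bounds.values() if not tb.is_cue]

    def cue_text_bounds(self) -> list[TextBound]:
        return [tb for tb in self.text_bounds.values() if tb.is_cue]

    def sentence_of_span(self, span: Span) -> Sentence | None:
        for sent in self.sentences:
            if sent.span.contains(span):
                return sent
        return None

    def sentence_of_event(self, event: Event) -> Sentence | None:
        if event.trigger is None:
            return None
        return self.sentence_of_span(self.text_bounds[event.trigger].span)

    def event_anchor_span(self, target_id: str) -> Span:
        """Span of a text-bound, or of an argument event's trigger."""
        if target_id in self.text_bounds:
            return self.text_bounds[target_id].span
        ev = self.events[target_id]
        if ev.trigger is None:
            raise UnresolvedReferenceError(
                f"{self.doc_id}: event {target_id} has no trigger to anchor on"
            )
        return self.text_bounds[ev.trigger].span


# ---------------------------------------------------------------------------
# validation


def _check_textbound(doc: AnnotatedDocument, tb: TextBound) -> None:
    for frag in tb.fragments:
        if frag.end > len(doc.text):
            raise MalformedAnnotationError(
                f"{doc.doc_id}: {tb.id} offset {frag.end} beyond text length {len(doc.text)}"
            )
    surface = " ".join(doc.text[f.start : f.end] for f in tb.fragments)
    if surface != tb.surface:
        raise MalformedAnnotationError(
            f"{doc.doc_id}: {tb.id} surface {tb.surface!r} != text {surface!r}"
        )


def _check_acyclic(doc: AnnotatedDocument) -> None:
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    def visit(eid: str, stack: tuple[str, ...]) -> None:
        if state.get(eid) == 1:
            return
        if state.get(eid) == 0:
            raise MalformedAnnotationError(
                f"{doc.doc_id}: event reference cycle through {' -> '.join(stack + (eid,))}"
            )
        state[eid] = 0
        for _, target in doc.events[eid].args:
            if target in doc.events:
                visit(target, stack + (eid,))
        state[eid] = 1

    for eid in doc.events:
        visit(eid, ())


def validate_document(doc: AnnotatedDocument) -> None:
    """Raise on any broken invariant; silent on a consistent document."""
    for tb in doc.text_bounds.values():
        _check_textbound(doc, tb)
    for ev in doc.events.values():
        if ev.trigger is not None and ev.trigger not in doc.text_bounds:
            raise UnresolvedReferenceError(
                f"{doc.doc_id}: event {ev.id} trigger {ev.trigger} unresolved"
            )
        for role, target in ev.args:
            if target not in doc.text_bounds and target not in doc.events:
                raise UnresolvedReferenceError(
                    f"{doc.doc_id}: event {ev.id} argument {role}:{target} unresolved"
                )
    _check_acyclic(doc)
    for eid, mk in doc.mk.items():
        if eid not in doc.events:
            raise UnresolvedReferenceError(
                f"{doc.doc_id}: meta-knowledge for unknown event {eid}"
            )
        mk.validate()
        for dim, cue_ids in mk.cues.items():
            for cid in cue_ids:
                if cid not in doc.text_bounds:
                    raise UnresolvedReferenceError(
                        f"{doc.doc_id}: cue reference {cid} ({dim}) unresolved"
                    )
    if doc.sentences:
        for sent in doc.sentences:
            prev_end = -1
            for tok in sent.tokens:
                if tok.span.start < prev_end:
                    raise MalformedAnnotationError(
                        f"{doc.doc_id}: overlapping tokens in sentence {sent.index}"
                    )
                prev_end = tok.span.end
        for ev in doc.events.values():
            if ev.trigger is None:
                continue
            if doc.sentence_of_event(ev) is None:
                raise MalformedAnnotationError(
                    f"{doc.doc_id}: trigger of event {ev.id} lies in no sentence"
                )


def filter_triggerless_events(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Drop events without an explicit trigger, transitively removing any
    event whose argument event was dropped (no dangling reference survives)."""
    removed: set[str] = {eid for eid, ev in doc.events.items() if ev.trigger is None}
    changed = True
    while changed:
        changed = False
        for eid, ev in doc.events.items():
            if eid in removed:
                continue
            if any(t in removed for t in ev.arg_ids()):
                removed.add(eid)
                changed = True
    for eid in removed:
        del doc.events[eid]
        doc.mk.pop(eid, None)
    if removed:
        logger.info("%s: removed %d trigger-less/dangling events", doc.doc_id, len(removed))
    return doc


# ---------------------------------------------------------------------------
# standoff reading


def _parse_textbound_line(line: str, lineno: int, path: str) -> TextBound:
    parts = line.split("\t")
    if len(parts) != 3:
        raise MalformedAnnotationError(f"{path}:{lineno}: expected 3 fields: {line!r}")
    tb_id, kind_offsets, surface = parts
    pieces = kind_offsets.split(" ")
    if len(pieces) < 3:
        raise MalformedAnnotationError(f"{path}:{lineno}: bad text-bound: {line!r}")
    kind = pieces[0]
    offset_str = " ".join(pieces[1:])
    fragments: list[Span] = []
    try:
        for frag in offset_str.split(";"):
            start_s, end_s = frag.split(" ")
            fragments.append(Span(int(start_s), int(end_s)))
    except (ValueError, TypeError) as exc:
        raise MalformedAnnotationError(f"{path}:{lineno}: bad offsets: {line!r}") from exc
    return TextBound(id=tb_id, kind=kind, fragments=fragments, surface=surface)


def _parse_event_line(line: str, lineno: int, path: str) -> Event:
    parts = line.split("\t")
    if len(parts) != 2:
        raise MalformedAnnotationError(f"{path}:{lineno}: expected 2 fields: {line!r}")
    ev_id, body = parts
    tokens = body.split(" ")
    head = tokens[0]
    if ":" in head:
        ev_type, trigger = head.split(":", 1)
    else:
        ev_type, trigger = head, None
    args: list[tuple[str, str]] = []
    for tok in tokens[1:]:
        if not tok:
            continue
        if ":" not in tok:
            raise MalformedAnnotationError(f"{path}:{lineno}: bad argument {tok!r}")
        role, target = tok.split(":", 1)
        args.append((role, target))
    return Event(id=ev_id, type=ev_type, trigger=trigger, args=args)


def read_standoff(
    text_path: str | Path,
    entity_path: str | Path,
    event_path: str | Path,
    doc_id: str | None = None,
) -> AnnotatedDocument:
    """Read a ``.txt``/``.a1``/``.a2`` triple into a resolved document.

    Surfaces are verified against the text; dangling references and bad
    offsets raise with the offending file and line named.
    """
    text_path, entity_path, event_path = Path(text_path), Path(entity_path), Path(event_path)
    doc = AnnotatedDocument(
        doc_id=doc_id or text_path.stem,
        text=text_path.read_text(encoding="utf-8"),
    )
    for path in (entity_path, event_path):
        if not path.exists():
            continue
        for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not raw.strip():
                continue
            tag = raw[0]
            if tag == "T":
                tb = _parse_textbound_line(raw, lineno, str(path))
                if tb.id in doc.text_bounds:
                    raise MalformedAnnotationError(
                        f"{path}:{lineno}: duplicate text-bound id {tb.id}"
                    )
                doc.text_bounds[tb.id] = tb
            elif tag == "E":
                ev = _parse_event_line(raw, lineno, str(path))
                doc.events[ev.id] = ev
            elif tag == "A":
                fields = raw.split("\t")
                if len(fields) != 2 or len(fields[1].split(" ")) != 3:
                    raise MalformedAnnotationError(f"{path}:{lineno}: bad attribute: {raw!r}")
                dim, ev_id, value = fields[1].split(" ")
                if not is_legal(dim, value):
                    raise MalformedAnnotationError(
                        f"{path}:{lineno}: illegal attribute {dim}={value}"
                    )
                doc.mk.setdefault(ev_id, MetaKnowledge()).set_value(dim, value)
            elif tag == "#":
                fields = raw.split("\t")
                body = fields[1].split(" ") if len(fields) == 2 else []
                if len(body) != 4 or body[0] != "CueLink":
                    raise MalformedAnnotationError(f"{path}:{lineno}: bad note: {raw!r}")
                _, ev_id, dim, cue_id = body
                doc.mk.setdefault(ev_id, MetaKnowledge()).cues.setdefault(dim, []).append(cue_id)
            else:
                raise MalformedAnnotationError(f"{path}:{lineno}: unknown line type: {raw!r}")
    validate_document(doc)
    return doc


# ---------------------------------------------------------------------------
# parse reading


def _align_tokens(
    doc: AnnotatedDocument, sent_span: Span, rows: list[tuple[int, str, str, str]]
) -> list[Token]:
    tokens: list[Token] = []
    pos = sent_span.start
    for index, form, lemma, tag in rows:
        while pos < sent_span.end and doc.text[pos].isspace():
            pos += 1
        if doc.text[pos : pos + len(form)] != form:
            raise AlignmentError(
                f"{doc.doc_id}: token {form!r} does not match text at offset {pos}"
            )
        tokens.append(Token(index, form, lemma, tag, Span(pos, pos + len(form))))
        pos += len(form)
    return tokens


def read_parse(parse_path: str | Path, doc: AnnotatedDocument) -> AnnotatedDocument:
    """Attach sentences and labelled dependency graphs to ``doc``.

    A sentence may carry several graphs (one per parser); all parsers must
    share one tokenisation.
    """
    parse_path = Path(parse_path)
    blocks: list[list[str]] = [[]]
    for raw in parse_path.read_text(encoding="utf-8").splitlines():
        if raw.strip():
            blocks[-1].append(raw)
        elif blocks[-1]:
            blocks.append([])
    sentences: dict[int, Sentence] = {}
    for block in blocks:
        if not block:
            continue
        header: dict[str, str] = {}
        rows: list[tuple[int, str, str, str]] = []
        deps: list[tuple[int, int, str]] = []
        for raw in block:
            if raw.startswith("#"):
                key, _, value = raw.lstrip("# ").partition(" = ")
                header[key.strip()] = value.strip()
                continue
            cols = raw.split("\t")
            if len(cols) != 6:
                raise MalformedAnnotationError(f"{parse_path}: expected 6 columns: {raw!r}")
            index, form, lemma, pos_tag, head, rel = cols
            rows.append((int(index), form, lemma, pos_tag))
            if int(head) != 0:
                deps.append((int(head), int(index), rel))
        try:
            sent_index = int(header["sent_id"])
            start_s, end_s = header["span"].split(" ")
            sent_span = Span(int(start_s), int(end_s))
        except (KeyError, ValueError) as exc:
            raise MalformedAnnotationError(
                f"{parse_path}: block missing sent_id/span headers"
            ) from exc
        parser = header.get("parser", "default")
        tokens = _align_tokens(doc, sent_span, rows)
        for head, dep, _ in deps:
            if not (1 <= head <= len(tokens)) or not (1 <= dep <= len(tokens)):
                raise MalformedAnnotationError(
                    f"{parse_path}: edge endpoint out of range in sentence {sent_index}"
                )
        sent = sentences.get(sent_index)
        if sent is None:
            sent = Sentence(index=sent_index, span=sent_span, tokens=tokens)
            sentences[sent_index] = sent
        elif [t.surface for t in sent.tokens] != [t.surface for t in tokens]:
            raise AlignmentError(
                f"{doc.doc_id}: parsers disagree on tokenisation of sentence {sent_index}"
            )
        sent.graphs[parser] = DependencyGraph(parser=parser, tokens=tokens, edges=deps)
    doc.sentences = [sentences[i] for i in sorted(sentences)]
    validate_document(doc)
    return doc


# ---------------------------------------------------------------------------
# writing


def _format_textbound(tb: TextBound) -> str:
    offsets = ";".join(f"{f.start} {f.end}" for f in tb.fragments)
    return f"{tb.id}\t{tb.kind} {offsets}\t{tb.surface}"


def _id_sort_key(identifier: str) -> tuple[str, int]:
    head = identifier.rstrip("0123456789")
    digits = identifier[len(head) :]
    return (head, int(digits) if digits else 0)


def write_standoff(doc: AnnotatedDocument, out_dir: str | Path) -> list[Path]:
    """Write ``doc`` as ``.txt``/``.a1``/``.a2`` (and ``.conll`` when parsed).

    The output is canonical: reading it back and writing again is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    txt = out_dir / f"{doc.doc_id}.txt"
    txt.write_text(doc.text, encoding="utf-8")
    written.append(txt)

    entity_ids = sorted(
        (tb.id for tb in doc.text_bounds.values() if not tb.is_cue and _is_entity(doc, tb)),
        key=_id_sort_key,
    )
    a1_lines = [_format_textbound(doc.text_bounds[i]) for i in entity_ids]
    a1 = out_dir / f"{doc.doc_id}.a1"
    a1.write_text("".join(line + "\n" for line in a1_lines), encoding="utf-8")
    written.append(a1)

    a2_lines: list[str] = []
    other_tb_ids = sorted(
        (i for i in doc.text_bounds if i not in set(entity_ids)), key=_id_sort_key
    )
    for i in other_tb_ids:
        a2_lines.append(_format_textbound(doc.text_bounds[i]))
    for ev_id in sorted(doc.events, key=_id_sort_key):
        ev = doc.events[ev_id]
        head = f"{ev.type}:{ev.trigger}" if ev.trigger else ev.type
        body = " ".join([head] + [f"{role}:{target}" for role, target in ev.args])
        a2_lines.append(f"{ev.id}\t{body}")
    attr_no = 0
    for ev_id in sorted(doc.mk, key=_id_sort_key):
        mk = doc.mk[ev_id]
        for dim in DIMENSIONS:
            attr_no += 1
            a2_lines.append(f"A{attr_no}\t{dim} {ev_id} {mk.value(dim)}")
    note_no = 0
    for ev_id in sorted(doc.mk, key=_id_sort_key):
        mk = doc.mk[ev_id]
        for dim in DIMENSIONS:
            for cue_id in mk.cues.get(dim, []):
                note_no += 1
                a2_lines.append(f"#{note_no}\tCueLink {ev_id} {dim} {cue_id}")
    a2 = out_dir / f"{doc.doc_id}.a2"
    a2.write_text("".join(line + "\n" for line in a2_lines), encoding="utf-8")
    written.append(a2)

    if doc.sentences:
        conll = out_dir / f"{doc.doc_id}.conll"
        conll.write_text(format_parse(doc), encoding="utf-8")
        written.append(conll)
    return written


def _is_entity(doc: AnnotatedDocument, tb: TextBound) -> bool:
    """Entities go to .a1; triggers (referenced by events) and cues to .a2."""
    if tb.is_cue:
        return False
    for ev in doc.events.values():
        if ev.trigger == tb.id:
            return False
    return True


def format_parse(doc: AnnotatedDocument) -> str:
    lines: list[str] = []
    for sent in doc.sentences:
        for parser in sorted(sent.graphs):
            graph = sent.graphs[parser]
            lines.append(f"# sent_id = {sent.index}")
            lines.append(f"# span = {sent.span.start} {sent.span.end}")
            lines.append(f"# parser = {parser}")
            heads = {dep: (head, rel) for head, dep, rel in graph.edges}
            for tok in graph.tokens:
                head, rel = heads.get(tok.index, (0, "ROOT"))
                lines.append(
                    f"{tok.index}\t{tok.surface}\t{tok.lemma}\t{tok.pos}\t{head}\t{rel}"
                )
            lines.append("")
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# corpus-level helpers


def read_document(directory: str | Path, doc_id: str) -> AnnotatedDocument:
    directory = Path(directory)
    doc = read_standoff(
        directory / f"{doc_id}.txt",
        directory / f"{doc_id}.a1",
        directory / f"{doc_id}.a2",
        doc_id=doc_id,
    )
    conll = directory / f"{doc_id}.conll"
    if conll.exists():
        read_parse(conll, doc)
    return doc


def iter_corpus(directory: str | Path) -> Iterator[AnnotatedDocument]:
    directory = Path(directory)
    for txt in sorted(directory.glob("*.txt")):
        yield read_document(directory, txt.stem)


def read_corpus(directory: str | Path) -> list[AnnotatedDocument]:
    return list(iter_corpus(directory))


def write_corpus(docs: Iterable[AnnotatedDocument], out_dir: str | Path) -> None:
    for doc in docs:
        write_standoff(doc, out_dir)
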