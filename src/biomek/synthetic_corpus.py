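"""Synthetic standoff corpora with parses, events, cues and gold
meta-knowledge.

Sentences are built from templates whose dependency structure is known by
construction, e.g. (cue slot marked ``*``)::

    In a [*cues*] manner , it seems that AGENT activates TARGET [12] .

All events of a sentence share one sampled meta-knowledge assignment; each
non-default value emits its configured cue word into the cue slot (with a
configurable emission probability), annotated as a ``<Dim>-cue`` text-bound
and linked to the events.  The cue slot is placed more than two dependency
steps and more than three words away from every event participant, so cue
evidence reaches the classifiers only through cue-path features.

Knowledge-Type sampling can be biased by document position (Fact and
Observation early, Analysis late); citations are injected as bracketed
numbers; label noise resamples a gold value without touching the cues.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .corpus_io import (
    AnnotatedDocument,
    DependencyGraph,
    Event,
    Sentence,
    Span,
    TextBound,
    Token,
    validate_document,
)
from .scheme import DEFAULTS, DIMENSIONS, VALUES, MetaKnowledge

#: default cue word per non-default (dimension, value)
DEFAULT_CUE_INVENTORY: dict[tuple[str, str], str] = {
    ("KT", "Investigation"): "investigative",
    ("KT", "Observation"): "observable",
    ("KT", "Analysis"): "suggestive",
    ("KT", "Fact"): "established",
    ("KT", "Method"): "methodological",
    ("CL", "L1"): "speculative",
    ("CL", "L2"): "probable",
    ("Polarity", "Negative"): "not",
    ("Manner", "High"): "strong",
    ("Manner", "Low"): "weak",
    ("Source", "Other"): "previous",
}

#: one ambiguous cue shared by two (dimension, value) pairs
AMBIGUOUS_CUE = "may"
AMBIGUOUS_PAIRS = (("KT", "Analysis"), ("CL", "L1"))

_PROTEINS = [
    "p53", "NF-kappaB", "TNF-alpha", "IL-2", "STAT3", "IFN-gamma",
    "TGF-beta1", "c-Myc", "BCL-2", "CD28", "JAK2", "GATA3",
]

_VERBS = [
    ("activates", "activate", "Positive_regulation"),
    ("inhibits", "inhibit", "Negative_regulation"),
    ("phosphorylates", "phosphorylate", "Phosphorylation"),
    ("expresses", "express", "Gene_expression"),
    ("binds", "bind", "Binding"),
]

_REG_VERBS = [
    ("activates", "activate", "Positive_regulation"),
    ("inhibits", "inhibit", "Negative_regulation"),
]

_IRREGULAR_LEMMA = {"seems": "seem", "were": "be", "is": "be"}


def _default_dists() -> dict[str, dict[str, float]]:
    return {
        "KT": {
            "Other": 0.30, "Investigation": 0.10, "Observation": 0.20,
            "Analysis": 0.15, "Fact": 0.15, "Method": 0.10,
        },
        "CL": {"L3": 0.60, "L2": 0.20, "L1": 0.20},
        "Polarity": {"Positive": 0.80, "Negative": 0.20},
        "Manner": {"Neutral": 0.70, "High": 0.15, "Low": 0.15},
        "Source": {"Current": 0.80, "Other": 0.20},
    }


@dataclass
class SynthConfig:
    n_documents: int = 50
    sentences_per_doc: tuple[int, int] = (4, 8)
    value_dists: dict[str, dict[str, float]] = field(default_factory=_default_dists)
    cue_inventory: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_CUE_INVENTORY)
    )
    cue_emission_prob: float = 1.0
    ambiguity_rate: float = 0.0
    noise_rate: float = 0.0
    citation_prob: float = 0.05
    citation_prob_source_other: float = 0.7
    kt_position_bias: float = 0.5
    nested_prob: float = 0.2
    cause_prob: float = 0.7
    triggerless_prob: float = 0.0
    parsers: tuple[str, ...] = ("gdep",)
    seed: int = 0

    def validate(self) -> None:
        if self.n_documents <= 0:
            raise ValueError("n_documents must be positive")
        lo, hi = self.sentences_per_doc
        if not (0 < lo <= hi):
            raise ValueError("bad sentences_per_doc range")
        for dim in DIMENSIONS:
            dist = self.value_dists[dim]
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{dim} value distribution does not sum to 1")
            for value, p in dist.items():
                if value not in VALUES[dim] or not (0.0 <= p <= 1.0):
                    raise ValueError(f"bad probability for {dim}={value}")
        for p in (
            self.cue_emission_prob, self.ambiguity_rate, self.noise_rate,
            self.citation_prob, self.citation_prob_source_other,
            self.nested_prob, self.cause_prob, self.triggerless_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


_VERB_LEMMA = {s: l for s, l, _ in _VERBS}


def _lemma_of(surface: str) -> str:
    """Lower-cased surface except a small irregular table."""
    if surface in _IRREGULAR_LEMMA:
        return _IRREGULAR_LEMMA[surface]
    return _VERB_LEMMA.get(surface, surface.lower())


def _sample(rng: random.Random, dist: dict[str, float]) -> str:
    r = rng.random()
    acc = 0.0
    for value, p in dist.items():
        acc += p
        if r < acc:
            return value
    return list(dist)[-1]


def _kt_dist_at(dist: dict[str, float], rel_pos: float, bias: float) -> dict[str, float]:
    weights = dict(dist)
    for v in ("Fact", "Observation"):
        if v in weights:
            weights[v] *= 1.0 + bias * (1.0 - rel_pos)
    if "Analysis" in weights:
        weights["Analysis"] *= 1.0 + bias * rel_pos
    z = sum(weights.values())
    return {v: w / z for v, w in weights.items()}


class _DocBuilder:
    def __init__(self, doc_id: str, parsers: tuple[str, ...]):
        self.doc = AnnotatedDocument(doc_id=doc_id, text="")
        self.parsers = parsers
        self.tb_no = 0
        self.ev_no = 0

    def new_tb(self, kind: str, span: Span) -> TextBound:
        self.tb_no += 1
        tb = TextBound(
            id=f"T{self.tb_no}",
            kind=kind,
            fragments=[span],
            surface=self.doc.text[span.start : span.end],
        )
        self.doc.text_bounds[tb.id] = tb
        return tb

    def new_event(self, etype: str, trigger: str | None, args: list[tuple[str, str]]) -> Event:
        self.ev_no += 1
        ev = Event(id=f"E{self.ev_no}", type=etype, trigger=trigger, args=args)
        self.doc.events[ev.id] = ev
        return ev


def _build_sentence(rng: random.Random, config: SynthConfig, builder: _DocBuilder,
                    sent_index: int, n_sents: int) -> None:
    doc = builder.doc
    rel_pos = sent_index / n_sents

    # --- sample the sentence-level meta-knowledge -------------------------
    true_values: dict[str, str] = {}
    for dim in DIMENSIONS:
        dist = config.value_dists[dim]
        if dim == "KT" and config.kt_position_bias > 0:
            dist = _kt_dist_at(dist, rel_pos, config.kt_position_bias)
        true_values[dim] = _sample(rng, dist)

    # cue words to emit (dimension -> surface)
    cue_words: list[tuple[str, str, str]] = []  # (dim, value, surface)
    for dim in DIMENSIONS:
        value = true_values[dim]
        if value == DEFAULTS[dim]:
            continue
        if rng.random() >= config.cue_emission_prob:
            continue
        surface = config.cue_inventory.get((dim, value))
        if surface is None:
            continue
        if (dim, value) in AMBIGUOUS_PAIRS and rng.random() < config.ambiguity_rate:
            surface = AMBIGUOUS_CUE
        cue_words.append((dim, value, surface))

    nested = rng.random() < config.nested_prob
    with_cause = rng.random() < config.cause_prob
    cite = rng.random() < (
        config.citation_prob_source_other
        if true_values["Source"] == "Other"
        else config.citation_prob
    )
    agent = rng.choice(_PROTEINS)
    target = rng.choice([p for p in _PROTEINS if p != agent])
    if nested:
        verb_s, verb_l, verb_t = rng.choice(_REG_VERBS)
    else:
        verb_s, verb_l, verb_t = rng.choice(_VERBS)

    # --- assemble tokens with their parse ---------------------------------
    # rows: (surface, lemma, pos, head_name, rel); head resolved by name later
    rows: list[tuple[str, str, str, str | None, str]] = []
    names: dict[str, int] = {}

    def put(surface: str, lemma: str, pos: str, head: str | None, rel: str,
            name: str | None = None) -> int:
        rows.append((surface, lemma, pos, head, rel))
        idx = len(rows)
        if name:
            names[name] = idx
        return idx

    put("In", "in", "IN", "seems", "VMOD", name="In")
    put("a", "a", "DT", "manner", "NMOD")
    cue_idx: list[tuple[str, str, int]] = []
    for dim, value, surface in cue_words:
        i = put(surface, _lemma_of(surface), "JJ", "manner", "NMOD")
        cue_idx.append((dim, value, i))
    put("manner", "manner", "NN", "In", "PMOD", name="manner")
    put(",", ",", ",", "seems", "PUN")
    put("it", "it", "PRP", "seems", "SUB")
    put("seems", "seem", "VBZ", None, "ROOT", name="seems")
    put("that", "that", "IN", "verb", "VMOD")
    agent_i = put(agent, agent.lower(), "NN", "verb", "SUB")
    verb_i = put(verb_s, _VERB_LEMMA.get(verb_s, verb_l), "VBZ", "seems", "VMOD", name="verb")
    if nested:
        put("the", "the", "DT", "noun", "NMOD")
        noun_i = put("expression", "expression", "NN", "verb", "OBJ", name="noun")
        put("of", "of", "IN", "noun", "NMOD", name="of")
        target_i = put(target, target.lower(), "NN", "of", "PMOD")
    else:
        target_i = put(target, target.lower(), "NN", "verb", "OBJ")
    if cite:
        put(f"[{rng.randint(1, 150)}]", "[num]", "CD", "seems", "PUN")
    put(".", ".", ".", "seems", "PUN")

    # --- lay out text and spans -------------------------------------------
    if doc.text:
        doc.text += " "
    sent_start = len(doc.text)
    spans: list[Span] = []
    for i, (surface, _, _, _, _) in enumerate(rows):
        if i:
            doc.text += " "
        start = len(doc.text)
        doc.text += surface
        spans.append(Span(start, start + len(surface)))
    sent_span = Span(sent_start, len(doc.text))

    tokens = [
        Token(i + 1, surface, lemma, pos, spans[i])
        for i, (surface, lemma, pos, _, _) in enumerate(rows)
    ]
    edges = []
    for i, (_, _, _, head, rel) in enumerate(rows):
        if head is not None:
            edges.append((names[head], i + 1, rel))
    sent = Sentence(index=sent_index, span=sent_span, tokens=tokens)
    for parser in config.parsers:
        sent.graphs[parser] = DependencyGraph(parser=parser, tokens=tokens, edges=edges)
    doc.sentences.append(sent)

    # --- annotations -------------------------------------------------------
    agent_tb = builder.new_tb("Protein", spans[agent_i - 1])
    target_tb = builder.new_tb("Protein", spans[target_i - 1])
    cue_tbs: dict[str, str] = {}  # dim -> text-bound id
    for dim, _value, i in cue_idx:
        cue_tbs[dim] = builder.new_tb(f"{dim}-cue", spans[i - 1]).id

    events: list[Event] = []
    triggerless = rng.random() < config.triggerless_prob
    if nested:
        noun_tb = builder.new_tb("Gene_expression", spans[noun_i - 1])
        inner = builder.new_event("Gene_expression", noun_tb.id, [("Theme", target_tb.id)])
        events.append(inner)
        verb_tb = None if triggerless else builder.new_tb(verb_t, spans[verb_i - 1])
        args = [("Theme", inner.id)]
        if with_cause:
            args.append(("Cause", agent_tb.id))
        outer = builder.new_event(verb_t, verb_tb.id if verb_tb else None, args)
        events.append(outer)
    else:
        verb_tb = None if triggerless else builder.new_tb(verb_t, spans[verb_i - 1])
        args = [("Theme", target_tb.id)]
        if with_cause:
            args.append(("Cause", agent_tb.id))
        events.append(builder.new_event(verb_t, verb_tb.id if verb_tb else None, args))

    for ev in events:
        mk = MetaKnowledge()
        for dim in DIMENSIONS:
            value = true_values[dim]
            if config.noise_rate > 0 and rng.random() < config.noise_rate:
                value = rng.choice([v for v in VALUES[dim] if v != value])
            mk.set_value(dim, value)
        for dim, tb_id in cue_tbs.items():
            mk.cues.setdefault(dim, []).append(tb_id)
        doc.mk[ev.id] = mk


def generate_corpus(config: SynthConfig) -> list[AnnotatedDocument]:
    """Deterministically generate a validated corpus from ``config``."""
    config.validate()
    rng = random.Random(config.seed)
    docs = []
    for d in range(config.n_documents):
        builder = _DocBuilder(f"synth{d + 1:04d}", config.parsers)
        n_sents = rng.randint(*config.sentences_per_doc)
        for s in range(1, n_sents + 1):
            _build_sentence(rng, config, builder, s, n_sents)
        validate_document(builder.doc)
        docs.append(builder.doc)
    return docs


# ---------------------------------------------------------------------------
# transfer fixtures


@dataclass
class IdMappedPair:
    source: list[AnnotatedDocument]
    target: list[AnnotatedDocument]
    #: doc id -> {source event id -> target event id}
    id_map: dict[str, dict[str, str]]
    perturbed: int = 0


def generate_idmapped_pair(
    config: SynthConfig,
    target_fraction: float = 1.0,
    perturb_fraction: float = 0.0,
) -> IdMappedPair:
    """Source corpus with meta-knowledge plus a target copy with remapped
    event ids and no meta-knowledge.

    ``target_fraction`` of source events appear in the target;
    ``perturb_fraction`` of those are altered (event type changed or an
    argument span shifted) so that exact-match transfer must skip them.
    """
    if not (0.0 <= target_fraction <= 1.0 and 0.0 <= perturb_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    source = generate_corpus(config)
    rng = random.Random(config.seed + 104729)
    target: list[AnnotatedDocument] = []
    id_map: dict[str, dict[str, str]] = {}
    n_perturbed = 0
    for doc in source:
        tdoc = AnnotatedDocument(
            doc_id=doc.doc_id,
            text=doc.text,
            text_bounds={tb.id: replace(tb, fragments=list(tb.fragments)) for tb in doc.text_bounds.values()},
            sentences=doc.sentences,
        )
        mapping: dict[str, str] = {}
        keep = {eid for eid in doc.events if rng.random() < target_fraction}
        # an event whose argument event is dropped cannot be kept coherently
        changed = True
        while changed:
            changed = False
            for eid in list(keep):
                if any(t not in keep for t in doc.events[eid].arg_ids() if t in doc.events):
                    keep.discard(eid)
                    changed = True
        for n, eid in enumerate(sorted(keep, key=lambda e: int(e[1:])), 1):
            mapping[eid] = f"E{n + 1000}"
        for eid, tid in mapping.items():
            ev = doc.events[eid]
            args = [
                (role, mapping.get(tgt, tgt)) for role, tgt in ev.args
            ]
            tev = Event(id=tid, type=ev.type, trigger=ev.trigger, args=args)
            if rng.random() < perturb_fraction:
                n_perturbed += 1
                if rng.random() < 0.5 or not _shiftable_arg(tdoc, tev):
                    tev.type = ev.type + "_variant"
                else:
                    _shift_one_arg(tdoc, tev)
            tdoc.events[tid] = tev
        validate_document(tdoc)
        target.append(tdoc)
        id_map[doc.doc_id] = mapping
    return IdMappedPair(source=source, target=target, id_map=id_map, perturbed=n_perturbed)


def _shiftable_arg(doc: AnnotatedDocument, ev: Event) -> bool:
    return any(tgt in doc.text_bounds for _, tgt in ev.args)


def _shift_one_arg(doc: AnnotatedDocument, ev: Event) -> None:
    """Point the first text-bound argument at a one-character-shifted copy."""
    for pos, (role, tgt) in enumerate(ev.args):
        if tgt not in doc.text_bounds:
            continue
        tb = doc.text_bounds[tgt]
        frag = tb.fragments[0]
        start = frag.start + 1 if frag.end < len(doc.text) else frag.start - 1
        new_span = Span(start, start + (frag.end - frag.start))
        new_tb = TextBound(
            id=f"T{len(doc.text_bounds) + 9000}",
            kind=tb.kind,
            fragments=[new_span],
            surface=doc.text[new_span.start : new_span.end],
        )
        doc.text_bounds[new_tb.id] = new_tb
        ev.args[pos] = (role, new_tb.id)
        return
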