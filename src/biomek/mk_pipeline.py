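"""End-to-end meta-knowledge assignment.

Per event the pipeline assembles feature groups (cue paths, trigger
neighbourhood, trigger-argument pair n-grams, sentence position, citation,
optionally stacked scores from an auxiliary model), hashes and normalises
them, trains one one-vs-rest model set per dimension, and assigns exactly
one value per dimension to every event plus the two derived hyper-dimension
flags.  It also covers learned cue detection, annotation transfer between
id-mapped corpora, and score stacking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np

from .corpus_io import (
    AnnotatedDocument,
    DependencyGraph,
    Event,
    Sentence,
    Token,
    UnresolvedReferenceError,
)
from .cue_lexicon import CueEntry, CueLexicon, CueMention, detect_citations, match_cues
from .features import (
    FeatureConfig,
    FeatureGroup,
    HashedVector,
    citation_feature,
    cue_path_features,
    hash_features,
    head_token,
    neighbouring_word_features,
    normalise_typewise,
    pair_ngram_features,
    sentence_position_features,
    stack_vectors,
    token_features,
)
from .learning import (
    ModelSet,
    TrainingConfig,
    predict_multi_label,
    predict_single_label,
    train_ovr,
    train_ovr_multilabel,
)
from .scheme import (
    DIMENSIONS,
    VALUES,
    MetaKnowledge,
    derive_hyperdimensions,
)

logger = logging.getLogger(__name__)

#: feature groups that can be disabled for ablation runs
ABLATABLE_GROUPS = ("cue-path", "trigger", "pair", "sentence", "citation")

_GROUP_TAGS = {"pair": "pair-ngram"}  # ablation flag -> group tag


class ExtractionError(Exception):
    pass


class LexiconMismatchError(Exception):
    """Model was trained against a different cue lexicon."""


@dataclass
class PipelineConfig:
    features: FeatureConfig = field(default_factory=FeatureConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    disabled_groups: frozenset[str] = frozenset()
    use_type_norm: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.disabled_groups) - set(ABLATABLE_GROUPS)
        if unknown:
            raise ValueError(f"unknown ablation groups: {sorted(unknown)}")

    def enabled(self, flag: str) -> bool:
        return flag not in self.disabled_groups


@dataclass
class MKInstance:
    doc_id: str
    event_id: str
    groups: list[FeatureGroup]
    vector: HashedVector
    gold: MetaKnowledge | None = None
    cue_mentions: list[CueMention] = field(default_factory=list)


def _mention_tokens(doc: AnnotatedDocument, sent: Sentence, target_id: str) -> list[Token]:
    """Sentence tokens of a text-bound, or of an argument event's trigger."""
    if target_id in doc.text_bounds:
        tb = doc.text_bounds[target_id]
    else:
        ev = doc.events[target_id]
        if ev.trigger is None:
            return []
        tb = doc.text_bounds[ev.trigger]
    return [t for frag in tb.fragments for t in sent.tokens_in(frag)]


def _participants(
    doc: AnnotatedDocument, event: Event, sent: Sentence, graph: DependencyGraph
) -> list[tuple[str, Token]]:
    out: list[tuple[str, Token]] = []
    trig_tokens = _mention_tokens(doc, sent, event.trigger)
    if trig_tokens:
        out.append(("trigger", head_token(trig_tokens, graph)))
    for role, target in event.args:
        toks = _mention_tokens(doc, sent, target)
        if toks:
            out.append(("arg", head_token(toks, graph)))
    return out


def extract_mk_instance(
    event: Event,
    doc: AnnotatedDocument,
    lexicon: CueLexicon,
    config: PipelineConfig | None = None,
    aux_model: "MKModel | None" = None,
    cue_mentions: Sequence[CueMention] | None = None,
) -> MKInstance:
    """Build the hashed, normalised feature vector of one event.

    ``cue_mentions`` overrides dictionary matching (used when cues come from
    a learned detector).  ``aux_model`` adds its per-value decision scores
    as a stacked feature group.
    """
    config = config or PipelineConfig()
    if event.trigger is None:
        raise ExtractionError(f"{doc.doc_id}/{event.id}: trigger-less event")
    sent = doc.sentence_of_event(event)
    if sent is None:
        raise ExtractionError(f"{doc.doc_id}/{event.id}: trigger outside any sentence")

    if cue_mentions is None:
        cue_mentions = match_cues(sent, lexicon)
    groups: list[FeatureGroup] = []
    multi_parser = len(sent.graphs) > 1
    for parser in sorted(sent.graphs):
        graph = sent.graphs[parser]
        subtag = parser if multi_parser else ""
        participants = _participants(doc, event, sent, graph)
        if config.enabled("cue-path"):
            g = cue_path_features(participants, cue_mentions, sent, graph, config.features)
            g.subtag = subtag
            groups.append(g)
        if config.enabled("trigger") and participants:
            trig_tok = participants[0][1]
            g = neighbouring_word_features(trig_tok, graph, config.features)
            g.tag, g.subtag = "trigger", subtag
            groups.append(g)
    if config.enabled("pair"):
        pair_group = FeatureGroup(tag="pair-ngram")
        trig_tokens = _mention_tokens(doc, sent, event.trigger)
        for role, target in event.args:
            arg_tokens = _mention_tokens(doc, sent, target)
            if not trig_tokens or not arg_tokens:
                continue
            g = pair_ngram_features(trig_tokens, arg_tokens, sent, config.features)
            pair_group.merge(g, prefix=f"{role}|")
        groups.append(pair_group)
    if config.enabled("sentence"):
        groups.append(sentence_position_features(sent, len(doc.sentences)))
    if config.enabled("citation"):
        flag, _ = detect_citations(doc.text[sent.span.start : sent.span.end])
        groups.append(citation_feature(flag))
    if aux_model is not None:
        groups.append(stack_scores(event, doc, aux_model))

    vector = (
        normalise_typewise(groups, config.features)
        if config.use_type_norm
        else _global_norm(groups, config.features)
    )
    return MKInstance(
        doc_id=doc.doc_id,
        event_id=event.id,
        groups=groups,
        vector=vector,
        gold=doc.mk.get(event.id),
        cue_mentions=list(cue_mentions),
    )


def _global_norm(groups: Sequence[FeatureGroup], fc: FeatureConfig) -> HashedVector:
    vec = hash_features(groups, fc)
    norm = vec.norm()
    if norm > 0:
        vec.scale(1.0 / norm)
    return vec


# ---------------------------------------------------------------------------
# model bundle


@dataclass
class MKModel:
    """Versioned bundle: five per-dimension model sets, the lexicon they
    were trained with, and the pipeline configuration."""

    model_sets: dict[str, ModelSet]
    lexicon: CueLexicon
    config: PipelineConfig
    lexicon_checksum: str
    version: str = "1"

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @classmethod
    def load(cls, path: str | Path) -> "MKModel":
        model = joblib.load(Path(path))
        if not isinstance(model, cls):
            raise TypeError(f"{path} is not a model archive")
        return model

    def check_lexicon(self, lexicon: CueLexicon) -> None:
        if lexicon.checksum() != self.lexicon_checksum:
            raise LexiconMismatchError(
                "cue lexicon does not match the one the model was trained with"
            )


def _iter_events(docs: Iterable[AnnotatedDocument]):
    for doc in docs:
        for eid in sorted(doc.events, key=lambda e: (len(e), e)):
            yield doc, doc.events[eid]


def build_instances(
    docs: Sequence[AnnotatedDocument],
    lexicon: CueLexicon,
    config: PipelineConfig,
    aux_model: "MKModel | None" = None,
    require_gold: bool = False,
) -> list[MKInstance]:
    instances = []
    for doc, event in _iter_events(docs):
        if event.trigger is None:
            logger.warning("%s/%s: skipping trigger-less event", doc.doc_id, event.id)
            continue
        if require_gold and event.id not in doc.mk:
            logger.warning("%s/%s: no gold meta-knowledge; skipped", doc.doc_id, event.id)
            continue
        instances.append(extract_mk_instance(event, doc, lexicon, config, aux_model))
    return instances


def train_mk(
    docs: Sequence[AnnotatedDocument],
    lexicon: CueLexicon,
    config: PipelineConfig | None = None,
    aux_model: "MKModel | None" = None,
) -> MKModel:
    """Train the five per-dimension one-vs-rest model sets."""
    config = config or PipelineConfig()
    instances = build_instances(docs, lexicon, config, aux_model, require_gold=True)
    if not instances:
        raise ValueError("no trainable events in the corpus")
    X = stack_vectors([i.vector for i in instances], config.features.dimension)
    model_sets = {}
    for dim in DIMENSIONS:
        labels = [i.gold.value(dim) for i in instances]
        model_sets[dim] = train_ovr(X, labels, dim, VALUES[dim], config.training)
    return MKModel(
        model_sets=model_sets,
        lexicon=lexicon,
        config=config,
        lexicon_checksum=lexicon.checksum(),
    )


def assign_metaknowledge(
    docs: Sequence[AnnotatedDocument],
    model: MKModel,
    lexicon: CueLexicon | None = None,
    aux_model: "MKModel | None" = None,
) -> dict[tuple[str, str], MetaKnowledge]:
    """Predict one value per dimension (plus hyper-dimension flags) for every
    event with a trigger.  Raises on a lexicon/model mismatch."""
    lexicon = lexicon if lexicon is not None else model.lexicon
    model.check_lexicon(lexicon)
    instances = build_instances(docs, lexicon, model.config, aux_model)
    if not instances:
        return {}
    X = stack_vectors([i.vector for i in instances], model.config.features.dimension)
    predictions: dict[tuple[str, str], MetaKnowledge] = {}
    per_dim = {
        dim: predict_single_label(model.model_sets[dim], X) for dim in DIMENSIONS
    }
    for row, inst in enumerate(instances):
        mk = MetaKnowledge()
        for dim in DIMENSIONS:
            mk.set_value(dim, per_dim[dim][row])
        mk.new_knowledge, mk.hypothesis = derive_hyperdimensions(mk)
        predictions[(inst.doc_id, inst.event_id)] = mk
    return predictions


def stack_scores(event: Event, doc: AnnotatedDocument, aux_model: MKModel) -> FeatureGroup:
    """Auxiliary-model decision scores, one real-valued feature per legal
    (dimension, value) pair, as a separate group so type-based normalisation
    applies to it."""
    group = FeatureGroup(tag="stacked-score")
    try:
        inst = extract_mk_instance(event, doc, aux_model.lexicon, aux_model.config)
    except ExtractionError:
        return group
    X = stack_vectors([inst.vector], aux_model.config.features.dimension)
    for dim in DIMENSIONS:
        scores = aux_model.model_sets[dim].scores(X)
        for value in VALUES[dim]:
            s = float(scores[value][0])
            if np.isfinite(s):
                group.add(f"{dim}:{value}", s)
    return group


# ---------------------------------------------------------------------------
# learned cue detection


CUE_NONE = "NONE"


@dataclass
class CueDetector:
    """Token-level multi-label cue classifier with an explicit NONE class."""

    model_set: ModelSet
    feature_config: FeatureConfig
    dictionary: frozenset[str] = frozenset()


def _token_cue_labels(doc: AnnotatedDocument, sent: Sentence) -> dict[int, set[str]]:
    """Gold ``dim:value`` classes per token index, from cue annotations and
    the values of the events they are linked to."""
    labels: dict[int, set[str]] = {}
    for tb in doc.cue_text_bounds():
        if not sent.span.contains(tb.span):
            continue
        values: set[str] = set()
        for eid, mk in doc.mk.items():
            if tb.id in mk.cues.get(tb.cue_dimension, []):
                values.add(mk.value(tb.cue_dimension))
        for frag in tb.fragments:
            for tok in sent.tokens_in(frag):
                for value in values:
                    labels.setdefault(tok.index, set()).add(f"{tb.cue_dimension}:{value}")
    return labels


def _cue_token_vector(
    tok: Token, sent: Sentence, fc: FeatureConfig
) -> HashedVector:
    groups = [token_features(tok, fc)]
    for parser in sorted(sent.graphs):
        g = neighbouring_word_features(tok, sent.graphs[parser], fc)
        if len(sent.graphs) > 1:
            g.subtag = parser
        groups.append(g)
    return normalise_typewise(groups, fc)


def train_cue_detector(
    docs: Sequence[AnnotatedDocument],
    config: PipelineConfig | None = None,
    dictionary: Iterable[str] | None = None,
) -> CueDetector:
    """Train a token classifier over ``dim:value`` cue classes plus NONE."""
    config = config or PipelineConfig()
    fc = config.features
    vectors, label_sets = [], []
    classes: set[str] = set()
    for doc in docs:
        for sent in doc.sentences:
            gold = _token_cue_labels(doc, sent)
            for tok in sent.tokens:
                token_classes = gold.get(tok.index, {CUE_NONE})
                vectors.append(_cue_token_vector(tok, sent, fc))
                label_sets.append(set(token_classes))
                classes.update(token_classes)
    if not vectors:
        raise ValueError("no tokens to train the cue detector on")
    order = [CUE_NONE] + sorted(classes - {CUE_NONE})
    X = stack_vectors(vectors, fc.dimension)
    model_set = train_ovr_multilabel(X, label_sets, "cue", order, config.training)
    dict_words = frozenset(w.lower() for w in dictionary) if dictionary else frozenset()
    return CueDetector(model_set=model_set, feature_config=fc, dictionary=dict_words)


def detect_cues_learned(
    sentence: Sentence,
    detector: CueDetector,
    use_dictionary_filter: bool = True,
) -> list[CueMention]:
    """Predict cue mentions in a sentence with the learned detector.

    With the filter on, only tokens whose lemma appears in the detector's
    dictionary are candidates.  A token predicted NONE (and nothing else
    positive) yields no mention.
    """
    candidates = []
    for tok in sentence.tokens:
        if use_dictionary_filter and detector.dictionary:
            if tok.lemma.lower() not in detector.dictionary:
                continue
        candidates.append(tok)
    if not candidates:
        return []
    vectors = [_cue_token_vector(t, sentence, detector.feature_config) for t in candidates]
    X = stack_vectors(vectors, detector.feature_config.dimension)
    predicted = predict_multi_label(detector.model_set, X)
    mentions = []
    for tok, classes in zip(candidates, predicted):
        entries = []
        for cls in sorted(classes - {CUE_NONE}):
            dim, value = cls.split(":", 1)
            entries.append(CueEntry(tok.lemma.lower(), dim, value, 0.0))
        if entries:
            mentions.append(CueMention(span=tok.span, word=tok.lemma.lower(), entries=entries))
    return mentions


# ---------------------------------------------------------------------------
# annotation transfer


@dataclass
class TransferReport:
    total_target: int = 0
    transferred: int = 0
    no_source: int = 0
    mismatched: int = 0
    ambiguous: int = 0

    def summary(self) -> str:
        return (
            f"transferred {self.transferred}/{self.total_target} events "
            f"(no source: {self.no_source}, mismatched: {self.mismatched}, "
            f"ambiguous: {self.ambiguous})"
        )


def _core_arg_signature(doc: AnnotatedDocument, event: Event) -> tuple | None:
    sig = []
    for role, target in event.args:
        if role.rstrip("0123456789") not in ("Theme", "Cause"):
            continue  # secondary arguments do not take part in matching
        try:
            span = doc.event_anchor_span(target)
        except (KeyError, UnresolvedReferenceError):
            return None
        sig.append((role, span.start, span.end))
    return tuple(sorted(sig))


def transfer_annotations(
    source_docs: Sequence[AnnotatedDocument],
    target_docs: Sequence[AnnotatedDocument],
    id_map: Mapping[str, Mapping[str, str]],
) -> TransferReport:
    """Copy meta-knowledge onto target events that match a source event on
    event type, mapped event id and core argument text spans.

    Ambiguous matches (several source events mapping to one target id) are
    skipped.  Target documents are modified in place; the report carries the
    transferred/untransferred counts.
    """
    source_by_id = {doc.doc_id: doc for doc in source_docs}
    report = TransferReport()
    for tdoc in target_docs:
        sdoc = source_by_id.get(tdoc.doc_id)
        mapping = id_map.get(tdoc.doc_id, {})
        reverse: dict[str, list[str]] = {}
        for src, tgt in mapping.items():
            reverse.setdefault(tgt, []).append(src)
        for tid, tev in tdoc.events.items():
            report.total_target += 1
            sources = reverse.get(tid, [])
            if sdoc is None or not sources:
                report.no_source += 1
                continue
            if len(sources) > 1:
                logger.warning("%s/%s: ambiguous id mapping; skipped", tdoc.doc_id, tid)
                report.ambiguous += 1
                continue
            sev = sdoc.events.get(sources[0])
            if sev is None or sev.id not in sdoc.mk:
                report.no_source += 1
                continue
            if sev.type != tev.type or _core_arg_signature(
                sdoc, sev
            ) != _core_arg_signature(tdoc, tev):
                report.mismatched += 1
                continue
            tdoc.mk[tid] = sdoc.mk[sev.id].copy()
            tdoc.mk[tid].cues = {}  # cue ids are not valid in the target
            report.transferred += 1
    return report
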