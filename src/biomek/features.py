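"""Feature extraction over tokens, windows and dependency paths.

Five base functions build named, typed feature groups:

* token features (character types, character n-grams, base form, POS);
* neighbouring-word features (all dependency paths of up to 2 steps);
* word n-grams in a +-3-word window;
* pair n-grams over the window spanning a mention pair;
* shortest-dependency-path features (length, n-grams, governor-dependent
  units, edge walks and vertex walks).

Dependency paths are searched on the undirected view of the graph; edge
direction is kept in the feature names as arrows pointing at the governor
(``-REL>`` when the following word is the head, ``<REL-`` when the
preceding word is).  N-grams over mixed word/dependency material count the
alternating elements of the path sequence as units.

Named features are hashed into a fixed space of ``2**hash_bits`` indices
(default 2**20); type-based normalisation scales each group to unit L2
length before the concatenated vector is itself L2-normalised.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse

from .corpus_io import DependencyGraph, Sentence, Token
from .cue_lexicon import CueMention


@dataclass
class FeatureConfig:
    char_ngram_orders: tuple[int, ...] = (1, 2, 3, 4)
    window: int = 3  # words before/after for the window functions
    neighbour_depth: int = 2
    hash_bits: int = 20

    def __post_init__(self) -> None:
        if self.window <= 0 or self.neighbour_depth <= 0 or self.hash_bits <= 0:
            raise ValueError("window/depth/bits must be positive")
        if any(n <= 0 for n in self.char_ngram_orders):
            raise ValueError("n-gram orders must be positive")

    @property
    def dimension(self) -> int:
        return 1 << self.hash_bits


@dataclass
class FeatureGroup:
    """A named sparse bag of features under one group tag.

    ``tag`` is the normalisation/ablation type; ``subtag`` distinguishes
    e.g. per-parser variants without splitting the type for ablation.
    """

    tag: str
    features: dict[str, float] = field(default_factory=dict)
    subtag: str = ""

    def add(self, name: str, value: float = 1.0) -> None:
        if not np.isfinite(value):
            raise ValueError(f"non-finite feature value for {name!r}")
        self.features[name] = self.features.get(name, 0.0) + value

    def merge(self, other: "FeatureGroup", prefix: str = "") -> None:
        for name, value in other.features.items():
            self.add(prefix + name, value)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def hash_key(self) -> str:
        return f"{self.tag}|{self.subtag}" if self.subtag else self.tag


def feature_dump(groups: Iterable[FeatureGroup]) -> str:
    """Debug/golden-file dump: one ``group<TAB>name<TAB>value`` line each."""
    lines = []
    for g in groups:
        for name in sorted(g.features):
            lines.append(f"{g.hash_key}\t{name}\t{g.features[name]:g}")
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# token features


def _char_types(surface: str) -> list[str]:
    out = []
    if any(c.isdigit() for c in surface):
        out.append("has-digit")
    if any(not c.isalnum() for c in surface):
        out.append("has-symbol")
    if surface.isupper():
        out.append("all-upper")
    if surface[:1].isupper():
        out.append("init-cap")
    if "-" in surface:
        out.append("has-hyphen")
    return out


def token_features(token: Token, config: FeatureConfig = FeatureConfig()) -> FeatureGroup:
    group = FeatureGroup(tag="token")
    for ct in _char_types(token.surface):
        group.add(f"ct:{ct}")
    low = token.surface.lower()
    for n in config.char_ngram_orders:
        for i in range(len(low) - n + 1):
            group.add(f"cn{n}:{low[i : i + n]}")
    group.add(f"lemma:{token.lemma.lower()}")
    group.add(f"pos:{token.pos}")
    return group


# ---------------------------------------------------------------------------
# dependency path machinery


def _dep_element(graph: DependencyGraph, prev: int, nxt: int) -> str:
    """Arrow element between consecutive path tokens, pointing at the head."""
    for head, dep, rel in graph.edges:
        if head == prev and dep == nxt:
            return f"<{rel}-"
        if head == nxt and dep == prev:
            return f"-{rel}>"
    raise ValueError(f"no edge between token {prev} and {nxt}")


def _lemma(graph: DependencyGraph, index: int) -> str:
    return graph.tokens[index - 1].lemma.lower()


def _alternating(graph: DependencyGraph, path: Sequence[int]) -> list[str]:
    """Path as alternating [word, dep, word, ...] elements (lemmas)."""
    out: list[str] = []
    for pos, idx in enumerate(path):
        if pos:
            out.append(_dep_element(graph, path[pos - 1], idx))
        out.append(_lemma(graph, idx))
    return out


def _ngrams(seq: Sequence[str], orders: Iterable[int]) -> Iterable[tuple[int, str]]:
    for n in orders:
        for i in range(len(seq) - n + 1):
            yield n, " ".join(seq[i : i + n])


def neighbouring_word_features(
    token: Token, graph: DependencyGraph, config: FeatureConfig = FeatureConfig()
) -> FeatureGroup:
    """Features from every dependency path of up to ``neighbour_depth`` steps.

    Paths are oriented with the target word last, so a 2-step path prints as
    ``far <REL- mid <REL- target``.  Emits token features for every word
    reached, word+dependency n-grams (n=2..4), word n-grams (n=2,3) and
    dependency n-grams (n=2).
    """
    group = FeatureGroup(tag="neighbour")
    paths: list[list[int]] = []

    def walk(path: list[int]) -> None:
        if len(path) > 1:
            paths.append(list(reversed(path)))  # target last
        if len(path) > config.neighbour_depth:
            return
        for other, _, _ in sorted(graph.neighbours(path[-1])):
            if other not in path:
                walk(path + [other])

    walk([token.index])

    reached = sorted({idx for p in paths for idx in p})  # empty when no edges
    for idx in reached:
        group.merge(token_features(graph.tokens[idx - 1], config), prefix="tok:")
    for path in paths:
        seq = _alternating(graph, path)
        words = seq[0::2]
        deps = seq[1::2]
        for n, gram in _ngrams(seq, (2, 3, 4)):
            group.add(f"wd{n}:{gram}")
        for n, gram in _ngrams(words, (2, 3)):
            group.add(f"w{n}:{gram}")
        for n, gram in _ngrams(deps, (2,)):
            group.add(f"d{n}:{gram}")
    return group


def shortest_path(
    first: Token, second: Token, graph: DependencyGraph
) -> list[int] | None:
    """Token-index sequence of the shortest undirected path, or None.

    Among equally short paths the lexicographically smallest index sequence
    is chosen (deterministic; unique anyway on trees).
    """
    g = nx.Graph()
    g.add_nodes_from(t.index for t in graph.tokens)
    g.add_edges_from((h, d) for h, d, _ in graph.edges)
    try:
        return min(nx.all_shortest_paths(g, first.index, second.index))
    except nx.NetworkXNoPath:
        return None


def shortest_path_features(
    first: Token,
    second: Token,
    graph: DependencyGraph,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureGroup:
    group = FeatureGroup(tag="shortest-path")
    path = shortest_path(first, second, graph)
    if path is None:
        group.add("no-path")
        return group
    group.add(f"len:{len(path) - 1}")
    if len(path) < 2:
        return group
    seq = _alternating(graph, path)
    words = seq[0::2]
    deps = seq[1::2]
    for n, gram in _ngrams(words, (2, 3, 4)):
        group.add(f"w{n}:{gram}")
    for n, gram in _ngrams(deps, (2, 3, 4)):
        group.add(f"d{n}:{gram}")
    # governor-dependent units: arrow points at the governor of each pair
    units = []
    for i in range(len(words) - 1):
        arrow = "->" if deps[i].startswith("-") else "<-"
        units.append(f"{words[i]}{arrow}{words[i + 1]}")
    for n, gram in _ngrams(units, (1, 2, 3)):
        group.add(f"gd{n}:{gram}")
    # edge walks (word-dep-word) and sub-structures
    for i in range(len(deps)):
        w1, d, w2 = words[i], deps[i], words[i + 1]
        group.add(f"ew:{w1} {d} {w2}")
        group.add(f"ews:{w1} {d}")
        group.add(f"ews:{d} {w2}")
    # vertex walks (dep-word-dep) and sub-structures
    for i in range(len(deps) - 1):
        d1, w, d2 = deps[i], words[i + 1], deps[i + 1]
        group.add(f"vw:{d1} {w} {d2}")
        group.add(f"vws:{d1} {d2}")
    return group


# ---------------------------------------------------------------------------
# window functions


def _window_encode(token: Token, mark: str) -> str:
    return f"{token.lemma.lower()}/{token.pos}/{mark}"


def word_ngram_features(
    token: Token, sentence: Sentence, config: FeatureConfig = FeatureConfig()
) -> FeatureGroup:
    """Word n-grams (n=1..4) in the +-``window``-word context of ``token``.

    Each word is encoded as lemma/POS/position mark (B before, T target,
    A after); windows truncate at sentence boundaries.
    """
    group = FeatureGroup(tag="word-ngram")
    positions = [t.index for t in sentence.tokens]
    i = positions.index(token.index)
    lo, hi = max(0, i - config.window), min(len(sentence.tokens), i + config.window + 1)
    encoded = []
    for j in range(lo, hi):
        mark = "T" if j == i else ("B" if j < i else "A")
        encoded.append(_window_encode(sentence.tokens[j], mark))
    for n, gram in _ngrams(encoded, (1, 2, 3, 4)):
        group.add(f"w{n}:{gram}")
    return group


class CrossSentenceError(ValueError):
    """Pair features requested for mentions in different sentences."""


def pair_ngram_features(
    first: Sequence[Token],
    second: Sequence[Token],
    sentence: Sentence,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureGroup:
    """Word n-grams (n=1..4) from ``window`` words before the pair's first
    word to ``window`` words after its last, with before/between/after marks
    (the pair's own words count as between)."""
    group = FeatureGroup(tag="pair-ngram")
    sent_ids = {t.index for t in sentence.tokens}
    mention_tokens = list(first) + list(second)
    if any(t.index not in sent_ids for t in mention_tokens):
        raise CrossSentenceError("pair mentions must lie in one sentence")
    positions = [t.index for t in sentence.tokens]
    idxs = sorted(positions.index(t.index) for t in mention_tokens)
    lo_pair, hi_pair = idxs[0], idxs[-1]
    lo = max(0, lo_pair - config.window)
    hi = min(len(sentence.tokens), hi_pair + config.window + 1)
    encoded = []
    for j in range(lo, hi):
        mark = "M" if lo_pair <= j <= hi_pair else ("B" if j < lo_pair else "A")
        encoded.append(_window_encode(sentence.tokens[j], mark))
    for n, gram in _ngrams(encoded, (1, 2, 3, 4)):
        group.add(f"w{n}:{gram}")
    return group


def sentence_position_features(sentence: Sentence, sentence_count: int) -> FeatureGroup:
    group = FeatureGroup(tag="sentence")
    group.add(f"abs:{sentence.index}")
    group.add("rel", sentence.index / sentence_count)
    return group


def citation_feature(flag: bool) -> FeatureGroup:
    group = FeatureGroup(tag="citation")
    if flag:
        group.add("has-citation")
    return group


# ---------------------------------------------------------------------------
# cue paths


def head_token(tokens: Sequence[Token], graph: DependencyGraph) -> Token:
    """Head word of a mention: the token whose governor lies outside the
    mention, else the last token."""
    inside = {t.index for t in tokens}
    for tok in tokens:
        head = graph.head_of(tok.index)
        if head is None or head[0] not in inside:
            return tok
    return tokens[-1]


def cue_path_features(
    participants: Sequence[tuple[str, Token]],
    cue_mentions: Sequence[CueMention],
    sentence: Sentence,
    graph: DependencyGraph,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureGroup:
    """Shortest-path features between each participant head token and each
    matched cue, emitted once per lexicon entry of the cue under a
    ``dimension:value`` prefix.

    ``participants`` are (role, head token) pairs, role "trigger" or "arg".
    """
    group = FeatureGroup(tag="cue-path")
    for mention in cue_mentions:
        cue_tokens = sentence.tokens_in(mention.span)
        if not cue_tokens:
            continue
        cue_head = head_token(cue_tokens, graph)
        for role, part_tok in participants:
            path_group = shortest_path_features(part_tok, cue_head, graph, config)
            for entry in mention.entries:
                prefix = f"{entry.dimension}:{entry.value}|{role}|"
                group.merge(path_group, prefix=prefix)
                group.add(f"{entry.dimension}:{entry.value}|present")
    return group


# ---------------------------------------------------------------------------
# hashing and normalisation


def hash_index(group_key: str, name: str, bits: int) -> int:
    digest = hashlib.blake2b(
        f"{group_key}\x1f{name}".encode("utf-8"), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (1 << bits)


@dataclass
class HashedVector:
    dimension: int
    data: dict[int, float] = field(default_factory=dict)

    def add(self, index: int, value: float) -> None:
        if not (0 <= index < self.dimension):
            raise IndexError(f"hash index {index} outside [0, {self.dimension})")
        self.data[index] = self.data.get(index, 0.0) + value

    def norm(self) -> float:
        return float(np.sqrt(sum(v * v for v in self.data.values())))

    def scale(self, factor: float) -> None:
        for k in self.data:
            self.data[k] *= factor

    def to_csr(self) -> sparse.csr_matrix:
        if not self.data:
            return sparse.csr_matrix((1, self.dimension))
        idx = sorted(self.data)
        vals = [self.data[i] for i in idx]
        return sparse.csr_matrix(
            (vals, ([0] * len(idx), idx)), shape=(1, self.dimension)
        )


def hash_features(
    groups: Iterable[FeatureGroup], config: FeatureConfig = FeatureConfig()
) -> HashedVector:
    """Hash all named features into one fixed-dimension sparse vector;
    colliding features sum."""
    vec = HashedVector(dimension=config.dimension)
    for group in groups:
        for name, value in group.features.items():
            vec.add(hash_index(group.hash_key, name, config.hash_bits), value)
    return vec


def normalise_typewise(
    groups: Iterable[FeatureGroup], config: FeatureConfig = FeatureConfig()
) -> HashedVector:
    """Hash each group, scale it to unit L2 length (empty/zero groups are
    left alone), sum, then scale the whole vector to unit L2 length."""
    total = HashedVector(dimension=config.dimension)
    for group in groups:
        part = hash_features([group], config)
        norm = part.norm()
        if norm > 0:
            part.scale(1.0 / norm)
        for idx, value in part.data.items():
            total.add(idx, value)
    norm = total.norm()
    if norm > 0:
        total.scale(1.0 / norm)
    return total


def stack_vectors(
    vectors: Sequence[HashedVector], dimension: int
) -> sparse.csr_matrix:
    """Stack hashed vectors into a CSR design matrix."""
    if not vectors:
        return sparse.csr_matrix((0, dimension))
    rows, cols, vals = [], [], []
    for r, vec in enumerate(vectors):
        for idx in sorted(vec.data):
            rows.append(r)
            cols.append(idx)
            vals.append(vec.data[idx])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(len(vectors), dimension))
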