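import math
import random

import pytest

from biomek.corpus_io import DependencyGraph, Sentence, Span, Token
from biomek.cue_lexicon import CueEntry, CueMention
from biomek.features import (
    CrossSentenceError,
    FeatureConfig,
    FeatureGroup,
    HashedVector,
    cue_path_features,
    feature_dump,
    hash_features,
    hash_index,
    head_token,
    neighbouring_word_features,
    normalise_typewise,
    pair_ngram_features,
    sentence_position_features,
    shortest_path,
    shortest_path_features,
    token_features,
    word_ngram_features,
)
from tests.conftest import build_sentence, token_by_surface


def _tok(surface, lemma=None, pos="NN", index=1, start=0):
    lemma = lemma if lemma is not None else surface.lower()
    return Token(index, surface, lemma, pos, Span(start, start + len(surface)))


class TestTokenFeatures:
    def test_char_ngrams_of_long_word(self):
        g = token_features(_tok("transactivate"))
        for name in ("cn1:t", "cn1:r", "cn2:tr", "cn2:ra", "cn3:tra", "cn3:ran",
                     "cn4:tran", "cn4:rans"):
            assert name in g.features

    def test_lemma_and_pos(self):
        g = token_features(_tok("were", lemma="be", pos="VBD"))
        assert "lemma:be" in g.features
        assert "pos:VBD" in g.features

    def test_single_character_token(self):
        g = token_features(_tok("a", pos="DT"))
        grams = [n for n in g.features if n.startswith("cn")]
        assert grams == ["cn1:a"]

    def test_char_type_indicators(self):
        g = token_features(_tok("IEXC29S"))
        assert "ct:has-digit" in g.features
        assert "ct:all-upper" in g.features
        g2 = token_features(_tok("c-sis/PDGF-B"))
        assert "ct:has-hyphen" in g2.features
        assert "ct:has-symbol" in g2.features


class TestNeighbouringWordFeatures:
    def test_two_step_path_of_worked_example(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        target = token_by_surface(sent, "transactivate")
        g = neighbouring_word_features(target, worked_graph)
        # the printed 2-step path, lemma-rendered, target last
        assert "wd2:be <PRD-" in g.features
        assert "wd3:<PRD- unable <AMOD-" in g.features
        assert "w2:be unable" in g.features
        assert "w2:unable transactivate" in g.features
        assert "w3:be unable transactivate" in g.features
        assert "d2:<PRD- <AMOD-" in g.features

    def test_token_features_of_reached_words(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        g = neighbouring_word_features(token_by_surface(sent, "transactivate"), worked_graph)
        assert "tok:lemma:unable" in g.features
        assert "tok:lemma:be" in g.features

    def test_isolated_token_empty_group(self):
        tok = _tok("alone")
        graph = DependencyGraph(parser="p", tokens=[tok], edges=[])
        g = neighbouring_word_features(tok, graph)
        assert len(g) == 0


class TestWordNgramFeatures:
    def test_window_contents_worked_example(self, worked_example):
        sent = worked_example.sentences[0]
        target = token_by_surface(sent, "transactivate")
        g = word_ngram_features(target, sent)
        unigrams = sorted(n for n in g.features if n.startswith("w1:"))
        words = {u.split(":", 1)[1].rsplit("/", 2)[0] for u in unigrams}
        assert words == {
            "unable", "to", "significantly", "transactivate", "the",
            "c-sis/pdgf-b", "promoter",
        }

    def test_sentence_initial_truncation(self, worked_example):
        sent = worked_example.sentences[0]
        g = word_ngram_features(sent.tokens[0], sent)
        words = {
            n.split(":", 1)[1].rsplit("/", 2)[0]
            for n in g.features
            if n.startswith("w1:")
        }
        # only the target plus the three following words
        assert words == {"iexc29s", "be", "unable", "to"}

    def test_mixed_position_marks_across_target(self):
        rows = [
            ("aa", "aa", "NN", 0, "ROOT"),
            ("bb", "bb", "NN", 1, "X"),
            ("cc", "cc", "NN", 1, "X"),
            ("dd", "dd", "NN", 1, "X"),
            ("ee", "ee", "NN", 1, "X"),
        ]
        sent, _ = build_sentence(rows)
        g = word_ngram_features(sent.tokens[2], sent)  # target "cc"
        assert "w3:bb/NN/B cc/NN/T dd/NN/A" in g.features


class TestPairNgramFeatures:
    def test_worked_example_segmentation(self, worked_example):
        sent = worked_example.sentences[0]
        trig = [token_by_surface(sent, "transactivate")]
        arg = [token_by_surface(sent, "c-sis/PDGF-B")]
        g = pair_ngram_features(trig, arg, sent)
        marks = {}
        for name in g.features:
            if name.startswith("w1:"):
                word, _, mark = name.split(":", 1)[1].rsplit("/", 2)
                marks.setdefault(mark, set()).add(word)
        assert marks["B"] == {"unable", "to", "significantly"}
        assert marks["M"] == {"transactivate", "the", "c-sis/pdgf-b"}
        assert marks["A"] == {"promoter"}

    def test_adjacent_pair_between_is_pair_only(self):
        rows = [("x", "x", "NN", 0, "ROOT"), ("y", "y", "NN", 1, "X")]
        sent, _ = build_sentence(rows)
        g = pair_ngram_features([sent.tokens[0]], [sent.tokens[1]], sent)
        between = {
            n.split(":", 1)[1].rsplit("/", 2)[0]
            for n in g.features
            if n.startswith("w1:") and n.endswith("/M")
        }
        assert between == {"x", "y"}

    def test_pair_at_sentence_end_no_after(self, worked_example):
        sent = worked_example.sentences[0]
        g = pair_ngram_features(
            [token_by_surface(sent, "transactivate")],
            [token_by_surface(sent, "promoter")],
            sent,
        )
        assert not any(n.endswith("/A") for n in g.features if n.startswith("w1:"))

    def test_cross_sentence_raises(self, worked_example):
        sent = worked_example.sentences[0]
        foreign = _tok("foreign", index=99, start=500)
        with pytest.raises(CrossSentenceError):
            pair_ngram_features([sent.tokens[0]], [foreign], sent)


class TestShortestPathFeatures:
    def test_worked_example_length_three(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        g = shortest_path_features(
            token_by_surface(sent, "IEXC29S"),
            token_by_surface(sent, "transactivate"),
            worked_graph,
        )
        assert "len:3" in g.features

    def test_governor_dependent_units(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        g = shortest_path_features(
            token_by_surface(sent, "IEXC29S"),
            token_by_surface(sent, "transactivate"),
            worked_graph,
        )
        assert "gd1:iexc29s->be" in g.features
        assert "gd1:be<-unable" in g.features

    def test_edge_and_vertex_walks(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        g = shortest_path_features(
            token_by_surface(sent, "IEXC29S"),
            token_by_surface(sent, "transactivate"),
            worked_graph,
        )
        assert "ew:iexc29s -SUB> be" in g.features
        assert "ews:iexc29s -SUB>" in g.features
        assert "vw:-SUB> be <PRD-" in g.features
        assert "vws:-SUB> <PRD-" in g.features

    def test_identical_endpoints(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        tok = token_by_surface(sent, "unable")
        g = shortest_path_features(tok, tok, worked_graph)
        assert g.features == {"len:0": 1.0}

    def test_disconnected_pair(self):
        toks = [_tok("a", index=1, start=0), _tok("b", index=2, start=2)]
        graph = DependencyGraph(parser="p", tokens=toks, edges=[])
        g = shortest_path_features(toks[0], toks[1], graph)
        assert g.features == {"no-path": 1.0}


def _brute_force_shortest(edges, n, a, b):
    """Independent oracle: enumerate every simple path by DFS."""
    adj = {i: set() for i in range(1, n + 1)}
    for h, d, _ in edges:
        adj[h].add(d)
        adj[d].add(h)
    best = None

    def dfs(path):
        nonlocal best
        if path[-1] == b:
            cand = (len(path), path[:])
            if best is None or cand < best:
                best = cand
            return
        for nxt in sorted(adj[path[-1]]):
            if nxt not in path:
                dfs(path + [nxt])

    dfs([a])
    return None if best is None else best[1]


class TestShortestPathOracle:
    def test_random_trees_match_brute_force(self):
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(2, 10)
            tokens = [_tok(f"w{i}", index=i, start=3 * i) for i in range(1, n + 1)]
            edges = [
                (rng.randint(1, i - 1), i, "DEP") for i in range(2, n + 1)
            ]  # random tree
            graph = DependencyGraph(parser="p", tokens=tokens, edges=edges)
            a, b = rng.sample(range(1, n + 1), 2)
            expected = _brute_force_shortest(edges, n, a, b)
            got = shortest_path(tokens[a - 1], tokens[b - 1], graph)
            assert got == expected


class TestSentenceAndCitationFeatures:
    def test_second_of_eight(self):
        sent, _ = build_sentence([("x", "x", "NN", 0, "ROOT")], index=2)
        g = sentence_position_features(sent, 8)
        assert g.features["abs:2"] == 1.0
        assert g.features["rel"] == pytest.approx(0.25)

    def test_only_sentence(self):
        sent, _ = build_sentence([("x", "x", "NN", 0, "ROOT")], index=1)
        g = sentence_position_features(sent, 1)
        assert g.features["rel"] == pytest.approx(1.0)

    def test_third_of_four(self):
        sent, _ = build_sentence([("x", "x", "NN", 0, "ROOT")], index=3)
        assert sentence_position_features(sent, 4).features["rel"] == pytest.approx(0.75)


class TestCuePathFeatures:
    def test_paths_tagged_with_entry(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        trig = token_by_surface(sent, "transactivate")
        cue_tok = token_by_surface(sent, "significantly")
        mention = CueMention(
            span=cue_tok.span,
            word="significantly",
            entries=[CueEntry("significantly", "Manner", "High", 1.0)],
        )
        g = cue_path_features([("trigger", trig)], [mention], sent, worked_graph)
        assert "Manner:High|present" in g.features
        assert "Manner:High|trigger|len:1" in g.features

    def test_ambiguous_cue_emitted_under_both_prefixes(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        trig = token_by_surface(sent, "transactivate")
        cue_tok = token_by_surface(sent, "unable")
        mention = CueMention(
            span=cue_tok.span,
            word="unable",
            entries=[
                CueEntry("unable", "KT", "Analysis", 1.0),
                CueEntry("unable", "CL", "L1", 1.0),
            ],
        )
        g = cue_path_features([("trigger", trig)], [mention], sent, worked_graph)
        kt = {n[len("KT:Analysis|"):] for n in g.features if n.startswith("KT:Analysis|")}
        cl = {n[len("CL:L1|"):] for n in g.features if n.startswith("CL:L1|")}
        assert kt == cl and kt  # identical path features under both prefixes

    def test_no_cues_empty(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        trig = token_by_surface(sent, "transactivate")
        g = cue_path_features([("trigger", trig)], [], sent, worked_graph)
        assert len(g) == 0


class TestHeadToken:
    def test_head_is_token_with_external_governor(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        mention = [token_by_surface(sent, "the"), token_by_surface(sent, "promoter")]
        assert head_token(mention, worked_graph).surface == "promoter"


class TestHashing:
    def test_default_dimension(self):
        assert FeatureConfig().dimension == 2**20 == 1048576

    def test_deterministic_across_calls(self):
        assert hash_index("g", "feat", 20) == hash_index("g", "feat", 20)

    def test_indices_in_range(self):
        for i in range(200):
            idx = hash_index("group", f"name{i}", 20)
            assert 0 <= idx < 2**20

    def test_collision_additivity(self):
        cfg = FeatureConfig(hash_bits=4)  # force collisions in a 16-slot space
        by_idx = {}
        collision = None
        for i in range(200):
            idx = hash_index("g", f"n{i}", 4)
            if idx in by_idx:
                collision = (by_idx[idx], f"n{i}", idx)
                break
            by_idx[idx] = f"n{i}"
        assert collision is not None
        n1, n2, idx = collision
        g = FeatureGroup(tag="g", features={n1: 1.5, n2: 2.5})
        vec = hash_features([g], cfg)
        assert vec.data[idx] == pytest.approx(4.0)

    def test_purity_identical_named_sets(self, worked_example, worked_graph):
        sent = worked_example.sentences[0]
        tok = token_by_surface(sent, "transactivate")
        g1 = neighbouring_word_features(tok, worked_graph)
        g2 = neighbouring_word_features(tok, worked_graph)
        assert g1.features == g2.features
        assert feature_dump([g1]) == feature_dump([g2])


class TestNormaliseTypewise:
    def test_three_four_five(self):
        g = FeatureGroup(tag="g", features={"a": 3.0, "b": 4.0})
        vec = normalise_typewise([g])
        vals = sorted(vec.data.values())
        assert vals == pytest.approx([0.6, 0.8])

    def test_global_norm_is_one(self):
        g1 = FeatureGroup(tag="g1", features={"a": 3.0, "b": 4.0})
        g2 = FeatureGroup(tag="g2", features={"c": 7.0})
        vec = normalise_typewise([g1, g2])
        assert vec.norm() == pytest.approx(1.0)

    def test_each_group_unit_before_global(self):
        g1 = FeatureGroup(tag="g1", features={"a": 3.0, "b": 4.0})
        g2 = FeatureGroup(tag="g2", features={"c": 7.0})
        cfg = FeatureConfig()
        part1 = hash_features([g1], cfg)
        part1.scale(1.0 / part1.norm())
        assert part1.norm() == pytest.approx(1.0)

    def test_all_zero_input(self):
        vec = normalise_typewise([FeatureGroup(tag="g")])
        assert vec.data == {}

    def test_out_of_range_index_rejected(self):
        vec = HashedVector(dimension=16)
        with pytest.raises(IndexError):
            vec.add(16, 1.0)
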