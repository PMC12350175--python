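"""Stem extraction, zipper/downstream stems, graphs, MEE and occlusion."""

import networkx as nx
import numpy as np
import pytest

from intron_atlas.features import (
    IntronAnnotation,
    StemCall,
    avg_helix_confidence,
    coarse_graph,
    extract_stems,
    find_downstream_stem,
    find_zipper_stem,
    fine_graph,
    high_confidence_stems,
    longest_stem,
    max_extrusion_from_ends,
    splice_site_occlusion,
    ss_bp_graph_distance,
)
from intron_atlas.folding import PairSupport
from intron_atlas.structures import SecondaryStructure
from conftest import random_rna


def support_all(structure, value=1.0, n_boot=100):
    return PairSupport(structure.n, {p: value for p in structure.pairs}, n_boot)


def intron_with_stem(length, stem_i, stem_j, stem_len, bp_pos):
    """A synthetic intron whose only helix pairs [stem_i..] with [..stem_j]."""
    seq = ["A"] * length
    pairs = set()
    for k in range(stem_len):
        i = stem_i + k
        j = stem_j - k
        seq[i], seq[j] = "G", "C"
        pairs.add((i, j))
    struct = SecondaryStructure("".join(seq), frozenset(pairs))
    ann = IntronAnnotation("toy", struct.sequence, bp_pos=bp_pos, three_ss=length - 1)
    return struct, ann


class TestExtractStems:
    def test_single_stem(self):
        s = SecondaryStructure.from_dot_bracket("GGGGAAAACCCC", "((((....))))")
        stems = extract_stems(s)
        assert len(stems) == 1 and stems[0].n_bp == 4 and stems[0].bulge_nt == 0

    def test_bulge_merging_threshold(self):
        s = SecondaryStructure.from_dot_bracket("GGGAAGGGAAAACCCCC", "(((..(((...))))))")
        merged = extract_stems(s, max_bulge=2)
        assert [(x.n_bp, x.bulge_nt) for x in merged] == [(6, 2)]
        split = extract_stems(s, max_bulge=1)
        assert [(x.n_bp, x.bulge_nt) for x in split] == [(3, 0), (3, 0)]

    def test_unpaired_structure_empty(self):
        assert extract_stems(SecondaryStructure("AAAAAAA")) == []

    def test_spans(self):
        s = SecondaryStructure.from_dot_bracket("GGGGAAAACCCC", "((((....))))")
        stem = extract_stems(s)[0]
        assert stem.span5 == (0, 3) and stem.span3 == (8, 11)


class TestHighConfidenceStems:
    def _stem(self, n_bp):
        pairs = tuple((i, 50 - i) for i in range(n_bp))
        return StemCall(pairs=pairs, bulge_nt=0)

    def test_rule_boundaries(self):
        for n_bp, conf, kept in [(5, 0.71, True), (4, 0.99, False), (5, 0.70, False)]:
            stem = self._stem(n_bp)
            sup = PairSupport(60, {p: conf for p in stem.pairs}, 100)
            got = high_confidence_stems([stem], sup)
            assert bool(got) is kept, (n_bp, conf)


class TestLongestStem:
    def test_filter_then_max(self):
        s8 = StemCall(tuple((i, 60 - i) for i in range(8)), 0)
        s12 = StemCall(tuple((100 + i, 200 - i) for i in range(12)), 0)
        sup = PairSupport(
            201,
            {**{p: 0.95 for p in s8.pairs}, **{p: 0.85 for p in s12.pairs}},
            100,
        )
        best = longest_stem([s8, s12], sup)
        assert best is not None and best.n_bp == 8

    def test_none_when_no_confident_stem(self):
        s = StemCall(tuple((i, 40 - i) for i in range(6)), 0)
        sup = PairSupport(50, {p: 0.5 for p in s.pairs}, 100)
        assert longest_stem([s], sup) is None


class TestZipperStem:
    def test_accepts_stem_in_linker_window(self, engine):
        # strands at [20,29] and [60,69], bp at 100: L5=20, L3=31, total 51
        struct, ann = intron_with_stem(130, 20, 69, 10, bp_pos=100)
        stem = find_zipper_stem(struct, ann, support_all(struct), engine)
        assert stem is not None and stem.n_bp == 10
        assert stem.dG is not None and stem.dG < 0

    def test_rejects_stem_too_close_to_five_ss(self, engine):
        struct, ann = intron_with_stem(130, 5, 69, 10, bp_pos=100)
        assert find_zipper_stem(struct, ann, support_all(struct), engine) is None

    def test_rejects_linker_out_of_bounds(self, engine):
        # L5=12, L3=21 -> total 33 < 42
        struct, ann = intron_with_stem(90, 12, 48, 8, bp_pos=70)
        assert find_zipper_stem(struct, ann, support_all(struct), engine) is None

    def test_unpaired_intron_none(self, engine):
        struct = SecondaryStructure("A" * 120)
        ann = IntronAnnotation("toy", struct.sequence, bp_pos=100, three_ss=119)
        assert find_zipper_stem(struct, ann, support_all(struct), engine) is None

    def test_low_confidence_rejected(self, engine):
        struct, ann = intron_with_stem(130, 20, 69, 10, bp_pos=100)
        weak = support_all(struct, value=0.5)
        assert find_zipper_stem(struct, ann, weak, engine) is None


class TestDownstreamStem:
    def test_stem_between_bp_and_three_ss(self, engine):
        struct, ann = intron_with_stem(160, 110, 150, 7, bp_pos=100)
        stem = find_downstream_stem(struct, ann, support_all(struct), engine)
        assert stem is not None and stem.n_bp == 7

    def test_stem_straddling_bp_rejected(self, engine):
        struct, ann = intron_with_stem(160, 95, 150, 7, bp_pos=100)
        assert find_downstream_stem(struct, ann, support_all(struct), engine) is None

    def test_longer_of_two_returned(self, engine):
        length, bp = 200, 100
        seq = ["A"] * length
        pairs = set()
        for k in range(6):  # 6-bp stem
            i, j = 110 + k, 140 - k
            seq[i], seq[j] = "G", "C"
            pairs.add((i, j))
        for k in range(9):  # 9-bp stem further downstream
            i, j = 150 + k, 190 - k
            seq[i], seq[j] = "G", "C"
            pairs.add((i, j))
        struct = SecondaryStructure("".join(seq), frozenset(pairs))
        ann = IntronAnnotation("toy", struct.sequence, bp_pos=bp, three_ss=length - 1)
        stem = find_downstream_stem(struct, ann, support_all(struct), engine)
        assert stem is not None and stem.n_bp == 9


def brute_force_stem_selection(struct, ann, support, engine, mode):
    """Independent re-derivation: walk sorted pairs into merged runs, then
    filter and select with plain loops."""
    partner = struct.partner()
    plist = sorted(struct.pairs)
    runs, cur, bulge = [], [], 0
    for p in plist:
        if cur:
            i1, j1 = cur[-1]
            i2, j2 = p
            interior = list(range(i1 + 1, i2)) + list(range(j2 + 1, j1))
            ok = (
                i2 > i1
                and j2 < j1
                and all(q not in partner for q in interior)
                and bulge + len(interior) <= 5
            )
            if ok:
                cur.append(p)
                bulge += len(interior)
                continue
            runs.append((cur, bulge))
            cur, bulge = [], 0
        cur = [p]
    if cur:
        runs.append((cur, bulge))
    best = None
    for pairs, _ in runs:
        n_bp = len(pairs)
        conf = 100 * np.mean([support.get(i, j) for i, j in pairs])
        first_i = pairs[0][0]
        last_j = max(j for _, j in pairs)
        if n_bp < 6 or conf < 70:
            continue
        if mode == "zipper":
            l5, l3 = first_i, ann.bp_pos - last_j
            if l5 < 10 or l3 < 20 or not (42 <= l5 + l3 <= 85):
                continue
        else:
            if not (first_i > ann.bp_pos and last_j < ann.three_ss):
                continue
        if best is None or n_bp > len(best):
            best = pairs
    return tuple(best) if best else None


@pytest.mark.parametrize("mode", ["zipper", "downstream"])
def test_stem_selection_matches_brute_force(mode, engine, rng):
    """Zipper/downstream selection agrees with an exhaustive independent
    enumeration over all merged stems on random structures."""
    for trial in range(30):
        n = int(rng.integers(120, 200))
        seq = random_rna(rng, n)
        struct = engine.fold(seq)
        sup = PairSupport(
            n, {p: float(rng.uniform(0.5, 1.0)) for p in struct.pairs}, 100
        )
        bp_pos = int(rng.integers(n // 2, n - 20))
        ann = IntronAnnotation("r", seq, bp_pos=bp_pos, three_ss=n - 1)
        if mode == "zipper":
            got = find_zipper_stem(struct, ann, sup, engine)
        else:
            got = find_downstream_stem(struct, ann, sup, engine)
        expected = brute_force_stem_selection(struct, ann, sup, engine, mode)
        if expected is None:
            assert got is None, trial
        else:
            assert got is not None and got.n_bp == len(expected), trial


class TestGraphsAndMee:
    def test_unpaired_chain_midpoint(self):
        assert max_extrusion_from_ends(SecondaryStructure("AAAAA")) == pytest.approx(0.4)

    def test_hairpin_fine_graph_bfs(self):
        s = SecondaryStructure.from_dot_bracket("GGGGAAAACCCC", "((((....))))")
        assert fine_graph(s).number_of_nodes() == 8
        assert max_extrusion_from_ends(s) == pytest.approx(5 / 12)

    def test_single_nucleotide(self):
        assert max_extrusion_from_ends(SecondaryStructure("A")) == 0.0

    def test_mee_matches_explicit_bfs(self, engine, rng):
        for _ in range(20):
            seq = random_rna(rng, int(rng.integers(20, 90)))
            struct = engine.fold(seq)
            g = fine_graph(struct)
            partner = struct.partner()

            def node(p):
                if p in partner:
                    return ("bp", min(p, partner[p]), max(p, partner[p]))
                return ("ss", p)

            d0 = nx.single_source_shortest_path_length(g, node(0))
            d1 = nx.single_source_shortest_path_length(g, node(struct.n - 1))
            expected = max(min(d0[v], d1[v]) for v in g) / struct.n
            assert max_extrusion_from_ends(struct) == pytest.approx(expected)

    def test_mee_bounded_for_unpaired(self, rng):
        for n in (2, 5, 11, 30):
            mee = max_extrusion_from_ends(SecondaryStructure("A" * n))
            assert mee <= 0.5

    def test_coarse_graph_nodes(self):
        s = SecondaryStructure.from_dot_bracket("GGGGAAAACCCCAA", "((((....))))..")
        kinds = {n[0] for n in coarse_graph(s).nodes}
        assert kinds == {"stem", "loop"}


class TestSsBpDistance:
    def test_unpaired_chain(self):
        struct = SecondaryStructure("A" * 100)
        ann = IntronAnnotation("t", struct.sequence, bp_pos=70, three_ss=99)
        assert ss_bp_graph_distance(struct, ann) == 70

    def test_zipper_stem_shortens_distance(self, engine):
        struct, ann = intron_with_stem(130, 10, 99, 30, bp_pos=100)
        d = ss_bp_graph_distance(struct, ann)
        assert d < 100
        # explicit BFS oracle on the constructed fine graph
        g = fine_graph(struct)
        partner = struct.partner()
        src = ("ss", 0)
        dst = ("ss", 100) if 100 not in partner else ("bp", min(100, partner[100]), max(100, partner[100]))
        assert d == nx.shortest_path_length(g, src, dst)

    def test_bp_at_start_zero(self):
        struct = SecondaryStructure("A" * 20)
        ann = IntronAnnotation("t", struct.sequence, bp_pos=1, three_ss=19)
        assert ss_bp_graph_distance(struct, ann) == 1

    def test_adding_pairs_never_increases_distance(self, rng):
        n = 120
        seq = ["A"] * n
        stems = [(10, 99, 8), (30, 80, 6)]
        pair_sets = []
        pairs = set()
        for si, sj, sl in stems:
            for k in range(sl):
                i, j = si + k, sj - k
                seq[i], seq[j] = "G", "C"
                pairs.add((i, j))
            pair_sets.append(set(pairs))
        sequence = "".join(seq)
        ann = IntronAnnotation("t", sequence, bp_pos=105, three_ss=n - 1)
        dists = [
            ss_bp_graph_distance(SecondaryStructure(sequence, frozenset(ps)), ann)
            for ps in [set()] + pair_sets
        ]
        assert all(b <= a for a, b in zip(dists, dists[1:]))


class TestOcclusion:
    def _flanked(self, protected_in_5ss=0):
        flank = "A" * 50
        intron_len = 200
        seq = ["A"] * intron_len
        pairs = set()
        if protected_in_5ss:
            # 9-bp stem starting right at the intron start (flanked coords 50+)
            for k in range(9):
                i, j = 50 + k, 90 - k
                pairs.add((i, j))
        full = flank + "".join(seq) + flank
        chars = list(full)
        for i, j in pairs:
            chars[i], chars[j] = "G", "C"
        struct = SecondaryStructure("".join(chars), frozenset(pairs))
        ann = IntronAnnotation(
            "t", struct.sequence[50 : 50 + intron_len], bp_pos=150, three_ss=intron_len - 1,
            flank5=flank, flank3=flank,
        )
        return struct, ann

    def test_fully_unpaired_zero(self):
        struct, ann = self._flanked()
        res = splice_site_occlusion(struct, ann, support_all(struct))
        assert all(r.protected_fraction == 0.0 for r in res.values())

    def test_one_third_protected(self):
        struct, ann = self._flanked(protected_in_5ss=True)
        res = splice_site_occlusion(struct, ann, support_all(struct))
        # 27-nt 5'SS window [34, 60]; stem 5' strand covers 50-58 -> 9 nt
        assert res["five_ss"].protected_fraction == pytest.approx(9 / 27)

    def test_matches_per_position_membership(self):
        struct, ann = self._flanked(protected_in_5ss=True)
        sup = support_all(struct)
        res = splice_site_occlusion(struct, ann, sup)
        stems = high_confidence_stems(extract_stems(struct, 5), sup)
        for r in res.values():
            lo, hi = r.interval
            count = 0
            for p in range(lo, hi + 1):
                inside = any(
                    s.span5[0] <= p <= s.span5[1] or s.span3[0] <= p <= s.span3[1]
                    for s in stems
                )
                count += inside
            assert r.protected_fraction == pytest.approx(count / (hi - lo + 1))


def test_avg_helix_confidence_min_length_rule():
    long_stem = StemCall(tuple((i, 60 - i) for i in range(6)), 0)
    short_stem = StemCall(tuple((100 + i, 140 - i) for i in range(4)), 0)
    sup = PairSupport(
        141, {**{p: 0.9 for p in long_stem.pairs}, **{p: 0.1 for p in short_stem.pairs}}, 100
    )
    # only stems of >= 6 bp enter the average
    assert avg_helix_confidence([long_stem, short_stem], sup) == pytest.approx(90.0)
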