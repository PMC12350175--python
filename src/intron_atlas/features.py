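"""Structural feature extraction for introns.

Builds stems and structure graphs from a secondary structure, then derives
the features used throughout the analysis: high-confidence stems, zipper
stems (linking the 5' splice site to the branch point under spliceosome
geometric constraints), downstream stems (between branch point and 3'
splice site), maximum extrusion from ends (MEE), longest stem, splice-site
occlusion and the 5'SS-branch-point graph distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import networkx as nx
import numpy as np

from .folding import FoldingEngine, PairSupport, stem_confidence
from .structures import SecondaryStructure

# Geometric constants for the zipper-stem definition: derived from 3D
# modelling of intron stems in the A-complex spliceosome and consumed here
# as fixed configuration defaults.
ZIPPER_LINKER_MIN = 42
ZIPPER_LINKER_MAX = 85
ZIPPER_MIN_FROM_5SS = 10
ZIPPER_MIN_FROM_BP = 20
ZIPPER_MAX_BULGE = 5

#: occlusion-analysis windows (upstream, downstream) around each landmark,
#: where intron nucleotides thread through spliceosome structures
OCCLUSION_WINDOWS = {"five_ss": (16, 10), "bp": (33, 21), "three_ss": (8, 20)}


@dataclass(frozen=True)
class IntronAnnotation:
    """Intron landmarks, 0-based within the intron sequence.

    ``five_ss`` is position 0 by convention (first base of the GUAUGU
    motif), ``bp_pos`` is the index of the branch adenosine (6th nt of
    UACUAAC), and ``three_ss`` indexes the last intron nucleotide (the G
    of YAG).
    """

    gene_id: str
    intron_seq: str
    bp_pos: int
    three_ss: int
    five_ss: int = 0
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self):
        if not (0 < self.bp_pos < self.three_ss):
            raise ValueError("require 0 < bp_pos < three_ss")
        if len(self.intron_seq) != self.three_ss + 1:
            raise ValueError("intron_seq length must equal three_ss + 1")


@dataclass(frozen=True)
class StemCall:
    """A helix, possibly spanning small interior bulges.

    ``pairs`` are ordered outermost-to-innermost; ``span5``/``span3`` are
    inclusive (start, end) intervals of the 5' and 3' strands, and
    ``bulge_nt`` counts unpaired nucleotides interior to the stem.
    """

    pairs: tuple
    bulge_nt: int
    confidence: Optional[float] = None  # percent
    dG: Optional[float] = None  # kcal/mol

    @property
    def n_bp(self) -> int:
        return len(self.pairs)

    @property
    def span5(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0])

    @property
    def span3(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1])


# ---------------------------------------------------------------------------
# stems


def extract_stems(structure: SecondaryStructure, max_bulge: int = 0) -> list[StemCall]:
    """Merge stacked base pairs into stems, bridging small bulges.

    Consecutive pairs are merged while every intervening position on both
    strands is unpaired and the stem's total interior bulge stays at or
    below ``max_bulge`` nucleotides. Stems are returned 5'-to-3' by their
    outermost pair.
    """
    partner = structure.partner()
    plist = sorted(structure.pairs)
    stems: list[StemCall] = []
    current: list[tuple[int, int]] = []
    current_bulge = 0

    def flush():
        nonlocal current, current_bulge
        if current:
            stems.append(StemCall(pairs=tuple(current), bulge_nt=current_bulge))
        current, current_bulge = [], 0

    for pair in plist:
        if not current:
            current = [pair]
            continue
        i1, j1 = current[-1]
        i2, j2 = pair
        if i2 > i1 and j2 < j1:
            gap5 = range(i1 + 1, i2)
            gap3 = range(j2 + 1, j1)
            if all(p not in partner for p in gap5) and all(p not in partner for p in gap3):
                added = len(gap5) + len(gap3)
                if current_bulge + added <= max_bulge:
                    current.append(pair)
                    current_bulge += added
                    continue
        flush()
        current = [pair]
    flush()
    stems.sort(key=lambda s: s.pairs[0][0])
    return stems


def with_confidence(stems: list[StemCall], support: PairSupport, aggregate: str = "mean") -> list[StemCall]:
    return [replace(s, confidence=stem_confidence(s, support, aggregate)) for s in stems]


def high_confidence_stems(
    stems: list[StemCall],
    support: PairSupport,
    min_bp: int = 5,
    min_conf: float = 70.0,
) -> list[StemCall]:
    """Stems with at least ``min_bp`` pairs and confidence strictly above
    ``min_conf`` percent (the generic high-confidence rule)."""
    out = []
    for stem in with_confidence(stems, support):
        if stem.n_bp >= min_bp and stem.confidence > min_conf:
            out.append(stem)
    return out


def avg_helix_confidence(stems: list[StemCall], support: PairSupport, min_bp: int = 6) -> float:
    """Mean confidence (percent) over stems of at least ``min_bp`` pairs."""
    confs = [stem_confidence(s, support) for s in stems if s.n_bp >= min_bp]
    return float(np.mean(confs)) if confs else float("nan")


def longest_stem(
    stems: list[StemCall],
    support: PairSupport,
    max_loop: int = 10,
    min_conf: float = 90.0,
) -> Optional[StemCall]:
    """Longest stem among those with confidence >= ``min_conf`` percent.

    Expects ``stems`` extracted with ``max_bulge=max_loop`` so the loop
    budget is already enforced; ties go to the 5'-most stem.
    """
    best = None
    for stem in with_confidence(stems, support):
        if stem.bulge_nt > max_loop or stem.confidence < min_conf:
            continue
        if best is None or stem.n_bp > best.n_bp:
            best = stem
    return best


# ---------------------------------------------------------------------------
# zipper and downstream stems


def _attach_dG(stem: StemCall, structure: SecondaryStructure, engine: FoldingEngine) -> StemCall:
    seq = structure.sequence
    strand5 = "".join(seq[i] for i, _ in stem.pairs)
    strand3 = "".join(seq[j] for _, j in reversed(stem.pairs))
    return replace(stem, dG=engine.duplex_dG(strand5, strand3))


def find_zipper_stem(
    structure: SecondaryStructure,
    annotation: IntronAnnotation,
    support: PairSupport,
    engine: FoldingEngine,
    min_bp: int = 6,
    min_conf: float = 70.0,
    max_bulge: int = ZIPPER_MAX_BULGE,
    linker_min: int = ZIPPER_LINKER_MIN,
    linker_max: int = ZIPPER_LINKER_MAX,
    min_from_5ss: int = ZIPPER_MIN_FROM_5SS,
    min_from_bp: int = ZIPPER_MIN_FROM_BP,
) -> Optional[StemCall]:
    """Longest stem linking the 5' splice site and branch point.

    Both strands must lie between the 5'SS and the branch adenosine; the
    stem must start at least ``min_from_5ss`` nt into the intron and end
    at least ``min_from_bp`` nt before the branch point, with the total
    linker (both sides) between ``linker_min`` and ``linker_max`` nt.
    Ties on length go to the more stable duplex, then 5'-most.
    """
    bp_pos = annotation.bp_pos
    candidates = []
    for stem in with_confidence(extract_stems(structure, max_bulge), support):
        l5 = stem.span5[0]
        l3 = bp_pos - stem.span3[1]
        if l5 < min_from_5ss or l3 < min_from_bp:
            continue
        if not (linker_min <= l5 + l3 <= linker_max):
            continue
        if stem.n_bp < min_bp or stem.confidence < min_conf:
            continue
        candidates.append(_attach_dG(stem, structure, engine))
    if not candidates:
        return None
    return min(candidates, key=lambda s: (-s.n_bp, s.dG, s.span5[0]))


def find_downstream_stem(
    structure: SecondaryStructure,
    annotation: IntronAnnotation,
    support: PairSupport,
    engine: FoldingEngine,
    min_bp: int = 6,
    min_conf: float = 70.0,
    max_bulge: int = ZIPPER_MAX_BULGE,
) -> Optional[StemCall]:
    """Longest qualifying stem with both strands strictly between the
    branch point and the 3' splice site."""
    bp_pos, three_ss = annotation.bp_pos, annotation.three_ss
    candidates = []
    for stem in with_confidence(extract_stems(structure, max_bulge), support):
        if not (stem.span5[0] > bp_pos and stem.span3[1] < three_ss):
            continue
        if stem.n_bp < min_bp or stem.confidence < min_conf:
            continue
        candidates.append(_attach_dG(stem, structure, engine))
    if not candidates:
        return None
    return min(candidates, key=lambda s: (-s.n_bp, s.dG, s.span5[0]))


# ---------------------------------------------------------------------------
# structure graphs


def fine_graph(structure: SecondaryStructure) -> nx.Graph:
    """Graph with a node per base pair and per unpaired position, edges
    between backbone-consecutive elements."""
    partner = structure.partner()
    node_of = {}
    for p in range(structure.n):
        if p in partner:
            i, j = min(p, partner[p]), max(p, partner[p])
            node_of[p] = ("bp", i, j)
        else:
            node_of[p] = ("ss", p)
    g = nx.Graph()
    g.add_nodes_from(set(node_of.values()))
    for p in range(structure.n - 1):
        a, b = node_of[p], node_of[p + 1]
        if a != b:
            g.add_edge(a, b)
    return g


def coarse_graph(structure: SecondaryStructure) -> nx.Graph:
    """Graph with a node per stem and per maximal unpaired run.

    Stems use zero-bulge merging; unpaired runs are labelled by their
    interval. Edges connect backbone-adjacent elements.
    """
    partner = structure.partner()
    stems = extract_stems(structure, max_bulge=0)
    node_of: dict[int, tuple] = {}
    for si, stem in enumerate(stems):
        for i, j in stem.pairs:
            node_of[i] = ("stem", si)
            node_of[j] = ("stem", si)
    run_start = None
    for p in range(structure.n + 1):
        unpaired = p < structure.n and p not in partner
        if unpaired and run_start is None:
            run_start = p
        elif not unpaired and run_start is not None:
            for q in range(run_start, p):
                node_of[q] = ("loop", run_start, p - 1)
            run_start = None
    g = nx.Graph()
    g.add_nodes_from(set(node_of.values()))
    for p in range(structure.n - 1):
        a, b = node_of[p], node_of[p + 1]
        if a != b:
            g.add_edge(a, b)
    return g


def _element_node(structure: SecondaryStructure, pos: int):
    partner = structure.partner()
    if pos in partner:
        i, j = min(pos, partner[pos]), max(pos, partner[pos])
        return ("bp", i, j)
    return ("ss", pos)


def max_extrusion_from_ends(structure: SecondaryStructure) -> float:
    """Normalized maximum extrusion from ends (MEE).

    On the fine graph, each node's distance is the shorter of its BFS
    distances to the node containing position 0 and the node containing
    the last position; MEE is the maximum such distance divided by the
    sequence length.
    """
    n = structure.n
    if n == 0:
        raise ValueError("empty structure")
    if n == 1:
        return 0.0
    g = fine_graph(structure)
    d0 = nx.single_source_shortest_path_length(g, _element_node(structure, 0))
    d1 = nx.single_source_shortest_path_length(g, _element_node(structure, n - 1))
    mee = max(min(d0[v], d1[v]) for v in g.nodes)
    return mee / n


def ss_bp_graph_distance(structure: SecondaryStructure, annotation: IntronAnnotation) -> int:
    """Shortest fine-graph path (edge count) from the 5' splice site to
    the branch adenosine."""
    if annotation.bp_pos >= structure.n:
        raise ValueError("branch point outside structure")
    g = fine_graph(structure)
    src = _element_node(structure, annotation.five_ss)
    dst = _element_node(structure, annotation.bp_pos)
    return nx.shortest_path_length(g, src, dst)


# ---------------------------------------------------------------------------
# splice-site occlusion


@dataclass(frozen=True)
class OcclusionResult:
    interval: tuple[int, int]  # inclusive, in flanked coordinates
    protected_fraction: float
    truncated: bool = False


def splice_site_occlusion(
    structure_with_flanks: SecondaryStructure,
    annotation: IntronAnnotation,
    support: PairSupport,
    windows: dict = None,
    min_bp: int = 5,
    min_conf: float = 70.0,
) -> dict[str, OcclusionResult]:
    """Fraction of nucleotides occluded by high-confidence stems in the
    windows around each splice-site landmark.

    The structure must cover flank5 + intron + flank3; landmark positions
    are shifted by the 5' flank length. Windows extend (upstream,
    downstream) nucleotides inclusive of the landmark itself.
    """
    windows = dict(OCCLUSION_WINDOWS if windows is None else windows)
    offset = len(annotation.flank5)
    n = structure_with_flanks.n
    expected = offset + len(annotation.intron_seq) + len(annotation.flank3)
    if n != expected:
        raise ValueError("flanked structure length inconsistent with annotation")
    hc = high_confidence_stems(
        extract_stems(structure_with_flanks, max_bulge=ZIPPER_MAX_BULGE),
        support,
        min_bp=min_bp,
        min_conf=min_conf,
    )
    protected = np.zeros(n, dtype=bool)
    for stem in hc:
        protected[stem.span5[0] : stem.span5[1] + 1] = True
        protected[stem.span3[0] : stem.span3[1] + 1] = True
    landmarks = {
        "five_ss": offset + annotation.five_ss,
        "bp": offset + annotation.bp_pos,
        "three_ss": offset + annotation.three_ss,
    }
    out = {}
    for name, (up, down) in windows.items():
        center = landmarks[name]
        lo, hi = center - up, center + down
        truncated = lo < 0 or hi > n - 1
        lo, hi = max(lo, 0), min(hi, n - 1)
        seg = protected[lo : hi + 1]
        out[name] = OcclusionResult((lo, hi), float(seg.mean()), truncated)
    return out
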