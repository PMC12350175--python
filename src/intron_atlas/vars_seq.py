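"""VARS-seq: design and quantification of intron structure variants.

Variant design mutates the 5' strands of a target stem set (or a loop),
scores candidates against the native secondary structure with variable-
and constant-region penalties, and installs compensatory 3'-strand
rescues. Quantification assigns barcodes to variants by genomic
consensus, classifies RNA reads as spliced or unspliced by exact junction
matching, deduplicates UMIs, and tests variant-versus-wild-type retained
intron (RI) fractions with two-sided permutation tests summarized as
signed RI scores.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from math import comb, log10
from itertools import combinations
from typing import Optional

import numpy as np

from .structures import SecondaryStructure, clean_rna

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# design types


@dataclass(frozen=True)
class StemSetTarget:
    """A set of stems (or one loop) targeted for disruption.

    ``variable_region`` is the union of half-open intervals to mutate;
    it must not touch the 5' splice site, branch point or 3' splice site
    motifs (the caller's responsibility, checked against ``protected``
    intervals when provided).
    """

    intron_id: str
    stems: tuple  # tuple of pair-tuples, one per member stem
    variable_region: tuple  # tuple of (start, stop) half-open intervals
    kind: str = "stem_set"  # stem_set | loop
    protected: tuple = ()

    def positions(self) -> list[int]:
        out = []
        for start, stop in self.variable_region:
            out.extend(range(start, stop))
        return sorted(set(out))

    def __post_init__(self):
        pos = set(self.positions())
        for start, stop in self.protected:
            if pos & set(range(start, stop)):
                raise ValueError("variable region overlaps a protected splice-site motif")


@dataclass(frozen=True)
class VariantRecord:
    variant_id: str
    sequence: str
    kind: str  # wild_type | disruption | rescue
    penalties: tuple = (0.0, 0.0, 0.0)  # (variable, constant, rescue)
    selected: bool = False

    @property
    def total_penalty(self) -> float:
        return float(sum(p for p in self.penalties if p == p))


# ---------------------------------------------------------------------------
# candidate generation and scoring


def generate_candidates(
    target: StemSetTarget,
    wild_type: str,
    n_random: int = 10_000,
    n_shuffled: int = 10_000,
    seed: int = 0,
) -> list[str]:
    """Random and shuffled mutations of the variable region.

    Randomized candidates draw uniform bases over the region; shuffled
    candidates permute the region's own bases. The output is
    deduplicated (wild type excluded) and deterministic under the seed.
    """
    wt = clean_rna(wild_type)
    positions = target.positions()
    if not positions:
        raise ValueError("variable region is empty")
    if max(positions) >= len(wt):
        raise ValueError("variable region outside the wild-type sequence")
    rng = np.random.default_rng(seed)
    region = [wt[p] for p in positions]
    out: dict[str, None] = {}

    def install(bases) -> str:
        chars = list(wt)
        for p, b in zip(positions, bases):
            chars[p] = b
        return "".join(chars)

    for _ in range(n_random):
        bases = [("ACGU")[k] for k in rng.integers(0, 4, size=len(positions))]
        out.setdefault(install(bases))
    if len(positions) > 1:
        for _ in range(n_shuffled):
            out.setdefault(install(rng.permutation(region)))
    candidates = [s for s in out if s != wt]
    return candidates


def score_variant(
    candidate: str,
    wild_type: str,
    native_structure: SecondaryStructure,
    target: StemSetTarget,
    engine,
) -> tuple[float, float]:
    """(variable, constant) penalties for a candidate.

    The candidate is folded in the full intron context. The variable
    penalty is the number of paired residues inside the variable region
    plus the number of base pairs touching it; the constant penalty is
    the number of native base pairs (outside the region) disrupted plus
    half the number of base pairs gained there.
    """
    region = set(target.positions())
    folded = engine.fold(candidate)
    var_residues = sum(1 for p in folded.partner() if p in region)
    var_pairs = sum(1 for i, j in folded.pairs if i in region or j in region)
    variable_penalty = float(var_residues + var_pairs)

    native_out = {p for p in native_structure.pairs if p[0] not in region and p[1] not in region}
    variant_out = {p for p in folded.pairs if p[0] not in region and p[1] not in region}
    disrupted = len(native_out - variant_out)
    gained = len(variant_out - native_out)
    constant_penalty = disrupted + 0.5 * gained
    return variable_penalty, float(constant_penalty)


def design_rescue(
    candidate: str,
    target: StemSetTarget,
    wild_type: str,
    designable_window: Optional[tuple[int, int]] = None,
) -> Optional[str]:
    """Compensatory 3'-strand rescue for a disruption candidate.

    For each pair (i, j) of the target stems whose 5' base was mutated,
    the 3' base is replaced by the Watson-Crick complement of the
    candidate's 5' base, preserving pair geometry. Returns None when any
    3'-strand position falls outside the designable window.
    """
    wt = clean_rna(wild_type)
    cand = clean_rna(candidate)
    chars = list(cand)
    for stem_pairs in target.stems:
        for i, j in stem_pairs:
            if designable_window is not None and not (designable_window[0] <= j < designable_window[1]):
                return None
            chars[j] = WC_COMPLEMENT[cand[i]]
    return "".join(chars)


def rescue_penalty(rescue: str, native_structure: SecondaryStructure, engine) -> float:
    """Base pairs altered between the native structure and the rescue fold."""
    folded = engine.fold(rescue)
    return float(len(folded.pairs ^ native_structure.pairs))


def select_top(candidates: list[VariantRecord], k_min: int = 4, k_max: int = 8) -> list[VariantRecord]:
    """Top candidates by total penalty (ascending), unique by sequence.

    Ties break lexicographically on sequence. Returns up to ``k_max``
    records flagged selected; if fewer than ``k_min`` are available all
    are returned.
    """
    unique: dict[str, VariantRecord] = {}
    for rec in sorted(candidates, key=lambda r: (r.total_penalty, r.sequence)):
        unique.setdefault(rec.sequence, rec)
    ranked = list(unique.values())[:k_max]
    return [replace(r, selected=True) for r in ranked]


# ---------------------------------------------------------------------------
# barcode assignment (genomic DNA)


@dataclass(frozen=True)
class BarcodeAssignment:
    barcode: str
    variant_id: Optional[str]  # None => consensus unmatched to any design
    consensus: str
    genomic_count: int


def assign_barcodes(
    reads_by_barcode: dict[str, list[str]],
    designs: dict[str, str],
    min_reads: int = 5,
    max_secondary: float = 0.05,
) -> list[BarcodeAssignment]:
    """Map barcodes to designed variants by per-position majority consensus.

    Barcodes with fewer than ``min_reads`` reads, or with more than
    ``max_secondary`` of reads disagreeing with the consensus, are
    dropped. The consensus is matched exactly to a design; unmatched
    consensuses are retained with ``variant_id=None``.
    """
    seq_of_design = {seq: vid for vid, seq in designs.items()}
    out = []
    for barcode in sorted(reads_by_barcode):
        reads = reads_by_barcode[barcode]
        if len(reads) < min_reads:
            continue
        modal_len = Counter(len(r) for r in reads).most_common(1)[0][0]
        exact = [r for r in reads if len(r) == modal_len]
        cols = ["".join(col) for col in zip(*exact)]
        consensus = "".join(Counter(c).most_common(1)[0][0] for c in cols)
        secondary = sum(1 for r in reads if r != consensus) / len(reads)
        if secondary > max_secondary:
            continue
        out.append(
            BarcodeAssignment(
                barcode=barcode,
                variant_id=seq_of_design.get(consensus),
                consensus=consensus,
                genomic_count=len(reads),
            )
        )
    return out


# ---------------------------------------------------------------------------
# read classification and quantification (RNA)


def classify_read(
    read: str,
    spliced_junction_seq: str,
    unspliced_junction_seq: str,
    spliced_junction_pos: int,
    unspliced_junction_pos: int,
    min_agreement: int = 14,
) -> str:
    """Classify a read as 'spliced', 'unspliced' or 'other'.

    A read matches a junction when it contains an exact window of at
    least ``min_agreement`` nt from the junction reference that spans the
    junction point with at least 1 nt on each side. Reads matching both
    junctions (or neither) are 'other'.
    """
    if len(read) < min_agreement:
        return "other"
    hits_spliced = _spans_junction(read, spliced_junction_seq, spliced_junction_pos, min_agreement)
    hits_unspliced = _spans_junction(read, unspliced_junction_seq, unspliced_junction_pos, min_agreement)
    if hits_spliced and not hits_unspliced:
        return "spliced"
    if hits_unspliced and not hits_spliced:
        return "unspliced"
    return "other"


def _spans_junction(read: str, ref: str, junction: int, window: int) -> bool:
    # junction sits between ref[junction-1] and ref[junction]
    for s in range(max(0, junction - window + 1), junction):
        if s + window > len(ref):
            break
        if s + window < junction + 1:
            continue
        if ref[s : s + window] in read:
            return True
    return False


@dataclass(frozen=True)
class BarcodeCounts:
    barcode: str
    variant_id: Optional[str]
    spliced_umis: int
    unspliced_umis: int
    genomic_count: int
    other_umis: int = 0

    @property
    def ri_fraction(self) -> float:
        total = self.spliced_umis + self.unspliced_umis
        return self.unspliced_umis / total if total else float("nan")

    @property
    def normalized_mrna(self) -> float:
        return self.spliced_umis / self.genomic_count if self.genomic_count else float("nan")


@dataclass(frozen=True)
class QuantResult:
    counts: list
    alternative_events: dict  # variant_id -> n_barcodes with a reported alt event


def quantify(
    rna_reads: list[tuple[str, str, str]],
    assignments: list[BarcodeAssignment],
    junctions: dict[str, tuple[str, str, int, int]],
    min_alt_umis: int = 10,
    min_alt_barcodes: int = 3,
    min_agreement: int = 14,
) -> QuantResult:
    """UMI-deduplicated spliced/unspliced quantification per barcode.

    ``rna_reads`` are (barcode, umi, read_seq) records; ``junctions``
    maps variant_id to (spliced_seq, unspliced_seq, spliced_pos,
    unspliced_pos). Barcodes with zero classified UMIs are excluded.
    Alternative ('other') events are reported per variant only when seen
    in at least ``min_alt_umis`` UMIs in a barcode and at least
    ``min_alt_barcodes`` barcodes of that variant.
    """
    assignment_of = {a.barcode: a for a in assignments}
    per_barcode: dict[str, dict[str, set]] = defaultdict(lambda: {"spliced": set(), "unspliced": set(), "other": set()})
    for barcode, umi, read in rna_reads:
        a = assignment_of.get(barcode)
        if a is None or a.variant_id is None:
            continue
        sj, uj, sp, up = junctions[a.variant_id]
        cat = classify_read(read, sj, uj, sp, up, min_agreement)
        per_barcode[barcode][cat].add(umi)
    counts = []
    alt_barcodes: dict[str, int] = defaultdict(int)
    for barcode in sorted(per_barcode):
        cats = per_barcode[barcode]
        spliced, unspliced = len(cats["spliced"]), len(cats["unspliced"])
        if spliced + unspliced == 0:
            continue
        a = assignment_of[barcode]
        counts.append(
            BarcodeCounts(
                barcode=barcode,
                variant_id=a.variant_id,
                spliced_umis=spliced,
                unspliced_umis=unspliced,
                genomic_count=a.genomic_count,
                other_umis=len(cats["other"]),
            )
        )
        if len(cats["other"]) >= min_alt_umis:
            alt_barcodes[a.variant_id] += 1
    alt_events = {vid: nb for vid, nb in alt_barcodes.items() if nb >= min_alt_barcodes}
    return QuantResult(counts=counts, alternative_events=alt_events)


# ---------------------------------------------------------------------------
# statistics


def permutation_test(
    group_a,
    group_b,
    n_resamples: int = 100_000,
    seed: int = 0,
    exact_threshold: int = 10_000,
) -> float:
    """Two-sided permutation p-value for the difference in means.

    Labels are exchanged between groups; when the number of label
    assignments C(n, |a|) is at most ``exact_threshold`` the null is
    enumerated exactly, otherwise Monte-Carlo resampling with the add-one
    correction p = (1 + #extreme) / (1 + n_resamples) is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    eps = 1e-12
    if comb(n, na) <= exact_threshold:
        extreme = total = 0
        idx = np.arange(n)
        for pick in combinations(idx, na):
            mask = np.zeros(n, dtype=bool)
            mask[list(pick)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            extreme += stat >= observed - eps
            total += 1
        return extreme / total
    rng = np.random.default_rng(seed)
    # vectorized label shuffles
    perms = np.argsort(rng.random((n_resamples, n)), axis=1)
    shuffled = pooled[perms]
    mean_a = shuffled[:, :na].mean(axis=1)
    mean_b = shuffled[:, na:].mean(axis=1)
    stats_null = np.abs(mean_a - mean_b)
    extreme = int(np.sum(stats_null >= observed - eps))
    return (1 + extreme) / (1 + n_resamples)


def ri_score(p: float, wt_mean: float, variant_mean: float, max_score: float = 16.0) -> float:
    """Signed -log10 p: positive when the variant lowers the RI fraction."""
    if not (0 <= p <= 1):
        raise ValueError("p must be in (0, 1]")
    if p == 0:
        magnitude = max_score
    else:
        magnitude = min(-log10(p), max_score)
    sign = 1.0 if variant_mean < wt_mean else -1.0
    return sign * magnitude if magnitude != 0 else 0.0
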