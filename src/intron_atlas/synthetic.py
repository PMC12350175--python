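"""Synthetic data generation for the whole pipeline.

Generates genomes with planted consensus introns (5'SS GUAUGU, branch
point UACUAACN with the branch adenosine at least 42 nt into the intron,
3'SS YAG, bimodal intron lengths), DMS reactivity profiles tied to known
structures (A/C modification rates near 2.7%/2.3%, background 0.35%),
VARS-seq barcode/UMI tables with planted retained-intron effects, and
feature-class matrices for clustering tests. Every generator is bitwise
reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import IntronAnnotation
from .reactivity import ReactivityProfile
from .structures import SecondaryStructure, clean_rna

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_PAIR_CHOICES = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]

#: minimum nt between branch-point motif end and the 3' splice site
MIN_BP_TO_3SS_GAP = 10
#: minimum branch-adenosine offset from the intron start (spliceosome geometry)
MIN_BP_OFFSET = 42

FIVE_SS = "GUAUGU"
BP_CORE = "UACUAAC"  # branch adenosine is the 6th nt (index 5)


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


# ---------------------------------------------------------------------------
# genomes with planted introns


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    n_genes: int = 20
    intron_fraction: float = 1.0
    short_len_range: tuple = (70, 130)
    long_len_range: tuple = (400, 500)
    short_fraction: float = 0.3
    exon_len_range: tuple = (60, 120)
    gc_content: float = 0.4
    minus_strand_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.short_len_range, self.long_len_range, self.exon_len_range):
            if hi < lo:
                raise ValueError("empty length range")
        for p in (self.intron_fraction, self.short_fraction, self.gc_content, self.minus_strand_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class PlantedIntron:
    """Annotation for one planted intron, genomic plus-strand coordinates.

    ``start``/``end`` are the 0-based half-open intron interval on the
    plus strand; ``bp_offset`` is the branch adenosine's index within the
    sense-strand intron sequence.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    bp_offset: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SyntheticGenome:
    sequences: dict  # chrom -> RNA-alphabet sense of plus strand
    introns: list
    genes: dict  # gene_id -> (chrom, start, end, strand)

    def intron_sequence(self, ann: PlantedIntron) -> str:
        """Sense-strand intron sequence (minus-strand genes reverse-
        complemented at read time)."""
        raw = self.sequences[ann.chrom][ann.start : ann.end]
        return revcomp(raw) if ann.strand == "-" else raw

    def intron_annotation(self, ann: PlantedIntron, flank: int = 0) -> IntronAnnotation:
        seq = self.intron_sequence(ann)
        flank5 = flank3 = ""
        if flank:
            chrom_seq = self.sequences[ann.chrom]
            left = chrom_seq[max(0, ann.start - flank) : ann.start]
            right = chrom_seq[ann.end : ann.end + flank]
            if ann.strand == "-":
                flank5, flank3 = revcomp(right), revcomp(left)
            else:
                flank5, flank3 = left, right
        return IntronAnnotation(
            gene_id=ann.gene_id,
            intron_seq=seq,
            bp_pos=ann.bp_offset,
            three_ss=len(seq) - 1,
            flank5=flank5,
            flank3=flank3,
        )


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=n, p=p)]) if n else ""


def min_intron_length(min_bp_offset: int = MIN_BP_OFFSET, gap: int = MIN_BP_TO_3SS_GAP) -> int:
    """Shortest intron that can hold the 5'SS, a branch point at least
    ``min_bp_offset`` nt in, the BP->3'SS gap and the 3'SS."""
    # branch motif ends at min_bp_offset + 3 (N included), then gap, then YAG
    return min_bp_offset + 3 + gap + 3


def plant_intron(rng, length: int, gc: float, min_bp_offset: int = MIN_BP_OFFSET) -> tuple[str, int]:
    """Build one consensus intron of the given length; returns (seq, bp_offset)."""
    if length < min_intron_length(min_bp_offset):
        raise ValueError(
            f"intron length {length} cannot satisfy the {min_bp_offset}-nt "
            "5'SS-to-branch-point spacing plus the 3' splice site"
        )
    a_min = min_bp_offset
    a_max = length - MIN_BP_TO_3SS_GAP - 6  # room for N + gap + YAG
    bp = int(rng.integers(a_min, a_max + 1))
    mid1 = _random_seq(rng, bp - 5 - len(FIVE_SS), gc)
    n_base = "ACGU"[rng.integers(4)]
    mid2 = _random_seq(rng, length - (bp + 3) - 3, gc)
    y = "CU"[rng.integers(2)]
    seq = FIVE_SS + mid1 + BP_CORE + n_base + mid2 + y + "AG"
    assert len(seq) == length and seq[bp] == "A"
    return seq, bp


def generate_genome(config: SyntheticGenomeConfig) -> SyntheticGenome:
    """Generate a single-contig genome of spliced genes with planted
    consensus introns; deterministic under the config seed."""
    rng = np.random.default_rng(config.seed)
    if config.short_len_range[1] < min_intron_length():
        raise ValueError(
            "short_len_range cannot place the branch point >=42 nt from the "
            "5' splice site along with the 3' splice site"
        )
    chrom = "chr1"
    parts: list[str] = []
    pos = 0
    introns: list[PlantedIntron] = []
    genes: dict[str, tuple] = {}
    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:04d}"
        exon_lo, exon_hi = config.exon_len_range
        exon5 = _random_seq(rng, int(rng.integers(exon_lo, exon_hi + 1)), config.gc_content)
        exon3 = _random_seq(rng, int(rng.integers(exon_lo, exon_hi + 1)), config.gc_content)
        has_intron = rng.random() < config.intron_fraction
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        if has_intron:
            if rng.random() < config.short_fraction:
                lo, hi = config.short_len_range
            else:
                lo, hi = config.long_len_range
            lo = max(lo, min_intron_length())
            if hi < lo:
                raise ValueError("length range too small for a consensus intron")
            length = int(rng.integers(lo, hi + 1))
            intron_seq, bp = plant_intron(rng, length, config.gc_content)
            gene_seq = exon5 + intron_seq + exon3
            i_start = pos + len(exon5)
            i_end = i_start + length
        else:
            gene_seq = exon5 + exon3
            i_start = i_end = bp = None
        if strand == "-":
            placed = revcomp(gene_seq)
            if has_intron:
                # intron interval on the plus strand after reverse complement
                g_start, g_end = pos, pos + len(gene_seq)
                rel_start = len(exon5)
                i_start = g_end - (rel_start + length)
                i_end = g_end - rel_start
        else:
            placed = gene_seq
        genes[gene_id] = (chrom, pos, pos + len(gene_seq), strand)
        if has_intron:
            introns.append(
                PlantedIntron(gene_id, chrom, i_start, i_end, bp, strand)
            )
        parts.append(placed)
        spacer = _random_seq(rng, int(rng.integers(20, 60)), config.gc_content)
        parts.append(spacer)
        pos += len(gene_seq) + len(spacer)
    return SyntheticGenome(sequences={chrom: "".join(parts)}, introns=introns, genes=genes)


# ---------------------------------------------------------------------------
# DMS reactivity simulation


@dataclass(frozen=True)
class ReactivitySimParams:
    rate_mod_A: float = 0.027
    rate_mod_C: float = 0.023
    rate_background: float = 0.0035
    coverage_per_pos: int = 10_000
    seed: int = 0

    def __post_init__(self):
        rates = (self.rate_mod_A, self.rate_mod_C, self.rate_background)
        if not all(0 <= r <= 1 for r in rates):
            raise ValueError("rates must be in [0, 1]")
        if not (self.rate_background < self.rate_mod_A and self.rate_background < self.rate_mod_C):
            raise ValueError("background rate must be below both modified rates")


def simulate_reactivity(structure: SecondaryStructure, params: ReactivitySimParams) -> ReactivityProfile:
    """Binomial mutation counts from a known structure.

    Unpaired A and C positions mutate at the modified rates; paired
    positions and all G/U mutate at background. Zero coverage yields
    all-zero counts with an invalid mask.
    """
    rng = np.random.default_rng(params.seed)
    seq = structure.sequence
    paired = structure.paired_mask()
    rates = np.full(len(seq), params.rate_background)
    for idx, base in enumerate(seq):
        if not paired[idx]:
            if base == "A":
                rates[idx] = params.rate_mod_A
            elif base == "C":
                rates[idx] = params.rate_mod_C
    cov = np.full(len(seq), int(params.coverage_per_pos))
    counts = rng.binomial(cov, rates)
    return ReactivityProfile(seq, counts, cov)


def random_hairpin(
    rng,
    stem_len: int = 10,
    loop_len: int = 5,
    tail_len: int = 5,
) -> SecondaryStructure:
    """A clean hairpin with a random complementary stem, A/C-rich loop
    and tails (informative for DMS round-trip tests)."""
    stem5, stem3 = [], []
    for _ in range(stem_len):
        a, b = _PAIR_CHOICES[rng.integers(len(_PAIR_CHOICES))]
        stem5.append(a)
        stem3.append(b)
    loop = "".join("AC"[rng.integers(2)] for _ in range(loop_len))
    tail5 = "".join("AC"[rng.integers(2)] for _ in range(tail_len))
    tail3 = "".join("AC"[rng.integers(2)] for _ in range(tail_len))
    seq = tail5 + "".join(stem5) + loop + "".join(reversed(stem3)) + tail3
    pairs = frozenset(
        (tail_len + k, tail_len + stem_len + loop_len + (stem_len - 1 - k))
        for k in range(stem_len)
    )
    return SecondaryStructure(seq, pairs)


# ---------------------------------------------------------------------------
# VARS-seq simulation


@dataclass(frozen=True)
class VarsSimEffect:
    variant_id: str
    true_ri: float
    n_barcodes: int = 8
    umis_per_barcode: int = 100
    genomic_count: int = 10

    def __post_init__(self):
        if not 0 <= self.true_ri <= 1:
            raise ValueError("true_ri must be in [0, 1]")
        if self.n_barcodes < 1:
            raise ValueError("need at least one barcode")


@dataclass(frozen=True)
class VarsSimResult:
    genomic_reads: dict  # barcode -> list of insert reads
    rna_reads: list  # (barcode, umi, read_seq)
    junctions: dict  # variant_id -> (spliced, unspliced, spliced_pos, unspliced_pos)
    designs: dict  # variant_id -> insert sequence
    truth: dict  # variant_id -> true RI fraction
    barcode_variant: dict  # barcode -> variant_id


def _encode_tag(value: int, length: int) -> str:
    chars = []
    for _ in range(length):
        chars.append("ACGU"[value % 4])
        value //= 4
    return "".join(chars)


def simulate_varsseq(
    designs: dict[str, str],
    effects: list[VarsSimEffect],
    seed: int = 0,
    exon5: str = "GCGAUCGUAGCUAGGCAUGC",
    exon3: str = "UUAGCCGAUAGCGAUGCAUG",
    read_half: int = 20,
    barcode_len: int = 12,
    umi_len: int = 10,
) -> VarsSimResult:
    """Emit genomic and RNA read records with planted RI effects.

    Each effect plants ``n_barcodes`` unique 12-nt barcodes for its
    variant; each barcode emits genomic reads of the variant insert and
    RNA reads whose junction windows are unspliced with probability
    ``true_ri``. UMIs are unique per molecule. Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    missing = [e.variant_id for e in effects if e.variant_id not in designs]
    if missing:
        raise ValueError(f"effects reference unknown designs: {missing}")
    junctions = {}
    for vid, intron in designs.items():
        intron = clean_rna(intron)
        spliced = exon5 + exon3
        unspliced = exon5 + intron + exon3
        junctions[vid] = (spliced, unspliced, len(exon5), len(exon5))
    barcode_variant: dict[str, str] = {}
    genomic_reads: dict[str, list] = {}
    rna_reads: list[tuple[str, str, str]] = []
    umi_counter = 0
    for effect in effects:
        intron = clean_rna(designs[effect.variant_id])
        spliced, unspliced, sp, up = junctions[effect.variant_id]
        spliced_read = spliced[max(0, sp - read_half) : sp + read_half]
        unspliced_read = unspliced[max(0, up - read_half) : up + read_half]
        for _ in range(effect.n_barcodes):
            while True:
                barcode = _encode_tag(int(rng.integers(0, 4**barcode_len)), barcode_len)
                if barcode not in barcode_variant:
                    break
            barcode_variant[barcode] = effect.variant_id
            genomic_reads[barcode] = [intron] * effect.genomic_count
            unspliced_draws = rng.random(effect.umis_per_barcode) < effect.true_ri
            for is_unspliced in unspliced_draws:
                umi = _encode_tag(umi_counter, umi_len)
                umi_counter += 1
                rna_reads.append((barcode, umi, unspliced_read if is_unspliced else spliced_read))
    return VarsSimResult(
        genomic_reads=genomic_reads,
        rna_reads=rna_reads,
        junctions=junctions,
        designs={k: clean_rna(v) for k, v in designs.items()},
        truth={e.variant_id: e.true_ri for e in effects},
        barcode_variant=barcode_variant,
    )


# ---------------------------------------------------------------------------
# barcode collision simulation


def barcode_collision_sim(
    n_clones: int,
    barcode_len: int = 12,
    n_trials: int = 5,
    seed: int = 0,
) -> float:
    """Fraction of random barcodes whose nearest neighbour is at edit
    distance >= 2, averaged over trials.

    For equal-length barcodes, edit distance <= 1 means identical or a
    single substitution, so neighbours are found exactly by hashing each
    barcode once per wildcarded position.
    """
    if n_clones < 2:
        raise ValueError("need at least 2 clones")
    if barcode_len < 1:
        raise ValueError("barcode_len must be >= 1")
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_trials):
        codes = rng.integers(0, 4, size=(n_clones, barcode_len))
        strings = ["".join("ACGU"[b] for b in row) for row in codes]
        has_neighbor = np.zeros(n_clones, dtype=bool)
        buckets: dict[str, int] = {}
        for p in range(barcode_len):
            buckets.clear()
            for idx, s in enumerate(strings):
                key = s[:p] + "*" + s[p + 1 :]
                other = buckets.get(key)
                if other is None:
                    buckets[key] = idx
                else:
                    has_neighbor[idx] = True
                    has_neighbor[other] = True
        fractions.append(1.0 - has_neighbor.mean())
    return float(np.mean(fractions))


# ---------------------------------------------------------------------------
# planted feature classes for clustering tests


CLASS_TEMPLATES = {
    # class name -> feature template mirroring the seven structural classes:
    # zipper-only, zipper+downstream, downstream-only, structured long,
    # unstructured long, unstructured short, structured short
    "zipper": dict(length=450, zipper_flag=1, zipper_dG=-15, downstream_flag=0, downstream_dG=0,
                   mee_norm=0.15, longest_stem_bp=12, avg_helix_conf=85, max_gini=0.55, ss_accessibility=0.5),
    "zipper_downstream": dict(length=460, zipper_flag=1, zipper_dG=-14, downstream_flag=1, downstream_dG=-10,
                              mee_norm=0.18, longest_stem_bp=13, avg_helix_conf=90, max_gini=0.60, ss_accessibility=0.45),
    "downstream": dict(length=440, zipper_flag=0, zipper_dG=0, downstream_flag=1, downstream_dG=-11,
                       mee_norm=0.14, longest_stem_bp=11, avg_helix_conf=82, max_gini=0.50, ss_accessibility=0.5),
    "structured_long": dict(length=470, zipper_flag=0, zipper_dG=0, downstream_flag=0, downstream_dG=0,
                            mee_norm=0.20, longest_stem_bp=16, avg_helix_conf=88, max_gini=0.60, ss_accessibility=0.4),
    "unstructured_long": dict(length=430, zipper_flag=0, zipper_dG=0, downstream_flag=0, downstream_dG=0,
                              mee_norm=0.08, longest_stem_bp=6, avg_helix_conf=40, max_gini=0.30, ss_accessibility=0.8),
    "unstructured_short": dict(length=100, zipper_flag=0, zipper_dG=0, downstream_flag=0, downstream_dG=0,
                               mee_norm=0.07, longest_stem_bp=4, avg_helix_conf=30, max_gini=0.25, ss_accessibility=0.85),
    "structured_short": dict(length=120, zipper_flag=0, zipper_dG=0, downstream_flag=0, downstream_dG=0,
                             mee_norm=0.15, longest_stem_bp=9, avg_helix_conf=80, max_gini=0.55, ss_accessibility=0.5),
}

_NOISE_SD = dict(length=20, zipper_dG=1.5, downstream_dG=1.2, mee_norm=0.015,
                 longest_stem_bp=1.0, avg_helix_conf=4.0, max_gini=0.03, ss_accessibility=0.05)


def generate_feature_classes(n_per_class: int = 12, seed: int = 0) -> tuple[list[dict], np.ndarray]:
    """Feature-vector rows drawn from the seven structural-class
    templates with Gaussian noise; returns (rows, true labels)."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for label, (name, template) in enumerate(CLASS_TEMPLATES.items()):
        for k in range(n_per_class):
            row = {"gene_id": f"{name}_{k}"}
            for feat, value in template.items():
                sd = _NOISE_SD.get(feat, 0.0)
                noisy = value + (rng.normal(0, sd) if sd else 0.0)
                if feat.endswith("_dG") and value != 0:
                    noisy = min(noisy, -0.5)
                row[feat] = noisy
            rows.append(row)
            labels.append(label)
    return rows, np.asarray(labels)
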