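# Methods

This note records the models, parameter choices and numerical decisions
behind intron-atlas, and what the synthetic-data tests do and do not show
about real probing data.

## Reactivity model and normalization

DMS methylates the Watson–Crick faces of unpaired A (N1) and C (N3);
read out by mutational profiling, the per-position substitution
frequency is a proxy for single-strandedness. Frequencies are mutation
counts over coverage, masked where coverage is zero.

Normalization restricts to unmasked A/C positions, discards the top 2%
of frequencies as outliers, divides everything by the mean of the next
8% and caps the result at 4.0. The 2%/8% split is this package's fixed
reading of the boxplot-style normalization common in mutational-profiling
pipelines; both fractions and the cap are keyword arguments. Profiles
with fewer than 10 usable A/C positions are flagged unnormalizable
rather than scaled by an unstable denominator.

Two coverage constants are carried as configuration defaults rather than
derived quantities: 7,673 (mean construct coverage at which replicate
agreement reaches r² ≈ 0.6) and 15,346 (per-position floor for Gini
windows). The windowed Gini uses 20-nt windows stepped by 10 nt;
Gini = Σᵢⱼ|xᵢ−xⱼ| / (2n²μ), defined as 0 for an all-zero window.
ROC AUC is the rank-based (Mann–Whitney) probability that a positive
outranks a negative, ties counted half.

## Baseline folding engine

The built-in engine is a Nussinov-style maximum-pairing dynamic program
over canonical pairs (Watson–Crick + GU, minimum hairpin 3 nt) with a
reactivity pseudo-energy: a candidate pair (i, j) scores
1 + w·(t − rᵢ) + w·(t − rⱼ) over positions with defined reactivity
(defaults w = 0.5, t = 0.5), so unreactive positions are rewarded for
pairing and positions above reactivity ~2 in effect cannot pair.
Traceback is deterministic: the 5′ base of each interval pairs with the
smallest partner index that achieves the optimum, preferring pairing on
exact ties. This engine is intentionally simple — it has no stacking
thermodynamics or loop entropies — and exists so the whole pipeline runs
and is testable with no external binaries. A ViennaRNA-backed engine
satisfies the same contract (fold / sample / duplex_dG) for production
folding when the bindings are installed; `sample` on the baseline engine
draws a structure ensemble by seeded Gaussian jitter (sd 0.35) of the
pair-score matrix, which is deterministic under its seed.

The inner dynamic program is JIT-compiled with numba; for sequences up
to 14 nt an exhaustive enumerator over all non-crossing structures
provides an independent optimum for equivalence testing.

## Duplex free energies

Stem stabilities are nearest-neighbour sums at 37 °C using the
Turner-2004 Watson–Crick and GU stack table embedded as data (0.01
kcal/mol resolution), plus a duplex initiation penalty of 4.10 kcal/mol
and 0.50 kcal/mol per AU/GU-closing helix end. The self-complementarity
symmetry correction is deliberately omitted: stem calls compare and rank
duplexes, and a constant 0.43 kcal/mol term on the rare self-complementary
stem does not change any ranking used here. Bulged nucleotides are
removed before the caller passes the paired segments, so bulge loop
penalties are not modelled; reported ΔG values are therefore slightly
more stable than a full loop-energy model would give, uniformly across
stems.

## Bootstrap helix confidence

Helix confidence is estimated by non-parametric bootstrap: each
iteration resamples every position's mutation count as
binomial(coverage, frequency) — preserving the coverage profile, which
is the dominant term in per-position uncertainty — renormalizes, and
refolds. Support of a base pair is the fraction of iterations containing
it; a stem's confidence is the mean per-pair support in percent (the
minimum is available as an option for a stricter helix-level reading).
The default is 1,000 iterations; tests and the acceptance script use 100,
which is sufficient to resolve the 70%/90% thresholds used downstream.

## Stems and structural features

Stems are maximal runs of stacked pairs merged across interior bulges
totalling at most `max_bulge` nt (greedy 5′→3′ merge). High-confidence
stems have ≥5 bp and confidence strictly >70%; zipper and downstream
stems use ≥6 bp at ≥70% (inclusive), mirroring the distinct wordings of
the two rules; all thresholds are parameters.

Zipper stems: both strands must lie between the 5′ splice site and
branch point; the 5′ linker L5 (intron start to the first paired base)
must be ≥10 nt, the 3′ linker L3 (last paired base to the branch
adenosine) ≥20 nt, and 42 ≤ L5+L3 ≤ 85 nt. These geometric constants
come from 3D modelling of intron stems inside the assembling spliceosome
and are consumed as fixed defaults, not re-derived. Linkers are measured
from the motif anchors (intron position 0 and the branch adenosine); the
measurement endpoints are configurable since motif-edge conventions
differ. Tie-breaks for equal stem length: more stable duplex ΔG, then
5′-most. Downstream stems are the same selection with both strands
strictly between the branch point and the 3′ splice site.

The fine structure graph has a node per base pair and per unpaired
position with backbone-adjacency edges. Maximum extrusion from ends is
the largest over nodes of the smaller BFS distance to either terminal
node, normalized by sequence length; the 5′SS→branch-point distance is
the BFS distance between the nodes holding those positions. Splice-site
occlusion uses inclusive windows of (16 up, 10 down) around the 5′SS,
(33, 21) around the branch point and (8, 20) around the 3′SS —
positions threading through spliceosome structures — and reports the
fraction of window nucleotides inside high-confidence stems (either
strand, interior bulges included), on structures predicted with 50-nt
flanks.

## Splice-site models, decoys and cryptic sites

PWMs (5′SS 4×6, branch point 4×8 with the branch adenosine at motif
index 5, 3′SS 4×3) use a 0.5 pseudocount per cell and log₂-odds scores
against a uniform background. Score cutoffs and length bounds (total,
5′SS→BP, BP→3′SS) are set so the *joint* capture of training introns is
at least 95%: the 5% exclusion budget is split evenly across the six
criteria (each length bound spending its share half per side), since
six independent per-criterion 95% cutoffs would only guarantee 70%
jointly. Decoy scanning enumerates all (5′SS, BP, 3′SS) triples passing
all six criteria, 5′→3′ per contig, dropping exact duplicates and
annotated introns; overlapping decoys are all reported.

Cryptic-site search windows follow spliceosome geometry: alternative 5′
splice sites must keep ≥42 nt to the canonical branch point (search
region [0, bp−42]); cryptic branch points place the adenosine between
42 nt downstream of the 5′SS and the 3′SS; cryptic 3′ splice sites start
≥10 nt downstream of the branch adenosine. The motif catalog is
injectable — observed splice-site motifs are external data — with a
synthetic default of consensus variants plus the Prp18-dependent 3′SS
set (GAG, UG, CG, GG); consensus 3′SS are UAG/CAG/AAG. Protection
enrichment is Pearson's chi-squared with 1 df, no continuity correction
(a flag restores it), on the 2×2 protected/unprotected table; a zero
margin flags the p-value undefined.

## Landscape clustering and comparisons

Feature vectors hold length, zipper/downstream flags and ΔG, normalized
MEE, longest stem length (stems with ≤10 loop nt and ≥90% support),
average helix confidence (stems ≥6 bp), maximum window Gini and
splice-site accessibility. Missing ΔG is imputed to 0 — the least stable
value, keeping absent stems neutral while the flag column carries the
presence signal — and columns are z-scored before Ward clustering
(scipy linkage, Euclidean distance, optimal leaf ordering, tree cut to
7 classes). Standardization before clustering is this package's choice;
heat-map visualizations of such features imply per-feature scaling but
do not pin it down.

Intron-vs-control comparisons use the Wilcoxon rank-sum test: exact null
distribution when both samples are ≤20 and tie-free, otherwise the
tie-corrected normal approximation. Divergence between homologous
introns is measured on a global pairwise alignment (match 1, mismatch
−1, gap open −2, extend −0.5): substitution rate over gap-free columns,
and indel rate as gap *openings* per alignment column — opening counts
keep the rate comparable across indel lengths. MSA conservation is mean
percent identity of non-reference rows to the reference row, columns
gapped in either row excluded.

## VARS-seq design and quantification

For each stem set, 10,000 randomized and 10,000 shuffled mutations of
the member stems' 5′ strands are generated (20,000 for loops, where no
rescue is possible); a length-1 region degenerates to randomization
only. Candidates are scored on the engine's fold of the full variant:
variable penalty = paired residues in the variable region + base pairs
touching it; constant penalty = native pairs (outside the region)
disrupted + ½ × pairs gained; rescue penalty = pairs altered between the
native structure and the rescue fold. Rescues install Watson–Crick
complements of the mutated 5′ strand on the 3′ strand, preserving pair
geometry, and are only emitted when the 3′ strand lies inside the
designable window. The top 4–8 unique variants by total penalty are
selected, ties broken lexicographically. Designs are substitution-only
(fixed-length oligo pools).

Barcode→variant assignment takes a per-position majority consensus over
each barcode's reads (modal read length), requiring ≥5 reads and ≤5% of
reads disagreeing with the consensus; base-level quality modelling is
deliberately out of scope, so consensus calling is a majority vote
rather than a quality-weighted caller. Read classification requires a
≥14-nt contiguous exact match to the spliced or unspliced junction
reference spanning the junction point with ≥1 nt on each side
(contiguous-window reading of "14 nt of agreement"; the split is
configurable); reads matching both or neither are "other". Counts are
UMI-deduplicated; RI fraction = unspliced/(spliced+unspliced),
normalized mRNA = spliced UMIs / genomic count. Alternative events are
reported only with ≥10 UMIs in a barcode and ≥3 barcodes per variant.

The permutation test enumerates label assignments exactly when
C(n, n₁) ≤ 10⁴ and otherwise uses Monte-Carlo resampling (default 10⁵)
with the add-one correction p = (1+k)/(1+N) so p is never 0. The RI
score is −log₁₀ p (base 10 chosen and documented here; capped at 16),
signed positive when the variant lowers the RI fraction.

## Synthetic data: what it emulates, and what it does not

The genome generator plants consensus introns — GUAUGU at the start,
UACUAACN with the branch adenosine ≥42 nt in, YAG at the end, and ≥10 nt
between the branch-point motif and the 3′SS — inside random exons on a
single contig, with bimodal lengths (defaults 70–130 and 400–500 nt,
30% short) matching the two observed intron-length populations; length
ranges that cannot satisfy the spacing are rejected. Intron GC content
and exon composition are uniform-random and configurable, since no
canonical values are asserted for them. Minus-strand genes are placed
reverse-complemented and re-oriented at read time, so the pipeline only
sees sense-strand introns. The annotation TSV on disk is 1-based
inclusive (stated in its header); everything in memory is 0-based
half-open.

Reactivity simulation draws binomial counts at 2.7% (unpaired A), 2.3%
(unpaired C) and 0.35% (everything else) — the observed modified and
background substitution rates. The VARS-seq simulator emits unique 12-nt
barcodes, unique 10-nt UMIs and junction-spanning reads that are
unspliced with probability true_ri. The barcode collision simulator
exploits that equal-length barcodes are within edit distance 1 exactly
when identical or Hamming-1, reducing nearest-neighbour search to
wildcard hashing.

None of the simulators model sequencing error, quality scores, PCR
duplicates beyond UMI multiplicity, coverage heterogeneity along a
construct, or reverse-transcription drop-off. Passing round-trip tests
therefore shows the inference machinery is correct and calibrated under
the stated noise model — not that real libraries, with their correlated
errors and coverage biases, will reach the same recovery rates.

## Problem sizes and observed behaviour

The test-suite and acceptance-script runs use 20 hairpin constructs at
coverage 10⁴ with 100 bootstrap iterations, a ~50-kb synthetic genome
(80 genes) for the decoy scan, 84 introns (7 classes × 12) for
clustering, and 200 null VARS-seq comparisons at 10⁴ resamples —
sizes at which every check runs in seconds while leaving the tested
logic identical to full-scale runs. The null false-positive rate of the
permutation test sits slightly below the nominal 5% (2–5% across seeds):
permutation tests are exactly valid but conservative on discretized RI
fractions (multiples of 1/100 at 100 UMIs per barcode).

## Known limitations

* The baseline engine maximizes pairing, not free energy; its folds are
  a test-time reference, and real analyses should plug a thermodynamic
  engine into the `FoldingEngine` contract (acceptance numbers here use
  the baseline only).
* No pseudoknots and no multi-conformation deconvolution, matching the
  single-conformation, pseudoknot-free regime the pipeline targets.
* Duplex ΔG ignores bulge-loop penalties (stems are scored on their
  paired segments).
* `ViennaEngine.sample` seeds ViennaRNA's global RNG where the bindings
  allow; the baseline engine is the reference for strictly reproducible
  sampling.
* The decoy scan is exhaustive over motif triples and is quadratic in
  the number of candidate sites per contig in the worst case; it is
  intended for gene-scale contigs, not whole mammalian chromosomes.
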