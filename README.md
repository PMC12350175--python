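# intron-atlas

Secondary-structure analysis of budding-yeast introns from DMS chemical
probing. Pre-mRNA introns in *Saccharomyces cerevisiae* fold into
secondary structures — "zipper stems" that link the 5′ splice site
(consensus GUAUGU) to the branch point (UACUAAC, reactive adenosine), and
"downstream stems" between the branch point and the 3′ splice site (YAG)
— that can modulate splicing and pre-mRNA decay. This package implements
the full computational pathway for characterizing those structures, for
researchers working with DMS-MaPseq-style mutational-profiling data or
studying intron structure computationally:

* **reactivity** — per-position mutation frequencies, 2%-exclude /
  8%-band normalization of A/C reactivities, replicate r², per-base
  coverage, sliding-window Gini coefficients (20-nt windows, 10-nt step)
  and rank-based ROC AUC against accessibility labels.
* **folding** — a pluggable engine contract with a built-in
  reactivity-guided maximum-pairing engine (no external binaries needed),
  an optional ViennaRNA thermodynamic engine, embedded Turner-2004
  nearest-neighbour duplex free energies, and bootstrap helix-confidence
  estimation: counts are resampled as binomial(coverage, frequency),
  renormalized and refolded; a pair's support is the fraction of
  bootstrap structures containing it.
* **features** — stem extraction with bulge merging, high-confidence
  stems (≥5 bp, confidence >70%), zipper stems (≥6 bp, ≥70% confidence,
  both strands between the 5′SS and branch point with a 42–85-nt total
  linker, ≥10 nt from the 5′SS and ≥20 nt from the branch point),
  downstream stems, normalized maximum extrusion from ends (MEE) on the
  fine structure graph, splice-site occlusion windows and 5′SS→BP graph
  distance.
* **intron_models** — splice-site PWMs and intron length models with
  ≥95% joint capture of training introns, genome scans for unspliced
  decoy introns, shifted/shuffled/sequence-matched/phylogenetic controls,
  cryptic splice-site discovery and chi-squared protection enrichment.
* **landscape** — ten-feature intron vectors, Ward-linkage clustering
  with optimal leaf ordering into structural classes, Wilcoxon rank-sum
  intron-vs-control comparisons and genus-level MSA conservation
  statistics.
* **vars_seq** — VARS-seq variant design (randomized/shuffled 5′-strand
  mutations scored by variable/constant/rescue penalties, compensatory
  rescues), barcode→variant consensus assignment, spliced/unspliced
  junction classification (≥14-nt exact agreement spanning the junction),
  UMI-deduplicated retained-intron (RI) fractions, permutation tests and
  signed RI scores.
* **synthetic** — generators for every input: genomes with planted
  consensus introns (bimodal lengths), reactivity profiles tied to known
  structures (A/C modified rates 2.7%/2.3%, background 0.35%), VARS-seq
  read tables with planted RI effects, and barcode edit-distance
  simulations. Everything is reproducible under a fixed seed, so the
  whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
from intron_atlas.folding import BaselineEngine, bootstrap_support
from intron_atlas.features import find_zipper_stem, max_extrusion_from_ends
from intron_atlas.synthetic import (
    SyntheticGenomeConfig, generate_genome, simulate_reactivity, ReactivitySimParams,
)

engine = BaselineEngine()
genome = generate_genome(SyntheticGenomeConfig(n_genes=5, seed=7))
ann = genome.intron_annotation(genome.introns[0])

structure = engine.fold(ann.intron_seq)
profile = simulate_reactivity(structure, ReactivitySimParams(coverage_per_pos=10_000, seed=1))
support = bootstrap_support(profile, engine, n_boot=100, seed=2)

zipper = find_zipper_stem(structure, ann, support, engine)
print("intron length:", len(ann.intron_seq))
print("MEE:", round(max_extrusion_from_ends(structure), 3))
if zipper is not None:
    print("zipper stem:", zipper.n_bp, "bp, dG", zipper.dG, "kcal/mol,",
          f"confidence {zipper.confidence:.0f}%")
```

Output:

```
intron length: 120
MEE: 0.308
zipper stem: 7 bp, dG -4.0 kcal/mol, confidence 100%
```

The maximum extrusion from ends of 0.308 means the farthest structural
element sits 37 graph edges from the nearer sequence end of this 120-nt
intron. The 7-bp zipper stem (duplex free energy −4.0 kcal/mol) carries
100% bootstrap support: it appears in every one of 100 refolds of
resampled reactivities, so the probing data (simulated here) strongly
support it.

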