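"""Splice-site sequence models, decoy introns, controls and cryptic sites.

Position weight matrices (PWMs) for the 5' splice site (6 nt, consensus
GUAUGU), branch point (8 nt, UACUAACN; branch adenosine at motif index 5)
and 3' splice site (3 nt, YAG) are trained from annotated introns with
log-odds scoring against a uniform background. Score and length cutoffs
jointly capture at least 95% of the training introns; the exclusion
budget is split across the six criteria so that the joint bound holds by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .features import IntronAnnotation
from .structures import clean_rna

BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MOTIF_LEN = {"five_ss": 6, "bp": 8, "three_ss": 3}
#: offset of the branch adenosine within the 8-nt branch-point motif
BP_MOTIF_A_OFFSET = 5

#: 3' splice-site motifs observed only upon Prp18 inactivation
PRP18_DEPENDENT_3SS = ("GAG", "UG", "CG", "GG")
#: standard consensus 3' splice sites
CONSENSUS_3SS = ("UAG", "CAG", "AAG")

DEFAULT_MOTIF_CATALOG = {
    "five_ss": ("GUAUGU", "GUACGU", "GUAAGU", "GUCUGU"),
    "bp": ("UACUAAC", "GACUAAC", "AACUAAC", "UGCUAAC"),
    "three_ss": CONSENSUS_3SS + PRP18_DEPENDENT_3SS,
}


def _intron_motifs(ann: IntronAnnotation) -> Optional[dict[str, str]]:
    seq = ann.intron_seq
    b0 = ann.bp_pos - BP_MOTIF_A_OFFSET
    if b0 < 0 or b0 + MOTIF_LEN["bp"] > len(seq) or len(seq) < MOTIF_LEN["five_ss"]:
        return None
    return {
        "five_ss": seq[: MOTIF_LEN["five_ss"]],
        "bp": seq[b0 : b0 + MOTIF_LEN["bp"]],
        "three_ss": seq[-MOTIF_LEN["three_ss"] :],
    }


@dataclass(frozen=True)
class SpliceSitePWMs:
    """Frequency PWMs with log-odds score cutoffs per motif."""

    pwm: dict  # kind -> (4, L) frequency matrix
    score_cutoffs: dict  # kind -> minimum log-odds score

    def score(self, kind: str, motif: str) -> float:
        m = self.pwm[kind]
        motif = clean_rna(motif)
        if len(motif) != m.shape[1]:
            raise ValueError(f"{kind} motif must be {m.shape[1]} nt")
        return float(sum(np.log2(m[BASE_INDEX[b], k] / 0.25) for k, b in enumerate(motif)))

    def passes(self, kind: str, motif: str) -> bool:
        return self.score(kind, motif) >= self.score_cutoffs[kind]


@dataclass(frozen=True)
class LengthModel:
    """Empirical length bounds: total, 5'SS->BP, BP->3'SS."""

    bounds: dict  # key -> (lo, hi) inclusive

    def passes(self, total: int, d5b: int, db3: int) -> bool:
        checks = {"total": total, "five_to_bp": d5b, "bp_to_three": db3}
        return all(self.bounds[k][0] <= v <= self.bounds[k][1] for k, v in checks.items())


def build_models(
    introns: list[IntronAnnotation],
    pseudocount: float = 0.5,
    capture: float = 0.95,
) -> tuple[SpliceSitePWMs, LengthModel]:
    """Train PWMs and length bounds from annotated introns.

    The (1 - capture) exclusion budget is split evenly across the six
    criteria (three motif scores, three length ranges) so the fraction of
    training introns passing all criteria jointly is at least ``capture``.
    Introns whose motifs fall out of bounds are skipped.
    """
    if len(introns) < 2:
        raise ValueError("need at least 2 introns to build models")
    motif_sets: dict[str, list[str]] = {k: [] for k in MOTIF_LEN}
    lengths: dict[str, list[int]] = {"total": [], "five_to_bp": [], "bp_to_three": []}
    usable = []
    for ann in introns:
        motifs = _intron_motifs(ann)
        if motifs is None:
            continue
        usable.append(ann)
        for kind, m in motifs.items():
            motif_sets[kind].append(m)
        lengths["total"].append(len(ann.intron_seq))
        lengths["five_to_bp"].append(ann.bp_pos)
        lengths["bp_to_three"].append(ann.three_ss - ann.bp_pos)
    n = len(usable)
    if n < 2:
        raise ValueError("fewer than 2 introns had extractable motifs")

    pwm = {}
    for kind, motifs in motif_sets.items():
        counts = np.full((4, MOTIF_LEN[kind]), pseudocount)
        for m in motifs:
            for k, b in enumerate(m):
                counts[BASE_INDEX[b], k] += 1
        pwm[kind] = counts / counts.sum(axis=0, keepdims=True)

    budget = (1.0 - capture) / 6.0
    k_score = int(np.floor(budget * n))
    cutoffs = {}
    model = SpliceSitePWMs(pwm=pwm, score_cutoffs={k: -np.inf for k in pwm})
    for kind, motifs in motif_sets.items():
        scores = np.sort([model.score(kind, m) for m in motifs])
        cutoffs[kind] = float(scores[k_score])
    pwms = SpliceSitePWMs(pwm=pwm, score_cutoffs=cutoffs)

    k_side = int(np.floor(budget * n / 2))
    bounds = {}
    for key, vals in lengths.items():
        v = np.sort(vals)
        bounds[key] = (int(v[k_side]), int(v[len(v) - 1 - k_side]))
    return pwms, LengthModel(bounds=bounds)


# ---------------------------------------------------------------------------
# decoy scan


@dataclass(frozen=True)
class DecoyIntron:
    contig: str
    start: int  # 0-based intron start (first nt of 5'SS motif)
    bp_pos: int  # branch adenosine, contig coordinates
    end: int  # index of last intron nt (3' G of YAG)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def scan_decoys(
    sequences: dict[str, str],
    annotated: list[DecoyIntron],
    pwms: SpliceSitePWMs,
    lengths: LengthModel,
) -> list[DecoyIntron]:
    """Find unspliced decoy introns: (5'SS, BP, 3'SS) triples passing the
    PWM cutoffs and length bounds, excluding annotated introns.

    Scan order is deterministic, 5' to 3' per contig; duplicates by
    identical (start, bp, end) are reported once.
    """
    annotated_keys = {(d.contig, d.start, d.bp_pos, d.end) for d in annotated}
    l5, lb, l3 = MOTIF_LEN["five_ss"], MOTIF_LEN["bp"], MOTIF_LEN["three_ss"]
    t_lo, t_hi = lengths.bounds["total"]
    d5b_lo, d5b_hi = lengths.bounds["five_to_bp"]
    db3_lo, db3_hi = lengths.bounds["bp_to_three"]
    out = []
    for contig in sorted(sequences):
        seq = clean_rna(sequences[contig])
        n = len(seq)
        p5 = [s for s in range(n - l5 + 1) if pwms.passes("five_ss", seq[s : s + l5])]
        pb = [b for b in range(n - lb + 1) if pwms.passes("bp", seq[b : b + lb])]
        p3 = [e for e in range(l3 - 1, n) if pwms.passes("three_ss", seq[e - l3 + 1 : e + 1])]
        pb_arr = np.asarray(pb, dtype=int)
        p3_arr = np.asarray(p3, dtype=int)
        for s in p5:
            bp_cand = pb_arr[(pb_arr + BP_MOTIF_A_OFFSET - s >= d5b_lo) & (pb_arr + BP_MOTIF_A_OFFSET - s <= d5b_hi)]
            for b in bp_cand:
                bp_pos = int(b) + BP_MOTIF_A_OFFSET
                e_cand = p3_arr[
                    (p3_arr - bp_pos >= db3_lo)
                    & (p3_arr - bp_pos <= db3_hi)
                    & (p3_arr - s + 1 >= t_lo)
                    & (p3_arr - s + 1 <= t_hi)
                ]
                for e in e_cand:
                    key = (contig, s, bp_pos, int(e))
                    if key not in annotated_keys:
                        out.append(DecoyIntron(contig, s, bp_pos, int(e)))
    # dedupe while preserving scan order
    seen = set()
    unique = []
    for d in out:
        k = (d.contig, d.start, d.bp_pos, d.end)
        if k not in seen:
            seen.add(k)
            unique.append(d)
    return unique


# ---------------------------------------------------------------------------
# controls


def make_controls(
    introns: list[DecoyIntron],
    mode: str,
    sequences: Optional[dict[str, str]] = None,
    intron_seqs: Optional[list[str]] = None,
    homologs: Optional[list[str]] = None,
    mutation_rate: float = 0.0,
    indel_rate: float = 0.0,
    shift: int = 500,
    seed: int = 0,
) -> list[Optional[str]]:
    """Build length-matched control sequences per intron.

    Modes: ``shifted`` (genome interval shifted ``shift`` nt downstream of
    the 5' splice site), ``sequence_matched`` (shifted, with splice-site
    motifs replaced by the intron's), ``shuffled`` (seeded permutation of
    the intron sequence) and ``phylogenetic`` (mutations and indels
    inserted into the homologous sequence at the measured rates). Entries
    are None where a control cannot be built (e.g. shift runs off the
    contig).
    """
    rng = np.random.default_rng(seed)
    if mode in ("shifted", "sequence_matched"):
        if sequences is None:
            raise ValueError(f"mode {mode!r} requires genome sequences")
        out = []
        for idx, d in enumerate(introns):
            seq = clean_rna(sequences[d.contig])
            s, e = d.start + shift, d.end + shift
            if e >= len(seq):
                out.append(None)
                continue
            ctrl = seq[s : e + 1]
            if mode == "sequence_matched":
                intron = clean_rna(sequences[d.contig])[d.start : d.end + 1]
                rel_bp = d.bp_pos - d.start
                b0 = rel_bp - BP_MOTIF_A_OFFSET
                chars = list(ctrl)
                chars[: MOTIF_LEN["five_ss"]] = intron[: MOTIF_LEN["five_ss"]]
                chars[b0 : b0 + MOTIF_LEN["bp"]] = intron[b0 : b0 + MOTIF_LEN["bp"]]
                chars[-MOTIF_LEN["three_ss"] :] = intron[-MOTIF_LEN["three_ss"] :]
                ctrl = "".join(chars)
            out.append(ctrl)
        return out
    if mode == "shuffled":
        if intron_seqs is None:
            raise ValueError("mode 'shuffled' requires intron_seqs")
        return ["".join(rng.permutation(list(clean_rna(s)))) for s in intron_seqs]
    if mode == "phylogenetic":
        if homologs is None:
            raise ValueError("mode 'phylogenetic' requires homolog sequences")
        return [
            mutate_sequence(h, mutation_rate, indel_rate, rng)
            for h in homologs
        ]
    raise ValueError(f"unknown control mode {mode!r}")


def mutate_sequence(seq: str, mutation_rate: float, indel_rate: float, rng) -> str:
    """Apply random substitutions and single-nt indels at the given rates."""
    seq = clean_rna(seq)
    out = []
    for ch in seq:
        if rng.random() < indel_rate:
            if rng.random() < 0.5:
                continue  # deletion
            out.append("ACGU"[rng.integers(4)])  # insertion before ch
        if rng.random() < mutation_rate:
            choices = [b for b in "ACGU" if b != ch]
            ch = choices[rng.integers(3)]
        out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# cryptic splice sites


@dataclass(frozen=True)
class CrypticSite:
    kind: str  # five_ss | bp | three_ss
    position: int  # motif start, intron coordinates
    motif: str
    category: str = ""  # consensus | prp18_dependent | other (3'SS only)


def find_cryptic_sites(
    annotation: IntronAnnotation,
    motif_catalog: Optional[dict] = None,
    min_5ss_bp_spacing: int = 42,
    min_bp_3ss_spacing: int = 10,
) -> list[CrypticSite]:
    """Locate intron-internal splice-site motifs in the permitted windows.

    Cryptic 5' splice sites may start anywhere up to ``min_5ss_bp_spacing``
    nt upstream of the canonical branch point; cryptic branch points must
    place the branch adenosine at least ``min_5ss_bp_spacing`` nt
    downstream of the 5' splice site and before the 3' splice site;
    cryptic 3' splice sites must start at least ``min_bp_3ss_spacing`` nt
    downstream of the branch adenosine. Canonical sites are excluded.
    """
    catalog = DEFAULT_MOTIF_CATALOG if motif_catalog is None else motif_catalog
    seq = annotation.intron_seq
    bp_pos, three_ss = annotation.bp_pos, annotation.three_ss
    sites = []

    for motif in catalog.get("five_ss", ()):
        m = clean_rna(motif)
        for p in _find_all(seq, m):
            if p == 0:
                continue  # canonical
            if p <= bp_pos - min_5ss_bp_spacing:
                sites.append(CrypticSite("five_ss", p, m))

    for motif in catalog.get("bp", ()):
        m = clean_rna(motif)
        a_off = BP_MOTIF_A_OFFSET if len(m) >= 6 else len(m) - 1
        for p in _find_all(seq, m):
            a = p + a_off
            if a == bp_pos:
                continue  # canonical
            if min_5ss_bp_spacing <= a < three_ss:
                sites.append(CrypticSite("bp", p, m))

    for motif in catalog.get("three_ss", ()):
        m = clean_rna(motif)
        for p in _find_all(seq, m):
            if p + len(m) - 1 == three_ss:
                continue  # canonical
            if p - bp_pos >= min_bp_3ss_spacing and p + len(m) - 1 <= three_ss:
                if m in CONSENSUS_3SS:
                    cat = "consensus"
                elif m in PRP18_DEPENDENT_3SS:
                    cat = "prp18_dependent"
                else:
                    cat = "other"
                sites.append(CrypticSite("three_ss", p, m, cat))
    sites.sort(key=lambda s: (s.kind, s.position))
    return sites


def _find_all(seq: str, motif: str):
    start = 0
    while True:
        p = seq.find(motif, start)
        if p < 0:
            return
        yield p
        start = p + 1


# ---------------------------------------------------------------------------
# protection enrichment


@dataclass(frozen=True)
class EnrichmentResult:
    table: np.ndarray  # [[site_prot, site_unprot], [bg_prot, bg_unprot]]
    site_fraction: float
    background_fraction: float
    chi2: float
    p_value: float
    valid: bool = True


def protection_enrichment(
    site_protected: int,
    site_total: int,
    background_protected: int,
    background_total: int,
    correction: bool = False,
) -> EnrichmentResult:
    """Chi-squared test of protection at sites versus background.

    Builds the 2x2 contingency table of protected/unprotected counts and
    applies Pearson's chi-squared with 1 df (no continuity correction by
    default). A zero margin leaves the p-value undefined (NaN, flagged).
    """
    if site_protected > site_total or background_protected > background_total:
        raise ValueError("protected counts exceed totals")
    table = np.array(
        [
            [site_protected, site_total - site_protected],
            [background_protected, background_total - background_protected],
        ],
        dtype=float,
    )
    site_frac = site_protected / site_total if site_total else float("nan")
    bg_frac = background_protected / background_total if background_total else float("nan")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return EnrichmentResult(table, site_frac, bg_frac, float("nan"), float("nan"), valid=False)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return EnrichmentResult(table, site_frac, bg_frac, float(chi2), float(p))


def positions_protected(
    positions,
    high_conf_stems,
) -> np.ndarray:
    """Boolean protection flag per position: inside a high-confidence stem
    (either strand, bulges included)."""
    flags = []
    for p in positions:
        hit = False
        for stem in high_conf_stems:
            if stem.span5[0] <= p <= stem.span5[1] or stem.span3[0] <= p <= stem.span3[1]:
                hit = True
                break
        flags.append(hit)
    return np.asarray(flags, dtype=bool)
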