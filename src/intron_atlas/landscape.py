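"""Structural-landscape assembly: feature matrix, clustering and
intron-versus-control statistics, plus genus-level MSA summaries.

Introns are described by a ten-feature vector (length, zipper/downstream
stem flags and free energies, normalized MEE, longest stem length,
average helix confidence, maximum windowed Gini, splice-site
accessibility) and clustered into structural classes by Ward-linkage
hierarchical clustering with optimal leaf ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

FEATURE_COLUMNS = [
    "length",
    "zipper_flag",
    "zipper_dG",
    "downstream_flag",
    "downstream_dG",
    "mee_norm",
    "longest_stem_bp",
    "avg_helix_conf",
    "max_gini",
    "ss_accessibility",
]


def assemble_features(rows: list[dict], standardize: bool = True) -> pd.DataFrame:
    """Build the per-intron feature matrix.

    ``rows`` map feature names to values, one dict per intron (index key
    ``gene_id``). Missing stem free energies are imputed to 0 (least
    stable) while the presence flags are kept, so absent stems carry no
    stability signal. Columns are z-score standardized by default;
    all-missing or zero-variance columns are dropped with a warning
    attribute recorded in ``df.attrs``.
    """
    df = pd.DataFrame(rows)
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    df = df[cols].astype(float)
    for col in ("zipper_dG", "downstream_dG"):
        if col in df.columns:
            df[col] = df[col].fillna(0.0)
    dropped = [c for c in df.columns if df[c].isna().all()]
    df = df.drop(columns=dropped)
    df = df.fillna(df.mean())
    df.attrs["dropped_columns"] = dropped
    df.attrs["standardized"] = standardize
    if standardize:
        sd = df.std(ddof=0)
        zero_var = sd[sd == 0].index.tolist()
        df.attrs["dropped_columns"] = dropped + zero_var
        df = df.drop(columns=zero_var)
        df = (df - df.mean()) / df.std(ddof=0)
    return df


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray  # 1..n_classes per row
    leaf_order: np.ndarray  # row indices in dendrogram order
    linkage: np.ndarray


def cluster_introns(matrix, n_classes: int = 7) -> ClusterResult:
    """Ward-linkage hierarchical clustering with optimal leaf ordering.

    The tree is cut to ``n_classes`` flat clusters. Deterministic for a
    given matrix; duplicate rows are allowed.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < n_classes:
        raise ValueError("need at least n_classes rows to cluster")
    Z = hierarchy.ward(pdist(X))
    Z = hierarchy.optimal_leaf_ordering(Z, X)
    labels = hierarchy.fcluster(Z, t=n_classes, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    return ClusterResult(labels=labels, leaf_order=order, linkage=Z)


def compare_distributions(
    intron_values,
    control_values,
    alternative: str = "two-sided",
    exact_max_n: int = 20,
) -> float:
    """Wilcoxon rank-sum p-value comparing introns with controls.

    Uses the exact null distribution when both samples are small and
    tie-free, otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(intron_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size <= exact_max_n and b.size <= exact_max_n
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


@dataclass(frozen=True)
class OrthologStats:
    n_orthologs: int
    n_zipper_orthologs: Optional[int]
    intron_conservation_pct: float
    zipper_conservation_pct: Optional[float]


def ortholog_stats(
    msa: dict[str, str],
    scer_id: str = "scer",
    zipper_span: Optional[tuple[int, int]] = None,
) -> OrthologStats:
    """Ortholog counts and conservation from an intron MSA.

    ``msa`` maps species to aligned rows (gaps as '-'). A species counts
    as an ortholog when it has any non-gap character over the reference
    intron columns; zipper orthologs require a non-empty region aligned
    to ``zipper_span`` (inclusive ungapped reference coordinates).
    Conservation is the mean percent identity of the non-reference rows
    to the reference row, with columns gapped in either sequence
    excluded from the denominator.
    """
    if scer_id not in msa:
        raise ValueError(f"reference row {scer_id!r} absent from MSA")
    ref = msa[scer_id].upper().replace("T", "U")
    intron_cols = [c for c, ch in enumerate(ref) if ch != "-"]
    zipper_cols = None
    if zipper_span is not None:
        lo, hi = zipper_span
        zipper_cols = intron_cols[lo : hi + 1]

    def identity(row: str, cols) -> Optional[float]:
        matches = total = 0
        for c in cols:
            a, b = ref[c], row[c]
            if a == "-" or b == "-":
                continue
            total += 1
            matches += a == b
        return 100.0 * matches / total if total else None

    n_orth = 0
    n_zip = 0
    intron_ids = []
    zipper_ids = []
    for species, row in msa.items():
        row = row.upper().replace("T", "U")
        if len(row) != len(ref):
            raise ValueError("ragged alignment")
        is_ref = species == scer_id
        if any(row[c] != "-" for c in intron_cols):
            n_orth += 1
            ident = identity(row, intron_cols)
            if ident is not None and not is_ref:
                intron_ids.append(ident)
        if zipper_cols is not None and any(row[c] != "-" for c in zipper_cols):
            n_zip += 1
            zident = identity(row, zipper_cols)
            if zident is not None and not is_ref:
                zipper_ids.append(zident)
    return OrthologStats(
        n_orthologs=n_orth,
        n_zipper_orthologs=n_zip if zipper_cols is not None else None,
        intron_conservation_pct=float(np.mean(intron_ids)) if intron_ids else float("nan"),
        zipper_conservation_pct=(
            float(np.mean(zipper_ids)) if zipper_cols is not None and zipper_ids else None
        ),
    )


@dataclass(frozen=True)
class DivergenceRates:
    mutation_rate: float
    indel_rate: float


def measure_divergence(seq: str, homolog: str, aligned: bool = False) -> DivergenceRates:
    """Substitution and indel rates between an intron and its homolog.

    If not pre-aligned, a simple global alignment is computed. The
    substitution rate is mismatches over aligned (gap-free) columns; the
    indel rate counts gap openings over the alignment length.
    """
    if not seq or not homolog:
        raise ValueError("empty sequence")
    if aligned:
        a, b = seq.upper(), homolog.upper()
        if len(a) != len(b):
            raise ValueError("pre-aligned sequences must have equal length")
    else:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -0.5
        aln = aligner.align(seq.upper().replace("T", "U"), homolog.upper().replace("T", "U"))[0]
        a, b = str(aln[0]), str(aln[1])
    aligned_cols = mismatches = 0
    gap_openings = 0
    prev_gap_a = prev_gap_b = False
    for ca, cb in zip(a, b):
        ga, gb = ca == "-", cb == "-"
        if not ga and not gb:
            aligned_cols += 1
            mismatches += ca != cb
        if ga and not prev_gap_a:
            gap_openings += 1
        if gb and not prev_gap_b:
            gap_openings += 1
        prev_gap_a, prev_gap_b = ga, gb
    mut = mismatches / aligned_cols if aligned_cols else float("nan")
    return DivergenceRates(mutation_rate=mut, indel_rate=gap_openings / len(a))
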