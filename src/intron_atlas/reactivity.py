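"""Per-position reactivity processing and construct-level quality metrics.

DMS methylates accessible adenine N1 and cytosine N3, read out as
reverse-transcription mutations; the per-position mutation frequency is a
proxy for single-strandedness. This module turns raw mutation counts and
coverage into normalized reactivities and quality statistics: replicate
r-squared, per-base coverage, windowed Gini coefficients and ROC AUC
against external accessibility labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .structures import clean_rna

#: construct-level mean coverage below which replicate agreement degrades
#: (carried as a configuration constant; r^2 ~ 0.6 at this depth)
CONSTRUCT_COVERAGE_CUTOFF = 7_673
#: per-position coverage floor for Gini windows
GINI_COVERAGE_CUTOFF = 15_346
#: reactivity ceiling applied after normalization
REACTIVITY_CAP = 4.0


@dataclass(frozen=True)
class ReactivityProfile:
    """Mutation counts, coverage and derived reactivity for one construct.

    ``frequency`` is mut_counts/coverage where coverage > 0. ``reactivity``
    is defined only for unmasked A/C positions after :func:`normalize`;
    other entries are NaN. ``mask`` is True where a position is usable.
    """

    sequence: str
    mut_counts: np.ndarray
    coverage: np.ndarray
    frequency: np.ndarray = field(default=None)
    reactivity: np.ndarray = field(default=None)
    mask: np.ndarray = field(default=None)
    normalizable: bool = True

    def __post_init__(self):
        seq = clean_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        counts = np.asarray(self.mut_counts, dtype=float)
        cov = np.asarray(self.coverage, dtype=float)
        if counts.shape != cov.shape or counts.shape != (len(seq),):
            raise ValueError("sequence, counts and coverage lengths differ")
        if np.any(counts < 0):
            raise ValueError("negative mutation counts")
        if np.any(counts > cov):
            raise ValueError("mutation counts exceed coverage")
        object.__setattr__(self, "mut_counts", counts)
        object.__setattr__(self, "coverage", cov)
        if self.frequency is None:
            freq = compute_frequencies(counts, cov)
            object.__setattr__(self, "frequency", freq)
        if self.mask is None:
            object.__setattr__(self, "mask", cov > 0)
        if self.reactivity is None:
            object.__setattr__(self, "reactivity", np.full(len(seq), np.nan))

    @property
    def n(self) -> int:
        return len(self.sequence)

    def ac_mask(self) -> np.ndarray:
        """Unmasked A/C positions (the DMS-informative subset)."""
        bases = np.frombuffer(self.sequence.encode(), dtype="S1")
        is_ac = (bases == b"A") | (bases == b"C")
        return is_ac & self.mask


def compute_frequencies(counts, coverage) -> np.ndarray:
    """Elementwise mutation frequency; NaN where coverage is zero."""
    counts = np.asarray(counts, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if counts.shape != coverage.shape:
        raise ValueError("counts and coverage must have equal length")
    if np.any(counts < 0):
        raise ValueError("negative mutation counts")
    if np.any(counts > coverage):
        raise ValueError("mutation counts exceed coverage")
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(coverage > 0, counts / np.where(coverage > 0, coverage, 1), np.nan)
    return freq


def normalize(
    profile: ReactivityProfile,
    top_exclude: float = 0.02,
    norm_band: float = 0.08,
    cap: float = REACTIVITY_CAP,
    min_positions: int = 10,
) -> ReactivityProfile:
    """Normalize A/C mutation frequencies to reactivity units.

    The top ``top_exclude`` fraction of A/C frequencies is excluded as
    outliers and the remaining values are divided by the mean of the next
    ``norm_band`` fraction, then capped at ``cap``. Profiles with fewer
    than ``min_positions`` usable A/C positions are flagged
    unnormalizable (reactivity stays NaN).
    """
    ac = profile.ac_mask()
    vals = profile.frequency[ac]
    vals = vals[~np.isnan(vals)]
    if vals.size < min_positions:
        return replace(profile, normalizable=False)
    order = np.sort(vals)[::-1]
    n = order.size
    k_excl = int(np.floor(top_exclude * n + 1e-9))
    band = max(1, int(np.floor(norm_band * n + 1e-9)))
    denom_vals = order[k_excl : k_excl + band]
    denom = float(np.mean(denom_vals))
    if denom <= 0:
        return replace(profile, normalizable=False)
    reactivity = np.full(profile.n, np.nan)
    idx = np.where(ac)[0]
    reactivity[idx] = np.minimum(profile.frequency[idx] / denom, cap)
    return replace(profile, reactivity=reactivity, normalizable=True)


def replicate_r2(prof_a: ReactivityProfile, prof_b: ReactivityProfile, min_positions: int = 10) -> float:
    """Squared Pearson correlation over jointly unmasked A/C positions."""
    if prof_a.sequence != prof_b.sequence:
        raise ValueError("replicate profiles must share a sequence")
    joint = prof_a.ac_mask() & prof_b.ac_mask()
    a = prof_a.frequency[joint]
    b = prof_b.frequency[joint]
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < min_positions:
        raise ValueError(f"fewer than {min_positions} co-masked A/C positions")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a replicate; r^2 undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def per_base_coverage(n_reads: float, read_len: float, construct_len: float) -> float:
    """Mean per-base coverage: reads x read length / construct length."""
    if construct_len <= 0:
        raise ValueError("construct length must be positive")
    return n_reads * read_len / construct_len


@dataclass(frozen=True)
class GiniWindow:
    start: int
    end: int  # half-open
    gini: float


def gini_coefficient(values: np.ndarray) -> float:
    """Mean-normalized mean absolute difference: sum|xi-xj| / (2 n^2 mu)."""
    x = np.asarray(values, dtype=float)
    n = x.size
    mu = x.mean()
    if mu == 0:
        return 0.0
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2 * n * n * mu))


def windowed_gini(
    frequencies,
    coverage,
    window: int = 20,
    step: int = 10,
    min_cov: float = GINI_COVERAGE_CUTOFF,
) -> tuple[list[GiniWindow], float]:
    """Sliding-window Gini coefficients of mutation frequency.

    Windows containing any position with coverage below ``min_cov`` are
    omitted. Returns the window list and the maximum window Gini (NaN if
    no window qualifies).
    """
    freq = np.asarray(frequencies, dtype=float)
    cov = np.asarray(coverage, dtype=float)
    if window > freq.size:
        raise ValueError("window longer than sequence")
    out = []
    for start in range(0, freq.size - window + 1, step):
        stop = start + window
        if np.any(cov[start:stop] < min_cov) or np.any(np.isnan(freq[start:stop])):
            continue
        out.append(GiniWindow(start, stop, gini_coefficient(freq[start:stop])))
    max_gini = max((w.gini for w in out), default=float("nan"))
    return out, max_gini


def roc_auc(values, labels) -> float:
    """Rank-based AUC: P(positive outranks negative), ties counted half."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if v.shape != y.shape:
        raise ValueError("values and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    ranks = stats.rankdata(v)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
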