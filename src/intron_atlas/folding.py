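"""Folding engines and bootstrap helix-confidence estimation.

The built-in baseline engine scores non-crossing structures by a
maximum-pairing dynamic program with a reactivity pseudo-energy: pairing
a low-reactivity position is rewarded and pairing a high-reactivity
position is penalized, so chemical-probing data steer the fold without an
external thermodynamic package. A thermodynamic engine (ViennaRNA) can be
plugged in through the same contract when its bindings are installed.

Helix confidence is estimated by non-parametric bootstrapping: mutation
counts are resampled binomially per position (preserving coverage), the
profile is renormalized and refolded, and each base pair's support is the
fraction of bootstrap structures that contain it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
from numba import njit

from . import thermo
from .reactivity import ReactivityProfile, normalize
from .structures import CANONICAL_PAIRS, MIN_HAIRPIN, SecondaryStructure, clean_rna

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# engine contract


@runtime_checkable
class FoldingEngine(Protocol):
    """Contract for pluggable secondary-structure engines."""

    def fold(self, sequence: str, reactivity=None) -> SecondaryStructure: ...

    def sample(self, sequence: str, n: int, seed: int) -> list[SecondaryStructure]: ...

    def duplex_dG(self, strand5: str, strand3: str) -> float: ...


# ---------------------------------------------------------------------------
# baseline engine


@njit(cache=False)
def _fill_dp(S):  # pragma: no cover - exercised via fold()
    n = S.shape[0]
    W = np.zeros((n, n))
    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            best = W[i + 1, j]
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                sc = S[i, k]
                if sc == NEG_INF:
                    continue
                left = W[i + 1, k - 1] if k - 1 > i else 0.0
                right = W[k + 1, j] if k + 1 < n and k < j else 0.0
                v = sc + left + right
                if v > best:
                    best = v
            W[i, j] = best
    return W


class BaselineEngine:
    """Reactivity-aware maximum-pairing engine (Nussinov-style DP).

    Each candidate pair (i, j) scores ``1 + weight * sum(threshold - r)``
    over the two positions with defined reactivity r, so unreactive
    positions gain a bonus and highly reactive positions are pushed
    toward single-strandedness. With no reactivity the engine returns the
    maximum-base-pair structure (minimum hairpin 3), breaking ties toward
    5'-most pairs.
    """

    def __init__(self, weight: float = 0.5, threshold: float = 0.5):
        self.weight = weight
        self.threshold = threshold

    # -- scoring ----------------------------------------------------------
    def pair_score_matrix(self, sequence: str, reactivity=None) -> np.ndarray:
        seq = clean_rna(sequence)
        n = len(seq)
        if reactivity is None:
            bonus = np.zeros(n)
        else:
            r = np.asarray(reactivity, dtype=float)
            if r.shape != (n,):
                raise ValueError("reactivity length must match sequence")
            bonus = np.where(np.isnan(r), 0.0, self.weight * (self.threshold - r))
        S = np.full((n, n), NEG_INF)
        for i in range(n):
            for j in range(i + MIN_HAIRPIN + 1, n):
                if (seq[i], seq[j]) in CANONICAL_PAIRS:
                    S[i, j] = 1.0 + bonus[i] + bonus[j]
        return S

    # -- folding ----------------------------------------------------------
    def _traceback(self, S: np.ndarray, W: np.ndarray) -> frozenset:
        n = S.shape[0]
        pairs = set()
        stack = [(0, n - 1)]
        eps = 1e-9
        while stack:
            i, j = stack.pop()
            if i >= j:
                continue
            target = W[i, j]
            chosen = -1
            for k in range(i + MIN_HAIRPIN + 1, j + 1):
                sc = S[i, k]
                if sc == NEG_INF:
                    continue
                left = W[i + 1, k - 1] if k - 1 > i else 0.0
                right = W[k + 1, j] if k + 1 < n and k < j else 0.0
                if sc + left + right >= target - eps:
                    chosen = k
                    break
            if chosen >= 0:
                pairs.add((i, chosen))
                if chosen - 1 > i:
                    stack.append((i + 1, chosen - 1))
                if chosen < j:
                    stack.append((chosen + 1, j))
            else:
                stack.append((i + 1, j))
        return frozenset(pairs)

    def fold_with_scores(self, sequence: str, S: np.ndarray) -> SecondaryStructure:
        seq = clean_rna(sequence)
        if len(seq) < MIN_HAIRPIN + 2:
            return SecondaryStructure(seq)
        W = _fill_dp(S)
        return SecondaryStructure(seq, self._traceback(S, W))

    def fold(self, sequence: str, reactivity=None) -> SecondaryStructure:
        S = self.pair_score_matrix(sequence, reactivity)
        return self.fold_with_scores(sequence, S)

    def optimal_score(self, sequence: str, reactivity=None) -> float:
        """Optimal DP score (used for oracle-equivalence checks)."""
        seq = clean_rna(sequence)
        if len(seq) < MIN_HAIRPIN + 2:
            return 0.0
        S = self.pair_score_matrix(seq, reactivity)
        return float(_fill_dp(S)[0, len(seq) - 1])

    # -- sampling ---------------------------------------------------------
    def sample(self, sequence: str, n: int, seed: int, noise_sd: float = 0.35) -> list[SecondaryStructure]:
        """Draw alternative structures by jittering pair scores.

        Seeded Gaussian noise is added to every candidate-pair score
        before refolding, yielding a deterministic, diverse ensemble.
        """
        rng = np.random.default_rng(seed)
        seq = clean_rna(sequence)
        base = self.pair_score_matrix(seq)
        out = []
        for _ in range(n):
            noise = rng.normal(0.0, noise_sd, size=base.shape)
            S = np.where(base == NEG_INF, NEG_INF, base + noise)
            out.append(self.fold_with_scores(seq, S))
        return out

    # -- thermodynamics ---------------------------------------------------
    def duplex_dG(self, strand5: str, strand3: str) -> float:
        return thermo.duplex_dG(strand5, strand3)


# ---------------------------------------------------------------------------
# exhaustive enumeration (reference oracle for short sequences)


def enumerate_structures(sequence: str) -> Iterable[frozenset]:
    """Yield every non-crossing structure (canonical pairs, hairpin >= 3).

    Exponential; intended for sequences of roughly <= 16 nt as an
    independent reference for the DP engine.
    """
    seq = clean_rna(sequence)
    n = len(seq)

    def rec(lo: int, hi: int):
        # structures over positions [lo, hi)
        if lo >= hi:
            yield frozenset()
            return
        # position lo unpaired
        for rest in rec(lo + 1, hi):
            yield rest
        for k in range(lo + MIN_HAIRPIN + 1, hi):
            if (seq[lo], seq[k]) in CANONICAL_PAIRS:
                for inner in rec(lo + 1, k):
                    for outer in rec(k + 1, hi):
                        yield frozenset({(lo, k)}) | inner | outer

    yield from rec(0, n)


def best_enumerated_score(sequence: str, engine: BaselineEngine, reactivity=None) -> float:
    """Optimal score over all structures by brute-force enumeration."""
    S = engine.pair_score_matrix(sequence, reactivity)
    best = 0.0
    for pairs in enumerate_structures(sequence):
        score = sum(S[i, j] for i, j in pairs)
        if score > best:
            best = score
    return best


# ---------------------------------------------------------------------------
# bootstrap helix confidence


@dataclass(frozen=True)
class PairSupport:
    """Fraction of bootstrap structures containing each base pair."""

    n: int
    support: dict
    n_boot: int

    def get(self, i: int, j: int) -> float:
        return self.support.get((i, j), 0.0)


def bootstrap_support(
    profile: ReactivityProfile,
    engine: FoldingEngine,
    n_boot: int = 1000,
    seed: int = 0,
    **norm_kwargs,
) -> PairSupport:
    """Non-parametric bootstrap of reactivity-guided folds.

    Per iteration, mutation counts are resampled as
    binomial(coverage, frequency) position-wise, the profile is
    renormalized, and the engine refolds the sequence; support(i, j) is
    the fraction of iterations whose structure contains (i, j).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    base = normalize(profile, **norm_kwargs)
    if not base.normalizable:
        raise ValueError("profile is not normalizable; cannot bootstrap")
    rng = np.random.default_rng(seed)
    cov = profile.coverage.astype(np.int64)
    freq = np.where(np.isnan(profile.frequency), 0.0, profile.frequency)
    counts: dict[tuple[int, int], int] = {}
    for _ in range(n_boot):
        resampled = rng.binomial(cov, freq)
        prof_b = ReactivityProfile(profile.sequence, resampled, profile.coverage)
        prof_b = normalize(prof_b, **norm_kwargs)
        react = prof_b.reactivity if prof_b.normalizable else None
        structure = engine.fold(profile.sequence, react)
        for pair in structure.pairs:
            counts[pair] = counts.get(pair, 0) + 1
    support = {pair: c / n_boot for pair, c in counts.items()}
    return PairSupport(n=profile.n, support=support, n_boot=n_boot)


def stem_confidence(stem, support: PairSupport, aggregate: str = "mean") -> float:
    """Helix confidence in percent, aggregated over a stem's base pairs.

    ``stem`` may be a StemCall-like object with a ``pairs`` attribute or a
    bare iterable of (i, j) pairs. The default aggregation is the mean
    per-pair bootstrap support; ``aggregate='min'`` uses the weakest pair.
    """
    pairs = list(getattr(stem, "pairs", stem))
    if not pairs:
        raise ValueError("stem has no base pairs")
    vals = [support.get(i, j) for i, j in pairs]
    if aggregate == "mean":
        agg = float(np.mean(vals))
    elif aggregate == "min":
        agg = float(np.min(vals))
    else:
        raise ValueError(f"unknown aggregation {aggregate!r}")
    return 100.0 * agg


# ---------------------------------------------------------------------------
# optional thermodynamic engine (ViennaRNA bindings)


class ViennaEngine:
    """Thermodynamic engine backed by ViennaRNA's python bindings.

    Reactivity guidance uses the standard log-linear pseudo-energy
    conversion (slope 1.8, intercept -0.6 kcal/mol) on A/C positions.
    Raises ImportError at construction when the bindings are absent.
    """

    def __init__(self, slope: float = 1.8, intercept: float = -0.6):
        import RNA  # noqa: F401 - availability check

        self._RNA = RNA
        self.slope = slope
        self.intercept = intercept

    def fold(self, sequence: str, reactivity=None) -> SecondaryStructure:
        RNA = self._RNA
        seq = clean_rna(sequence)
        fc = RNA.fold_compound(seq)
        if reactivity is not None:
            r = np.asarray(reactivity, dtype=float)
            shape = [float(x) if np.isfinite(x) else -999.0 for x in r]
            fc.sc_add_SHAPE_deigan(shape, self.slope, self.intercept)
        db, _ = fc.mfe()
        pairs = frozenset(
            (i, j)
            for i, j in _pairs_from_db_tolerant(db)
            if j - i - 1 >= MIN_HAIRPIN
        )
        return SecondaryStructure(seq, pairs)

    def sample(self, sequence: str, n: int, seed: int) -> list[SecondaryStructure]:
        RNA = self._RNA
        seq = clean_rna(sequence)
        fc = RNA.fold_compound(seq)
        fc.pf()
        try:
            RNA.init_rand(seed)
        except Exception:
            pass
        out = []
        for db in fc.pbacktrack(n):
            pairs = frozenset(
                (i, j)
                for i, j in _pairs_from_db_tolerant(db)
                if j - i - 1 >= MIN_HAIRPIN
            )
            out.append(SecondaryStructure(seq, pairs))
        return out

    def duplex_dG(self, strand5: str, strand3: str) -> float:
        duplex = self._RNA.duplexfold(clean_rna(strand5), clean_rna(strand3))
        return float(duplex.energy)


def _pairs_from_db_tolerant(db: str):
    stack = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            yield (stack.pop(), idx)
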