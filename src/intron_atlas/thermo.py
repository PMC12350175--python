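"""Nearest-neighbour duplex free energies (Turner 2004, 37 degC).

Stack free energies are tabulated for Watson-Crick and GU wobble pairs at
the 0.01 kcal/mol resolution of the published parameter set. The duplex
free energy is the initiation penalty plus the sum of stack terms plus a
terminal penalty for AU/GU-closing ends. A more negative value is a more
stable duplex.
"""

from __future__ import annotations

from .structures import CANONICAL_PAIRS, clean_rna

#: duplex initiation penalty, kcal/mol
DUPLEX_INIT = 4.10
#: penalty per helix end closed by an AU or GU pair, kcal/mol
TERMINAL_AU_GU = 0.50

_PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")

# Rows: first pair (5' base, 3' partner); columns: second pair reversed
# (reading the bottom strand 3'->5'). Units kcal/mol.
_STACK_MATRIX = (
    (-2.40, -3.30, -2.10, -1.40, -2.10, -2.10),  # CG
    (-3.30, -3.40, -2.50, -1.50, -2.20, -2.40),  # GC
    (-2.10, -2.50, +1.30, -0.50, -1.40, -1.30),  # GU
    (-1.40, -1.50, -0.50, +0.30, -0.60, -1.00),  # UG
    (-2.10, -2.20, -1.40, -0.60, -1.10, -0.90),  # AU
    (-2.10, -2.40, -1.30, -1.00, -0.90, -1.30),  # UA
)

STACK_DG: dict[tuple[str, str], float] = {}
for _r, _p1 in enumerate(_PAIR_ORDER):
    for _c, _p2 in enumerate(_PAIR_ORDER):
        STACK_DG[(_p1, _p2)] = _STACK_MATRIX[_r][_c]


def stack_dg(pair1: tuple[str, str], pair2: tuple[str, str]) -> float:
    """Free energy of stacking pair2 on pair1.

    ``pair1 = (a, a')`` and ``pair2 = (b, b')`` describe the duplex
    5'-a b-3' / 3'-a' b'-5'; the table is indexed by pair1 read top-to-
    bottom and pair2 read bottom-to-top, following the standard
    nearest-neighbour convention.
    """
    key = ("".join(pair1), pair2[1] + pair2[0])
    try:
        return STACK_DG[key]
    except KeyError:
        raise ValueError(f"non-canonical stack {pair1}/{pair2}") from None


def duplex_dG(strand5: str, strand3: str) -> float:
    """Free energy (kcal/mol, 37 degC) of a fully paired duplex.

    ``strand5`` and ``strand3`` are the two paired segments, each written
    5'->3', so position k of ``strand5`` pairs with position (L-1-k) of
    ``strand3``. The caller is expected to have removed bulged
    nucleotides; every opposed base pair must be Watson-Crick or GU.
    """
    s5 = clean_rna(strand5)
    s3 = clean_rna(strand3)
    if len(s5) == 0 or len(s3) == 0:
        raise ValueError("duplex strands must be non-empty")
    if len(s5) != len(s3):
        raise ValueError("paired segments must have equal length")
    pairs = [(s5[k], s3[len(s3) - 1 - k]) for k in range(len(s5))]
    for p in pairs:
        if p not in CANONICAL_PAIRS:
            raise ValueError(f"non-canonical base pair {p} in duplex")
    dg = DUPLEX_INIT
    for k in range(len(pairs) - 1):
        dg += stack_dg(pairs[k], pairs[k + 1])
    for end in (pairs[0], pairs[-1]):
        if end not in (("G", "C"), ("C", "G")):
            dg += TERMINAL_AU_GU
    return round(dg, 10)
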