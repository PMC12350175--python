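"""RNA secondary structure container and dot-bracket utilities.

A structure is a set of non-crossing base pairs over an RNA sequence
(pseudoknot-free by construction). Hairpin loops of fewer than 3 nt are
rejected, matching the geometric minimum used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")

#: canonical Watson-Crick plus wobble pairs
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

MIN_HAIRPIN = 3


def clean_rna(seq: str) -> str:
    """Uppercase a sequence and map DNA T to RNA U; reject other letters."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGU characters in sequence: {sorted(bad)}")
    return s


def pairs_from_dot_bracket(db: str) -> frozenset[tuple[int, int]]:
    stack: list[int] = []
    pairs = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif ch != ".":
            raise ValueError(f"unsupported dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket string")
    return frozenset(pairs)


def dot_bracket_from_pairs(n: int, pairs) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure for one RNA sequence.

    Attributes
    ----------
    sequence:
        RNA string (ACGU).
    pairs:
        Frozen set of (i, j) base pairs with i < j, non-crossing, each
        index in at most one pair, hairpin loops of at least 3 nt.
    """

    sequence: str
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        seq = clean_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        pairs = frozenset((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        n = len(seq)
        seen: set[int] = set()
        for i, j in pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair ({i},{j}) out of range for length {n}")
            if j - i - 1 < MIN_HAIRPIN:
                raise ValueError(f"pair ({i},{j}) closes a loop shorter than {MIN_HAIRPIN} nt")
            if i in seen or j in seen:
                raise ValueError(f"index in more than one pair near ({i},{j})")
            seen.update((i, j))
        plist = sorted(pairs)
        for a in range(len(plist)):
            i1, j1 = plist[a]
            for b in range(a + 1, len(plist)):
                i2, j2 = plist[b]
                if i2 > j1:
                    break
                if not (i1 < i2 and j2 < j1):
                    raise ValueError(f"crossing pairs ({i1},{j1}) and ({i2},{j2})")

    @classmethod
    def from_dot_bracket(cls, sequence: str, db: str) -> "SecondaryStructure":
        sequence = clean_rna(sequence)
        if len(sequence) != len(db):
            raise ValueError("sequence and dot-bracket lengths differ")
        return cls(sequence, pairs_from_dot_bracket(db))

    @property
    def dot_bracket(self) -> str:
        return dot_bracket_from_pairs(len(self.sequence), self.pairs)

    @property
    def n(self) -> int:
        return len(self.sequence)

    def partner(self) -> dict[int, int]:
        """Map each paired index to its partner."""
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out

    def paired_mask(self):
        import numpy as np

        mask = np.zeros(self.n, dtype=bool)
        for i, j in self.pairs:
            mask[i] = True
            mask[j] = True
        return mask

    def to_ct(self, title: str = "structure") -> str:
        """Serialize in connectivity-table (CT) format."""
        partner = self.partner()
        lines = [f"{self.n} {title}"]
        for idx, base in enumerate(self.sequence):
            j = partner.get(idx, -1)
            lines.append(
                f"{idx + 1} {base} {idx} {idx + 2 if idx + 1 < self.n else 0} "
                f"{j + 1 if j >= 0 else 0} {idx + 1}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_ct(cls, text: str) -> "SecondaryStructure":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        seq = []
        pairs = set()
        for ln in lines[1 : n + 1]:
            fields = ln.split()
            idx = int(fields[0]) - 1
            seq.append(fields[1])
            j = int(fields[4]) - 1
            if j > idx:
                pairs.add((idx, j))
        return cls("".join(seq), frozenset(pairs))
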