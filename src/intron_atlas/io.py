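"""Plain-text I/O: FASTA, annotation/reactivity/support TSVs, dot-bracket.

FASTA handling goes through Biopython; readers accept DNA (T) and map to
RNA (U). The annotation TSV dialect is 1-based inclusive on disk (stated
in the file header) and 0-based half-open in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .folding import PairSupport
from .reactivity import ReactivityProfile
from .structures import clean_rna
from .synthetic import PlantedIntron

ANNOTATION_HEADER = (
    "# intron annotations: 1-based inclusive coordinates; bp_pos is the "
    "branch adenosine on the sense strand, 1-based within the intron\n"
)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: RNA sequence}; T is mapped to U."""
    return {rec.id: clean_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str], as_dna: bool = False) -> None:
    records = []
    for name, seq in sequences.items():
        s = seq.replace("U", "T") if as_dna else seq
        records.append(SeqRecord(Seq(s), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_annotations(path, introns: list[PlantedIntron]) -> None:
    rows = [
        {
            "gene_id": d.gene_id,
            "chrom": d.chrom,
            "intron_start": d.start + 1,
            "intron_end": d.end,  # half-open end == 1-based inclusive end
            "bp_pos": d.bp_offset + 1,
            "strand": d.strand,
        }
        for d in introns
    ]
    with open(path, "w") as fh:
        fh.write(ANNOTATION_HEADER)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_annotations(path) -> list[PlantedIntron]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        PlantedIntron(
            gene_id=r.gene_id,
            chrom=r.chrom,
            start=int(r.intron_start) - 1,
            end=int(r.intron_end),
            bp_offset=int(r.bp_pos) - 1,
            strand=r.strand,
        )
        for r in df.itertuples()
    ]


def write_reactivity(path, profile: ReactivityProfile) -> None:
    df = pd.DataFrame(
        {
            "pos": np.arange(profile.n),
            "base": list(profile.sequence),
            "mut_count": profile.mut_counts.astype(int),
            "coverage": profile.coverage.astype(int),
            "frequency": profile.frequency,
            "reactivity": profile.reactivity,
            "mask": profile.mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_reactivity(path) -> ReactivityProfile:
    df = pd.read_csv(path, sep="\t")
    profile = ReactivityProfile(
        sequence="".join(df["base"]),
        mut_counts=df["mut_count"].to_numpy(),
        coverage=df["coverage"].to_numpy(),
    )
    if "reactivity" in df.columns and df["reactivity"].notna().any():
        object.__setattr__(profile, "reactivity", df["reactivity"].to_numpy(dtype=float))
    return profile


def write_pair_support(path, support: PairSupport) -> None:
    rows = [{"i": i, "j": j, "support": s} for (i, j), s in sorted(support.support.items())]
    with open(path, "w") as fh:
        fh.write(f"# n={support.n} n_boot={support.n_boot}\n")
        pd.DataFrame(rows, columns=["i", "j", "support"]).to_csv(fh, sep="\t", index=False)


def read_pair_support(path) -> PairSupport:
    with open(path) as fh:
        header = fh.readline()
    meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
    df = pd.read_csv(path, sep="\t", comment="#")
    support = {(int(r.i), int(r.j)): float(r.support) for r in df.itertuples()}
    return PairSupport(n=int(meta["n"]), support=support, n_boot=int(meta["n_boot"]))


def write_dot_bracket(path, name: str, structure) -> None:
    Path(path).write_text(f">{name}\n{structure.sequence}\n{structure.dot_bracket}\n")


def read_dot_bracket(path):
    from .structures import SecondaryStructure

    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    return SecondaryStructure.from_dot_bracket(lines[0], lines[1])
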