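"""Evolutionary site utilities.

Three independent tools: scanning a multi-species protein alignment for
columns where the focal species alone differs from an otherwise identical
background, summing root-to-tip branch lengths on rooted gene trees, and
aggregating five per-gene boolean adaptation signals into a
multiple-signs-of-adaptation (MSA) call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

SIGNAL_COLUMNS = ("HBW", "RTT", "PSG", "USF", "PSS")
GENE_WIDE = ("HBW", "RTT", "PSG")
SITE_SPECIFIC = ("USF", "PSS")

__all__ = [
    "SIGNAL_COLUMNS",
    "GENE_WIDE",
    "SITE_SPECIFIC",
    "ProteinAlignment",
    "UniqueSubstitution",
    "find_unique_substitutions",
    "root_to_tip_distances",
    "focal_is_strict_max",
    "aggregate_msa",
]


@dataclass
class ProteinAlignment:
    """An aligned set of protein sequences with a designated focal species.

    Sequences use the amino-acid alphabet plus gap ``-`` and unknown ``X``;
    all must have equal length and the focal species must be present.
    """

    sequences: dict[str, str]
    focal: str

    def __post_init__(self) -> None:
        if self.focal not in self.sequences:
            raise ValueError(f"focal species {self.focal!r} absent from alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @classmethod
    def from_fasta(cls, path: str | Path, focal: str) -> "ProteinAlignment":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(sequences=seqs, focal=focal)


@dataclass(frozen=True)
class UniqueSubstitution:
    """An alignment column where the focal species alone differs."""

    column: int  # 1-based alignment column
    background_aa: str
    focal_aa: str


def find_unique_substitutions(aln: ProteinAlignment, gap_flank: int = 5) -> list[UniqueSubstitution]:
    """Scan for focal-unique substitution columns.

    A column qualifies iff every non-focal residue is identical, the focal
    residue differs, no sequence carries a gap or ``X`` in the column, and
    the column lies more than ``gap_flank`` columns away from every column
    containing a gap in any sequence. Distances are measured in alignment
    columns.
    """
    non_focal = [s for name, s in aln.sequences.items() if name != aln.focal]
    if len(non_focal) < 2:
        raise ValueError("need at least 2 non-focal species to define a background")
    focal_seq = aln.sequences[aln.focal]
    length = aln.length

    gap_cols = [i for i in range(length) if any(seq[i] == "-" for seq in aln.sequences.values())]
    excluded = set()
    for col in gap_cols:
        excluded.update(range(max(0, col - gap_flank), min(length, col + gap_flank + 1)))

    hits: list[UniqueSubstitution] = []
    for i in range(length):
        if i in excluded:
            continue
        residues = [seq[i] for seq in non_focal]
        focal_aa = focal_seq[i]
        column = residues + [focal_aa]
        if any(r in "-X" for r in column):
            continue
        background = residues[0]
        if any(r != background for r in residues[1:]):
            continue
        if focal_aa == background:
            continue
        hits.append(UniqueSubstitution(column=i + 1, background_aa=background, focal_aa=focal_aa))
    return hits


def root_to_tip_distances(
    tree: "dendropy.Tree | str | Path", focal: str | None = None
) -> tuple[dict[str, float], bool | None]:
    """Sum branch lengths from the root to every leaf.

    ``tree`` may be a dendropy Tree, a Newick string, or a path to a Newick
    file; it must be rooted (root degree <= 2) with non-negative branch
    lengths on every non-root edge. Returns the per-leaf distances and, when
    ``focal`` is given, whether its distance strictly exceeds every other
    leaf's.
    """
    if not isinstance(tree, dendropy.Tree):
        text = str(tree)
        if "(" not in text and Path(text).exists():
            tree = dendropy.Tree.get(path=text, schema="newick")
        else:
            tree = dendropy.Tree.get(data=text, schema="newick")
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        raise ValueError("tree is unrooted (root has more than two children); root it first")

    distances: dict[str, float] = {}

    def walk(node, acc: float) -> None:
        for child in node.child_nodes():
            if child.edge.length is None:
                raise ValueError("tree has a missing branch length")
            if child.edge.length < 0:
                raise ValueError(f"negative branch length {child.edge.length}")
            d = acc + child.edge.length
            if child.is_leaf():
                distances[child.taxon.label] = d
            else:
                walk(child, d)

    if root.is_leaf():
        distances[root.taxon.label] = 0.0
    walk(root, 0.0)

    strict_max: bool | None = None
    if focal is not None:
        if focal not in distances:
            raise ValueError(f"focal leaf {focal!r} not in tree")
        strict_max = all(distances[focal] > d for name, d in distances.items() if name != focal)
    return distances, strict_max


def focal_is_strict_max(distances: Mapping[str, float], focal: str) -> bool:
    """Whether ``focal`` has the strictly largest root-to-tip distance."""
    return all(distances[focal] > d for name, d in distances.items() if name != focal)


def aggregate_msa(signals: pd.DataFrame, threshold: int = 3) -> tuple[pd.DataFrame, dict[str, int]]:
    """Aggregate the five adaptation signals per gene.

    ``signals`` needs a ``gene_id`` column plus boolean columns HBW, RTT,
    PSG, USF, PSS (missing columns/cells are treated as False and logged).
    A gene is MSA when at least ``threshold`` signals are true. Also returns
    the full 32-pattern intersection census (upset-plot input) whose counts
    sum to the number of genes; keys are '+'-joined signal names, with
    'none' for the all-false pattern.
    """
    df = signals.copy()
    if "gene_id" not in df.columns:
        raise ValueError("signals table needs a gene_id column")
    for col in SIGNAL_COLUMNS:
        if col not in df.columns:
            warnings.warn(f"signal column {col} missing; treated as all-False", stacklevel=2)
            df[col] = False
        n_missing = int(df[col].isna().sum())
        if n_missing:
            warnings.warn(f"{n_missing} missing cells in signal column {col} treated as False", stacklevel=2)
        df[col] = df[col].fillna(False).astype(bool)

    df["n_signals"] = df[list(SIGNAL_COLUMNS)].sum(axis=1)
    df["msa"] = df["n_signals"] >= threshold
    df["gene_wide_all3"] = df[list(GENE_WIDE)].all(axis=1)
    df["site_specific_both"] = df[list(SITE_SPECIFIC)].all(axis=1)

    census: dict[str, int] = {}
    pattern = df[list(SIGNAL_COLUMNS)].apply(
        lambda row: "+".join(c for c in SIGNAL_COLUMNS if row[c]) or "none", axis=1
    )
    for key, count in pattern.value_counts().items():
        census[key] = int(count)
    return df, census
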