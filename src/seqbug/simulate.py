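"""Synthetic fixtures with known ground truth.

Generates a random genome with non-overlapping gene models, injects
single-base assembly errors (the "corrupted" assembly), simulates
readcount pileups for two individuals at the count level (no reads, no
mapping — the correction method consumes counts), and fabricates protein
alignments / gene trees / signal tables with planted features for the
evolutionary utilities.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from seqbug.pileup_io import PileupRecord
from seqbug.signals import SIGNAL_COLUMNS, ProteinAlignment

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_truth",
    "simulate_pileup",
    "simulate_signal_fixtures",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# local codon table so ground-truth effect classes stay independent of the
# projection code under test
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_AA_ALPHABET = sorted(set(_CODON_TABLE.values()) - {"*"})


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    n_scaffolds: int = 2
    gc_fraction: float = 0.42
    n_genes: int = 20
    mean_exons_per_gene: float = 3.0
    coverage_mean: float = 60.0
    sequencing_error_rate: float = 0.01
    n_injected_errors: int = 500
    fraction_errors_in_cds: float = 0.2
    snp_rate: float = 0.0
    indel_site_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "sequencing_error_rate", "fraction_errors_in_cds", "snp_rate", "indel_site_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.n_injected_errors > self.genome_length:
            raise ValueError("n_injected_errors exceeds genome_length")


@dataclass
class GroundTruth:
    """Everything a test needs to score the pipeline."""

    true_genome: dict[str, str]
    corrupted_genome: dict[str, str]
    # (seq_id, pos) -> (true_base, corrupted_base), 1-based
    error_sites: dict[tuple[str, int], tuple[str, str]]
    # (seq_id, pos) -> independent-individual base differing from truth
    snp_sites: dict[tuple[str, int], str]
    # (seq_id, pos) of designated high-indel positions
    indel_sites: set[tuple[str, int]]
    # (transcript_id, 1-based codon index) -> effect class of injected errors
    coding_effects: dict[tuple[str, int], str]
    gtf_text: str = ""


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(_BASES[rng.choice(4, size=length, p=probs)])


@dataclass
class _Gene:
    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, ascending genomic order

    def cds_positions(self) -> list[int]:
        """Genomic positions 5'->3' in transcript orientation."""
        positions = [p for start, end in self.exons for p in range(start, end + 1)]
        return positions[::-1] if self.strand == "-" else positions


def _place_genes(rng: np.random.Generator, scaffold_lengths: dict[str, int], config: SimulationConfig) -> list[_Gene]:
    genes: list[_Gene] = []
    order = list(scaffold_lengths)
    per_scaffold = {s: config.n_genes // len(order) for s in order}
    for i in range(config.n_genes % len(order)):
        per_scaffold[order[i]] += 1

    counter = 0
    for seq_id in order:
        cursor = 1 + int(rng.integers(50, 200))
        length = scaffold_lengths[seq_id]
        for _ in range(per_scaffold[seq_id]):
            n_exons = max(1, 1 + int(rng.poisson(max(config.mean_exons_per_gene - 1, 0))))
            exon_lens = [int(rng.integers(30, 150)) for _ in range(n_exons)]
            total = sum(exon_lens)
            trim = total % 3
            if trim:
                exon_lens[-1] -= trim
            intron_lens = [int(rng.integers(20, 100)) for _ in range(n_exons - 1)]
            span = sum(exon_lens) + sum(intron_lens)
            if cursor + span - 1 > length:
                break
            exons = []
            p = cursor
            for j, el in enumerate(exon_lens):
                exons.append((p, p + el - 1))
                p += el + (intron_lens[j] if j < n_exons - 1 else 0)
            counter += 1
            genes.append(
                _Gene(
                    gene_id=f"gene{counter:04d}",
                    transcript_id=f"tx{counter:04d}",
                    seq_id=seq_id,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=exons,
                )
            )
            cursor += span + int(rng.integers(100, 400))
    if len(genes) < config.n_genes:
        raise ValueError(
            f"infeasible config: placed only {len(genes)} of {config.n_genes} genes in {config.genome_length} bp"
        )
    return genes


def _gtf_lines(genes: Iterable[_Gene]) -> str:
    lines = ["#!genome-build seqbug-sim", "#!genome-version 1"]
    for gene in genes:
        attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.transcript_id}"; gene_biotype "protein_coding";'
        ordered = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
        frame = 0
        for start, end in ordered:
            lines.append(
                "\t".join(
                    [gene.seq_id, "seqbug_sim", "CDS", str(start), str(end), ".", gene.strand, str(frame), attrs]
                )
            )
            frame = (3 - ((end - start + 1) - frame) % 3) % 3
    return "\n".join(lines) + "\n"


def _classify(codon_index: int, ref_codon: str, alt_codon: str) -> str:
    ref_aa = _CODON_TABLE[ref_codon]
    alt_aa = _CODON_TABLE[alt_codon]
    if codon_index == 1 and ref_codon == "ATG" and alt_aa != "M":
        return "start_loss"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gain"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_loss"
    return "synonymous" if ref_aa == alt_aa else "nonsynonymous"


def simulate_truth(config: SimulationConfig) -> tuple[dict[str, str], str, GroundTruth]:
    """Build the true genome, gene models, and the corrupted assembly.

    Returns ``(true_genome, gtf_text, ground_truth)``; the corrupted
    assembly (truth plus injected errors) lives on the ground-truth object.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    base_len = config.genome_length // config.n_scaffolds
    scaffold_lengths = {
        f"scaf{i + 1}": base_len + (config.genome_length % config.n_scaffolds if i == 0 else 0)
        for i in range(config.n_scaffolds)
    }
    true_genome = {s: _random_sequence(rng, ln, config.gc_fraction) for s, ln in scaffold_lengths.items()}
    genes = _place_genes(rng, scaffold_lengths, config)
    gtf_text = _gtf_lines(genes)

    cds_positions = {(g.seq_id, pos) for g in genes for s, e in g.exons for pos in range(s, e + 1)}
    all_positions = [(s, p) for s, ln in scaffold_lengths.items() for p in range(1, ln + 1)]
    non_cds = [sp for sp in all_positions if sp not in cds_positions]

    n_cds_err = min(int(round(config.n_injected_errors * config.fraction_errors_in_cds)), len(cds_positions))
    n_other = config.n_injected_errors - n_cds_err
    cds_list = sorted(cds_positions)
    chosen: list[tuple[str, int]] = []
    if n_cds_err:
        idx = rng.choice(len(cds_list), size=n_cds_err, replace=False)
        chosen += [cds_list[i] for i in idx]
    if n_other:
        idx = rng.choice(len(non_cds), size=n_other, replace=False)
        chosen += [non_cds[i] for i in idx]

    corrupted = {s: list(seq) for s, seq in true_genome.items()}
    error_sites: dict[tuple[str, int], tuple[str, str]] = {}
    for seq_id, pos in chosen:
        true_base = true_genome[seq_id][pos - 1]
        alternatives = [b for b in "ACGT" if b != true_base]
        corrupt_base = alternatives[int(rng.integers(3))]
        corrupted[seq_id][pos - 1] = corrupt_base
        error_sites[(seq_id, pos)] = (true_base, corrupt_base)
    corrupted_genome = {s: "".join(chars) for s, chars in corrupted.items()}

    taken = set(error_sites)
    snp_sites: dict[tuple[str, int], str] = {}
    if config.snp_rate > 0:
        mask = rng.random(len(all_positions)) < config.snp_rate
        for flag, sp in zip(mask, all_positions):
            if flag and sp not in taken:
                true_base = true_genome[sp[0]][sp[1] - 1]
                alternatives = [b for b in "ACGT" if b != true_base]
                snp_sites[sp] = alternatives[int(rng.integers(3))]
        taken |= set(snp_sites)

    indel_sites: set[tuple[str, int]] = set()
    if config.indel_site_rate > 0:
        mask = rng.random(len(all_positions)) < config.indel_site_rate
        indel_sites = {sp for flag, sp in zip(mask, all_positions) if flag and sp not in taken}

    coding_effects: dict[tuple[str, int], str] = {}
    for gene in genes:
        positions = gene.cds_positions()
        pos_to_offset = {p: i for i, p in enumerate(positions)}
        hit_codons = set()
        for seq_id, pos in error_sites:
            if seq_id == gene.seq_id and pos in pos_to_offset:
                hit_codons.add(pos_to_offset[pos] // 3)
        if not hit_codons:
            continue
        true_cds = _extract_cds(true_genome[gene.seq_id], gene)
        corrupt_cds = _extract_cds(corrupted_genome[gene.seq_id], gene)
        for ci in hit_codons:
            ref_codon = corrupt_cds[ci * 3 : ci * 3 + 3]  # assembly (pre-correction) codon
            alt_codon = true_cds[ci * 3 : ci * 3 + 3]  # codon after correction
            if ref_codon != alt_codon:
                coding_effects[(gene.transcript_id, ci + 1)] = _classify(ci + 1, ref_codon, alt_codon)

    truth = GroundTruth(
        true_genome=true_genome,
        corrupted_genome=corrupted_genome,
        error_sites=error_sites,
        snp_sites=snp_sites,
        indel_sites=indel_sites,
        coding_effects=coding_effects,
        gtf_text=gtf_text,
    )
    return true_genome, gtf_text, truth


def _extract_cds(scaffold: str, gene: _Gene) -> str:
    seq = "".join(scaffold[s - 1 : e] for s, e in gene.exons)
    if gene.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq


def simulate_pileup(
    truth: GroundTruth,
    config: SimulationConfig,
    individual: Literal["same", "independent"] = "same",
    reference: Literal["corrupted", "corrected", "true"] = "corrupted",
) -> list[PileupRecord]:
    """Simulate per-position readcount records at the count level.

    Depth is Poisson(``coverage_mean``); each read reports the individual's
    true base except with probability ``sequencing_error_rate`` it reports
    one of the three other bases uniformly. The ``independent`` individual
    carries the SNPs recorded in the ground truth. ``reference`` selects
    which assembly supplies the ref_base column (the validation workflow
    maps the independent individual to the corrected assembly, which here
    equals the true genome at error sites).
    """
    ref_genome = {
        "corrupted": truth.corrupted_genome,
        "true": truth.true_genome,
        "corrected": truth.true_genome,
    }[reference]
    rng = np.random.default_rng([config.seed, 1 if individual == "same" else 2, {"corrupted": 0, "true": 1, "corrected": 1}[reference]])
    base_index = {b: i for i, b in enumerate("ACGT")}
    records: list[PileupRecord] = []
    error_rate = config.sequencing_error_rate

    for seq_id in sorted(truth.true_genome):
        true_seq = truth.true_genome[seq_id]
        ref_seq = ref_genome[seq_id]
        length = len(true_seq)
        depths = rng.poisson(config.coverage_mean, size=length)
        n_wrong = rng.binomial(depths, error_rate)
        for pos in range(1, length + 1):
            depth = int(depths[pos - 1])
            true_base = true_seq[pos - 1]
            if individual == "independent" and (seq_id, pos) in truth.snp_sites:
                true_base = truth.snp_sites[(seq_id, pos)]
            counts = {b: 0 for b in "ACGTN"}
            wrong = int(n_wrong[pos - 1])
            counts[true_base] = depth - wrong
            if wrong:
                others = [b for b in "ACGT" if b != true_base]
                split = rng.multinomial(wrong, [1 / 3] * 3)
                for b, k in zip(others, split):
                    counts[b] += int(k)
            indel_fraction = 0.0
            if (seq_id, pos) in truth.indel_sites and depth > 0:
                indel_reads = max(1, round(0.25 * depth))
                indel_fraction = indel_reads / (depth + indel_reads)
            records.append(
                PileupRecord(
                    seq_id=seq_id,
                    pos=pos,
                    ref_base=ref_seq[pos - 1],
                    counts=counts,
                    depth=depth,
                    indel_fraction=indel_fraction,
                )
            )
    return records


def _random_tree_newick(rng: np.random.Generator, species: list[str], focal: str, focal_extra: float) -> str:
    """Random rooted binary tree; the focal terminal branch gets ``focal_extra``
    added, which exceeds any other root-to-leaf path when
    ``focal_extra > len(species)`` (all other edges are < 1)."""

    def build(leaves: list[str]) -> str:
        if len(leaves) == 1:
            name = leaves[0]
            length = float(rng.uniform(0.05, 1.0))
            if name == focal:
                length += focal_extra
            return f"{name}:{length:.6f}"
        k = int(rng.integers(1, len(leaves)))
        left, right = leaves[:k], leaves[k:]
        return f"({build(left)},{build(right)}):{float(rng.uniform(0.05, 1.0)):.6f}"

    shuffled = list(species)
    rng.shuffle(shuffled)
    k = int(rng.integers(1, len(shuffled)))
    return f"({build(shuffled[:k])},{build(shuffled[k:])});"


def simulate_signal_fixtures(
    config: SimulationConfig,
    n_alignments: int = 5,
    n_species: int = 6,
    aln_length: int = 200,
    n_planted_subs: int = 10,
    n_gaps: int = 2,
    n_trees: int = 5,
    n_signal_genes: int = 100,
    signal_prob: float = 0.5,
) -> dict:
    """Fabricate fixtures for the evolutionary utilities.

    Returns a dict with:

    - ``alignments``: list of (ProteinAlignment, planted 1-based columns);
      planted unique-substitution columns are kept clear of gap neighborhoods.
    - ``trees``: list of (newick, focal) where the focal terminal branch is
      inflated beyond any other root-to-leaf path, so the focal distance is
      strictly maximal by construction.
    - ``signals``: DataFrame of ``n_signal_genes`` genes with independent
      Bernoulli(``signal_prob``) signals.
    """
    rng = np.random.default_rng([config.seed, 3])
    species = [f"sp{i + 1}" for i in range(n_species - 1)] + ["focal"]

    alignments = []
    for _ in range(n_alignments):
        consensus = [ _AA_ALPHABET[i] for i in rng.integers(0, len(_AA_ALPHABET), size=aln_length) ]
        seqs = {name: list(consensus) for name in species}
        gap_cols = set()
        while len(gap_cols) < n_gaps:
            gap_cols.add(int(rng.integers(0, aln_length)))
        for col in gap_cols:
            victim = species[int(rng.integers(0, n_species - 1))]  # never the focal
            seqs[victim][col] = "-"
        forbidden = set()
        for col in gap_cols:
            forbidden.update(range(col - 5, col + 6))
        candidates = [c for c in range(aln_length) if c not in forbidden]
        rng.shuffle(candidates)
        planted = sorted(candidates[:n_planted_subs])
        for col in planted:
            current = seqs["focal"][col]
            choices = [a for a in _AA_ALPHABET if a != current]
            seqs["focal"][col] = choices[int(rng.integers(len(choices)))]
        aln = ProteinAlignment(sequences={k: "".join(v) for k, v in seqs.items()}, focal="focal")
        alignments.append((aln, [c + 1 for c in planted]))

    trees = [(_random_tree_newick(rng, species, "focal", n_species + 1.0), "focal") for _ in range(n_trees)]

    table = pd.DataFrame({"gene_id": [f"gene{i + 1:05d}" for i in range(n_signal_genes)]})
    for col in SIGNAL_COLUMNS:
        table[col] = rng.random(n_signal_genes) < signal_prob

    return {"alignments": alignments, "trees": trees, "signals": table}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
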