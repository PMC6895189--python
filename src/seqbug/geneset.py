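"""Projection of corrected genomic sites into transcript codon space.

Transcript models are loaded from Ensembl-dialect GTF CDS features
(1-based inclusive coordinates). Corrected sites are mapped to the codon of
every overlapping transcript, multiple sites in one codon are merged, and
each codon change is classified against the standard nuclear genetic code.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from seqbug.correction import CorrectionDecision

EFFECTS = ("synonymous", "nonsynonymous", "stop_gain", "stop_loss", "start_loss")

__all__ = [
    "EFFECTS",
    "TranscriptModel",
    "CodonCorrection",
    "load_gtf",
    "project_corrections",
    "summarize_gene_effects",
    "write_cds_fasta",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass
class TranscriptModel:
    """One transcript's CDS structure.

    ``segments`` are (start, end, frame) tuples with 1-based inclusive
    genomic coordinates, ordered 5'->3' in transcript orientation (i.e.
    descending genomic coordinates on the minus strand). ``frame`` is the
    GTF phase: bases to skip at the segment's 5' end to reach a codon start.
    """

    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    segments: list[tuple[int, int, int]] = field(default_factory=list)
    partial: bool = False

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end, _ in self.segments)

    @property
    def frame_offset(self) -> int:
        """Bases to trim from the transcript 5' end (first segment's phase)."""
        return self.segments[0][2] if self.segments else 0

    def cds_sequence(self, scaffold: str) -> str:
        """Spliced CDS in transcript orientation (no frame trimming)."""
        parts = []
        for start, end, _ in self.segments:
            chunk = scaffold[start - 1 : end].upper()
            if self.strand == "-":
                chunk = chunk.translate(_COMPLEMENT)[::-1]
            parts.append(chunk)
        return "".join(parts)

    def genomic_to_cds(self, pos: int) -> int | None:
        """0-based CDS offset (transcript orientation) for a genomic position."""
        offset = 0
        for start, end, _ in self.segments:
            if start <= pos <= end:
                if self.strand == "+":
                    return offset + (pos - start)
                return offset + (end - pos)
            offset += end - start + 1
        return None


@dataclass(frozen=True)
class CodonCorrection:
    """A corrected codon in one transcript."""

    gene_id: str
    transcript_id: str
    codon_index: int  # 1-based position in the peptide
    ref_codon: str
    corrected_codon: str
    ref_aa: str
    corrected_aa: str
    effect: str
    genomic_sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.ref_codon == self.corrected_codon:
            raise ValueError("ref_codon equals corrected_codon")
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def load_gtf(path: str | Path) -> list[TranscriptModel]:
    """Assemble transcript models from the CDS features of a GTF file.

    Ensembl ``#!`` header lines are ignored. CDS rows lacking a
    transcript_id are skipped with a warning. Transcripts whose GTF phase
    chain is internally inconsistent, or whose trimmed CDS length is not a
    multiple of 3, are flagged ``partial`` and excluded from codon calls.
    """
    raw: dict[str, dict] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "CDS":
                continue
            attrs = _parse_attributes(fields[8])
            tid = attrs.get("transcript_id")
            if not tid:
                warnings.warn(f"{path}:{lineno}: CDS without transcript_id skipped", stacklevel=2)
                continue
            entry = raw.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "seq_id": fields[0],
                    "strand": fields[6],
                    "segments": [],
                },
            )
            frame = int(fields[7]) if fields[7] in {"0", "1", "2"} else 0
            entry["segments"].append((int(fields[3]), int(fields[4]), frame))

    models = []
    for tid, entry in raw.items():
        segments = sorted(entry["segments"], key=lambda s: s[0], reverse=(entry["strand"] == "-"))
        model = TranscriptModel(
            gene_id=entry["gene_id"],
            transcript_id=tid,
            seq_id=entry["seq_id"],
            strand=entry["strand"],
            segments=segments,
        )
        model.partial = not _frames_consistent(segments) or (model.cds_length - model.frame_offset) % 3 != 0
        models.append(model)
    models.sort(key=lambda m: (m.seq_id, m.segments[0][0] if m.segments else 0, m.transcript_id))
    return models


def _frames_consistent(segments: Sequence[tuple[int, int, int]]) -> bool:
    expected = segments[0][2] if segments else 0
    for start, end, frame in segments:
        if frame != expected:
            return False
        seg_len = end - start + 1
        expected = (3 - (seg_len - frame) % 3) % 3
    return True


def _classify_effect(codon_index: int, ref_codon: str, corrected_codon: str, ref_aa: str, corrected_aa: str) -> str:
    if codon_index == 1 and ref_codon in standard_dna_table.start_codons and ref_aa == "M" and corrected_aa != "M":
        return "start_loss"
    if ref_aa != "*" and corrected_aa == "*":
        return "stop_gain"
    if ref_aa == "*" and corrected_aa != "*":
        return "stop_loss"
    return "synonymous" if ref_aa == corrected_aa else "nonsynonymous"


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


def project_corrections(
    models: Iterable[TranscriptModel],
    decisions: Iterable[CorrectionDecision],
    sequences: Mapping[str, str],
) -> tuple[list[CodonCorrection], dict[str, str], list[tuple[str, int]]]:
    """Map corrected genomic sites into codons and rebuild corrected CDS.

    ``sequences`` must be the ORIGINAL (pre-correction) assembly so that
    reference codons are reconstructable. Returns the codon corrections, the
    full corrected CDS set keyed by transcript_id (every non-partial
    transcript, corrected or not), and a list of (transcript_id, pos) pairs
    that could not be projected because the transcript is flagged partial.
    """
    models = list(models)
    corrected = [d for d in decisions if d.status == "corrected"]
    by_seq: dict[str, list[CorrectionDecision]] = defaultdict(list)
    for dec in corrected:
        by_seq[dec.seq_id].append(dec)

    codon_corrections: list[CodonCorrection] = []
    corrected_cds: dict[str, str] = {}
    unprojectable: list[tuple[str, int]] = []

    for model in models:
        scaffold = sequences.get(model.seq_id)
        if scaffold is None:
            continue
        hits = [d for d in by_seq.get(model.seq_id, []) if model.genomic_to_cds(d.pos) is not None]
        if model.partial:
            unprojectable.extend((model.transcript_id, d.pos) for d in hits)
            continue

        cds = model.cds_sequence(scaffold)
        trimmed_start = model.frame_offset
        coding = list(cds[trimmed_start:])

        # group contributing sites per codon
        per_codon: dict[int, list[tuple[int, CorrectionDecision]]] = defaultdict(list)
        for dec in hits:
            cds_off = model.genomic_to_cds(dec.pos)
            coding_off = cds_off - trimmed_start
            if coding_off < 0:
                unprojectable.append((model.transcript_id, dec.pos))
                continue
            per_codon[coding_off // 3].append((coding_off, dec))

        for codon_i, sites in sorted(per_codon.items()):
            ref_codon = "".join(coding[codon_i * 3 : codon_i * 3 + 3])
            new = list(ref_codon)
            genomic_sites = []
            for coding_off, dec in sorted(sites):
                base = dec.max_base
                if model.strand == "-":
                    base = base.translate(_COMPLEMENT)
                new[coding_off - codon_i * 3] = base
                coding[coding_off] = base
                genomic_sites.append(dec.pos)
            corrected_codon = "".join(new)
            if corrected_codon == ref_codon:
                continue
            ref_aa = _translate_codon(ref_codon)
            corrected_aa = _translate_codon(corrected_codon)
            codon_corrections.append(
                CodonCorrection(
                    gene_id=model.gene_id,
                    transcript_id=model.transcript_id,
                    codon_index=codon_i + 1,
                    ref_codon=ref_codon,
                    corrected_codon=corrected_codon,
                    ref_aa=ref_aa,
                    corrected_aa=corrected_aa,
                    effect=_classify_effect(codon_i + 1, ref_codon, corrected_codon, ref_aa, corrected_aa),
                    genomic_sites=tuple(genomic_sites),
                )
            )

        corrected_cds[model.transcript_id] = cds[:trimmed_start] + "".join(coding)

    return codon_corrections, corrected_cds, unprojectable


def summarize_gene_effects(codon_corrections: Iterable[CodonCorrection]) -> pd.DataFrame:
    """Per-gene summary of corrected codons.

    Stop gains/losses and start losses count as non-synonymous changes at
    the gene level. A gene can have both synonymous and non-synonymous
    corrections; ``n_codons_corrected`` counts distinct (transcript,
    codon_index) pairs for the gene.
    """
    rows: dict[str, dict] = {}
    for cc in codon_corrections:
        row = rows.setdefault(
            cc.gene_id,
            {"gene_id": cc.gene_id, "codons": set(), "has_synonymous": False, "has_nonsynonymous": False},
        )
        row["codons"].add((cc.transcript_id, cc.codon_index))
        if cc.effect == "synonymous":
            row["has_synonymous"] = True
        else:
            row["has_nonsynonymous"] = True
    if not rows:
        return pd.DataFrame(columns=["gene_id", "n_codons_corrected", "has_synonymous", "has_nonsynonymous"])
    df = pd.DataFrame(
        [
            {
                "gene_id": r["gene_id"],
                "n_codons_corrected": len(r["codons"]),
                "has_synonymous": r["has_synonymous"],
                "has_nonsynonymous": r["has_nonsynonymous"],
            }
            for r in rows.values()
        ]
    ).sort_values("gene_id", ignore_index=True)
    return df


def write_cds_fasta(cds: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for tid in sorted(cds):
            fh.write(f">{tid}\n")
            seq = cds[tid]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
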