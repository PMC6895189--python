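"""Eligibility filters and the one-fifth replacement rule.

A position is eligible when its depth lies in ``[min_cov, max_cov]`` and its
indel fraction is at most ``max_indel_fraction``. Among eligible positions
the assembly base is replaced by the most frequent read base when the
assembly base's count is at most ``max_count / ratio_denominator``
(inclusive; compared as ``ref_count * ratio_denominator <= max_count`` to
avoid float boundary artifacts).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from seqbug.pileup_io import PileupRecord

REPLACEMENT_BASES = ("A", "C", "G", "T")  # N is never a replacement allele

STATUSES = (
    "corrected",
    "kept",
    "ineligible_low_cov",
    "ineligible_high_cov",
    "ineligible_indel",
    "ineligible_ref_N",
    "ambiguous_tie",
)

__all__ = [
    "STATUSES",
    "CorrectionParams",
    "CorrectionDecision",
    "classify_position",
    "classify_pileup",
    "correct_assembly",
    "write_correction_ledger",
    "read_correction_ledger",
]


@dataclass(frozen=True)
class CorrectionParams:
    """Thresholds governing eligibility and replacement."""

    min_cov: int = 10
    max_cov: int = 200
    max_indel_fraction: float = 0.10
    ratio_denominator: int = 5
    correct_N_reference: bool = False

    def __post_init__(self) -> None:
        if self.min_cov < 1:
            raise ValueError(f"min_cov must be >= 1, got {self.min_cov}")
        if self.max_cov <= self.min_cov:
            raise ValueError(f"max_cov must exceed min_cov, got {self.max_cov} <= {self.min_cov}")
        if not 0.0 < self.max_indel_fraction < 1.0:
            raise ValueError(f"max_indel_fraction must be in (0,1), got {self.max_indel_fraction}")
        if self.ratio_denominator < 1:
            raise ValueError(f"ratio_denominator must be >= 1, got {self.ratio_denominator}")


@dataclass(frozen=True)
class CorrectionDecision:
    """Verdict for one assembly position."""

    seq_id: str
    pos: int
    ref_base: str
    max_base: str | None
    ref_count: int
    max_count: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def classify_position(record: PileupRecord, params: CorrectionParams | None = None) -> CorrectionDecision:
    """Classify one position. Total function: never raises on valid records.

    Filter order: low coverage, high coverage, indel fraction, reference N.
    An eligible position is ``corrected`` when the most frequent base differs
    from the assembly base and the assembly base's count is at most one
    ``ratio_denominator``-th of the top count. If two non-reference bases tie
    for the top count and the rule would fire, the position is
    ``ambiguous_tie`` and left untouched.
    """
    if params is None:
        params = CorrectionParams()

    ref_base = record.ref_base
    ref_count = record.counts.get(ref_base, 0)

    def decision(status: str, max_base: str | None = None, max_count: int = 0) -> CorrectionDecision:
        return CorrectionDecision(
            seq_id=record.seq_id,
            pos=record.pos,
            ref_base=ref_base,
            max_base=max_base,
            ref_count=ref_count,
            max_count=max_count,
            status=status,
        )

    if record.depth < params.min_cov:
        return decision("ineligible_low_cov")
    if record.depth > params.max_cov:
        return decision("ineligible_high_cov")
    if record.indel_fraction > params.max_indel_fraction:
        return decision("ineligible_indel")
    if ref_base == "N" and not params.correct_N_reference:
        return decision("ineligible_ref_N")

    max_count = max(record.counts.get(b, 0) for b in REPLACEMENT_BASES)
    top_bases = [b for b in REPLACEMENT_BASES if record.counts.get(b, 0) == max_count]

    if ref_base in top_bases:
        return decision("kept", max_base=ref_base, max_count=max_count)

    fires = ref_count * params.ratio_denominator <= max_count
    if not fires:
        return decision("kept", max_base=top_bases[0] if len(top_bases) == 1 else None, max_count=max_count)
    if len(top_bases) > 1:
        return decision("ambiguous_tie", max_base=None, max_count=max_count)
    return decision("corrected", max_base=top_bases[0], max_count=max_count)


def classify_pileup(
    records: Iterable[PileupRecord], params: CorrectionParams | None = None
) -> Iterator[CorrectionDecision]:
    """Classify every record in a pileup stream."""
    params = params or CorrectionParams()
    for record in records:
        yield classify_position(record, params)


def correct_assembly(
    sequences: Mapping[str, str],
    decisions: Iterable[CorrectionDecision],
    strict_positions: bool = True,
) -> tuple[dict[str, str], dict]:
    """Apply corrected decisions to assembly sequences.

    ``sequences`` maps scaffold id to sequence string. Soft-masked
    (lowercase) bases stay lowercase after replacement; all other positions
    are untouched. The assembly base at each corrected site must equal the
    decision's ``ref_base`` case-insensitively, otherwise a ``ValueError``
    names the offending site (guards against assembly/pileup version skew).

    Returns the corrected sequences and a summary report with per-status and
    per-scaffold counts plus genome-size denominators with and without Ns.
    """
    mutable = {name: bytearray(seq, "ascii") for name, seq in sequences.items()}
    status_counts: Counter[str] = Counter()
    per_scaffold: dict[str, Counter[str]] = {}
    n_applied = 0
    for dec in decisions:
        status_counts[dec.status] += 1
        per_scaffold.setdefault(dec.seq_id, Counter())[dec.status] += 1
        if dec.status != "corrected":
            continue
        if dec.seq_id not in mutable:
            if strict_positions:
                raise ValueError(f"corrected site {dec.seq_id}:{dec.pos}: scaffold not in assembly")
            continue
        seq = mutable[dec.seq_id]
        if not 1 <= dec.pos <= len(seq):
            raise ValueError(f"corrected site {dec.seq_id}:{dec.pos} outside scaffold of length {len(seq)}")
        current = chr(seq[dec.pos - 1])
        if current.upper() != dec.ref_base:
            raise ValueError(
                f"corrected site {dec.seq_id}:{dec.pos}: assembly has {current!r}, "
                f"ledger expects ref_base {dec.ref_base!r}"
            )
        replacement = dec.max_base.lower() if current.islower() else dec.max_base
        seq[dec.pos - 1] = ord(replacement)
        n_applied += 1

    total_bases = sum(len(s) for s in sequences.values())
    n_bases = sum(s.upper().count("N") for s in sequences.values())
    report = {
        "total_positions": sum(status_counts.values()),
        "eligible": sum(
            status_counts[s] for s in ("corrected", "kept", "ambiguous_tie")
        ),
        "corrected": status_counts["corrected"],
        "applied": n_applied,
        "status_counts": dict(status_counts),
        "per_scaffold": {k: dict(v) for k, v in per_scaffold.items()},
        "genome_size": total_bases,
        "genome_size_without_N": total_bases - n_bases,
        "corrected_fraction": (status_counts["corrected"] / total_bases) if total_bases else 0.0,
        "corrected_fraction_without_N": (
            status_counts["corrected"] / (total_bases - n_bases) if total_bases > n_bases else 0.0
        ),
    }
    return {name: seq.decode("ascii") for name, seq in mutable.items()}, report


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=seqbug
##INFO=<ID=RC,Number=1,Type=Integer,Description="Read count supporting the assembly (reference) base">
##INFO=<ID=MC,Number=1,Type=Integer,Description="Read count supporting the most frequent base">
##INFO=<ID=ST,Number=1,Type=String,Description="Correction status">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_correction_ledger(
    decisions: Iterable[CorrectionDecision],
    vcf_path: str | Path,
    tsv_path: str | Path | None = None,
    emit_all: bool = False,
) -> dict:
    """Write the correction ledger.

    The VCF carries one record per ``corrected`` site (REF = assembly base,
    ALT = max_base). The TSV mirrors corrected sites by default and every
    status when ``emit_all`` is set. Returns per-status counts.
    """
    counts: Counter[str] = Counter()
    tsv_fh = open(tsv_path, "wt") if tsv_path is not None else None
    try:
        if tsv_fh:
            tsv_fh.write("seq_id\tpos\tref_base\tmax_base\tref_count\tmax_count\tstatus\n")
        with open(vcf_path, "wt") as vcf:
            vcf.write(_VCF_HEADER)
            for dec in decisions:
                counts[dec.status] += 1
                if dec.status == "corrected":
                    vcf.write(
                        f"{dec.seq_id}\t{dec.pos}\t.\t{dec.ref_base}\t{dec.max_base}\t.\tPASS\t"
                        f"RC={dec.ref_count};MC={dec.max_count};ST={dec.status}\n"
                    )
                if tsv_fh and (emit_all or dec.status == "corrected"):
                    tsv_fh.write(
                        f"{dec.seq_id}\t{dec.pos}\t{dec.ref_base}\t{dec.max_base or '.'}\t"
                        f"{dec.ref_count}\t{dec.max_count}\t{dec.status}\n"
                    )
    finally:
        if tsv_fh:
            tsv_fh.close()
    return dict(counts)


def read_correction_ledger(vcf_path: str | Path) -> list[CorrectionDecision]:
    """Re-read a VCF ledger written by :func:`write_correction_ledger`."""
    decisions: list[CorrectionDecision] = []
    with open(vcf_path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _, ref, alt = fields[:5]
            info = dict(kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv)
            decisions.append(
                CorrectionDecision(
                    seq_id=chrom,
                    pos=int(pos),
                    ref_base=ref,
                    max_base=alt,
                    ref_count=int(info.get("RC", 0)),
                    max_count=int(info.get("MC", 0)),
                    status=info.get("ST", "corrected"),
                )
            )
    return decisions


def write_summary_json(report: dict, path: str | Path) -> None:
    with open(path, "wt") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
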