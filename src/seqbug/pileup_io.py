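"""Reading and writing per-base alignment metrics (bam-readcount TSV dialect).

Each row describes one assembly position: scaffold, 1-based position,
reference base, total depth, followed by per-allele blocks whose
colon-delimited fields start with ``base:count``. Indel alleles (leading
``+``/``-``) are collapsed into a single per-position indel fraction; any
other non-ACGTN allele symbol is folded into ``N``.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import gzip
import io
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

BASES = ("A", "C", "G", "T", "N")

__all__ = [
    "BASES",
    "PileupRecord",
    "PileupParseError",
    "read_pileup",
    "write_pileup",
    "coverage_histogram",
]


class PileupParseError(ValueError):
    """A malformed row in a readcount TSV; message names the line number."""


@dataclass(frozen=True)
class PileupRecord:
    """Per-position allele counts at one assembly coordinate.

    Attributes
    ----------
    seq_id : str
        Assembly scaffold identifier.
    pos : int
        1-based genomic coordinate.
    ref_base : str
        Assembly base at this position, one of ``A C G T N``.
    counts : dict
        Read count per base (quality filters assumed applied upstream).
        ``depth`` always equals the sum of these counts.
    depth : int
        Total base-supporting read depth.
    indel_fraction : float
        Fraction in [0, 1] of reads supporting an insertion/deletion.
    """

    seq_id: str
    pos: int
    ref_base: str
    counts: dict[str, int] = field(default_factory=dict)
    depth: int = 0
    indel_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError(f"indel_fraction out of [0,1]: {self.indel_fraction}")
        total = sum(self.counts.values())
        if self.depth != total:
            raise ValueError(f"depth {self.depth} != sum of counts {total}")

    @property
    def ref_count(self) -> int:
        return self.counts.get(self.ref_base, 0)


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _parse_allele_block(block: str) -> tuple[str, int]:
    fields = block.split(":")
    if len(fields) < 2:
        raise ValueError(f"allele block {block!r} lacks base:count fields")
    return fields[0], int(fields[1])


def _parse_row(line: str, lineno: int) -> PileupRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) == 1:  # tolerate space-separated toy rows
        fields = line.split()
    if len(fields) < 4:
        raise PileupParseError(f"line {lineno}: expected >=4 tab-separated fields, got {len(fields)}")
    seq_id = fields[0]
    try:
        pos = int(fields[1])
        reported_depth = int(fields[3])
    except ValueError as exc:
        raise PileupParseError(f"line {lineno}: {exc}") from None
    ref_base = fields[2].upper()
    if ref_base not in BASES:
        ref_base = "N"

    counts: Counter[str] = Counter({b: 0 for b in BASES})
    indel_reads = 0
    for block in fields[4:]:
        if not block:
            continue
        try:
            allele, count = _parse_allele_block(block)
        except ValueError as exc:
            raise PileupParseError(f"line {lineno}: {exc}") from None
        allele = allele.upper()
        if allele == "=":  # bam-readcount placeholder allele
            continue
        if allele.startswith("+") or allele.startswith("-"):
            indel_reads += count
        elif allele in BASES:
            counts[allele] += count
        else:
            counts["N"] += count

    base_total = sum(counts.values())
    total_reads = base_total + indel_reads
    if reported_depth != total_reads:
        warnings.warn(
            f"line {lineno}: reported depth {reported_depth} != observed reads {total_reads}; "
            "record kept with recomputed depth",
            stacklevel=3,
        )
        reported_depth = total_reads
    indel_fraction = indel_reads / reported_depth if reported_depth > 0 else 0.0
    return PileupRecord(
        seq_id=seq_id,
        pos=pos,
        ref_base=ref_base,
        counts=dict(counts),
        depth=base_total,
        indel_fraction=indel_fraction,
    )


def read_pileup(path: str | Path, region: str | None = None) -> Iterator[PileupRecord]:
    """Stream :class:`PileupRecord` objects from a readcount TSV.

    Parameters
    ----------
    path : path
        Plain or gzip-compressed TSV (compression detected from magic bytes).
    region : str, optional
        If given, only records on this scaffold are yielded.

    Yields records in file order; rows out of ascending position order within
    a scaffold raise :class:`PileupParseError`.
    """
    last: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            record = _parse_row(line, lineno)
            if region is not None and record.seq_id != region:
                continue
            prev = last.get(record.seq_id)
            if prev is not None and record.pos <= prev:
                raise PileupParseError(
                    f"line {lineno}: position {record.pos} on {record.seq_id} not ascending (previous {prev})"
                )
            last[record.seq_id] = record.pos
            yield record


def write_pileup(records: Iterable[PileupRecord], path: str | Path) -> None:
    """Write records back to the readcount TSV dialect.

    The indel fraction is re-expanded into a single ``-N:k`` allele block so
    that a subsequent :func:`read_pileup` reproduces every field.
    """
    with open(path, "wt") as fh:
        for rec in records:
            if rec.indel_fraction >= 1.0:
                indel_reads = 1  # depth 0, all-indel position
            elif rec.indel_fraction > 0:
                # k / (depth + k) == indel_fraction  =>  k = f/(1-f) * depth
                indel_reads = round(rec.indel_fraction / (1.0 - rec.indel_fraction) * rec.depth)
            else:
                indel_reads = 0
            total = rec.depth + indel_reads
            blocks = [f"{b}:{rec.counts.get(b, 0)}" for b in BASES]
            if indel_reads:
                blocks.append(f"-N:{indel_reads}")
            fh.write(f"{rec.seq_id}\t{rec.pos}\t{rec.ref_base}\t{total}\t" + "\t".join(blocks) + "\n")


def coverage_histogram(records: Iterable[PileupRecord], bin_width: int = 10) -> dict[int, int]:
    """Histogram of per-position depth.

    Returns a mapping from bin lower bound (inclusive; bin covers
    ``[lo, lo + bin_width)``) to the number of positions falling in it.
    Every input position is counted exactly once.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    hist: Counter[int] = Counter()
    for rec in records:
        hist[(rec.depth // bin_width) * bin_width] += 1
    return dict(sorted(hist.items()))
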