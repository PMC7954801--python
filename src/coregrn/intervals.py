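"""Genomic-interval data model and BED/TSV I/O.

All coordinates are 0-based, half-open (BED convention). Chromosome names
are compared verbatim: ``chr1`` and ``1`` are different sequences unless the
caller harmonizes them first (see :func:`harmonize_chrom_prefix`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "IntervalParseError",
    "read_intervals",
    "write_intervals",
    "overlap_length",
    "truncate_to_peak",
    "reciprocal_overlap",
    "harmonize_chrom_prefix",
]

STRANDS = ("+", "-", ".")


class IntervalParseError(ValueError):
    """Malformed interval record; carries the offending line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class PeakSet:
    """A named collection of intervals from one assay.

    ``assay`` is one of ``H3K4me3``, ``H3K27ac``, ``DNase``,
    ``TF-binding:<tf>`` or ``other``; it is fixed at construction.
    """

    assay: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    @property
    def tf(self) -> str | None:
        """TF name for ``TF-binding:<tf>`` peak sets, else None."""
        if self.assay.startswith("TF-binding:"):
            return self.assay.split(":", 1)[1]
        return None


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared bases between two intervals (0 if disjoint).

    Half-open adjacency ([100,200) vs [200,300)) does not overlap; a single
    shared base counts.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def truncate_to_peak(region: GenomicInterval, peak: GenomicInterval) -> GenomicInterval:
    """Intersection of ``region`` with ``peak``; requires >= 1 bp overlap."""
    if overlap_length(region, peak) < 1:
        raise ValueError(f"{region} and {peak} do not overlap; cannot truncate")
    return replace(
        region, start=max(region.start, peak.start), end=min(region.end, peak.end)
    )


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/|a|, overlap/|b|): the symmetric overlap fraction in [0,1]."""
    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))


def harmonize_chrom_prefix(peaks: PeakSet, prefix: str = "chr") -> PeakSet:
    """Return a copy in which every chromosome name carries ``prefix``."""
    fixed = [
        iv if iv.chrom.startswith(prefix) else replace(iv, chrom=prefix + iv.chrom)
        for iv in peaks.intervals
    ]
    return PeakSet(assay=peaks.assay, intervals=fixed, source=peaks.source)


def _parse_line(line: str, lineno: int, dialect: str) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    min_cols = 3 if dialect in ("bed3", "tsv") else 6
    if len(fields) < min_cols:
        raise IntervalParseError(
            f"line {lineno}: expected >= {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise IntervalParseError(f"line {lineno}: non-integer coordinates") from exc
    strand = "."
    if dialect == "bed6" or (len(fields) >= 6 and fields[5] in ("+", "-")):
        strand = fields[5] if fields[5] in ("+", "-") else "."
    try:
        return GenomicInterval(chrom=chrom, start=start, end=end, strand=strand)
    except ValueError as exc:
        raise IntervalParseError(f"line {lineno}: {exc}") from exc


def read_intervals(
    path: str | Path,
    dialect: str = "bed3",
    assay: str = "other",
    skip_header: bool = False,
) -> PeakSet:
    """Read a BED3/BED6/TSV interval file into a :class:`PeakSet`.

    Input order is preserved. Lines starting with ``#`` or ``track`` are
    skipped; malformed records raise :class:`IntervalParseError` naming the
    1-based line number.
    """
    if dialect not in ("bed3", "bed6", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            intervals.append(_parse_line(line, lineno, dialect))
    return PeakSet(assay=assay, intervals=intervals, source=str(path))


def write_intervals(
    peaks: PeakSet, path: str | Path, sort: bool = False
) -> Path:
    """Write a PeakSet as BED (chrom, start, end, name, score, strand).

    With ``sort=True`` output is ordered lexicographically by chromosome then
    by start. ``read_intervals(write_intervals(x))`` reproduces coordinates,
    chromosome names and strands.
    """
    path = Path(path)
    ivs: Iterable[GenomicInterval] = peaks.intervals
    if sort:
        ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with path.open("w", encoding="utf-8") as fh:
        for i, iv in enumerate(ivs):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peaks.assay}_{i}\t0\t{iv.strand}\n"
            )
    return path
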