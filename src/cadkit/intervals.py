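"""Genomic interval data model and algebra.

Peaks, gene models and the operations every downstream stage leans on:
BED / ENCODE narrowPeak I/O, interval-union merging, pairwise overlap
(intersection) and nearest-TSS lookup.  Coordinates are 0-based
half-open (the BED convention) throughout; 1-based coordinates appear
only in human-readable locus strings.

Overlap means "shares at least one base" unless a caller raises
``min_overlap_bp``; strand is ignored for peak overlap and used only to
derive a gene's transcription start site.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised for malformed BED/narrowPeak input; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` with an identifier.

    ``summit`` is the narrowPeak point-source offset relative to
    ``start`` (``None`` when absent or ``-1`` on disk).
    """

    chrom: str
    start: int
    end: int
    id: str
    strand: str = "."
    score: float = 0.0
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, ``floor((start + end) / 2)``."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        shared = min(self.end, other.end) - max(self.start, other.start)
        return shared >= min_bp

    def locus(self) -> str:
        """1-based inclusive human-readable locus, e.g. ``chr1:101-200``."""
        return f"{self.chrom}:{self.start + 1:,}-{self.end:,}"


@dataclass(frozen=True)
class GeneModel:
    """A gene as a stranded span; the TSS is the 5' end on the gene's strand."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class PeakSet:
    """An ordered, duplicate-free collection of :class:`GenomicInterval`.

    Always sorted by ``(chrom, start, end)`` after construction; interval
    ids must be unique.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        seen_ids: set[str] = set()
        seen_keys: set[tuple] = set()
        for iv in ivs:
            if iv.id in seen_ids:
                raise ValueError(f"duplicate interval id {iv.id!r}")
            key = (iv.chrom, iv.start, iv.end, iv.id)
            if key in seen_keys:
                raise ValueError(f"duplicate interval {key}")
            seen_ids.add(iv.id)
            seen_keys.add(key)
        self._intervals: list[GenomicInterval] = ivs
        self._by_id: dict[str, GenomicInterval] = {iv.id: iv for iv in ivs}

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self._intervals == other._intervals

    def by_id(self, id: str) -> GenomicInterval:
        return self._by_id[id]

    @property
    def ids(self) -> list[str]:
        return [iv.id for iv in self._intervals]

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for iv in self._intervals:
            if not out or out[-1] != iv.chrom:
                out.append(iv.chrom)
        return out

    def lengths(self) -> dict[str, int]:
        """Interval length in bp keyed by id."""
        return {iv.id: len(iv) for iv in self._intervals}

    def subset(self, ids: Iterable[str]) -> "PeakSet":
        wanted = set(ids)
        missing = wanted - self._by_id.keys()
        if missing:
            raise KeyError(f"unknown peak ids: {sorted(missing)[:5]}")
        return PeakSet(iv for iv in self._intervals if iv.id in wanted)

    def total_bases(self) -> int:
        """Covered bases counting overlaps once (computed via merge)."""
        return sum(len(iv) for iv in merge_intervals(self))

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self._intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand}\n"
                )

    def write_narrowpeak(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self._intervals:
                summit = -1 if iv.summit is None else iv.summit
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t"
                    f"{_fmt_score(iv.score)}\t{iv.strand}\t0\t-1\t-1\t{summit}\n"
                )


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


def read_peaks(path: str | Path, format: str = "bed") -> PeakSet:
    """Read a BED3/BED6 or ENCODE narrowPeak file into a :class:`PeakSet`.

    Ids are taken from column 4 when present, otherwise auto-generated as
    ``peak_000001``... in file order.  Malformed lines (non-integer or
    inverted coordinates, too few columns) raise :class:`BedParseError`
    naming the offending line.
    """
    if format not in {"bed", "narrowPeak"}:
        raise ValueError(f"unsupported format {format!r}")
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if format == "narrowPeak" and len(fields) != 10:
                raise BedParseError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, "
                    f"got {len(fields)}"
                )
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: need >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if not (0 <= start < end):
                raise BedParseError(
                    f"{path}:{lineno}: invalid interval start={start} end={end}"
                )
            name = (
                fields[3]
                if len(fields) > 3 and fields[3] not in {"", "."}
                else f"peak_{len(intervals) + 1:06d}"
            )
            score = 0.0
            if len(fields) > 4 and fields[4] not in {"", "."}:
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in _VALID_STRANDS else "."
            summit: int | None = None
            if format == "narrowPeak":
                s = int(fields[9])
                summit = None if s < 0 else s
            intervals.append(
                GenomicInterval(chrom, start, end, name, strand, score, summit)
            )
    return PeakSet(intervals)


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (span per gene) or a 4-column TSV
    ``chrom  tss  strand  gene_id`` (a 1 bp span anchored at the TSS)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 6:
                    genes.append(
                        GeneModel(f[0], int(f[1]), int(f[2]), f[5], f[3])
                    )
                elif len(f) == 4:
                    tss, strand = int(f[1]), f[2]
                    start = tss if strand == "+" else tss
                    genes.append(GeneModel(f[0], start, start + 1, strand, f[3]))
                else:
                    raise ValueError("need BED6 or 4-column TSV")
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def merge_intervals(ps: PeakSet, min_overlap_bp: int = 1) -> PeakSet:
    """Fuse intervals overlapping by at least ``min_overlap_bp`` bases.

    With the default of 1 bp, book-ended half-open intervals (sharing no
    base) stay separate; ``min_overlap_bp=0`` also fuses book-ended
    intervals.  The result is a minimal disjoint set covering the same
    bases, with fresh ids ``merged_000001``..., and the operation is
    idempotent.
    """
    merged: list[GenomicInterval] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0

    def _flush() -> None:
        if cur_chrom is not None:
            merged.append(
                GenomicInterval(
                    cur_chrom, cur_start, cur_end, f"merged_{len(merged) + 1:06d}"
                )
            )

    for iv in ps:
        if iv.chrom != cur_chrom:
            _flush()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
            continue
        # sorted order guarantees iv.start >= cur_start
        if cur_end - iv.start >= min_overlap_bp:
            cur_end = max(cur_end, iv.end)
        else:
            _flush()
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    _flush()
    return PeakSet(merged)


def _group_by_chrom(ps: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in ps:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def intersect(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> dict[str, list[str]]:
    """Map every a-interval id to the ids of b-intervals it overlaps.

    The bipartite overlap graph is symmetric: ``intersect(b, a)``
    describes the same edges from the other side.
    """
    b_by_chrom = _group_by_chrom(b)
    result: dict[str, list[str]] = {}
    for iv in a:
        hits: list[str] = []
        cands = b_by_chrom.get(iv.chrom, ())
        if cands:
            starts = [c.start for c in cands]
            # candidates can start anywhere before iv.end; scan from the
            # first whose start could still overlap is not bounded below
            # without max-end bookkeeping, so scan up to bisect on start.
            hi = bisect_left(starts, iv.end)
            for c in cands[:hi]:
                if min(iv.end, c.end) - max(iv.start, c.start) >= min_overlap_bp:
                    hits.append(c.id)
        result[iv.id] = hits
    return result


def nearest_feature(
    ps: PeakSet, genes: Sequence[GeneModel]
) -> dict[str, tuple[str, int] | None]:
    """Nearest-TSS annotation for every peak.

    Distance is 0 when the TSS falls inside the peak; otherwise the bp
    gap from the peak edge to the TSS, signed on the + genome axis
    (negative when the TSS lies left of the peak).  Ties are broken by
    lexicographically smallest gene_id.  Peaks on chromosomes with no
    genes map to ``None`` with a logged warning.
    """
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    for lst in tss_by_chrom.values():
        lst.sort()

    result: dict[str, tuple[str, int] | None] = {}
    orphans = 0
    for iv in ps:
        lst = tss_by_chrom.get(iv.chrom)
        if not lst:
            result[iv.id] = None
            orphans += 1
            continue
        positions = [t for t, _ in lst]
        lo = bisect_left(positions, iv.start)
        hi = bisect_right(positions, iv.end - 1)
        best: tuple[int, str] | None = None  # (|distance|, gene_id) for ranking
        best_signed = 0
        # any TSS inside [start, end) has distance 0
        candidates = range(max(0, lo - 1), min(len(lst), hi + 1))
        for j in candidates:
            tss, gid = lst[j]
            if iv.start <= tss < iv.end:
                signed = 0
            elif tss < iv.start:
                signed = tss - iv.start
            else:
                signed = tss - (iv.end - 1) - 1  # gap past the last covered base
            key = (abs(signed), gid)
            if best is None or key < best:
                best, best_signed = key, signed
        assert best is not None
        result[iv.id] = (best[1], best_signed)
    if orphans:
        logger.warning("%d peak(s) on chromosomes with no genes left unassigned", orphans)
    return result
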