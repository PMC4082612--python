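"""ChIP-Seq peak records: parsing, normalization and replicate pooling.

Peaks arrive in BED6, ENCODE narrowPeak (10 columns, with a summit offset
in the last column) or ENCODE broadPeak (9 columns, no summit).  For
topological analysis every peak is trimmed or extended to a constant odd
length centered on the read-frequency maximum (the summit, "peakMax"), or
on the peak's midpoint when no summit was reported.  Coordinates are
0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "PeakSet",
    "PooledRegion",
    "ReplicatePooling",
    "read_peaks",
    "write_peaks_bed6",
    "normalize_peaks",
    "extract_sequences",
    "pool_replicates",
]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    peak_max: int | None = None  # absolute summit coordinate
    score: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.id!r}: start {self.start} >= end {self.end}")
        if self.peak_max is not None and not (self.start <= self.peak_max < self.end):
            raise ValueError(
                f"peak {self.id!r}: peak_max {self.peak_max} outside [{self.start}, {self.end})"
            )

    @property
    def center(self) -> int:
        """The summit when present, else the midpoint (floor)."""
        return self.peak_max if self.peak_max is not None else (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    peaks: list[Peak]
    length: int | None = None  # common length after normalization
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate peak ids")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


_FORMAT_COLUMNS = {"bed6": (3, 6), "narrowPeak": (10, 10), "broadPeak": (9, 9)}


def read_peaks(path, format: str = "narrowPeak") -> PeakSet:
    """Read a peak file in the named dialect.

    A narrowPeak summit column of -1 means "no summit reported".  Input
    order and any name column are preserved; peaks without a name get
    ``peak_<line>``.
    """
    if format not in _FORMAT_COLUMNS:
        raise ValueError(f"unknown peak format {format!r}; expected one of {sorted(_FORMAT_COLUMNS)}")
    min_cols, _ = _FORMAT_COLUMNS[format]
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {min_cols} columns for {format}, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else f"peak_{lineno}"
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                peak_max = None
                if format == "narrowPeak":
                    summit = int(fields[9])
                    if summit >= 0:
                        peak_max = start + summit
                peak = Peak(chrom, start, end, peak_max, score, name)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            peaks.append(peak)
    return PeakSet(peaks, provenance={"path": str(path), "format": format})


def write_peaks_bed6(peak_set: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peak_set:
            score = 0 if p.score is None else p.score
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.id}\t{score:g}\t.\n")


def normalize_peaks(
    peak_set: PeakSet, length: int, chrom_sizes: dict[str, int] | None = None
) -> PeakSet:
    """Trim or extend every peak to a constant odd ``length`` around its center.

    The center base (the summit, or the midpoint when no summit exists)
    lands at index ``(length - 1) // 2`` of the output interval, i.e. the
    interval is ``[c - (L-1)/2, c + (L-1)/2 + 1)``.  Peaks that would
    extend past known chromosome bounds are skipped (not clipped) so all
    output peaks have identical length; the skip count is logged and
    recorded in provenance.
    """
    if length <= 0 or length % 2 == 0:
        raise ValueError(f"normalized length must be odd and positive, got {length}")
    half = (length - 1) // 2
    out, skipped = [], 0
    for p in peak_set:
        c = p.center
        start, end = c - half, c + half + 1
        if start < 0 or (
            chrom_sizes is not None and p.chrom in chrom_sizes and end > chrom_sizes[p.chrom]
        ):
            skipped += 1
            logger.warning("peak %s: normalized interval [%d, %d) out of bounds; skipped", p.id, start, end)
            continue
        out.append(replace(p, start=start, end=end, peak_max=c))
    if skipped:
        logger.warning("normalize_peaks: skipped %d/%d out-of-bounds peaks", skipped, len(peak_set))
    prov = dict(peak_set.provenance)
    prov.update({"normalized_length": length, "skipped_out_of_bounds": skipped})
    return PeakSet(out, length=length, provenance=prov)


def extract_sequences(peak_set: PeakSet, genome) -> dict[str, str]:
    """Slice one uppercase sequence per peak from a FASTA.

    ``genome`` is a path or an open :class:`pyfaidx.Fasta`.  Soft-masked
    bases are uppercased; non-ACGT characters become N.  Peaks on
    chromosomes absent from the FASTA, or overrunning the contig end, are
    skipped with a warning.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    seqs: dict[str, str] = {}
    skipped = 0
    for p in peak_set:
        if p.chrom not in fasta:
            skipped += 1
            logger.warning("peak %s: chromosome %s not in FASTA; skipped", p.id, p.chrom)
            continue
        record = fasta[p.chrom]
        if p.end > len(record):
            skipped += 1
            logger.warning("peak %s: interval past end of %s; skipped", p.id, p.chrom)
            continue
        raw = str(record[p.start : p.end]).upper()
        seqs[p.id] = "".join(b if b in "ACGT" else "N" for b in raw)
    if not seqs:
        raise ValueError("no peak sequences could be extracted")
    if skipped:
        logger.warning("extract_sequences: skipped %d peaks", skipped)
    return seqs


@dataclass
class PooledRegion:
    chrom: str
    members: list[tuple[str, Peak]]  # (replicate label, peak)

    @property
    def replicated(self) -> bool:
        return len({label for label, _ in self.members}) > 1

    @property
    def summits(self) -> list[int]:
        return [p.peak_max for _, p in self.members]


@dataclass
class ReplicatePooling:
    regions: list[PooledRegion]
    pooling_distance: int
    discordant_count: int = 0  # set by downstream label comparison

    def __len__(self) -> int:
        return len(self.regions)


def pool_replicates(rep_a: PeakSet, rep_b: PeakSet, pooling_distance: int) -> ReplicatePooling:
    """Merge two replicate experiments into pooled regions.

    Peaks from both replicates are ordered by summit per chromosome and
    chained greedily: consecutive summits within ``pooling_distance`` bp
    join one region (chains longer than two peaks collapse to a single
    region).  A region is *replicated* when it holds at least one peak
    from each replicate, otherwise *unique*.
    """
    if pooling_distance <= 0:
        raise ValueError("pooling_distance must be positive")
    tagged = [("A", p) for p in rep_a] + [("B", p) for p in rep_b]
    for _, p in tagged:
        if p.peak_max is None:
            raise ValueError(f"peak {p.id!r} lacks a summit; pooling is summit-based")
    by_chrom: dict[str, list[tuple[str, Peak]]] = {}
    for t in tagged:
        by_chrom.setdefault(t[1].chrom, []).append(t)
    regions = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda t: t[1].peak_max)
        current = [group[0]]
        for t in group[1:]:
            if t[1].peak_max - current[-1][1].peak_max <= pooling_distance:
                current.append(t)
            else:
                regions.append(PooledRegion(chrom, current))
                current = [t]
        regions.append(PooledRegion(chrom, current))
    return ReplicatePooling(regions, pooling_distance)
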