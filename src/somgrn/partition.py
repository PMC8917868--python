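"""Genome partitioning from peak calls and per-partition RPKM quantification.

Peak calls from every chromatin experiment are flattened into a single
non-overlapping partition of the peak-covered genome: the union of all peak
boundaries delimits segments, and segments shorter than ``min_size`` are
merged into a contiguous neighbour (or padded when isolated).  Each
partition is then quantified as RPKM per experiment, counting a read in the
partition that contains its 5' end.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class PartitionSet:
    """Sorted, non-overlapping partitions with stable integer ids.

    ``flags`` marks partitions that could not reach ``min_size`` because they
    were clipped at a chromosome end after symmetric padding.
    """

    intervals: list[GenomicInterval]
    min_size: int = 200
    provenance: list[str] = field(default_factory=list)
    flags: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals)
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping partitions {a} and {b}")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def ids(self) -> list[int]:
        return list(range(len(self.intervals)))

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "id": self.ids(),
            }
        )

    def to_bed(self, path) -> None:
        """Write as BED4 with the partition id in the name column."""
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 or MACS2 narrowPeak; only chrom/start/end are used."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: malformed interval start={start} end={end}"
                )
            out.append(GenomicInterval(chrom, start, end))
    return out


def _merge_short_segments(
    segments: list[tuple[int, int]],
    min_size: int,
    chrom_length: int | None,
) -> tuple[list[tuple[int, int]], list[int]]:
    """Enforce minimum segment size within one chromosome.

    A short covered segment merges into the contiguous (abutting) preceding
    segment if one exists, else into the contiguous following one; an
    isolated short segment is kept and symmetrically padded to ``min_size``,
    clipped at chromosome bounds.  Returns (segments, clipped_indices).
    """
    segs = [list(s) for s in segments]
    i = 0
    while i < len(segs):
        start, end = segs[i]
        if end - start >= min_size:
            i += 1
            continue
        prev_contig = i > 0 and segs[i - 1][1] == start
        next_contig = i + 1 < len(segs) and segs[i + 1][0] == end
        if prev_contig:
            segs[i - 1][1] = end
            del segs[i]
            # the enlarged predecessor may still be short; re-examine it
            i = max(i - 1, 0)
        elif next_contig:
            segs[i + 1][0] = start
            del segs[i]
        else:
            # isolated: pad symmetrically, clip at chromosome bounds
            pad = min_size - (end - start)
            left = pad // 2
            new_start = max(0, start - left)
            new_end = new_start + min_size
            if chrom_length is not None and new_end > chrom_length:
                new_end = chrom_length
                new_start = max(0, new_end - min_size)
            # avoid running into neighbours
            if i > 0:
                new_start = max(new_start, segs[i - 1][1])
            if i + 1 < len(segs):
                new_end = min(new_end, segs[i + 1][0])
            segs[i] = [new_start, new_end]
            i += 1
    clipped = [j for j, (s, e) in enumerate(segs) if e - s < min_size]
    return [tuple(s) for s in segs], clipped


def partition_genome(
    peak_sets: list[list[GenomicInterval]],
    min_size: int = 200,
    chrom_lengths: dict[str, int] | None = None,
    provenance: list[str] | None = None,
) -> PartitionSet:
    """Partition the peak-covered genome at the union of all peak boundaries.

    Parameters
    ----------
    peak_sets
        One interval list per chromatin experiment.
    min_size
        Minimum partition size in bp; shorter covered segments are merged
        into a contiguous neighbour (default 200).
    chrom_lengths
        Optional chromosome bounds, used to clip padding of isolated
        short segments.

    The result covers exactly the per-base union of all input peaks (up to
    padding of isolated short segments), split wherever any experiment's
    peak starts or ends.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for peaks in peak_sets:
        for iv in peaks:
            if chrom_lengths is not None:
                L = chrom_lengths.get(iv.chrom)
                if L is not None and iv.end > L:
                    raise ValueError(
                        f"peak {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {L}"
                    )
            by_chrom.setdefault(iv.chrom, []).append(iv)

    intervals: list[GenomicInterval] = []
    flags: dict[int, str] = {}
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        boundaries = sorted({p for iv in ivs for p in (iv.start, iv.end)})
        # covered segments between consecutive boundaries
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        segments: list[tuple[int, int]] = []
        for a, b in zip(boundaries, boundaries[1:]):
            mid = (a + b) / 2.0
            if np.any((starts <= mid) & (mid < ends)):
                # contiguous covered segments stay split: every peak boundary
                # delimits a partition
                segments.append((a, b))
        cl = None if chrom_lengths is None else chrom_lengths.get(chrom)
        merged, clipped = _merge_short_segments(segments, min_size, cl)
        base = len(intervals)
        for j in clipped:
            flags[base + j] = "chromosome-end-clipped"
        intervals.extend(GenomicInterval(chrom, s, e) for s, e in merged)

    return PartitionSet(
        intervals=intervals,
        min_size=min_size,
        provenance=provenance or [],
        flags=flags,
    )


@dataclass
class Read:
    """A single-end read placement; counted at its 5' end."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def quantify_rpkm(
    read_placements: dict[str, list[Read]],
    partitions: PartitionSet,
    total_mapped: dict[str, int],
) -> pd.DataFrame:
    """RPKM matrix: partitions x experiments.

    RPKM(r, e) = count(r, e) * 1e9 / (length_bp(r) * total_mapped(e)).
    A read is counted in the partition containing its 5' end; reads on
    chromosomes absent from the partition set are skipped with a warning.
    """
    for exp, tm in total_mapped.items():
        if tm <= 0:
            raise ValueError(f"total_mapped must be > 0 for experiment {exp!r}")
    # per-chromosome sorted partition arrays for bisection
    chrom_idx: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    frame = partitions.to_frame()
    for chrom, grp in frame.groupby("chrom"):
        chrom_idx[str(chrom)] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            grp["id"].to_numpy(),
        )
    n = len(partitions)
    lengths = np.array([iv.length for iv in partitions], dtype=float)
    experiments = sorted(read_placements)
    mat = np.zeros((n, len(experiments)))
    n_skipped = 0
    for j, exp in enumerate(experiments):
        counts = np.zeros(n)
        by_chrom: dict[str, list[int]] = {}
        for read in read_placements[exp]:
            by_chrom.setdefault(read.chrom, []).append(read.five_prime)
        for chrom, positions in by_chrom.items():
            idx = chrom_idx.get(chrom)
            if idx is None:
                n_skipped += len(positions)
                continue
            starts, ends, ids = idx
            pos = np.asarray(positions)
            k = np.searchsorted(starts, pos, side="right") - 1
            ok = (k >= 0) & (pos < ends[np.clip(k, 0, len(ends) - 1)])
            np.add.at(counts, ids[k[ok]], 1)
        mat[:, j] = counts * 1e9 / (lengths * total_mapped[exp])
    if n_skipped:
        logger.warning("skipped %d reads on chromosomes absent from partitions", n_skipped)
    return pd.DataFrame(mat, index=partitions.ids(), columns=experiments)
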