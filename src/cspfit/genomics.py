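"""Maxgap peak overlaps on stranded BED intervals.

Two peaks overlap when they lie on the same chromosome, their strands are
compatible, and the gap between them is at most ``max_gap`` base pairs
(150 by default). Coordinates are 0-based half-open throughout, so for
disjoint intervals [a, b) and [c, d) with c >= b the gap is ``c - b``:
touching or intersecting intervals have gap 0, and "within 150 bp" means
``c - b <= 150``. An unstranded peak (".") matches any strand, since most
ChIP-seq peak calls carry no strand.

The query uses a sorted sweep with a prefix-maximum over interval ends,
O((n + m) log m) overall; tests hold it to an all-pairs brute force.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import BedError

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "read_bed",
    "overlap_fraction",
    "overlap_flags",
    "multiway_overlap",
]

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise BedError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise BedError(f"invalid strand {self.strand!r}")


@dataclass
class PeakSet:
    """Named collection of intervals, kept sorted by (chrom, start, end)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Parse BED3/BED6 into a :class:`PeakSet`.

    Track/browser/comment lines are skipped; the strand defaults to "."
    when the file has fewer than six columns.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if (
                not stripped
                or stripped.startswith("#")
                or stripped.startswith(("track", "browser"))
            ):
                continue
            fields = stripped.split("\t") if "\t" in stripped else stripped.split()
            if len(fields) < 3:
                raise BedError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise BedError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            strand = fields[5] if len(fields) >= 6 else "."
            if strand not in STRANDS:
                raise BedError(f"{path}:{lineno}: invalid strand {strand!r}")
            intervals.append(GenomicInterval(fields[0], start, end, strand))
    return PeakSet(name=name or path.stem, intervals=intervals)


class _SubjectIndex:
    """Per-(chrom, strand) sorted starts with prefix-max ends, for O(log m)
    "any subject within max_gap?" queries."""

    def __init__(self, subject: PeakSet) -> None:
        self._by_key: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
        grouped: dict[tuple[str, str], list[GenomicInterval]] = {}
        for iv in subject:
            grouped.setdefault((iv.chrom, iv.strand), []).append(iv)
        for key, ivs in grouped.items():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
            starts = [iv.start for iv in ivs]
            prefix_max_end: list[int] = []
            running = -1
            for iv in ivs:
                running = max(running, iv.end)
                prefix_max_end.append(running)
            self._by_key[key] = (starts, prefix_max_end)

    def any_within(
        self, q: GenomicInterval, max_gap: int, same_strand: bool
    ) -> bool:
        if same_strand and q.strand != ".":
            strands: Sequence[str] = (q.strand, ".")
        else:
            strands = STRANDS
        for s in strands:
            entry = self._by_key.get((q.chrom, s))
            if entry is None:
                continue
            starts, prefix_max_end = entry
            # subjects starting at most max_gap past the query end ...
            hi = bisect_right(starts, q.end + max_gap)
            # ... of which the farthest-reaching must end within max_gap of
            # the query start
            if hi > 0 and prefix_max_end[hi - 1] >= q.start - max_gap:
                return True
        return False


def overlap_flags(
    query: PeakSet, subject: PeakSet, max_gap: int = 150, same_strand: bool = True
) -> np.ndarray:
    """Boolean flag per query interval: does any subject interval lie within
    ``max_gap`` on a compatible strand?"""
    index = _SubjectIndex(subject)
    return np.array(
        [index.any_within(q, max_gap, same_strand) for q in query], dtype=bool
    )


def overlap_fraction(
    query: PeakSet, subject: PeakSet, max_gap: int = 150, same_strand: bool = True
) -> tuple[float, int, int]:
    """Fraction of query peaks with a subject peak within ``max_gap``.

    Returns ``(fraction, n_query, n_overlapping)``. The fraction is
    anchored on the query set and is not symmetric.
    """
    if len(query) == 0 or len(subject) == 0:
        raise BedError("overlap_fraction requires non-empty peak sets")
    flags = overlap_flags(query, subject, max_gap, same_strand)
    n_hit = int(flags.sum())
    return n_hit / len(query), len(query), n_hit


def multiway_overlap(
    sets: Sequence[PeakSet], max_gap: int = 150, same_strand: bool = True
) -> pd.DataFrame:
    """Three-way Venn-style membership counts, anchored per set.

    Every peak of every set receives a membership signature from pairwise
    maxgap overlap against the other two sets. Counts are reported relative
    to the anchor set (interval-overlap Venn counts are not symmetric, so
    e.g. the triple region may differ depending on which set anchors it).

    Returns a tidy frame with columns ``anchor``, ``membership`` (ampersand-
    joined set names, always including the anchor) and ``count`` — the 7
    Venn regions as seen from each anchor.
    """
    if len(sets) != 3:
        raise ValueError("multiway_overlap expects exactly 3 peak sets")
    for ps in sets:
        if len(ps) == 0:
            raise BedError("multiway_overlap requires non-empty peak sets")
    names = [ps.name for ps in sets]
    if len(set(names)) != 3:
        raise ValueError("peak sets must have distinct names")
    rows = []
    for i, anchor in enumerate(sets):
        others = [j for j in range(3) if j != i]
        flags = {
            j: overlap_flags(anchor, sets[j], max_gap, same_strand) for j in others
        }
        counts: dict[tuple[bool, ...], int] = {}
        for k in range(len(anchor)):
            sig = tuple(bool(flags[j][k]) for j in others)
            counts[sig] = counts.get(sig, 0) + 1
        for sig_bits in [(False, False), (True, False), (False, True), (True, True)]:
            members = [names[i]] + [
                names[j] for j, bit in zip(others, sig_bits) if bit
            ]
            rows.append(
                {
                    "anchor": names[i],
                    "membership": "&".join(sorted(members)),
                    "count": counts.get(sig_bits, 0),
                }
            )
    return pd.DataFrame(rows)
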