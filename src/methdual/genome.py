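"""Genomic intervals, fixed-width windows, and overlap arithmetic.

All coordinates are 0-based half-open ``[start, end)`` (BED convention),
including windows. An interval "is in" a window iff it overlaps at least
one base of it. Strand is carried on intervals but ignored by every
overlap computation here — the downstream analyses are strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "Window",
    "TEAnnotation",
    "ChromHMMSegment",
    "make_windows",
    "window_frame",
    "overlap_join",
    "overlap_any",
    "intervals_to_window_indices",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (0-based half-open)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Window:
    """One tile of the fixed-width genome partition (default width 500 bp).

    Windows tile each chromosome from position 0 without overlap; the last
    window of a chromosome may be truncated at the chromosome end.
    """

    chrom: str
    index: int
    width: int = 500
    chrom_length: int | None = None

    @property
    def start(self) -> int:
        return self.index * self.width

    @property
    def end(self) -> int:
        end = (self.index + 1) * self.width
        if self.chrom_length is not None:
            end = min(end, self.chrom_length)
        return end

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class TEAnnotation:
    """One transposable-element copy with its subfamily/family/class labels."""

    interval: GenomicInterval
    subfamily: str
    family: str
    te_class: str


@dataclass(frozen=True)
class ChromHMMSegment:
    """A chromatin-state segment of one cell line."""

    interval: GenomicInterval
    state: str
    cell_line: str


def make_windows(chrom_sizes: Mapping[str, int], width: int = 500) -> list[Window]:
    """Tile each chromosome with ``ceil(length / width)`` half-open windows.

    Chromosomes appear in the input mapping order; the final window of each
    chromosome is truncated at the chromosome end.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    windows: list[Window] = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        n = -(-length // width)  # ceil
        windows.extend(Window(chrom, i, width, length) for i in range(n))
    return windows


@dataclass
class WindowFrame:
    """The shared window partition all per-window tracks are laid out on.

    Provides O(log n) interval -> flat window-index mapping. Flat indices run
    over chromosomes in ``chrom_sizes`` order.
    """

    chrom_sizes: dict[str, int]
    width: int = 500
    windows: list[Window] = field(init=False)
    _offsets: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.windows = make_windows(self.chrom_sizes, self.width)
        self._offsets = {}
        off = 0
        for chrom, length in self.chrom_sizes.items():
            self._offsets[chrom] = off
            off += -(-length // self.width)

    def __len__(self) -> int:
        return len(self.windows)

    def n_windows(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.width)

    def flat_index(self, chrom: str, window_index: int) -> int:
        return self._offsets[chrom] + window_index

    def window_of_position(self, chrom: str, pos: int) -> int:
        """Flat index of the window containing base ``pos``."""
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {chrom}:{pos} outside chromosome")
        return self._offsets[chrom] + pos // self.width

    def overlapping_indices(self, interval: GenomicInterval) -> list[int]:
        """Flat indices of every window the interval overlaps by >= 1 bp."""
        if interval.chrom not in self.chrom_sizes:
            return []
        length = self.chrom_sizes[interval.chrom]
        lo = interval.start // self.width
        hi = (min(interval.end, length) - 1) // self.width
        if interval.start >= length:
            return []
        off = self._offsets[interval.chrom]
        return [off + i for i in range(lo, hi + 1)]


def window_frame(chrom_sizes: Mapping[str, int], width: int = 500) -> WindowFrame:
    return WindowFrame(dict(chrom_sizes), width)


def _build_trees(subjects: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for j, sub in enumerate(subjects):
        trees.setdefault(sub.chrom, IntervalTree()).addi(sub.start, sub.end, j)
    return trees


def overlap_join(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> list[list[tuple[int, int]]]:
    """For each query, the ``(subject index, overlap length)`` pairs it hits.

    Half-open intersection; zero-length intersections (abutting intervals)
    are not overlaps. The outer list matches query order; inner lists are
    sorted by subject index.
    """
    trees = _build_trees(subjects)
    out: list[list[tuple[int, int]]] = []
    for q in queries:
        tree = trees.get(q.chrom)
        hits: list[tuple[int, int]] = []
        if tree is not None:
            for iv in tree.overlap(q.start, q.end):
                length = min(q.end, iv.end) - max(q.start, iv.begin)
                if length > 0:
                    hits.append((iv.data, length))
        hits.sort()
        out.append(hits)
    return out


def overlap_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> list[bool]:
    """Whether each query overlaps >= 1 bp of any subject."""
    trees = _build_trees(subjects)
    out = []
    for q in queries:
        tree = trees.get(q.chrom)
        out.append(bool(tree.overlap(q.start, q.end)) if tree is not None else False)
    return out


def intervals_to_window_indices(
    intervals: Iterable[GenomicInterval], frame: WindowFrame
) -> set[int]:
    """Flat window indices intersected by any of the intervals."""
    idx: set[int] = set()
    for iv in intervals:
        idx.update(frame.overlapping_indices(iv))
    return idx
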