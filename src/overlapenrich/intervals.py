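"""Genomic interval data model and arithmetic.

All coordinates are BED convention: 0-based, half-open.  Interval sets are
kept sorted by (natural chromosome order, start, end); ``merge`` produces the
union of overlapping *and book-ended* intervals, matching the default of
``bedtools merge``.  Strand is ignored throughout: the annotations this
package consumes (enhancer/promoter gains, accelerated regions, introgression
maps) are unstranded genomic regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomeDefinition",
    "GenomicInterval",
    "IntervalSet",
    "BedParseError",
    "BuildMismatchError",
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "merge",
    "intersect",
    "subtract",
    "overlap_proportion",
    "count_elements_with_overlap",
]

_DIGITS = re.compile(r"(\d+)")


def natural_key(name: str):
    """Sort key giving chr1 < chr2 < ... < chr10 < chrX ordering."""
    return tuple(int(tok) if tok.isdigit() else tok for tok in _DIGITS.split(name))


class BedParseError(ValueError):
    """Malformed BED/TSV input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class BuildMismatchError(ValueError):
    """Two interval sets on different genome builds were combined."""


@dataclass(frozen=True)
class GenomeDefinition:
    """A named genome build: ordered chromosome names and lengths (bp)."""

    build_label: str
    chromosomes: Mapping[str, int]

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genome must define at least one chromosome")
        for name, length in self.chromosomes.items():
            if int(length) < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        ordered = {
            name: int(self.chromosomes[name])
            for name in sorted(self.chromosomes, key=natural_key)
        }
        object.__setattr__(self, "chromosomes", ordered)

    @property
    def total_bp(self) -> int:
        return sum(self.chromosomes.values())

    def length_of(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r} in build {self.build_label!r}") from None


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """A sorted collection of genomic intervals on one genome build.

    Backed by numpy arrays (chrom codes, starts, ends) for fast arithmetic.
    ``merged`` is True when no two intervals on the same chromosome overlap
    or abut.
    """

    __slots__ = ("build_label", "chroms", "starts", "ends", "names", "merged")

    def __init__(
        self,
        build_label: str,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        names: Optional[Sequence[Optional[str]]] = None,
        merged: bool = False,
        _presorted: bool = False,
    ):
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if not (len(chroms) == len(starts) == len(ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if names is not None:
            names = np.asarray(names, dtype=object)
            if len(names) != len(chroms):
                raise ValueError("names length mismatch")
        if np.any(starts < 0) or np.any(starts >= ends):
            bad = int(np.flatnonzero((starts < 0) | (starts >= ends))[0])
            raise ValueError(
                f"invalid interval {chroms[bad]}:{starts[bad]}-{ends[bad]}"
            )
        if not _presorted and len(chroms):
            rank = {c: i for i, c in enumerate(sorted(set(chroms.tolist()), key=natural_key))}
            codes = np.fromiter((rank[c] for c in chroms), dtype=np.int64, count=len(chroms))
            order = np.lexsort((ends, starts, codes))
            chroms, starts, ends = chroms[order], starts[order], ends[order]
            if names is not None:
                names = names[order]
        self.build_label = build_label
        self.chroms = chroms
        self.starts = starts
        self.ends = ends
        self.names = names
        self.merged = bool(merged)

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[GenomicInterval | tuple],
        build_label: str = "custom",
        merged: bool = False,
    ) -> "IntervalSet":
        rows = []
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                rows.append((iv.chrom, iv.start, iv.end, iv.name))
            else:
                chrom, start, end, *rest = iv
                rows.append((chrom, start, end, rest[0] if rest else None))
        if not rows:
            return cls.empty(build_label)
        chroms, starts, ends, names = zip(*rows)
        has_names = any(n is not None for n in names)
        return cls(build_label, chroms, starts, ends, names if has_names else None, merged=merged)

    @classmethod
    def empty(cls, build_label: str = "custom") -> "IntervalSet":
        return cls(build_label, [], [], [], merged=True, _presorted=True)

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[GenomicInterval]:
        names = self.names if self.names is not None else [None] * len(self)
        for c, s, e, n in zip(self.chroms, self.starts, self.ends, names):
            yield GenomicInterval(str(c), int(s), int(e), n)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            self.build_label == other.build_label
            and len(self) == len(other)
            and bool(np.all(self.chroms == other.chroms))
            and bool(np.all(self.starts == other.starts))
            and bool(np.all(self.ends == other.ends))
        )

    def __repr__(self) -> str:
        return (
            f"IntervalSet({self.build_label!r}, n={len(self)}, "
            f"total_bp={self.total_bp}, merged={self.merged})"
        )

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bp(self) -> int:
        return int(np.sum(self.lengths)) if len(self) else 0

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row ranges per chromosome (set is sorted)."""
        out: dict[str, slice] = {}
        if not len(self):
            return out
        chroms = self.chroms
        boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        edges = [0, *boundaries.tolist(), len(chroms)]
        for i in range(len(edges) - 1):
            out[str(chroms[edges[i]])] = slice(edges[i], edges[i + 1])
        return out

    def check_bounds(self, genome: GenomeDefinition) -> None:
        for chrom, sl in self.chrom_slices().items():
            limit = genome.length_of(chrom)
            if int(self.ends[sl].max()) > limit:
                bad = int(np.argmax(self.ends[sl] > limit))
                raise ValueError(
                    f"interval {chrom}:{self.starts[sl][bad]}-{self.ends[sl][bad]} "
                    f"exceeds chromosome length {limit}"
                )


def _check_same_build(a: IntervalSet, b: IntervalSet) -> None:
    if a.build_label != b.build_label:
        raise BuildMismatchError(
            f"genome build mismatch: {a.build_label!r} vs {b.build_label!r}"
        )


def read_chrom_sizes(path, build_label: str = "custom") -> GenomeDefinition:
    """Read a UCSC-style two-column chrom.sizes file."""
    chromosomes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError("expected two tab-separated columns", lineno)
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise BedParseError(f"non-integer length {fields[1]!r}", lineno) from None
            if name in chromosomes:
                raise BedParseError(f"duplicate chromosome {name!r}", lineno)
            chromosomes[name] = length
    return GenomeDefinition(build_label, chromosomes)


def read_bed(path, genome: GenomeDefinition) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into a sorted IntervalSet.

    Columns beyond the optional 4th (name) are ignored.  Intervals on unknown
    chromosomes or exceeding chromosome bounds raise errors.
    """
    chroms, starts, ends, names = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError("expected >= 3 tab-separated columns", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", lineno
                ) from None
            if start < 0 or start >= end:
                raise BedParseError(f"invalid interval {chrom}:{start}-{end}", lineno)
            if chrom not in genome.chromosomes:
                raise BedParseError(f"unknown chromosome {chrom!r}", lineno)
            if end > genome.length_of(chrom):
                raise BedParseError(
                    f"interval {chrom}:{start}-{end} exceeds chromosome length "
                    f"{genome.length_of(chrom)}",
                    lineno,
                )
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) > 3 else None)
    has_names = any(n is not None for n in names)
    return IntervalSet(
        genome.build_label, chroms, starts, ends, names if has_names else None
    )


def write_bed(s: IntervalSet, path) -> None:
    """Write a sorted BED3/BED4 file (name column only when present)."""
    with open(path, "w") as fh:
        names = s.names if s.names is not None else None
        for i in range(len(s)):
            row = [str(s.chroms[i]), str(int(s.starts[i])), str(int(s.ends[i]))]
            if names is not None:
                row.append(str(names[i]) if names[i] is not None else ".")
            fh.write("\t".join(row) + "\n")


def merge(s: IntervalSet) -> IntervalSet:
    """Union of overlapping or book-ended intervals (bedtools-merge default)."""
    if not len(s):
        return IntervalSet.empty(s.build_label)
    out_c, out_s, out_e = [], [], []
    for chrom, sl in s.chrom_slices().items():
        starts, ends = s.starts[sl], s.ends[sl]
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for i in range(1, len(starts)):
            st, en = int(starts[i]), int(ends[i])
            if st > cur_e:  # strict gap; abutting intervals (st == cur_e) merge
                out_c.append(chrom)
                out_s.append(cur_s)
                out_e.append(cur_e)
                cur_s, cur_e = st, en
            else:
                cur_e = max(cur_e, en)
        out_c.append(chrom)
        out_s.append(cur_s)
        out_e.append(cur_e)
    return IntervalSet(s.build_label, out_c, out_s, out_e, merged=True, _presorted=True)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Overlapping sub-intervals of every (a, b) pair (bedtools-intersect)."""
    _check_same_build(a, b)
    out_c, out_s, out_e = [], [], []
    b_slices = b.chrom_slices()
    for chrom, sl in a.chrom_slices().items():
        if chrom not in b_slices:
            continue
        bsl = b_slices[chrom]
        b_starts, b_ends = b.starts[bsl], b.ends[bsl]
        for i in range(sl.start, sl.stop):
            a_s, a_e = int(a.starts[i]), int(a.ends[i])
            # candidates: b.start < a_e; scan them, keep those with b.end > a_s
            hi = int(np.searchsorted(b_starts, a_e, side="left"))
            for j in range(hi):
                if b_ends[j] > a_s:
                    out_c.append(chrom)
                    out_s.append(max(a_s, int(b_starts[j])))
                    out_e.append(min(a_e, int(b_ends[j])))
    return IntervalSet.from_intervals(
        list(zip(out_c, out_s, out_e)), build_label=a.build_label,
        merged=a.merged and b.merged,
    )


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Sub-intervals of ``a`` not covered by any interval of ``b``."""
    _check_same_build(a, b)
    bm = b if b.merged else merge(b)
    out_c, out_s, out_e, out_n = [], [], [], []
    a_names = a.names if a.names is not None else None
    b_slices = bm.chrom_slices()
    for chrom, sl in a.chrom_slices().items():
        bsl = b_slices.get(chrom)
        b_starts = bm.starts[bsl] if bsl else np.empty(0, dtype=np.int64)
        b_ends = bm.ends[bsl] if bsl else np.empty(0, dtype=np.int64)
        for i in range(sl.start, sl.stop):
            a_s, a_e = int(a.starts[i]), int(a.ends[i])
            name = a_names[i] if a_names is not None else None
            cursor = a_s
            hi = int(np.searchsorted(b_starts, a_e, side="left"))
            lo = int(np.searchsorted(b_ends, a_s, side="right"))
            for j in range(lo, hi):
                bs, be = int(b_starts[j]), int(b_ends[j])
                if bs > cursor:
                    out_c.append(chrom)
                    out_s.append(cursor)
                    out_e.append(bs)
                    out_n.append(name)
                cursor = max(cursor, be)
            if cursor < a_e:
                out_c.append(chrom)
                out_s.append(cursor)
                out_e.append(a_e)
                out_n.append(name)
    has_names = any(n is not None for n in out_n)
    return IntervalSet(
        a.build_label, out_c, out_s, out_e,
        out_n if has_names else None, merged=a.merged,
    )


def overlap_proportion(a: IntervalSet, b: IntervalSet) -> float:
    """Fraction of a's base pairs covered by b.  Asymmetric; both merged."""
    _check_same_build(a, b)
    if not (a.merged and b.merged):
        raise ValueError("overlap_proportion requires both interval sets merged")
    denom = a.total_bp
    if denom == 0:
        raise ValueError("overlap_proportion undefined for an empty interval set")
    return intersect(a, b).total_bp / denom


def overlap_flags(elements: IntervalSet, annot: IntervalSet) -> np.ndarray:
    """Boolean per element: does it overlap the merged annotation by >= 1 bp."""
    _check_same_build(elements, annot)
    if not annot.merged:
        raise ValueError("annotation must be merged before overlap counting")
    flags = np.zeros(len(elements), dtype=bool)
    a_slices = annot.chrom_slices()
    for chrom, sl in elements.chrom_slices().items():
        asl = a_slices.get(chrom)
        if asl is None:
            continue
        ann_starts, ann_ends = annot.starts[asl], annot.ends[asl]
        idx = np.searchsorted(ann_starts, elements.ends[sl], side="left")
        hit = idx > 0
        # merged annotation => ends sorted; the rightmost candidate has max end
        hit[hit] = ann_ends[idx[hit] - 1] > elements.starts[sl][hit]
        flags[sl] = hit
    return flags


def count_elements_with_overlap(
    elements: IntervalSet, annot: IntervalSet, mode: str = "unique"
) -> int:
    """Number of elements overlapping the annotation.

    mode="unique": each element counted at most once (bedtools intersect -u
    semantics); mode="pairs": total number of (element, annotation-interval)
    overlap pairs, for sensitivity checks.
    """
    if mode == "unique":
        return int(np.sum(overlap_flags(elements, annot)))
    if mode != "pairs":
        raise ValueError(f"unknown counting mode {mode!r}")
    _check_same_build(elements, annot)
    if not annot.merged:
        raise ValueError("annotation must be merged before overlap counting")
    total = 0
    a_slices = annot.chrom_slices()
    for chrom, sl in elements.chrom_slices().items():
        asl = a_slices.get(chrom)
        if asl is None:
            continue
        ann_starts, ann_ends = annot.starts[asl], annot.ends[asl]
        hi = np.searchsorted(ann_starts, elements.ends[sl], side="left")
        lo = np.searchsorted(ann_ends, elements.starts[sl], side="right")
        total += int(np.sum(np.maximum(hi - lo, 0)))
    return total
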