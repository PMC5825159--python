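"""Genomic-interval engine: BED I/O, replicate-consensus peaks, multi-set overlap classes.

All coordinates are 0-based, half-open throughout; conversion to other
conventions happens only at I/O boundaries (BED is itself 0-based half-open,
so no conversion is needed there).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "OverlapClassification",
    "BedFormatError",
    "read_bed",
    "write_bed",
    "center_extend",
    "overlaps",
    "intersect_sets",
    "merge_intervals",
    "consensus_peaks",
    "classify_overlap",
]


class BedFormatError(ValueError):
    """Malformed BED input; carries the 1-based line number of the offence."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str = field(default=".", compare=False)
    score: Optional[float] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor((start + end) / 2)."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakSet:
    """An ordered collection of intervals from one tissue (and optionally one replicate).

    Intervals are kept sorted by (chrom, start, end); they need not be
    disjoint unless produced by :func:`merge_intervals`.
    """

    intervals: tuple[GenomicInterval, ...]
    tissue: str = ""
    replicate: Optional[str] = None

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)))
        object.__setattr__(self, "intervals", ordered)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
            }
        )

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


def read_bed(path, tissue: str = "", replicate: Optional[str] = None) -> PeakSet:
    """Read BED3+ (tab-separated). Malformed lines raise BedFormatError with line numbers."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError("fewer than 3 tab-separated fields", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", lineno
                ) from None
            name = fields[3] if len(fields) > 3 else "."
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedFormatError(f"non-numeric score {fields[4]!r}", lineno) from None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise BedFormatError(str(exc), lineno) from None
    return PeakSet(tuple(intervals), tissue=tissue, replicate=replicate)


def write_bed(peakset: PeakSet, path) -> None:
    """Write BED6 (name '.', score '0' when absent; strand '.')."""
    with open(path, "w") as fh:
        for iv in peakset:
            score = "0" if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t.\n")


def center_extend(interval: GenomicInterval, ext_bp: int = 100) -> GenomicInterval:
    """Extend the interval center by +-ext_bp: [max(0, c-ext), c+ext), c = floor midpoint.

    Width is exactly 2*ext_bp except at a chromosome start, where the low end
    is clipped at 0.
    """
    if ext_bp <= 0:
        raise ValueError("ext_bp must be > 0")
    c = interval.center
    return replace(interval, start=max(0, c - ext_bp), end=c + ext_bp)


def overlaps(a: GenomicInterval, b: GenomicInterval, min_overlap_bp: int = 1) -> bool:
    """True if a and b share at least min_overlap_bp bases (half-open)."""
    if a.chrom != b.chrom:
        return False
    return min(a.end, b.end) - max(a.start, b.start) >= min_overlap_bp


def _overlap_mask(query: Sequence[GenomicInterval], targets: Iterable[GenomicInterval],
                  min_overlap_bp: int = 1) -> np.ndarray:
    """Boolean mask over `query`: does each interval overlap >=1 target?

    Sorted sweep per chromosome; equivalent to the all-pairs test.
    """
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in targets:
        grouped.setdefault(iv.chrom, []).append(iv)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom, ivs in grouped.items():
        s = np.array([iv.start for iv in ivs])
        e = np.array([iv.end for iv in ivs])
        order = np.argsort(s, kind="stable")
        starts[chrom], ends[chrom] = s[order], e[order]
    mask = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query):
        if q.chrom not in starts:
            continue
        s, e = starts[q.chrom], ends[q.chrom]
        # candidates must start early enough to share min_overlap_bp bases
        hi = np.searchsorted(s, q.end - min_overlap_bp, side="right")
        if hi == 0:
            continue
        mask[i] = bool(
            np.any(np.minimum(e[:hi], q.end) - np.maximum(s[:hi], q.start) >= min_overlap_bp)
        )
    return mask


def intersect_sets(A: PeakSet, B: PeakSet, min_overlap_bp: int = 1) -> PeakSet:
    """Members of A overlapping at least one member of B (by >= min_overlap_bp bases)."""
    mask = _overlap_mask(A.intervals, B.intervals, min_overlap_bp)
    kept = tuple(iv for iv, m in zip(A.intervals, mask) if m)
    return PeakSet(kept, tissue=A.tissue, replicate=A.replicate)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (>=1 bp) intervals into maximal runs, per chromosome."""
    merged: list[GenomicInterval] = []
    key = lambda iv: (iv.chrom, iv.start, iv.end)
    for iv in sorted(intervals, key=key):
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(replace(iv, name=".", score=None))
    return merged


def consensus_peaks(
    merged_calls: PeakSet,
    replicate_calls: Sequence[PeakSet],
    ext_bp: int = 100,
    min_overlap_bp: int = 1,
    exclude: Optional[PeakSet] = None,
) -> PeakSet:
    """Replicate-consensus peaks.

    Retains members of `merged_calls` that overlap >=1 peak in EVERY replicate
    call set, then extends each retained peak center by +-ext_bp. Output is
    sorted and deduplicated. This is the filter that turns merged-library peak
    calls plus per-duplicate calls into fixed-width high-confidence peaks.
    An optional exclusion set (e.g. known high-background regions) drops any
    merged call overlapping it; no default exclusion list ships.
    """
    if len(replicate_calls) == 0:
        raise ValueError("at least one replicate call set is required")
    keep = np.ones(len(merged_calls), dtype=bool)
    for rep in replicate_calls:
        keep &= _overlap_mask(merged_calls.intervals, rep.intervals, min_overlap_bp)
    if exclude is not None and len(exclude):
        keep &= ~_overlap_mask(merged_calls.intervals, exclude.intervals, min_overlap_bp)
    extended = {
        center_extend(iv, ext_bp)
        for iv, k in zip(merged_calls.intervals, keep)
        if k
    }
    return PeakSet(tuple(extended), tissue=merged_calls.tissue)


@dataclass(frozen=True)
class OverlapClassification:
    """Cross-tissue overlap classes of peaks (the multi-set Venn logic).

    per_tissue: one row per peak of each tissue with its class and the tissues
    it overlaps; union: one row per merged region of the union of all tissues.
    Classes are exhaustive and mutually exclusive:
    ``specific:<tissue>``, ``<layer>-common`` (all overlapping tissues in one
    germ layer), ``both-germ-layers`` (spans layers but not every tissue),
    ``all-common`` (every tissue).
    """

    per_tissue: pd.DataFrame
    union: pd.DataFrame
    per_tissue_counts: dict[str, dict[str, int]]
    union_counts: dict[str, int]


def _class_label(found_in: frozenset[str], germ_layers: Mapping[str, str],
                 all_tissues: frozenset[str]) -> str:
    if len(found_in) == 1:
        return f"specific:{next(iter(found_in))}"
    if found_in == all_tissues:
        return "all-common"
    layers = {germ_layers[t] for t in found_in}
    if len(layers) == 1:
        return f"{next(iter(layers))}-common"
    return "both-germ-layers"


def classify_overlap(
    peaksets: Mapping[str, PeakSet],
    germ_layers: Mapping[str, str],
    min_overlap_bp: int = 1,
) -> OverlapClassification:
    """Label each peak by the set of tissues it overlaps, and count classes.

    Counts are reported from every tissue's own perspective AND on the merged
    union of all tissues (one merged region = one countable unit); the union
    convention is the headline output, since per-tissue counts are not
    symmetric across sets of different sizes.
    """
    if len(peaksets) < 2:
        raise ValueError("need >=2 tissues to classify overlap")
    for t in peaksets:
        if t not in germ_layers:
            raise ValueError(f"tissue {t!r} has no germ-layer assignment")
    all_tissues = frozenset(peaksets)

    rows = []
    for tissue, ps in peaksets.items():
        masks = {
            other: _overlap_mask(ps.intervals, peaksets[other].intervals, min_overlap_bp)
            for other in peaksets
            if other != tissue
        }
        for i, iv in enumerate(ps.intervals):
            found = frozenset({tissue} | {o for o, m in masks.items() if m[i]})
            rows.append(
                {
                    "tissue": tissue,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "name": iv.name,
                    "found_in": ",".join(sorted(found)),
                    "class": _class_label(found, germ_layers, all_tissues),
                }
            )
    per_tissue = pd.DataFrame(
        rows, columns=["tissue", "chrom", "start", "end", "name", "found_in", "class"]
    )

    union_regions = merge_intervals(itertools.chain.from_iterable(ps.intervals for ps in peaksets.values()))
    union_rows = []
    region_masks = {
        t: _overlap_mask(union_regions, peaksets[t].intervals, min_overlap_bp)
        for t in peaksets
    }
    for i, iv in enumerate(union_regions):
        found = frozenset(t for t in peaksets if region_masks[t][i])
        union_rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "found_in": ",".join(sorted(found)),
                "class": _class_label(found, germ_layers, all_tissues),
            }
        )
    union = pd.DataFrame(union_rows, columns=["chrom", "start", "end", "found_in", "class"])

    per_tissue_counts = {
        t: grp["class"].value_counts().to_dict()
        for t, grp in per_tissue.groupby("tissue")
    }
    for t in peaksets:
        per_tissue_counts.setdefault(t, {})
    union_counts = union["class"].value_counts().to_dict() if len(union) else {}
    return OverlapClassification(per_tissue, union, per_tissue_counts, union_counts)
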