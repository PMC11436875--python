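"""Genomic interval arithmetic for chromatin-accessibility peak atlases.

Peaks are BED-style intervals: 0-based, half-open ``[start, end)``. Variant
positions arrive 1-based (VCF convention); the conversion to 0-based happens
here and nowhere else. Overlapping and book-ended intervals merge, matching
``bedtools merge`` with its default distance of 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "PeakAtlas",
    "DiseaseMap",
    "merge_intervals",
    "build_disease_peakset",
    "overlap_variants",
    "read_bed",
    "write_bed",
    "total_covered_bases",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort and merge overlapping or book-ended intervals per chromosome.

    Book-ended inputs (``end == next start``) merge, the bedtools default.
    Idempotent; preserves total covered bases.
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def total_covered_bases(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in merge_intervals(intervals))


@dataclass
class PeakAtlas:
    """Per cell-type/stage accessible-chromatin interval sets.

    Keys are cell-type identifiers such as ``"cMN7_e10.5"``. Interval lists
    are merged (sorted, non-overlapping) on construction.
    """

    peaks: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = {ct: merge_intervals(ivs) for ct, ivs in self.peaks.items()}

    def cell_types(self) -> list[str]:
        return list(self.peaks)

    def union(self, cell_types: Sequence[str] | None = None) -> list[GenomicInterval]:
        cts = self.cell_types() if cell_types is None else cell_types
        pool: list[GenomicInterval] = []
        for ct in cts:
            pool.extend(self.peaks[ct])
        return merge_intervals(pool)


@dataclass
class DiseaseMap:
    """Disease group -> disease-relevant cell types/stages.

    Encodes the phenotype-to-motor-neuron assignments (e.g. DRS -> cMN6,
    CFP -> cMN7, Moebius -> cMN6 and cMN7).
    """

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        for g, cts in self.groups.items():
            if not cts:
                raise ValueError(f"disease group {g!r} maps to no cell types")

    def cell_types_for(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown disease group {group!r}")
        return self.groups[group]


def build_disease_peakset(
    atlas: PeakAtlas, dmap: DiseaseMap, group: str
) -> list[GenomicInterval]:
    """Union-merge the peak sets of every cell type mapped to a disease group."""
    cts = dmap.cell_types_for(group)
    missing = [ct for ct in cts if ct not in atlas.peaks]
    if missing:
        raise KeyError(f"cell types absent from atlas: {missing}")
    return atlas.union(cts)


def _interval_arrays(intervals: Sequence[GenomicInterval]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[GenomicInterval]]] = {}
    for chrom in {iv.chrom for iv in intervals}:
        ivs = sorted(iv for iv in intervals if iv.chrom == chrom)
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        by_chrom[chrom] = (starts, ends, ivs)
    return by_chrom


def overlap_variants(
    variants: Sequence,
    intervals: Sequence[GenomicInterval],
    padding: int = 0,
) -> list[tuple[object, GenomicInterval]]:
    """Intersect variants with merged peak intervals.

    Overlap rules by variant class:

    - SNV/indel: the (0-based) anchor position must be contained in the
      interval, i.e. ``start <= pos0 < end``.
    - SV: any overlap between the SV span (0-based half-open) and the
      interval suffices.
    - TE: the insertion point must fall within the interval padded by
      ``padding`` bases on each side (the ±15 bp rule by default upstream).

    ``variants`` may be any objects with ``chrom``, ``pos`` (1-based),
    ``var_class`` and, for SVs, ``sv_span`` (0-based half-open tuple).
    Returns (variant, hit interval) pairs.
    """
    by_chrom = _interval_arrays(intervals)
    hits: list[tuple[object, GenomicInterval]] = []
    for v in variants:
        entry = by_chrom.get(v.chrom)
        if entry is None:
            continue
        starts, ends, ivs = entry
        var_class = getattr(v, "var_class", "SNV")
        if var_class == "SV":
            s, e = v.sv_span
            # any overlap: interval.start < e and interval.end > s
            i0 = int(np.searchsorted(ends, s, side="right"))
            for i in range(i0, len(ivs)):
                if starts[i] >= e:
                    break
                hits.append((v, ivs[i]))
        else:
            pos0 = v.pos - 1
            pad = padding if var_class == "TE" else 0
            i0 = int(np.searchsorted(ends + pad, pos0, side="right"))
            # padded intervals may overlap each other even after merging
            for i in range(i0, len(ivs)):
                if starts[i] - pad > pos0:
                    break
                hits.append((v, ivs[i]))
    return hits


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ into intervals (extra columns beyond the name are ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else ""
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), name))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name:
                fields.append(iv.name)
            fh.write("\t".join(fields) + "\n")
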