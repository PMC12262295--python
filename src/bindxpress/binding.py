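"""Peak-set intersection and nearest-TSS peak-to-gene assignment.

Two driver-specific ChIP peak sets are intersected keeping the original
entries of set A (the shared-tissue binding regions); each retained peak's
center is then matched to at most one gene per genomic side whose 5'-most
TSS lies strictly within a distance cutoff (default 1 kb).

Conventions: the peak center is floor((start+end)/2); "upstream/downstream"
is genomic left/right of the center, independent of gene strand (a switch
``strand_relative`` flips to gene-strand-relative sides); a TSS exactly at
the center counts once, as the left-side candidate at distance 0; distance
ties on a side are broken toward the lexicographically smaller gene_id.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GeneTss, PeakRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntersectedPeak:
    """A set-A peak retained because >=1 set-B peak shares a base with it."""

    source: PeakRecord

    @property
    def center(self) -> int:
        return (self.source.start + self.source.end) // 2

    @property
    def chrom(self) -> str:
        return self.source.chrom


@dataclass(frozen=True)
class AssignmentConfig:
    max_distance: int = 1000          # strict: distance < max_distance
    strand_relative: bool = False     # sides relative to gene strand instead

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise ValueError("max_distance must be non-negative")


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak: IntersectedPeak
    gene_id: str
    distance: int           # |center - tss|, non-negative
    side: str               # "upstream" (TSS <= center) or "downstream"

    @property
    def signed_distance(self) -> int:
        """center - tss; negative when the TSS lies right of the center."""
        return self.distance if self.side == "upstream" else -self.distance


def intersect_keep_a(
    set_a: Sequence[PeakRecord], set_b: Sequence[PeakRecord]
) -> list[IntersectedPeak]:
    """Return set-A peaks overlapping >=1 set-B peak (>=1 shared base under
    half-open semantics), each at most once, in set-A order."""
    b_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for b in set_b:
        b_by_chrom[b.chrom].append((b.start, b.end))
    # sort by start; track running max end for a sweep
    starts_ends: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in b_by_chrom.items():
        ivs.sort()
        starts = [s for s, _ in ivs]
        # prefix max of ends aligned with sorted starts
        maxend = []
        cur = -1
        for _, e in ivs:
            cur = max(cur, e)
            maxend.append(cur)
        starts_ends[chrom] = (starts, maxend)

    out: list[IntersectedPeak] = []
    for a in set_a:
        entry = starts_ends.get(a.chrom)
        if entry is None:
            continue
        starts, maxend = entry
        # candidates with b.start < a.end; overlap iff any has end > a.start
        idx = bisect_right(starts, a.end - 1)
        if idx and maxend[idx - 1] > a.start:
            out.append(IntersectedPeak(source=a))
    return out


def assign_peaks(
    peaks: Sequence[IntersectedPeak],
    tss_table: Sequence[GeneTss],
    cfg: AssignmentConfig = AssignmentConfig(),
) -> list[PeakGeneAssignment]:
    """Assign each intersected peak to <=1 gene per side of its center.

    Per side, the gene whose TSS is nearest wins, and only if its distance is
    strictly below ``cfg.max_distance``; hence 0-2 assignments per peak.
    """
    if not tss_table:
        logger.warning("empty TSS table: no assignments possible")
        return []

    by_chrom: dict[str, list[GeneTss]] = defaultdict(list)
    for g in tss_table:
        by_chrom[g.chrom].append(g)
    # sort by (tss, gene_id) so equidistant ties resolve to the smaller id
    pos_arrays: dict[str, tuple[np.ndarray, list[GeneTss]]] = {}
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.tss, g.gene_id))
        pos_arrays[chrom] = (np.array([g.tss for g in genes]), genes)

    out: list[PeakGeneAssignment] = []
    for peak in peaks:
        entry = pos_arrays.get(peak.chrom)
        if entry is None:
            continue
        positions, genes = entry
        center = peak.center
        i = int(np.searchsorted(positions, center, side="right"))

        left: GeneTss | None = None
        if i > 0:
            # nearest TSS at or left of center; among equal positions the
            # first (smallest gene_id) by scanning back over duplicates
            j = i - 1
            while j > 0 and positions[j - 1] == positions[j]:
                j -= 1
            if j != i - 1:
                logger.warning(
                    "TSS tie at %s:%d resolved to gene %s",
                    peak.chrom, int(positions[j]), genes[j].gene_id,
                )
            left = genes[j]
        right: GeneTss | None = None
        if i < len(genes):
            if i + 1 < len(genes) and positions[i + 1] == positions[i]:
                logger.warning(
                    "TSS tie at %s:%d resolved to gene %s",
                    peak.chrom, int(positions[i]), genes[i].gene_id,
                )
            right = genes[i]

        for gene, side in ((left, "upstream"), (right, "downstream")):
            if gene is None:
                continue
            dist = abs(center - gene.tss)
            if dist >= cfg.max_distance:
                continue
            resolved_side = side
            if cfg.strand_relative and gene.strand == "-":
                resolved_side = (
                    "downstream" if side == "upstream" else "upstream"
                )
            out.append(
                PeakGeneAssignment(
                    peak=peak, gene_id=gene.gene_id,
                    distance=dist, side=resolved_side,
                )
            )
    return out


def bound_genes(assignments: Iterable[PeakGeneAssignment]) -> set[str]:
    """Distinct genes across all assignments (multi-peak genes counted once)."""
    return {a.gene_id for a in assignments}


def tss_distance_histogram(
    assignments: Sequence[PeakGeneAssignment], bin_width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of signed center - TSS distances.

    Returns ``(counts, bin_edges)`` with bins of ``bin_width`` bases aligned
    to multiples of the bin width; counts sum to the number of assignments.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dists = np.array([a.signed_distance for a in assignments], dtype=float)
    if dists.size == 0:
        edges = np.array([0.0, float(bin_width)])
        return np.zeros(1, dtype=int), edges
    lo = int(np.floor(dists.min() / bin_width)) * bin_width
    hi = int(np.floor(dists.max() / bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width, dtype=float)
    counts, _ = np.histogram(dists, bins=edges)
    return counts, edges
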