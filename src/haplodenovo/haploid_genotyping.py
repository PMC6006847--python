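"""Per-haplotype pileups and deterministic haploid genotype calls.

After the alignments are partitioned by haplotype tag, each candidate
site gets one quality-filtered pileup per (individual, haplotype).  A
haploid genotype is then called by a deterministic rule: insufficient
depth is UNCOVERED; credible support for both alleles is CONFLICT (the
signature of a miscalled inherited het); otherwise the majority allele
wins (REF or ALT).
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .haplotype_assignment import query_base_at
from .model import (
    Haplotype,
    HaploidCall,
    HaploidState,
    PileupColumn,
    Role,
    VariantSite,
)

DEFAULT_MIN_DEPTH = 2  # per-haplotype depth below which a call is UNCOVERED (>1X)
DEFAULT_MIN_MINOR_COUNT = 2
DEFAULT_MIN_MINOR_FRACTION = 0.15
DEFAULT_MIN_BASE_QUALITY = 13
DEFAULT_MIN_MAPPING_QUALITY = 20


def pileup_at_sites(
    alignments: Iterable[pysam.AlignedSegment],
    sites: Sequence[VariantSite],
    owner: Role,
    haplotype: Haplotype,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_mapping_quality: int = DEFAULT_MIN_MAPPING_QUALITY,
) -> list[PileupColumn]:
    """Count ref/alt/other bases at each site from one alignment partition.

    A single linear sweep over the reads; sites on chromosomes absent
    from the alignments simply keep zero counts.
    """
    columns = [PileupColumn(site=s, haplotype=haplotype, owner=owner) for s in sites]
    by_chrom: dict[str, tuple[list[int], list[PileupColumn]]] = {}
    for col in columns:
        by_chrom.setdefault(col.site.chrom, ([], []))
        by_chrom[col.site.chrom][0].append(col.site.pos)
        by_chrom[col.site.chrom][1].append(col)
    for chrom in by_chrom:
        pos, cols = by_chrom[chrom]
        order = sorted(range(len(pos)), key=lambda i: pos[i])
        by_chrom[chrom] = ([pos[i] for i in order], [cols[i] for i in order])

    for read in alignments:
        if read.is_unmapped or read.mapping_quality < min_mapping_quality:
            continue
        entry = by_chrom.get(read.reference_name)
        if entry is None:
            continue
        positions, cols = entry
        start1 = read.reference_start + 1
        end1 = read.reference_end or (read.reference_start + read.query_length)
        lo = bisect_left(positions, start1)
        hi = bisect_right(positions, end1)
        for i in range(lo, hi):
            hit = query_base_at(read, positions[i] - 1)
            if hit is None:
                continue
            base, qual = hit
            if qual < min_base_quality:
                continue
            col = cols[i]
            if base == col.site.ref:
                col.ref_count += 1
            elif base == col.site.alt:
                col.alt_count += 1
            else:
                col.other_count += 1
    return columns


def call_haploid_genotype(
    column: PileupColumn,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_minor_count: int = DEFAULT_MIN_MINOR_COUNT,
    min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION,
) -> HaploidCall:
    """Call one haploid genotype from a pileup column.

    Rules, in order: ref+alt depth below ``min_depth`` is UNCOVERED;
    both alleles with count >= ``min_minor_count`` and minor fraction >=
    ``min_minor_fraction`` is CONFLICT; an exact ref/alt tie is CONFLICT
    (neither allele has a majority, and any directional tie-break would
    violate ref/alt exchange symmetry); otherwise the majority allele.
    Bases matching neither allele never vote but are retained on the
    column for audit.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not (0 < min_minor_fraction < 0.5):
        raise ValueError("min_minor_fraction must be in (0, 0.5)")
    ref, alt = column.ref_count, column.alt_count
    depth = ref + alt
    if depth < min_depth:
        return HaploidCall(HaploidState.UNCOVERED, depth)
    minor = min(ref, alt)
    if minor >= min_minor_count and minor / depth >= min_minor_fraction:
        return HaploidCall(HaploidState.CONFLICT, depth)
    if ref == alt:
        return HaploidCall(HaploidState.CONFLICT, depth)
    state = HaploidState.REF if ref > alt else HaploidState.ALT
    return HaploidCall(state, depth)


def pileup_table(columns: Iterable[PileupColumn]) -> pd.DataFrame:
    """Audit table of pileup columns (one row per site x haplotype)."""
    rows = [
        {
            "sample": c.owner.value,
            "haplotype": c.haplotype.value,
            "chrom": c.site.chrom,
            "pos": c.site.pos,
            "ref": c.site.ref,
            "alt": c.site.alt,
            "ref_count": c.ref_count,
            "alt_count": c.alt_count,
            "other_count": c.other_count,
        }
        for c in columns
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "haplotype", "chrom", "pos", "ref", "alt",
            "ref_count", "alt_count", "other_count",
        ],
    )


def write_pileup_table(columns: Iterable[PileupColumn], path: str) -> str:
    pileup_table(columns).to_csv(path, sep="\t", index=False)
    return path
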