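"""Assign barcoded reads to haplotypes within phase blocks.

Reads sharing a barcode that align near each other derive from one long
molecule, hence from one haplotype.  Each molecule votes with its bases
at the owner's phased het sites: bases matching haplotype 1's alleles
against bases matching haplotype 2's.  The majority assigns HP1 or HP2
to every read of the molecule; ties and uninformative molecules stay
HP0 (undetermined).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .model import (
    AlleleObservation,
    Haplotype,
    Molecule,
    PhaseBlock,
    PhasedHetSite,
    Role,
    TrioVariantRecord,
)

logger = logging.getLogger(__name__)

DEFAULT_GAP_THRESHOLD = 50_000  # bp between consecutive read starts of one molecule
DEFAULT_MIN_BASE_QUALITY = 13  # phred; excludes likely errors from the vote
BARCODE_TAG = "BX"
HAPLOTYPE_TAG = "HP"


def build_phase_blocks(
    records: Iterable[TrioVariantRecord],
) -> dict[Role, list[PhaseBlock]]:
    """Collect each individual's phased het sites into phase blocks.

    Only phased heterozygous calls carrying a phase-set ID contribute;
    unphased or homozygous sites never vote.
    """
    acc: dict[Role, dict[tuple[str, str], list[PhasedHetSite]]] = {
        role: defaultdict(list) for role in Role
    }
    for rec in records:
        for role in Role:
            call = rec.call(role)
            if call.phased and call.is_het and call.phase_set is not None:
                acc[role][(rec.site.chrom, call.phase_set)].append(
                    PhasedHetSite(
                        pos=rec.site.pos,
                        ref=rec.site.ref,
                        alt=rec.site.alt,
                        hap1=call.alleles[0],
                        hap2=call.alleles[1],
                    )
                )
    out: dict[Role, list[PhaseBlock]] = {}
    for role in Role:
        blocks = []
        for (chrom, ps), sites in acc[role].items():
            sites.sort(key=lambda s: s.pos)
            blocks.append(PhaseBlock(owner=role, block_id=ps, chrom=chrom, sites=sites))
        blocks.sort(key=lambda b: (b.chrom, b.sites[0].pos if b.sites else 0))
        out[role] = blocks
    return out


def group_reads_into_molecules(
    alignments: Iterable[pysam.AlignedSegment],
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
) -> list[Molecule]:
    """Chain coordinate-sorted barcoded reads into molecules.

    Same-barcode reads on one chromosome stay in one molecule while
    consecutive read starts are within ``gap_threshold``; a larger gap
    (or a chromosome change) starts a new molecule.  Reads without a
    barcode become singleton molecules.
    """
    molecules: list[Molecule] = []
    open_mol: dict[str, Molecule] = {}
    last_start: dict[str, int] = {}
    n_unbarcoded = 0
    for read in alignments:
        if read.is_unmapped:
            continue
        chrom = read.reference_name
        start = read.reference_start
        end = read.reference_end or (start + read.query_length)
        barcode = read.get_tag(BARCODE_TAG) if read.has_tag(BARCODE_TAG) else None
        if barcode is None:
            n_unbarcoded += 1
            molecules.append(
                Molecule(barcode="", chrom=chrom, start=start, end=end,
                         read_names=[read.query_name], reads=[read])
            )
            continue
        mol = open_mol.get(barcode)
        if (
            mol is None
            or mol.chrom != chrom
            or start - last_start[barcode] > gap_threshold
        ):
            mol = Molecule(barcode=barcode, chrom=chrom, start=start, end=end)
            molecules.append(mol)
            open_mol[barcode] = mol
        mol.end = max(mol.end, end)
        mol.read_names.append(read.query_name)
        mol.reads.append(read)
        last_start[barcode] = start
    if n_unbarcoded:
        logger.info("%d read(s) without a %s barcode became singleton molecules",
                    n_unbarcoded, BARCODE_TAG)
    return molecules


def query_base_at(read: pysam.AlignedSegment, pos0: int) -> Optional[tuple[str, int]]:
    """Base and quality of ``read`` at 0-based reference position ``pos0``."""
    cig = read.cigartuples
    if cig and len(cig) == 1 and cig[0][0] == 0:  # single-M fast path
        offset = pos0 - read.reference_start
        if 0 <= offset < read.query_length:
            seq = read.query_sequence
            qual = read.query_qualities
            return seq[offset], (qual[offset] if qual is not None else 60)
        return None
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == pos0:
            seq = read.query_sequence
            qual = read.query_qualities
            return seq[qpos], (qual[qpos] if qual is not None else 60)
    return None


class _BlockIndex:
    """Per-chromosome sorted index of phased het sites for fast lookup."""

    def __init__(self, blocks: Sequence[PhaseBlock]):
        by_chrom: dict[str, list[tuple[int, PhaseBlock, PhasedHetSite]]] = defaultdict(list)
        for block in blocks:
            for site in block.sites:
                by_chrom[block.chrom].append((site.pos, block, site))
        self._index = {
            chrom: sorted(entries, key=lambda e: e[0]) for chrom, entries in by_chrom.items()
        }
        self._positions = {
            chrom: [e[0] for e in entries] for chrom, entries in self._index.items()
        }

    def sites_in(self, chrom: str, start1: int, end1: int):
        """Het sites with 1-based position in [start1, end1]."""
        if chrom not in self._index:
            return ()
        pos = self._positions[chrom]
        lo = bisect_left(pos, start1)
        hi = bisect_right(pos, end1)
        return self._index[chrom][lo:hi]


def collect_observations(
    reads: Iterable[pysam.AlignedSegment],
    index: _BlockIndex,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> dict[PhaseBlock, list[AlleleObservation]]:
    """Gather per-block allele observations from reads at phased het sites."""
    obs: dict[PhaseBlock, list[AlleleObservation]] = defaultdict(list)
    for read in reads:
        if read.is_unmapped:
            continue
        start1 = read.reference_start + 1
        end1 = read.reference_end or (read.reference_start + read.query_length)
        for pos, block, site in index.sites_in(read.reference_name, start1, end1):
            hit = query_base_at(read, pos - 1)
            if hit is None:
                continue
            base, qual = hit
            if qual < min_base_quality:
                continue
            if base == site.ref:
                allele = 0
            elif base == site.alt:
                allele = 1
            else:
                allele = -1
            obs[block].append(AlleleObservation(pos=pos, allele_index=allele, base_quality=qual))
    return obs


def vote_haplotype(
    observations: Mapping[PhaseBlock, Sequence[AlleleObservation]],
) -> Haplotype:
    """Majority vote over allele observations, restricted to one block.

    When observations span several phase blocks the block holding the
    majority of informative observations is used; a tie between blocks,
    a tie between haplotypes, or zero informative observations all yield
    HP0.
    """
    best_block, best_count, tied = None, 0, False
    for block, obs_list in observations.items():
        informative = sum(1 for o in obs_list if o.allele_index in (0, 1))
        if informative > best_count:
            best_block, best_count, tied = block, informative, False
        elif informative == best_count and informative > 0:
            tied = True
    if best_block is None or best_count == 0 or tied:
        return Haplotype.HP0
    n1 = n2 = 0
    site_by_pos = {s.pos: s for s in best_block.sites}
    for o in observations[best_block]:
        site = site_by_pos.get(o.pos)
        if site is None or o.allele_index not in (0, 1):
            continue
        if o.allele_index == site.hap1:
            n1 += 1
        elif o.allele_index == site.hap2:
            n2 += 1
    if n1 > n2:
        return Haplotype.HP1
    if n2 > n1:
        return Haplotype.HP2
    return Haplotype.HP0


def assign_haplotype(
    molecule: Molecule,
    blocks: Sequence[PhaseBlock],
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> Haplotype:
    """Tag one molecule (hence all its reads) by majority haplotype vote."""
    index = blocks if isinstance(blocks, _BlockIndex) else _BlockIndex(blocks)
    return vote_haplotype(collect_observations(molecule.reads, index, min_base_quality))


def assign_reads(
    alignments: Sequence[pysam.AlignedSegment],
    blocks: Sequence[PhaseBlock],
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    per_read: bool = False,
    trust_existing_tags: bool = False,
) -> list[tuple[pysam.AlignedSegment, Haplotype]]:
    """Assign a haplotype tag to every alignment, in input order.

    By default reads vote together at molecule level (a barcode chain is
    one haplotype); ``per_read=True`` makes each read vote alone, for
    comparison.  ``trust_existing_tags`` honours a pre-computed integer
    HP tag instead of recomputing.
    """
    if trust_existing_tags:
        out = []
        for read in alignments:
            if read.has_tag(HAPLOTYPE_TAG):
                out.append((read, Haplotype.HP1 if read.get_tag(HAPLOTYPE_TAG) == 1 else Haplotype.HP2))
            else:
                out.append((read, Haplotype.HP0))
        return out
    index = _BlockIndex(blocks)
    tag_of: dict[int, Haplotype] = {}
    if per_read:
        for read in alignments:
            tag_of[id(read)] = vote_haplotype(
                collect_observations([read], index, min_base_quality)
            )
    else:
        for mol in group_reads_into_molecules(alignments, gap_threshold):
            tag = vote_haplotype(collect_observations(mol.reads, index, min_base_quality))
            for read in mol.reads:
                tag_of[id(read)] = tag
    return [(read, tag_of.get(id(read), Haplotype.HP0)) for read in alignments]


def split_by_tag(
    tagged: Iterable[tuple[pysam.AlignedSegment, Haplotype]],
) -> dict[Haplotype, list[pysam.AlignedSegment]]:
    """Partition tagged alignments into HP1/HP2/HP0 sets, order preserved."""
    parts: dict[Haplotype, list[pysam.AlignedSegment]] = {h: [] for h in Haplotype}
    for read, tag in tagged:
        parts[tag].append(read)
    return parts


def read_alignments(path: str) -> tuple[list[pysam.AlignedSegment], pysam.AlignmentHeader]:
    """Load a SAM/BAM file into memory (coordinate order as stored)."""
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        header = fh.header
        reads = [r for r in fh]
    return reads, header


def write_alignments(
    reads: Iterable[pysam.AlignedSegment], header: pysam.AlignmentHeader, path: str
) -> str:
    mode = "wb" if path.endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for read in reads:
            out.write(read)
    return path


def tag_and_split(
    in_path: str,
    blocks: Sequence[PhaseBlock],
    out_prefix: Optional[str] = None,
    gap_threshold: int = DEFAULT_GAP_THRESHOLD,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    trust_existing_tags: bool = False,
    fmt: str = "sam",
) -> dict[Haplotype, list[pysam.AlignedSegment]]:
    """Tag one individual's alignment file and split it three ways.

    When ``out_prefix`` is given, writes ``<prefix>.hp1/.hp2/.hp0`` files
    (plus ``<prefix>.tagged``) in ``fmt`` (sam or bam); always returns
    the in-memory partition.
    """
    reads, header = read_alignments(in_path)
    tagged = assign_reads(
        reads,
        blocks,
        gap_threshold=gap_threshold,
        min_base_quality=min_base_quality,
        trust_existing_tags=trust_existing_tags,
    )
    for read, tag in tagged:
        if tag is Haplotype.HP1:
            read.set_tag(HAPLOTYPE_TAG, 1)
        elif tag is Haplotype.HP2:
            read.set_tag(HAPLOTYPE_TAG, 2)
        elif read.has_tag(HAPLOTYPE_TAG):
            read.set_tag(HAPLOTYPE_TAG, None)
    parts = split_by_tag(tagged)
    if out_prefix:
        ext = "bam" if fmt == "bam" else "sam"
        write_alignments([r for r, _ in tagged], header, f"{out_prefix}.tagged.{ext}")
        for hap, suffix in ((Haplotype.HP1, "hp1"), (Haplotype.HP2, "hp2"), (Haplotype.HP0, "hp0")):
            write_alignments(parts[hap], header, f"{out_prefix}.{suffix}.{ext}")
    counts = {h.value: len(parts[h]) for h in Haplotype}
    logger.info("tagged %s: %s", in_path, counts)
    return parts
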