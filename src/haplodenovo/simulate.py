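"""Synthetic linked-read trio simulator with full ground truth.

The simulator builds abstract allele-vector genomes (constant filler
sequence with planted variant positions), transmits one haplotype per
parent to the child, injects de novo mutations on the child haplotypes,
and injects *artifact sites*: inherited parental heterozygous variants
whose alt-bearing parental molecules suffer allele-specific coverage
dropout, so the parent is miscalled homozygous reference and the
inherited variant masquerades as a DNM.  This is the principal false
positive mechanism the haplotype-based classifier must recognise.

Long molecules are sampled per haplotype with exponential lengths and
stationary uniform starts; short reads are scattered along each molecule
to reach the target per-haplotype read depth in expectation, with
independent per-base substitution errors.  Every read records its source
molecule and haplotype in the truth set.  Phase blocks in the emitted
VCFs reflect molecule co-coverage connectivity, which is how linked-read
phasing fragments in practice.

Outputs are plain SAM and uncompressed VCF 4.2 plus tab-separated truth
tables; a fixed configuration (including seed) reproduces byte-identical
files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pysam
import yaml

from .model import Origin, Role, Sex

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_FILLER = ord("A")
READ_QUALITY = 30

SITE_KIND_HET = "inherited-het"
SITE_KIND_DNM = "dnm"
SITE_KIND_ARTIFACT = "artifact"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic trio.

    Defaults model a desk-scale linked-read experiment: a 400 kb
    contig, human-like heterozygosity (~1 het / 1.3 kb), 40 kb mean
    molecules at ~40x molecule coverage per haplotype, 8x read depth
    per haplotype, 0.5% base error, and severe (90%) allele-specific
    dropout at the injected artifact sites.
    """

    genome_length: int = 400_000
    chrom: str = "chr1"
    n_het_sites_per_individual: int = 300
    n_dnms: int = 20
    dnm_parent_split: float = 0.5  # fraction of DNMs of maternal origin
    n_artifact_sites: int = 200
    mean_molecule_length: int = 40_000
    molecules_per_haplotype: int = 440
    read_length: int = 150
    target_depth_per_haplotype: float = 8.0
    base_error_rate: float = 0.005
    dropout_severity: float = 0.9
    seed: int = 0
    x_mode: bool = False  # treat the contig as X-nonPAR
    child_sex: str = Sex.FEMALE.value
    emit_truth_tags: bool = False  # write truth HP tags into the SAM

    def __post_init__(self) -> None:
        for name in ("n_het_sites_per_individual", "n_dnms", "n_artifact_sites",
                     "molecules_per_haplotype", "genome_length", "read_length",
                     "mean_molecule_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dnm_parent_split", "base_error_rate", "dropout_severity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total_sites = (
            2 * self.n_het_sites_per_individual + self.n_dnms + self.n_artifact_sites
        )
        if total_sites > self.genome_length // 2:
            raise ValueError(
                f"{total_sites} variant sites will not fit a {self.genome_length} bp genome"
            )
        Sex(self.child_sex)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path


@dataclass
class SiteTruth:
    pos: int  # 1-based
    ref: str
    alt: str
    kind: str
    genotypes: dict  # Role -> tuple of true allele indices, haplotype order
    origin: Optional[Origin] = None  # DNMs only
    artifact_parent: Optional[Role] = None
    artifact_parent_hap: Optional[int] = None  # index of the alt-bearing haplotype


@dataclass
class MoleculeTruth:
    mol_id: int
    barcode: str
    role: Role
    hap_index: int
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    dropped_sites: list = field(default_factory=list)  # artifact positions with local dropout
    n_reads: int = 0


@dataclass
class SimRead:
    name: str
    start: int  # 0-based
    seq: str
    barcode: str
    role: Role
    hap_index: int
    mol_id: int


@dataclass
class TruthSet:
    config: SimulationConfig
    haplotypes: dict  # Role -> list[np.ndarray] (1 or 2 allele-vector genomes)
    sites: dict  # pos -> SiteTruth
    transmitted: dict  # Role(parent) -> transmitted haplotype index
    child_hap_origin: dict  # child hap index -> Role of the contributing parent
    molecules: list = field(default_factory=list)  # MoleculeTruth
    reads: list = field(default_factory=list)  # SimRead

    @property
    def dnm_positions(self) -> list[int]:
        return sorted(p for p, s in self.sites.items() if s.kind == SITE_KIND_DNM)

    @property
    def artifact_positions(self) -> list[int]:
        return sorted(p for p, s in self.sites.items() if s.kind == SITE_KIND_ARTIFACT)

    def child_het_positions(self) -> list[int]:
        out = []
        for pos, site in self.sites.items():
            gt = site.genotypes[Role.CHILD]
            if len(gt) == 2 and sorted(gt) == [0, 1]:
                out.append(pos)
        return sorted(out)


def _hap_count(role: Role, config: SimulationConfig) -> int:
    if not config.x_mode:
        return 2
    if role is Role.FATHER:
        return 1
    if role is Role.CHILD and Sex(config.child_sex) is Sex.MALE:
        return 1
    return 2


def simulate_trio_haplotypes(config: SimulationConfig) -> TruthSet:
    """Build the variant layer: parental hets, transmission, DNMs, artifacts.

    The child receives one whole haplotype from each parent (no
    recombination at this scale).  Artifact alt alleles are planted on
    the *transmitted* parental haplotype so that every artifact site is
    inherited by the child and, once the parent is miscalled hom-ref,
    passes the DNM candidate definition.  In X mode the father is
    hemizygous, a male child carries a single maternal X haplotype, and
    artifact sites are restricted to the mother.
    """
    rng = np.random.default_rng(config.seed)
    G = config.genome_length
    male_child = config.x_mode and Sex(config.child_sex) is Sex.MALE

    n_parent_het = config.n_het_sites_per_individual
    n_father_het = 0 if config.x_mode else n_parent_het  # hemizygous father has no hets
    total = n_father_het + n_parent_het + config.n_dnms + config.n_artifact_sites
    positions = rng.choice(G, size=total, replace=False) + 1  # 1-based
    positions = [int(p) for p in positions]
    father_het = positions[:n_father_het]
    mother_het = positions[n_father_het:n_father_het + n_parent_het]
    cursor = n_father_het + n_parent_het
    dnm_pos = positions[cursor:cursor + config.n_dnms]
    artifact_pos = positions[cursor + config.n_dnms:]

    haps = {
        role: [np.full(G, _FILLER, dtype=np.uint8) for _ in range(_hap_count(role, config))]
        for role in Role
    }
    ref_base: dict[int, str] = {}
    alt_base: dict[int, str] = {}

    def draw_alleles(pos: int) -> tuple[str, str]:
        ref = "A"  # filler is the reference sequence
        alt = chr(_BASES[rng.integers(1, 4)])  # C, G or T
        ref_base[pos], alt_base[pos] = ref, alt
        return ref, alt

    transmitted = {
        Role.FATHER: int(rng.integers(_hap_count(Role.FATHER, config))),
        Role.MOTHER: int(rng.integers(2)),
    }
    if male_child:
        child_hap_origin = {0: Role.MOTHER}
    else:
        child_hap_origin = {0: Role.FATHER, 1: Role.MOTHER}

    sites: dict[int, SiteTruth] = {}

    def plant_parent_het(pos: int, parent: Role, alt_hap: int, kind: str) -> SiteTruth:
        ref, alt = draw_alleles(pos)
        haps[parent][alt_hap][pos - 1] = ord(alt)
        n_haps = _hap_count(parent, config)
        parent_gt = tuple(1 if h == alt_hap else 0 for h in range(n_haps))
        other = Role.MOTHER if parent is Role.FATHER else Role.FATHER
        other_gt = tuple(0 for _ in range(_hap_count(other, config)))
        # child inherits the allele on the transmitted haplotype
        inherited = parent_gt[transmitted[parent]]
        child_gt = []
        for h, origin in sorted(child_hap_origin.items()):
            child_gt.append(inherited if origin is parent else 0)
        child_gt = tuple(child_gt)
        if inherited:
            for h, origin in child_hap_origin.items():
                if origin is parent:
                    haps[Role.CHILD][h][pos - 1] = ord(alt)
        truth = SiteTruth(
            pos=pos, ref=ref, alt=alt, kind=kind,
            genotypes={parent: parent_gt, other: other_gt, Role.CHILD: child_gt},
        )
        sites[pos] = truth
        return truth

    for pos in father_het:
        plant_parent_het(pos, Role.FATHER, int(rng.integers(2)), SITE_KIND_HET)
    for pos in mother_het:
        plant_parent_het(pos, Role.MOTHER, int(rng.integers(2)), SITE_KIND_HET)

    # artifact sites: inherited parental hets with the alt allele on the
    # transmitted haplotype (so the child carries it)
    for pos in artifact_pos:
        if config.x_mode:
            parent = Role.MOTHER
        else:
            parent = Role.FATHER if rng.integers(2) == 0 else Role.MOTHER
        truth = plant_parent_het(pos, parent, transmitted[parent], SITE_KIND_ARTIFACT)
        truth.artifact_parent = parent
        truth.artifact_parent_hap = transmitted[parent]

    # DNMs: on a child haplotype only, absent from every parental haplotype
    for pos in dnm_pos:
        ref, alt = draw_alleles(pos)
        if male_child:
            hap, origin = 0, Origin.MATERNAL
        else:
            maternal = rng.random() < config.dnm_parent_split
            hap = 1 if maternal else 0
            origin = Origin.MATERNAL if maternal else Origin.PATERNAL
        haps[Role.CHILD][hap][pos - 1] = ord(alt)
        child_gt = tuple(1 if h == hap else 0 for h in range(len(haps[Role.CHILD])))
        sites[pos] = SiteTruth(
            pos=pos, ref=ref, alt=alt, kind=SITE_KIND_DNM,
            genotypes={
                Role.FATHER: tuple(0 for _ in haps[Role.FATHER]),
                Role.MOTHER: (0, 0),
                Role.CHILD: child_gt,
            },
            origin=origin,
        )

    return TruthSet(
        config=config,
        haplotypes=haps,
        sites=sites,
        transmitted=transmitted,
        child_hap_origin=child_hap_origin,
    )


def simulate_molecules_and_reads(truth: TruthSet, config: SimulationConfig) -> TruthSet:
    """Sample barcoded molecules per haplotype and scatter reads on them.

    Molecule starts are drawn so that coverage is stationary across the
    contig; read counts per molecule are Poisson with mean chosen to hit
    the target per-haplotype read depth in expectation.  At each
    artifact site, each alt-bearing parental molecule covering the site
    suffers local dropout with probability ``dropout_severity``: its
    reads at that locus are removed while its coverage elsewhere (and
    hence its phasing evidence) is intact.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    G = config.genome_length
    mean_len = config.mean_molecule_length
    n_mol = config.molecules_per_haplotype
    read_len = config.read_length

    artifact_sites = [truth.sites[p] for p in truth.artifact_positions]

    molecules: list[MoleculeTruth] = []
    span_sum: dict[tuple[Role, int], int] = {}
    mol_id = 0
    for role in (Role.FATHER, Role.MOTHER, Role.CHILD):
        for hap_index in range(len(truth.haplotypes[role])):
            span_sum[(role, hap_index)] = 0
            lengths = rng.exponential(mean_len, size=n_mol)
            for L in lengths:
                L = max(int(L), read_len)
                start = int(rng.integers(-L + 1, G))
                s, e = max(start, 0), min(start + L, G)
                if e - s < read_len:
                    continue
                molecules.append(
                    MoleculeTruth(
                        mol_id=mol_id,
                        barcode=f"BC{mol_id:07d}-1",
                        role=role,
                        hap_index=hap_index,
                        start=s,
                        end=e,
                    )
                )
                span_sum[(role, hap_index)] += e - s
                mol_id += 1

    # per-molecule read density calibrated on the realised spans so that
    # mean read depth over the contig equals the target in expectation
    reads_per_bp = {
        key: (config.target_depth_per_haplotype * G / (total * read_len) if total else 0.0)
        for key, total in span_sum.items()
    }

    # allele-specific coverage dropout: each alt-bearing parental molecule
    # loses its reads AT the artifact locus with probability
    # dropout_severity (local coverage failure of one allele, the
    # mechanism that makes a diploid caller miss the parental het);
    # the molecule's coverage elsewhere is unaffected
    for site in artifact_sites:
        parent, hap = site.artifact_parent, site.artifact_parent_hap
        pos0 = site.pos - 1
        for mol in molecules:
            if (
                mol.role is parent
                and mol.hap_index == hap
                and mol.start <= pos0 < mol.end
                and rng.random() < config.dropout_severity
            ):
                mol.dropped_sites.append(site.pos)

    reads: list[SimRead] = []
    err = config.base_error_rate
    for mol in molecules:
        span = mol.end - mol.start
        n_reads = int(rng.poisson(span * reads_per_bp[(mol.role, mol.hap_index)]))
        if n_reads == 0:
            continue
        hap_arr = truth.haplotypes[mol.role][mol.hap_index]
        starts = np.sort(rng.integers(mol.start, mol.end - read_len + 1, size=n_reads))
        kept = 0
        for i, rstart in enumerate(starts):
            rstart = int(rstart)
            if any(rstart <= p - 1 < rstart + read_len for p in mol.dropped_sites):
                continue
            seq = hap_arr[rstart:rstart + read_len].copy()
            if err > 0:
                k = rng.binomial(read_len, err)
                if k:
                    idx = rng.choice(read_len, size=k, replace=False)
                    shift = rng.integers(1, 4, size=k)
                    base_idx = np.searchsorted(_BASES, seq[idx])
                    seq[idx] = _BASES[(base_idx + shift) % 4]
            reads.append(
                SimRead(
                    name=f"{mol.role.value}_m{mol.mol_id}_r{i}",
                    start=rstart,
                    seq=seq.tobytes().decode(),
                    barcode=mol.barcode,
                    role=mol.role,
                    hap_index=mol.hap_index,
                    mol_id=mol.mol_id,
                )
            )
            kept += 1
        mol.n_reads = kept

    truth.molecules = molecules
    truth.reads = reads
    return truth


def derive_phase_blocks(truth: TruthSet, role: Role) -> dict[int, int]:
    """Map each het position of ``role`` to a phase-set ID via molecule
    connectivity: het sites co-covered by a (surviving) molecule share a
    block; the block ID is its smallest member position.

    Artifact sites are excluded from the *parent's* own phased VCF --
    the dropout made the caller miss them -- but remain ordinary phased
    hets in the child.
    """
    het_positions = []
    for pos, site in truth.sites.items():
        gt = site.genotypes[role]
        if len(gt) == 2 and sorted(gt) == [0, 1]:
            if role is not Role.CHILD and site.kind == SITE_KIND_ARTIFACT:
                continue
            het_positions.append(pos)
    het_positions.sort()
    if not het_positions:
        return {}
    parent = list(range(len(het_positions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    import bisect

    for mol in truth.molecules:
        if mol.role is not role or mol.n_reads == 0:
            continue
        lo = bisect.bisect_left(het_positions, mol.start + 1)
        hi = bisect.bisect_right(het_positions, mol.end)
        for i in range(lo + 1, hi):
            union(i - 1, i)

    return {pos: het_positions[find(i)] for i, pos in enumerate(het_positions)}


def _vcf_header(config: SimulationConfig, samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    header.contigs.add(config.chrom, length=config.genome_length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set identifier")
    for s in samples:
        header.add_sample(s)
    return header


SAMPLE_NAMES = {Role.FATHER: "FATHER", Role.MOTHER: "MOTHER", Role.CHILD: "CHILD"}


def _observed_genotype(site: SiteTruth, role: Role) -> tuple[int, ...]:
    """The genotype an upstream diploid caller reports: truth everywhere,
    except that dropout hides the artifact parent's alt allele."""
    if site.kind == SITE_KIND_ARTIFACT and role is site.artifact_parent:
        return tuple(0 for _ in site.genotypes[role])
    return site.genotypes[role]


def emit_standard_files(truth: TruthSet, out_dir: str) -> dict[str, str]:
    """Write VCFs, SAM alignments and truth tables; return path map.

    Files: ``trio.vcf`` (unphased multi-sample calls, the candidate
    source), ``{father,mother,child}.phased.vcf`` (per-individual phased
    hets with PS from molecule connectivity; singleton blocks are left
    unphased), ``{role}.sam`` (coordinate-sorted barcoded reads),
    ``dnm_truth.tsv``, ``artifact_truth.tsv``, ``molecules.tsv`` and
    ``sim_config.yaml``.
    """
    os.makedirs(out_dir, exist_ok=True)
    config = truth.config
    paths: dict[str, str] = {}

    # multi-sample (observed) trio VCF
    trio_path = os.path.join(out_dir, "trio.vcf")
    header = _vcf_header(config, [SAMPLE_NAMES[r] for r in Role])
    with pysam.VariantFile(trio_path, "w", header=header) as vcf:
        for pos in sorted(truth.sites):
            site = truth.sites[pos]
            rec = vcf.new_record(
                contig=config.chrom, start=pos - 1, alleles=(site.ref, site.alt)
            )
            for role in Role:
                rec.samples[SAMPLE_NAMES[role]]["GT"] = _observed_genotype(site, role)
            vcf.write(rec)
    paths["trio_vcf"] = trio_path

    # per-individual phased VCFs
    for role in Role:
        blocks = derive_phase_blocks(truth, role)
        path = os.path.join(out_dir, f"{role.value}.phased.vcf")
        header = _vcf_header(config, [SAMPLE_NAMES[role]])
        block_sizes: dict[int, int] = {}
        for ps in blocks.values():
            block_sizes[ps] = block_sizes.get(ps, 0) + 1
        with pysam.VariantFile(path, "w", header=header) as vcf:
            for pos in sorted(truth.sites):
                site = truth.sites[pos]
                gt = _observed_genotype(site, role)
                if not any(gt):
                    continue  # hom-ref sites are not emitted by a caller
                rec = vcf.new_record(
                    contig=config.chrom, start=pos - 1, alleles=(site.ref, site.alt)
                )
                fmt = rec.samples[SAMPLE_NAMES[role]]
                fmt["GT"] = gt
                if pos in blocks and block_sizes[blocks[pos]] > 1:
                    fmt.phased = True
                    fmt["PS"] = blocks[pos]
                vcf.write(rec)
        paths[f"{role.value}_phased_vcf"] = path

    # alignments
    for role in Role:
        path = os.path.join(out_dir, f"{role.value}.sam")
        sam_header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": "coordinate"},
                "SQ": [{"SN": config.chrom, "LN": config.genome_length}],
            }
        )
        role_reads = sorted(
            (r for r in truth.reads if r.role is role), key=lambda r: (r.start, r.name)
        )
        with pysam.AlignmentFile(path, "w", header=sam_header) as sam:
            for r in role_reads:
                seg = pysam.AlignedSegment(sam_header)
                seg.query_name = r.name
                seg.flag = 0
                seg.reference_id = 0
                seg.reference_start = r.start
                seg.mapping_quality = 60
                seg.cigarstring = f"{len(r.seq)}M"
                seg.query_sequence = r.seq
                seg.query_qualities = pysam.qualitystring_to_array(
                    chr(READ_QUALITY + 33) * len(r.seq)
                )
                seg.set_tag("BX", r.barcode)
                if config.emit_truth_tags:
                    seg.set_tag("HP", r.hap_index + 1)
                sam.write(seg)
        paths[f"{role.value}_sam"] = path

    # truth tables
    import csv

    dnm_path = os.path.join(out_dir, "dnm_truth.tsv")
    with open(dnm_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref", "alt", "parent_of_origin", "child_hap"])
        for pos in truth.dnm_positions:
            site = truth.sites[pos]
            hap = site.genotypes[Role.CHILD].index(1) + 1
            w.writerow([config.chrom, pos, site.ref, site.alt, site.origin.value, f"HP{hap}"])
    paths["dnm_truth"] = dnm_path

    art_path = os.path.join(out_dir, "artifact_truth.tsv")
    with open(art_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "pos", "ref", "alt", "parent", "parent_hap", "true_parent_gt"])
        for pos in truth.artifact_positions:
            site = truth.sites[pos]
            gt = "/".join(str(a) for a in site.genotypes[site.artifact_parent])
            w.writerow([
                config.chrom, pos, site.ref, site.alt,
                site.artifact_parent.value, f"HP{site.artifact_parent_hap + 1}", gt,
            ])
    paths["artifact_truth"] = art_path

    mol_path = os.path.join(out_dir, "molecules.tsv")
    with open(mol_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["barcode", "individual", "haplotype", "start", "end", "n_reads", "n_dropout_sites"])
        for mol in truth.molecules:
            w.writerow([
                mol.barcode, mol.role.value, f"HP{mol.hap_index + 1}",
                mol.start, mol.end, mol.n_reads, len(mol.dropped_sites),
            ])
    paths["molecules"] = mol_path

    paths["config"] = config.to_yaml(os.path.join(out_dir, "sim_config.yaml"))
    return paths


def simulate(config: SimulationConfig, out_dir: Optional[str] = None) -> tuple[TruthSet, dict]:
    """Run the full simulation; optionally emit the standard files."""
    truth = simulate_trio_haplotypes(config)
    truth = simulate_molecules_and_reads(truth, config)
    paths = emit_standard_files(truth, out_dir) if out_dir else {}
    return truth, paths
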