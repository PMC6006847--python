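"""End-to-end trio DNM filtering pipeline.

Chains the stages: merge per-individual phased VCFs -> extract candidate
DNMs (optionally from an external caller's multi-sample VCF, with score
thresholds) -> group barcoded reads into molecules and tag haplotypes ->
per-haplotype pileup and haploid genotyping at candidate sites ->
classify each candidate H / L / REMOVED -> infer parent-of-origin ->
write the flat-file report plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from . import __version__
from .dnm_classifier import (
    DEFAULT_PAR_REGIONS,
    chrom_class_of,
    classify_dnm,
    infer_parent_of_origin,
    load_par_bed,
    write_report,
)
from .haploid_genotyping import (
    DEFAULT_MIN_DEPTH,
    DEFAULT_MIN_MINOR_COUNT,
    DEFAULT_MIN_MINOR_FRACTION,
    call_haploid_genotype,
    pileup_at_sites,
    write_pileup_table,
)
from .haplotype_assignment import (
    DEFAULT_GAP_THRESHOLD,
    DEFAULT_MIN_BASE_QUALITY,
    build_phase_blocks,
    read_alignments,
    assign_reads,
    split_by_tag,
)
from .model import (
    ChromClass,
    DNMClassification,
    Haplotype,
    HaploidCall,
    NOT_APPLICABLE,
    Origin,
    Role,
    Sex,
    TrioHaploidProfile,
    TrioVariantRecord,
)
from .variant_io import (
    apply_score_threshold,
    extract_candidate_dnms,
    merge_phased_vcfs,
    read_trio_vcf,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPPING_QUALITY = 20


@dataclass
class PipelineConfig:
    father_phased_vcf: str = ""
    mother_phased_vcf: str = ""
    child_phased_vcf: str = ""
    father_bam: str = ""
    mother_bam: str = ""
    child_bam: str = ""
    out_prefix: str = "haplodenovo"
    candidates_vcf: Optional[str] = None
    candidate_roles: Optional[dict] = None  # sample name -> role for candidates_vcf
    min_depth: int = DEFAULT_MIN_DEPTH
    min_minor_count: int = DEFAULT_MIN_MINOR_COUNT
    min_minor_fraction: float = DEFAULT_MIN_MINOR_FRACTION
    gap_threshold: int = DEFAULT_GAP_THRESHOLD
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY
    min_mapping_quality: int = DEFAULT_MIN_MAPPING_QUALITY
    child_sex: Optional[str] = None
    par_bed: Optional[str] = None
    score_filters: list = field(default_factory=list)  # (label, threshold, direction)
    trust_existing_tags: bool = False
    per_read_vote: bool = False
    write_intermediates: bool = False


@dataclass
class PipelineResult:
    classifications: list
    report_path: str
    removed_path: str
    manifest_path: str
    candidates: list = field(default_factory=list)


def _md5(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _site_key(site) -> tuple:
    return (site.chrom, site.pos, site.ref, site.alt)


def build_profiles(
    candidates: Sequence[TrioVariantRecord],
    haploid_calls: dict,
    combined_calls: dict,
    hp0_columns: dict,
    merged_by_key: dict,
    child_sex: Optional[Sex],
    par_regions,
) -> list[TrioHaploidProfile]:
    """Assemble one TrioHaploidProfile per candidate.

    ``haploid_calls[(role, haplotype)]`` maps candidate index -> HaploidCall;
    ``combined_calls[role]`` holds the all-reads haploid call used for
    naturally phased X haplotypes; ``hp0_columns`` holds the child's HP0
    pileup columns for the rescue annotation.
    """
    profiles = []
    for i, rec in enumerate(candidates):
        cclass = chrom_class_of(rec.site.chrom, rec.site.pos, par_regions)
        merged = merged_by_key.get(_site_key(rec.site))
        child_call = merged.child if merged is not None else rec.child
        diploid_phased = bool(child_call.phased and child_call.phase_set)

        if cclass is ChromClass.X_NONPAR:
            father_hp1 = combined_calls[Role.FATHER][i]
            father_hp2 = NOT_APPLICABLE
            if child_sex is Sex.MALE:
                child_hp1, child_hp2 = combined_calls[Role.CHILD][i], NOT_APPLICABLE
                phased = True  # hemizygous: naturally phased
            else:
                child_hp1 = haploid_calls[(Role.CHILD, Haplotype.HP1)][i]
                child_hp2 = haploid_calls[(Role.CHILD, Haplotype.HP2)][i]
                phased = diploid_phased
        else:
            father_hp1 = haploid_calls[(Role.FATHER, Haplotype.HP1)][i]
            father_hp2 = haploid_calls[(Role.FATHER, Haplotype.HP2)][i]
            child_hp1 = haploid_calls[(Role.CHILD, Haplotype.HP1)][i]
            child_hp2 = haploid_calls[(Role.CHILD, Haplotype.HP2)][i]
            phased = diploid_phased

        alt_hap = None
        if phased:
            states = (child_hp1.state.value, child_hp2.state.value)
            if states == ("REF", "ALT"):
                alt_hap = Haplotype.HP2
            elif states == ("ALT", "REF"):
                alt_hap = Haplotype.HP1
            elif cclass is ChromClass.X_NONPAR and child_sex is Sex.MALE:
                alt_hap = Haplotype.HP1 if child_hp1.state.value == "ALT" else None

        hp0_col = hp0_columns.get(i)
        hp0_support = bool(hp0_col and hp0_col.ref_count >= 1 and hp0_col.alt_count >= 1)

        profiles.append(
            TrioHaploidProfile(
                site=rec.site,
                father_hp1=father_hp1,
                father_hp2=father_hp2,
                mother_hp1=haploid_calls[(Role.MOTHER, Haplotype.HP1)][i],
                mother_hp2=haploid_calls[(Role.MOTHER, Haplotype.HP2)][i],
                child_hp1=child_hp1,
                child_hp2=child_hp2,
                child_phased=phased,
                child_alt_haplotype=alt_hap,
                hp0_supports_candidate=hp0_support,
                chrom_class=cclass,
                child_sex=child_sex,
            )
        )
    return profiles


def _origin_for(
    profile: TrioHaploidProfile,
    child_call,
    child_blocks: dict,
    records: Sequence[TrioVariantRecord],
    missing_parent_is_hom_ref: bool,
) -> Origin:
    if profile.chrom_class is ChromClass.X_NONPAR and profile.child_sex is Sex.MALE:
        return Origin.MATERNAL  # a male's X haplotype is maternal by construction
    if profile.child_alt_haplotype is None or not child_call.phase_set:
        return Origin.UNKNOWN
    block = child_blocks.get((profile.site.chrom, child_call.phase_set))
    if block is None:
        return Origin.UNKNOWN
    return infer_parent_of_origin(
        block,
        profile.child_alt_haplotype,
        records,
        dnm_pos=profile.site.pos,
        missing_parent_is_hom_ref=missing_parent_is_hom_ref,
    )


def run_full(config: PipelineConfig) -> PipelineResult:
    """Execute the whole workflow and write the report files."""
    child_sex = Sex(config.child_sex) if config.child_sex else None
    par_regions = load_par_bed(config.par_bed) if config.par_bed else DEFAULT_PAR_REGIONS

    # step 1: merge individual phased VCFs; build per-individual phase blocks
    merged = list(
        merge_phased_vcfs(
            config.father_phased_vcf, config.mother_phased_vcf, config.child_phased_vcf
        )
    )
    blocks = build_phase_blocks(merged)
    merged_by_key = {_site_key(rec.site): rec for rec in merged}
    child_blocks = {(b.chrom, b.block_id): b for b in blocks[Role.CHILD]}

    # candidate extraction (external caller VCF, or the merged calls)
    score_label = config.score_filters[0][0] if config.score_filters else None
    if config.candidates_vcf:
        roles = config.candidate_roles or {
            "FATHER": Role.FATHER, "MOTHER": Role.MOTHER, "CHILD": Role.CHILD
        }
        source = list(
            read_trio_vcf(config.candidates_vcf, roles, score_label=score_label)
        )
    else:
        source = merged
    candidates = extract_candidate_dnms(source)
    for label, threshold, direction in config.score_filters:
        candidates = apply_score_threshold(candidates, label, threshold, direction)
    logger.info("%d candidate DNM(s) after extraction and thresholds", len(candidates))

    # step 2: molecule grouping, haplotype tagging, partitioning, pileups
    sites = [rec.site for rec in candidates]
    bam_of = {
        Role.FATHER: config.father_bam,
        Role.MOTHER: config.mother_bam,
        Role.CHILD: config.child_bam,
    }
    need_combined = {
        role
        for role in (Role.FATHER, Role.CHILD)
        for rec in candidates
        if chrom_class_of(rec.site.chrom, rec.site.pos, par_regions) is ChromClass.X_NONPAR
        and (role is Role.FATHER or child_sex is Sex.MALE)
    }

    haploid_calls: dict = {}
    combined_calls: dict = {}
    hp0_child_columns: dict = {}
    all_columns = []
    for role in Role:
        reads, _header = read_alignments(bam_of[role])
        tagged = assign_reads(
            reads,
            blocks[role],
            gap_threshold=config.gap_threshold,
            min_base_quality=config.min_base_quality,
            per_read=config.per_read_vote,
            trust_existing_tags=config.trust_existing_tags,
        )
        parts = split_by_tag(tagged)
        logger.info(
            "%s: reads tagged HP1/HP2/HP0 = %d/%d/%d",
            role.value,
            len(parts[Haplotype.HP1]),
            len(parts[Haplotype.HP2]),
            len(parts[Haplotype.HP0]),
        )
        for hap in Haplotype:
            columns = pileup_at_sites(
                parts[hap],
                sites,
                owner=role,
                haplotype=hap,
                min_base_quality=config.min_base_quality,
                min_mapping_quality=config.min_mapping_quality,
            )
            all_columns.extend(columns)
            calls = {
                i: call_haploid_genotype(
                    col,
                    min_depth=config.min_depth,
                    min_minor_count=config.min_minor_count,
                    min_minor_fraction=config.min_minor_fraction,
                )
                for i, col in enumerate(columns)
            }
            haploid_calls[(role, hap)] = calls
            if role is Role.CHILD and hap is Haplotype.HP0:
                hp0_child_columns = dict(enumerate(columns))
        if role in need_combined:
            columns = pileup_at_sites(
                reads,
                sites,
                owner=role,
                haplotype=Haplotype.HP0,
                min_base_quality=config.min_base_quality,
                min_mapping_quality=config.min_mapping_quality,
            )
            combined_calls[role] = {
                i: call_haploid_genotype(
                    col,
                    min_depth=config.min_depth,
                    min_minor_count=config.min_minor_count,
                    min_minor_fraction=config.min_minor_fraction,
                )
                for i, col in enumerate(columns)
            }
    if config.write_intermediates:
        write_pileup_table(all_columns, f"{config.out_prefix}.pileup.tsv")

    # step 3: profile assembly, classification, parent-of-origin, report
    profiles = build_profiles(
        candidates,
        haploid_calls,
        combined_calls,
        hp0_child_columns,
        merged_by_key,
        child_sex,
        par_regions,
    )
    classifications: list[DNMClassification] = []
    # transmission votes read parental genotypes from the multi-sample
    # candidate VCF when one was given (explicit 0/0 calls); with only
    # per-individual VCFs, an absent parental record means "no variant"
    origin_records = source
    missing_is_hom_ref = config.candidates_vcf is None
    for rec, profile in zip(candidates, profiles):
        merged_rec = merged_by_key.get(_site_key(rec.site))
        child_call = merged_rec.child if merged_rec is not None else rec.child
        origin = _origin_for(
            profile, child_call, child_blocks, origin_records, missing_is_hom_ref
        )
        classifications.append(classify_dnm(profile, parent_of_origin=origin))

    report_path, removed_path = write_report(classifications, config.out_prefix)
    manifest_path = f"{config.out_prefix}.manifest.json"
    inputs = {
        name: {"path": path, "md5": _md5(path)}
        for name, path in (
            ("father_phased_vcf", config.father_phased_vcf),
            ("mother_phased_vcf", config.mother_phased_vcf),
            ("child_phased_vcf", config.child_phased_vcf),
            ("father_bam", config.father_bam),
            ("mother_bam", config.mother_bam),
            ("child_bam", config.child_bam),
            ("candidates_vcf", config.candidates_vcf),
        )
        if path
    }
    label_counts: dict[str, int] = {}
    for cls in classifications:
        label_counts[cls.label.value] = label_counts.get(cls.label.value, 0) + 1
    with open(manifest_path, "w") as fh:
        json.dump(
            {
                "tool": "haplodenovo",
                "version": __version__,
                "parameters": asdict(config),
                "inputs": inputs,
                "n_candidates": len(candidates),
                "labels": label_counts,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return PipelineResult(
        classifications=classifications,
        report_path=report_path,
        removed_path=removed_path,
        manifest_path=manifest_path,
        candidates=list(candidates),
    )
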