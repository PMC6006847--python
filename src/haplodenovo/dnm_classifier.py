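"""Classify candidate DNMs from the trio's haploid genotypes.

A candidate (parents hom-ref, child het in the diploid calls) is judged
against the six haploid calls of the trio:

* **H** (high-confidence): all six haploids callable, all four parental
  haploids REF, child haploids exactly one REF and one ALT, and the
  child's variant phased.
* **REMOVED**: any parental haploid ALT, any haploid CONFLICT, or the
  child's haploids callable but not one REF + one ALT — positive
  evidence that the candidate is an inherited variant or artifact.
* **L** (low-confidence): a required haplotype lacks coverage (or the
  child is unphased) with no disqualifying evidence among the covered
  haplotypes; kept for further consideration.

On the X chromosome outside the pseudoautosomal regions a male's X is
naturally phased: the father contributes one haploid (five-haploid rule
for a female child) and a male child contributes a single X haploid
judged against the mother's two (two-haploid rule).  PAR sites follow
the autosomal rules.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (
    GenotypeCall,
    REASON_CHILD_NOT_01,
    REASON_CONFLICT,
    REASON_PARENTAL_ALT,
    REASON_UNCOVERED,
    REASON_UNPHASED,
    ChromClass,
    DNMClassification,
    Haplotype,
    HaploidCall,
    HaploidState,
    Label,
    Origin,
    PhaseBlock,
    Sex,
    TrioHaploidProfile,
    TrioVariantRecord,
)

logger = logging.getLogger(__name__)

# hg19 X pseudoautosomal regions, 1-based inclusive
DEFAULT_PAR_REGIONS = (("chrX", 60_001, 2_699_520), ("chrX", 154_931_044, 155_260_560))
X_NAMES = frozenset({"X", "chrX"})

_CALLABLE = (HaploidState.REF, HaploidState.ALT)


def load_par_bed(path: str) -> tuple[tuple[str, int, int], ...]:
    """Read PAR intervals from a BED file (0-based half-open on disk)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            regions.append((chrom, int(start) + 1, int(end)))
    return tuple(regions)


def in_par(chrom: str, pos: int, par_regions: Sequence[tuple[str, int, int]]) -> bool:
    return any(c == chrom and s <= pos <= e for c, s, e in par_regions)


def chrom_class_of(
    chrom: str,
    pos: int,
    par_regions: Sequence[tuple[str, int, int]] = DEFAULT_PAR_REGIONS,
) -> ChromClass:
    """Autosomal rules everywhere except X outside the PARs."""
    if chrom in X_NAMES and not in_par(chrom, pos, par_regions):
        return ChromClass.X_NONPAR
    return ChromClass.AUTOSOMAL


def classify_site_confidence(profile: TrioHaploidProfile) -> bool:
    """True iff all six haploid calls are callable (REF or ALT)."""
    return all(
        call.state in _CALLABLE
        for call in (
            profile.father_hp1,
            profile.father_hp2,
            profile.mother_hp1,
            profile.mother_hp2,
            profile.child_hp1,
            profile.child_hp2,
        )
    )


def _classify_haploid_set(
    site,
    parental: Sequence[HaploidCall],
    child: Sequence[HaploidCall],
    phased: bool,
    parent_of_origin: Origin = Origin.UNKNOWN,
    profile: Optional[TrioHaploidProfile] = None,
) -> DNMClassification:
    """Shared H/L/REMOVED logic over an applicable haploid set.

    ``child`` holds one haploid (male X) or two; a single child haploid
    must be ALT, a pair must be exactly one REF and one ALT.  Reason
    codes follow a fixed precedence so reporting is deterministic.
    """
    states = [c.state for c in parental] + [c.state for c in child]
    if any(c.state is HaploidState.ALT for c in parental):
        return DNMClassification(site, Label.REMOVED, parent_of_origin, REASON_PARENTAL_ALT, profile)
    if HaploidState.CONFLICT in states:
        return DNMClassification(site, Label.REMOVED, parent_of_origin, REASON_CONFLICT, profile)
    child_states = [c.state for c in child]
    if all(s in _CALLABLE for s in child_states):
        wanted = [HaploidState.ALT] if len(child) == 1 else [HaploidState.ALT, HaploidState.REF]
        if sorted(child_states, key=lambda s: s.value) != wanted:
            return DNMClassification(site, Label.REMOVED, parent_of_origin, REASON_CHILD_NOT_01, profile)
    if HaploidState.UNCOVERED in states:
        return DNMClassification(site, Label.LOW, parent_of_origin, REASON_UNCOVERED, profile)
    if not phased:
        # absence of phasing is missing information, not counter-evidence
        return DNMClassification(site, Label.LOW, parent_of_origin, REASON_UNPHASED, profile)
    return DNMClassification(site, Label.HIGH, parent_of_origin, "", profile)


def classify_autosomal_dnm(
    profile: TrioHaploidProfile, parent_of_origin: Origin = Origin.UNKNOWN
) -> DNMClassification:
    """Apply the six-haploid rule to an autosomal (or PAR) candidate."""
    return _classify_haploid_set(
        profile.site,
        parental=[profile.father_hp1, profile.father_hp2, profile.mother_hp1, profile.mother_hp2],
        child=[profile.child_hp1, profile.child_hp2],
        phased=profile.child_phased,
        parent_of_origin=parent_of_origin,
        profile=profile,
    )


def classify_chrX_dnm(
    profile: TrioHaploidProfile, parent_of_origin: Origin = Origin.UNKNOWN
) -> DNMClassification:
    """Apply the X-nonPAR rules (five haploids for a female child, two
    applicable parental-side haploids plus one child haploid for a male).

    The father's X haploid sits in ``father_hp1``; a male child's single
    X haploid sits in ``child_hp1``.  Hemizygous haploids are naturally
    phased, so a male child needs no separate phasing condition.
    """
    if profile.child_sex is None:
        raise ValueError(f"child sex required for X-nonPAR site {profile.site}")
    if profile.child_sex is Sex.FEMALE:
        return _classify_haploid_set(
            profile.site,
            parental=[profile.father_hp1, profile.mother_hp1, profile.mother_hp2],
            child=[profile.child_hp1, profile.child_hp2],
            phased=profile.child_phased,
            parent_of_origin=parent_of_origin,
            profile=profile,
        )
    # male child: only the mother's and the child's X haploids are considered
    return _classify_haploid_set(
        profile.site,
        parental=[profile.mother_hp1, profile.mother_hp2],
        child=[profile.child_hp1],
        phased=True,
        parent_of_origin=parent_of_origin,
        profile=profile,
    )


def classify_dnm(
    profile: TrioHaploidProfile, parent_of_origin: Origin = Origin.UNKNOWN
) -> DNMClassification:
    """Route a candidate to the autosomal or X-nonPAR classifier."""
    if profile.chrom_class is ChromClass.X_NONPAR:
        return classify_chrX_dnm(profile, parent_of_origin)
    return classify_autosomal_dnm(profile, parent_of_origin)


def infer_parent_of_origin(
    child_block: PhaseBlock,
    dnm_haplotype: Haplotype,
    trio_records: Iterable[TrioVariantRecord],
    dnm_pos: Optional[int] = None,
    missing_parent_is_hom_ref: bool = False,
) -> Origin:
    """Vote on which parent transmitted the DNM-bearing child haplotype.

    Each phased het site in the child's block where the allele carried by
    the DNM-bearing haplotype could have been transmitted by exactly one
    parent (only that parent carries it) casts one vote.  The majority
    decides; a tie or zero informative sites returns unknown.

    ``missing_parent_is_hom_ref`` treats an absent parental genotype as
    homozygous reference -- appropriate when the records come from a
    union of per-individual VCFs, where an uncalled site means "no
    variant" rather than "no data".
    """
    if dnm_haplotype not in (Haplotype.HP1, Haplotype.HP2):
        return Origin.UNKNOWN
    site_by_pos = {s.pos: s for s in child_block.sites}
    maternal = paternal = 0
    for rec in trio_records:
        pos = rec.site.pos
        if pos == dnm_pos or pos not in site_by_pos or rec.site.chrom != child_block.chrom:
            continue
        block_site = site_by_pos[pos]
        if rec.site.ref != block_site.ref or rec.site.alt != block_site.alt:
            continue
        allele = block_site.hap1 if dnm_haplotype is Haplotype.HP1 else block_site.hap2
        father, mother = rec.father, rec.mother
        if father.is_missing or mother.is_missing:
            if not missing_parent_is_hom_ref:
                continue
            if father.is_missing:
                father = GenotypeCall(alleles=(0, 0))
            if mother.is_missing:
                mother = GenotypeCall(alleles=(0, 0))
        father_has = father.carries(allele)
        mother_has = mother.carries(allele)
        if father_has and not mother_has:
            paternal += 1
        elif mother_has and not father_has:
            maternal += 1
    if maternal > paternal:
        return Origin.MATERNAL
    if paternal > maternal:
        return Origin.PATERNAL
    return Origin.UNKNOWN


def read_profile_table(path: str, child_sex: Optional[Sex] = None) -> list[TrioHaploidProfile]:
    """Parse a haploid-profile TSV into TrioHaploidProfiles.

    Expected columns: chrom, pos, ref, alt, father_hp1, father_hp2,
    mother_hp1, mother_hp2, child_hp1, child_hp2 (states REF / ALT /
    CONFLICT / UNCOVERED, or "." for not-applicable haploids on
    X-nonPAR), child_phased (0/1).  Optional: depth_<haploid> columns
    (default 2 for callable states, 0 for UNCOVERED), chrom_class,
    child_sex.  This is the entry point for hand-curated profiles or
    tables exported from another run.
    """
    from .model import NOT_APPLICABLE, VariantSite

    df = pd.read_csv(path, sep="\t", dtype=str)
    profiles = []
    for _, row in df.iterrows():
        calls = {}
        for name, _attr in _STATE_COLUMNS:
            raw = str(row[name]).strip()
            if raw == ".":
                calls[name] = NOT_APPLICABLE
                continue
            state = HaploidState(raw)
            depth_col = f"depth_{name}"
            if depth_col in df.columns and str(row[depth_col]).strip() not in (".", "nan"):
                depth = int(row[depth_col])
            else:
                depth = 0 if state is HaploidState.UNCOVERED else 2
            calls[name] = HaploidCall(state, depth)
        cclass = (
            ChromClass(row["chrom_class"])
            if "chrom_class" in df.columns
            else chrom_class_of(str(row["chrom"]), int(row["pos"]))
        )
        sex = Sex(row["child_sex"]) if "child_sex" in df.columns else child_sex
        phased = bool(int(row["child_phased"]))
        alt_hap = None
        if phased:
            pair = (calls["child_hp1"].state, calls["child_hp2"].state)
            if pair == (HaploidState.REF, HaploidState.ALT):
                alt_hap = Haplotype.HP2
            elif pair == (HaploidState.ALT, HaploidState.REF):
                alt_hap = Haplotype.HP1
        profiles.append(
            TrioHaploidProfile(
                site=VariantSite(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"])),
                father_hp1=calls["father_hp1"],
                father_hp2=calls["father_hp2"],
                mother_hp1=calls["mother_hp1"],
                mother_hp2=calls["mother_hp2"],
                child_hp1=calls["child_hp1"],
                child_hp2=calls["child_hp2"],
                child_phased=phased,
                child_alt_haplotype=alt_hap,
                chrom_class=cclass,
                child_sex=sex,
            )
        )
    return profiles


_STATE_COLUMNS = [
    ("father_hp1", "father_hp1"),
    ("father_hp2", "father_hp2"),
    ("mother_hp1", "mother_hp1"),
    ("mother_hp2", "mother_hp2"),
    ("child_hp1", "child_hp1"),
    ("child_hp2", "child_hp2"),
]

REPORT_COLUMNS = (
    ["chrom", "pos", "ref", "alt", "label", "parent_of_origin"]
    + [name for name, _ in _STATE_COLUMNS]
    + [f"depth_{name}" for name, _ in _STATE_COLUMNS]
    + ["hp0_support", "reason"]
)


def _rows(classifications: Iterable[DNMClassification]) -> list[dict]:
    rows = []
    for cls in classifications:
        row = {
            "chrom": cls.site.chrom,
            "pos": cls.site.pos,
            "ref": cls.site.ref,
            "alt": cls.site.alt,
            "label": cls.label.value,
            "parent_of_origin": cls.parent_of_origin.value,
            "hp0_support": int(cls.profile.hp0_supports_candidate) if cls.profile else 0,
            "reason": cls.reason or ".",
        }
        for name, attr in _STATE_COLUMNS:
            call = getattr(cls.profile, attr) if cls.profile else None
            if call is None or call.depth < 0:
                row[name], row[f"depth_{name}"] = ".", "."
            else:
                row[name], row[f"depth_{name}"] = call.state.value, call.depth
        rows.append(row)
    return rows


def write_report(
    classifications: Sequence[DNMClassification],
    prefix: str,
) -> tuple[str, str]:
    """Write ``<prefix>.dnm.tsv`` (H and L rows) and ``<prefix>.removed.tsv``.

    The main flat file carries only retained candidates annotated H or
    L; removed candidates go to the companion audit file with their
    reason codes.
    """
    main = [c for c in classifications if c.label is not Label.REMOVED]
    removed = [c for c in classifications if c.label is Label.REMOVED]
    main_path, removed_path = f"{prefix}.dnm.tsv", f"{prefix}.removed.tsv"
    pd.DataFrame(_rows(main), columns=REPORT_COLUMNS).to_csv(main_path, sep="\t", index=False)
    pd.DataFrame(_rows(removed), columns=REPORT_COLUMNS).to_csv(removed_path, sep="\t", index=False)
    tally = {label.value: 0 for label in Label}
    for c in classifications:
        tally[c.label.value] += 1
    logger.info("classification tally: %s", tally)
    return main_path, removed_path
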