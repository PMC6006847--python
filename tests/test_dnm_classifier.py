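"""H / L / REMOVED classification, X rules, parent-of-origin, reporting."""

import itertools

import pandas as pd
import pytest

from haplodenovo.dnm_classifier import (
    chrom_class_of,
    classify_autosomal_dnm,
    classify_chrX_dnm,
    classify_dnm,
    classify_site_confidence,
    infer_parent_of_origin,
    read_profile_table,
    write_report,
)
from haplodenovo.model import (
    ChromClass,
    GenotypeCall,
    Haplotype,
    HaploidCall,
    HaploidState,
    Label,
    NOT_APPLICABLE,
    Origin,
    PhaseBlock,
    PhasedHetSite,
    Role,
    Sex,
    TrioHaploidProfile,
    TrioVariantRecord,
    VariantSite,
)

S = HaploidState
SITE = VariantSite("chr1", 1000, "A", "G")
X_SITE = VariantSite("chrX", 5_000_000, "A", "G")  # outside both PARs


def _call(state):
    return HaploidCall(state, 0 if state is S.UNCOVERED else 5)


def _profile(f1, f2, m1, m2, c1, c2, phased, site=SITE,
             chrom_class=ChromClass.AUTOSOMAL, sex=None):
    alt_hap = None
    if phased and (c1, c2) == (S.REF, S.ALT):
        alt_hap = Haplotype.HP2
    elif phased and (c1, c2) == (S.ALT, S.REF):
        alt_hap = Haplotype.HP1
    return TrioHaploidProfile(
        site=site,
        father_hp1=_call(f1), father_hp2=_call(f2),
        mother_hp1=_call(m1), mother_hp2=_call(m2),
        child_hp1=_call(c1), child_hp2=_call(c2),
        child_phased=phased, child_alt_haplotype=alt_hap,
        chrom_class=chrom_class, child_sex=sex,
    )


# ------------------------------------------------------- written-rule oracle
# An independent encoding of the classification contract, phrased directly
# from the rule text rather than sharing code with the implementation.

CALLABLE = {S.REF, S.ALT}


def autosomal_oracle(f1, f2, m1, m2, c1, c2, phased):
    parental, child = (f1, f2, m1, m2), (c1, c2)
    high = (
        all(s is S.REF for s in parental)
        and set(child) == {S.REF, S.ALT}
        and phased
    )
    if high:
        return Label.HIGH
    if S.ALT in parental:
        return Label.REMOVED
    if S.CONFLICT in parental + child:
        return Label.REMOVED
    if set(child) <= CALLABLE and set(child) != {S.REF, S.ALT}:
        return Label.REMOVED  # child callable but not 0/1
    if S.UNCOVERED in parental + child:
        return Label.LOW
    return Label.LOW  # full pattern, unphased: missing information


def x_oracle(parental, child, phased):
    """Same contract over an arbitrary applicable haploid set."""
    single = len(child) == 1
    want = {S.ALT} if single else {S.REF, S.ALT}
    if all(s is S.REF for s in parental) and set(child) == want and phased \
            and (single or len(set(child)) == 2):
        return Label.HIGH
    if S.ALT in parental or S.CONFLICT in tuple(parental) + tuple(child):
        return Label.REMOVED
    if set(child) <= CALLABLE and (set(child) != want or (not single and len(set(child)) != 2)):
        return Label.REMOVED
    if S.UNCOVERED in tuple(parental) + tuple(child):
        return Label.LOW
    return Label.LOW


STATES = [S.REF, S.ALT, S.CONFLICT, S.UNCOVERED]


def test_truth_table_matches_oracle_over_all_profiles():
    """All 4^6 x {phased, unphased} autosomal profiles agree with the
    independently written rule."""
    for states in itertools.product(STATES, repeat=6):
        for phased in (True, False):
            got = classify_autosomal_dnm(_profile(*states, phased))
            assert got.label is autosomal_oracle(*states, phased), (states, phased)


def test_labels_partition_and_reason_contract():
    for states in itertools.product(STATES, repeat=6):
        cls = classify_autosomal_dnm(_profile(*states, True))
        assert cls.label in (Label.HIGH, Label.LOW, Label.REMOVED)
        if cls.label is Label.HIGH:
            assert cls.reason == ""
            assert classify_site_confidence(cls.profile)
        if cls.label is Label.REMOVED:
            assert cls.reason != ""
        if cls.label is Label.LOW:
            states6 = [c.state for c in (
                cls.profile.father_hp1, cls.profile.father_hp2,
                cls.profile.mother_hp1, cls.profile.mother_hp2,
                cls.profile.child_hp1, cls.profile.child_hp2)]
            assert S.UNCOVERED in states6 or cls.reason == "unphased"


@pytest.mark.parametrize(
    "states,phased,label,reason",
    [
        ((S.REF, S.REF, S.REF, S.REF, S.REF, S.ALT), True, Label.HIGH, ""),
        ((S.REF, S.UNCOVERED, S.REF, S.REF, S.REF, S.ALT), True, Label.LOW,
         "uncovered-haplotype"),
        ((S.ALT, S.REF, S.REF, S.REF, S.REF, S.ALT), True, Label.REMOVED,
         "parental-alt-haplotype"),
        ((S.REF, S.REF, S.REF, S.CONFLICT, S.REF, S.ALT), True, Label.REMOVED,
         "haploid-conflict"),
        ((S.REF, S.REF, S.REF, S.REF, S.REF, S.REF), True, Label.REMOVED,
         "child-not-0-1"),
        ((S.REF, S.REF, S.REF, S.REF, S.REF, S.ALT), False, Label.LOW, "unphased"),
        # parental ALT outranks a conflict elsewhere in the reason ordering
        ((S.ALT, S.CONFLICT, S.REF, S.REF, S.REF, S.ALT), True, Label.REMOVED,
         "parental-alt-haplotype"),
    ],
)
def test_named_examples_and_reason_precedence(states, phased, label, reason):
    cls = classify_autosomal_dnm(_profile(*states, phased))
    assert (cls.label, cls.reason) == (label, reason)


# ------------------------------------------------------------------- chrX


def _x_profile_male(m1, m2, c, site=X_SITE):
    return TrioHaploidProfile(
        site=site,
        father_hp1=NOT_APPLICABLE, father_hp2=NOT_APPLICABLE,
        mother_hp1=_call(m1), mother_hp2=_call(m2),
        child_hp1=_call(c), child_hp2=NOT_APPLICABLE,
        child_phased=True, child_alt_haplotype=None,
        chrom_class=ChromClass.X_NONPAR, child_sex=Sex.MALE,
    )


def _x_profile_female(fx, m1, m2, c1, c2, phased, site=X_SITE):
    p = _profile(fx, S.REF, m1, m2, c1, c2, phased, site=site,
                 chrom_class=ChromClass.X_NONPAR, sex=Sex.FEMALE)
    p.father_hp2 = NOT_APPLICABLE
    return p


def test_male_x_rules_match_oracle():
    for m1, m2, c in itertools.product(STATES, repeat=3):
        got = classify_chrX_dnm(_x_profile_male(m1, m2, c))
        assert got.label is x_oracle((m1, m2), (c,), True), (m1, m2, c)


def test_female_x_rules_match_oracle():
    for states in itertools.product(STATES, repeat=5):
        fx, m1, m2, c1, c2 = states
        for phased in (True, False):
            got = classify_chrX_dnm(_x_profile_female(fx, m1, m2, c1, c2, phased))
            assert got.label is x_oracle((fx, m1, m2), (c1, c2), phased), (states, phased)


def test_male_x_named_examples():
    ok = classify_chrX_dnm(_x_profile_male(S.REF, S.REF, S.ALT))
    assert ok.label is Label.HIGH
    removed = classify_chrX_dnm(_x_profile_male(S.ALT, S.REF, S.ALT))
    assert removed.label is Label.REMOVED


def test_female_x_father_alt_is_removed():
    cls = classify_chrX_dnm(_x_profile_female(S.ALT, S.REF, S.REF, S.REF, S.ALT, True))
    assert (cls.label, cls.reason) == (Label.REMOVED, "parental-alt-haplotype")


def test_par_positions_route_to_autosomal_classifier():
    par_pos = 100_000  # inside chrX:60001-2699520
    assert chrom_class_of("chrX", par_pos) is ChromClass.AUTOSOMAL
    assert chrom_class_of("chrX", 5_000_000) is ChromClass.X_NONPAR
    assert chrom_class_of("chr7", 5_000_000) is ChromClass.AUTOSOMAL
    site = VariantSite("chrX", par_pos, "A", "G")
    profile = _profile(S.REF, S.REF, S.REF, S.REF, S.REF, S.ALT, True, site=site,
                       chrom_class=chrom_class_of("chrX", par_pos), sex=Sex.FEMALE)
    assert classify_dnm(profile).label is Label.HIGH  # six-haploid rule applied


def test_unknown_sex_on_x_nonpar_is_fatal():
    p = _x_profile_male(S.REF, S.REF, S.ALT)
    p.child_sex = None
    with pytest.raises(ValueError):
        classify_chrX_dnm(p)


# --------------------------------------------------------- parent of origin


def _block(sites):
    return PhaseBlock(owner=Role.CHILD, block_id="child:1", chrom="chr1", sites=sites)


def _trio_rec(pos, father_gt, mother_gt, child_gt=(0, 1)):
    return TrioVariantRecord(
        site=VariantSite("chr1", pos, "A", "G"),
        father=GenotypeCall(alleles=father_gt),
        mother=GenotypeCall(alleles=mother_gt),
        child=GenotypeCall(alleles=child_gt),
    )


def test_unanimous_transmission_vote():
    # DNM-bearing haplotype carries the alt at three sites where only the
    # mother carries that allele
    sites = [PhasedHetSite(p, "A", "G", 1, 0) for p in (100, 200, 300)]
    records = [_trio_rec(p, (0, 0), (0, 1)) for p in (100, 200, 300)]
    origin = infer_parent_of_origin(_block(sites), Haplotype.HP1, records, dnm_pos=50)
    assert origin is Origin.MATERNAL


def test_zero_informative_sites_returns_unknown():
    sites = [PhasedHetSite(100, "A", "G", 1, 0)]
    # both parents carry the allele: not informative
    records = [_trio_rec(100, (0, 1), (0, 1))]
    assert infer_parent_of_origin(_block(sites), Haplotype.HP1, records) is Origin.UNKNOWN
    assert infer_parent_of_origin(_block([]), Haplotype.HP1, []) is Origin.UNKNOWN


def test_tie_votes_return_unknown():
    sites = [PhasedHetSite(100, "A", "G", 1, 0), PhasedHetSite(200, "A", "G", 1, 0)]
    records = [_trio_rec(100, (0, 0), (0, 1)), _trio_rec(200, (0, 1), (0, 0))]
    assert infer_parent_of_origin(_block(sites), Haplotype.HP1, records) is Origin.UNKNOWN


def test_missing_parent_handling_toggle():
    sites = [PhasedHetSite(100, "A", "G", 1, 0)]
    records = [_trio_rec(100, None, (0, 1))]
    assert infer_parent_of_origin(_block(sites), Haplotype.HP1, records) is Origin.UNKNOWN
    assert infer_parent_of_origin(
        _block(sites), Haplotype.HP1, records, missing_parent_is_hom_ref=True
    ) is Origin.MATERNAL


# ----------------------------------------------------------------- reports


def test_report_excludes_removed_rows(tmp_path):
    h = classify_autosomal_dnm(_profile(S.REF, S.REF, S.REF, S.REF, S.REF, S.ALT, True))
    r = classify_autosomal_dnm(_profile(S.ALT, S.REF, S.REF, S.REF, S.REF, S.ALT, True))
    main, removed = write_report([h, r], str(tmp_path / "out"))
    main_df = pd.read_csv(main, sep="\t")
    removed_df = pd.read_csv(removed, sep="\t")
    assert len(main_df) == 1 and main_df.iloc[0]["label"] == "H"
    assert len(removed_df) == 1 and removed_df.iloc[0]["reason"] == "parental-alt-haplotype"


def test_empty_report_is_header_only(tmp_path):
    main, removed = write_report([], str(tmp_path / "empty"))
    assert len(pd.read_csv(main, sep="\t")) == 0
    with open(main) as fh:
        assert len(fh.readlines()) == 1


def test_profile_table_round_trip(tmp_path):
    rows = [
        "chr1\t100\tA\tG\tREF\tREF\tREF\tREF\tREF\tALT\t1",
        "chr1\t200\tA\tG\tALT\tREF\tREF\tREF\tREF\tALT\t1",
        "chrX\t5000000\tA\tG\t.\t.\tREF\tREF\tALT\t.\t1",
    ]
    path = tmp_path / "profiles.tsv"
    path.write_text(
        "chrom\tpos\tref\talt\tfather_hp1\tfather_hp2\tmother_hp1\tmother_hp2\t"
        "child_hp1\tchild_hp2\tchild_phased\n" + "\n".join(rows) + "\n"
    )
    profiles = read_profile_table(str(path), child_sex=Sex.MALE)
    labels = [classify_dnm(p).label for p in profiles]
    assert labels == [Label.HIGH, Label.REMOVED, Label.HIGH]
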