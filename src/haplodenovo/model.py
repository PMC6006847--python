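"""Core domain types for haplotype-resolved trio de novo mutation analysis.

The vocabulary follows linked-read sequencing practice: reads carry a
barcode (BX tag) identifying the long source molecule; within a phase
block each molecule -- and hence each of its reads -- is attributed to
haplotype 1 (HP1), haplotype 2 (HP2), or left undetermined (HP0).  A
haploid genotype is the single-allele call obtained from the reads of
one haplotype at one site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Role(str, enum.Enum):
    """Trio member."""

    FATHER = "father"
    MOTHER = "mother"
    CHILD = "child"


class Haplotype(str, enum.Enum):
    """Per-read haplotype tag: haplotype 1, haplotype 2, or undetermined."""

    HP1 = "HP1"
    HP2 = "HP2"
    HP0 = "HP0"


class HaploidState(str, enum.Enum):
    """State of a haploid genotype call.

    REF/ALT are the homozygous haploid calls (0 and 1 in VCF notation);
    CONFLICT means both alleles are credibly supported on one haplotype
    (the hallmark of a miscalled inherited variant); UNCOVERED means the
    haplotype lacks sufficient read depth to call.
    """

    REF = "REF"
    ALT = "ALT"
    CONFLICT = "CONFLICT"
    UNCOVERED = "UNCOVERED"


class Label(str, enum.Enum):
    """Final classification of a candidate de novo mutation."""

    HIGH = "H"
    LOW = "L"
    REMOVED = "REMOVED"


class Origin(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNKNOWN = "unknown"


# machine-readable reason codes, in reporting precedence order
REASON_PARENTAL_ALT = "parental-alt-haplotype"
REASON_CONFLICT = "haploid-conflict"
REASON_CHILD_NOT_01 = "child-not-0-1"
REASON_UNPHASED = "unphased"
REASON_UNCOVERED = "uncovered-haplotype"


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV site, 1-based coordinates."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass
class GenotypeCall:
    """One individual's diploid (or hemizygous) genotype at a site.

    ``alleles`` holds allele indices (0=ref, 1=alt), ``None`` for a fully
    missing call; hemizygous calls have a single-element tuple.  ``score``
    is an externally computed quality (DQ, PP, GL or PL) carried through,
    never recomputed.
    """

    alleles: Optional[tuple[int, ...]]
    phased: bool = False
    phase_set: Optional[str] = None
    depth: Optional[int] = None
    score_label: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phased and self.phase_set is None:
            raise ValueError("phased call requires a phase_set")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None or any(a is None for a in self.alleles)

    @property
    def is_hom_ref(self) -> bool:
        return not self.is_missing and all(a == 0 for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return (
            not self.is_missing
            and len(self.alleles) == 2
            and sorted(self.alleles) == [0, 1]
        )

    def carries(self, allele: int) -> bool:
        return not self.is_missing and allele in self.alleles


MISSING_CALL = GenotypeCall(alleles=None)


@dataclass
class TrioVariantRecord:
    """One site with the three trio genotypes."""

    site: VariantSite
    father: GenotypeCall
    mother: GenotypeCall
    child: GenotypeCall

    def call(self, role: Role) -> GenotypeCall:
        return {Role.FATHER: self.father, Role.MOTHER: self.mother, Role.CHILD: self.child}[role]


@dataclass(frozen=True)
class PhasedHetSite:
    """A phased heterozygous site inside a phase block.

    ``hap1``/``hap2`` are the allele indices carried by haplotype 1 and 2
    (phased VCF order a|b); they always differ at a het site.
    """

    pos: int
    ref: str
    alt: str
    hap1: int
    hap2: int

    def __post_init__(self) -> None:
        if self.hap1 == self.hap2:
            raise ValueError(f"het site at {self.pos} has identical haplotype alleles")


@dataclass(eq=False)  # identity semantics: blocks are used as dict keys
class PhaseBlock:
    """One individual's phased het sites sharing a phase-set identifier."""

    owner: Role
    block_id: str
    chrom: str
    sites: list[PhasedHetSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [s.pos for s in self.sites]
        if positions != sorted(set(positions)):
            raise ValueError("phase block sites must be strictly increasing")

    def positions(self) -> list[int]:
        return [s.pos for s in self.sites]


@dataclass(frozen=True)
class AlleleObservation:
    """One read base at a phased het site, used as a haplotype vote."""

    pos: int
    allele_index: int  # 0, 1, or -1 for a base matching neither allele
    base_quality: int


@dataclass
class Molecule:
    """A chain of same-barcode reads presumed to share one source molecule."""

    barcode: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    read_names: list[str] = field(default_factory=list)
    reads: list = field(default_factory=list)  # pysam.AlignedSegment members


@dataclass
class PileupColumn:
    """Quality-filtered base counts for one (site, haplotype, individual)."""

    site: VariantSite
    haplotype: Haplotype
    owner: Role
    ref_count: int = 0
    alt_count: int = 0
    other_count: int = 0

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class HaploidCall:
    state: HaploidState
    depth: int


NOT_APPLICABLE = HaploidCall(HaploidState.UNCOVERED, -1)


class ChromClass(str, enum.Enum):
    AUTOSOMAL = "autosome-or-PAR"
    X_NONPAR = "X-nonPAR"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass
class TrioHaploidProfile:
    """The six (or five/two) haploid calls at one candidate site.

    On X-nonPAR sites the father's X is a single naturally phased haploid
    held in ``father_hp1`` (``father_hp2`` not applicable); a male child's
    single X haploid is held in ``child_hp1``.
    """

    site: VariantSite
    father_hp1: HaploidCall
    father_hp2: HaploidCall
    mother_hp1: HaploidCall
    mother_hp2: HaploidCall
    child_hp1: HaploidCall
    child_hp2: HaploidCall
    child_phased: bool = False
    child_alt_haplotype: Optional[Haplotype] = None  # None = unknown
    hp0_supports_candidate: bool = False
    chrom_class: ChromClass = ChromClass.AUTOSOMAL
    child_sex: Optional[Sex] = None

    def __post_init__(self) -> None:
        if self.child_alt_haplotype is not None and not self.child_phased:
            raise ValueError("child_alt_haplotype requires child_phased")


@dataclass
class DNMClassification:
    site: VariantSite
    label: Label
    parent_of_origin: Origin = Origin.UNKNOWN
    reason: str = ""
    profile: Optional[TrioHaploidProfile] = None

    def __post_init__(self) -> None:
        if self.label is Label.REMOVED and not self.reason:
            raise ValueError("REMOVED classification requires a reason")
        if self.label is Label.HIGH and self.reason:
            raise ValueError("H classification must not carry a reason")
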