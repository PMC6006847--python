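"""Trio variant I/O: read, merge and write VCFs; extract DNM candidates.

All coordinates in this layer are 1-based inclusive (VCF convention).
Multiallelic records are decomposed into biallelic records; by default
only SNVs are kept, since haploid re-genotyping of indels from raw
pileups is unreliable.  Phase-set identifiers are namespaced per
individual (``father:``/``mother:``/``child:``) when merging, because
phase blocks are never comparable across individuals.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pysam

from .model import (
    GenotypeCall,
    Role,
    TrioVariantRecord,
    VariantSite,
)

logger = logging.getLogger(__name__)

VALID_SCORE_LABELS = frozenset({"DQ", "PP", "GL", "PL"})

_DNA = frozenset("ACGT")


def _is_snv(ref: str, alt: str) -> bool:
    return len(ref) == 1 and len(alt) == 1 and ref in _DNA and alt in _DNA


def _scalarise(value) -> Optional[float]:
    """Reduce an ingested score to one number.

    DQ/PP are scalars; GL/PL arrive as per-genotype vectors, reduced by
    taking the maximum entry.
    """
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        vals = [v for v in value if v is not None]
        return float(max(vals)) if vals else None
    return float(value)


def _extract_score(record: pysam.VariantRecord, sample: str, label: str) -> Optional[float]:
    if label in record.info:
        return _scalarise(record.info[label])
    fmt = record.samples[sample]
    if label in fmt:
        return _scalarise(fmt[label])
    return None


def _decompose(
    record: pysam.VariantRecord,
    samples: Sequence[str],
    include_indels: bool,
    score_label: Optional[str] = None,
    score_sample: Optional[str] = None,
    namespace: Optional[Mapping[str, str]] = None,
) -> Iterator[tuple[VariantSite, dict[str, GenotypeCall]]]:
    """Split one VCF record into biallelic (site, per-sample call) units.

    Genotype indices pointing at a different alt allele become missing in
    the decomposed record (never ref), so decomposition cannot fabricate
    a hom-ref parent.
    """
    alts = record.alts or ()
    for alt_index, alt in enumerate(alts, start=1):
        if alt is None or alt in ("<NON_REF>", "*", "."):
            continue
        if not include_indels and not _is_snv(record.ref, alt):
            continue
        site = VariantSite(record.chrom, record.pos, record.ref.upper(), alt.upper())
        calls: dict[str, GenotypeCall] = {}
        ok = True
        for name in samples:
            fmt = record.samples[name]
            try:
                gt = fmt.get("GT")
            except Exception:  # malformed genotype field
                logger.warning("malformed GT at %s:%d sample %s; record skipped",
                               record.chrom, record.pos, name)
                ok = False
                break
            if gt is None or all(a is None for a in gt):
                calls[name] = GenotypeCall(alleles=None)
                continue
            mapped = tuple(
                None if a is None else (1 if a == alt_index else (0 if a == 0 else None))
                for a in gt
            )
            if any(a is None for a in mapped):
                mapped = None
            phased = bool(fmt.phased) and mapped is not None and len(gt) > 1
            ps = fmt.get("PS") if "PS" in fmt else None
            phase_set = None
            if ps is not None:
                phase_set = str(ps)
                if namespace:
                    phase_set = f"{namespace[name]}:{phase_set}"
            if not phased and len(gt) == 1 and mapped is not None:
                # hemizygous calls (male X) are naturally phased
                phased, phase_set = False, phase_set
            depth = fmt.get("DP") if "DP" in fmt else None
            score = None
            if score_label and (score_sample is None or name == score_sample):
                score = _extract_score(record, name, score_label)
            calls[name] = GenotypeCall(
                alleles=mapped,
                phased=phased and phase_set is not None,
                phase_set=phase_set if (phased and phase_set is not None) else phase_set,
                depth=depth,
                score_label=score_label if score is not None else None,
                score=score,
            )
        if ok:
            yield site, calls


def read_trio_vcf(
    path: str,
    roles: Mapping[str, Role | str],
    include_indels: bool = False,
    score_label: Optional[str] = None,
    namespace_phase_sets: bool = False,
) -> Iterator[TrioVariantRecord]:
    """Stream TrioVariantRecords from a multi-sample VCF.

    Parameters
    ----------
    path:
        VCF (optionally bgzipped) with at least the three trio samples.
    roles:
        Mapping of VCF sample name to trio role; all three roles required.
    include_indels:
        Keep non-SNV alleles (off by default; untested territory).
    score_label:
        One of DQ/PP/GL/PL; if given, the child's score is ingested from
        INFO or the child's FORMAT field for later thresholding.
    namespace_phase_sets:
        Prefix each phase-set ID with the individual's role, matching the
        output of :func:`merge_phased_vcfs`.
    """
    role_map = {name: Role(role) for name, role in roles.items()}
    if set(role_map.values()) != {Role.FATHER, Role.MOTHER, Role.CHILD}:
        raise ValueError("roles must map samples to father, mother and child")
    if score_label is not None and score_label not in VALID_SCORE_LABELS:
        raise ValueError(f"unknown score label {score_label!r}")
    by_role = {role: name for name, role in role_map.items()}
    with pysam.VariantFile(path) as vcf:
        missing = [s for s in role_map if s not in list(vcf.header.samples)]
        if missing:
            raise ValueError(f"sample(s) {missing} not present in {path}")
        ns = {name: role.value for name, role in role_map.items()} if namespace_phase_sets else None
        child_sample = by_role[Role.CHILD]
        for record in vcf:
            for site, calls in _decompose(
                record,
                samples=list(role_map),
                include_indels=include_indels,
                score_label=score_label,
                score_sample=child_sample,
                namespace=ns,
            ):
                yield TrioVariantRecord(
                    site=site,
                    father=calls[by_role[Role.FATHER]],
                    mother=calls[by_role[Role.MOTHER]],
                    child=calls[by_role[Role.CHILD]],
                )


def _read_single_sample(path: str, role: Role, include_indels: bool) -> tuple[dict, list[str]]:
    """Load one individual's phased VCF into {(chrom,pos,ref,alt): call}."""
    out: dict[tuple[str, int, str, str], GenotypeCall] = {}
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError(f"{path} must contain exactly one sample, found {samples}")
        contigs = list(vcf.header.contigs)
        sample = samples[0]
        ns = {sample: role.value}
        for record in vcf:
            for site, calls in _decompose(
                record, samples=[sample], include_indels=include_indels, namespace=ns
            ):
                out[(site.chrom, site.pos, site.ref, site.alt)] = calls[sample]
    return out, contigs


def merge_phased_vcfs(
    father_vcf: str,
    mother_vcf: str,
    child_vcf: str,
    include_indels: bool = False,
) -> Iterator[TrioVariantRecord]:
    """Merge three single-sample phased VCFs into trio records.

    The output is the union of sites, ordered by (contig, position);
    an individual without a call at a site gets a missing genotype.
    Phase sets are preserved and namespaced per individual.
    """
    loaded = {}
    contig_order: list[str] = []
    for role, path in ((Role.FATHER, father_vcf), (Role.MOTHER, mother_vcf), (Role.CHILD, child_vcf)):
        loaded[role], contigs = _read_single_sample(path, role, include_indels)
        for c in contigs:
            if c not in contig_order:
                contig_order.append(c)

    ref_at: dict[tuple[str, int], str] = {}
    for role in loaded:
        for (chrom, pos, ref, _alt) in loaded[role]:
            prev = ref_at.setdefault((chrom, pos), ref)
            if prev != ref:
                raise ValueError(
                    f"conflicting REF alleles at {chrom}:{pos}: {prev!r} vs {ref!r}"
                )

    all_keys = set()
    for role in loaded:
        all_keys.update(loaded[role])
    rank = {c: i for i, c in enumerate(contig_order)}
    for key in sorted(all_keys, key=lambda k: (rank.get(k[0], len(rank)), k[1], k[3])):
        chrom, pos, ref, alt = key
        yield TrioVariantRecord(
            site=VariantSite(chrom, pos, ref, alt),
            father=loaded[Role.FATHER].get(key, GenotypeCall(alleles=None)),
            mother=loaded[Role.MOTHER].get(key, GenotypeCall(alleles=None)),
            child=loaded[Role.CHILD].get(key, GenotypeCall(alleles=None)),
        )


def extract_candidate_dnms(records: Iterable[TrioVariantRecord]) -> list[TrioVariantRecord]:
    """Select putative DNMs: both parents hom-ref, child carries one alt.

    The child must be heterozygous (0/1), or hemizygous-alt for X
    chromosome sites in males.  Records with a missing parental genotype
    are never candidates.  Order is preserved; the operation is
    idempotent.
    """
    out = []
    for rec in records:
        if not (rec.father.is_hom_ref and rec.mother.is_hom_ref):
            continue
        child = rec.child
        if child.is_het or (not child.is_missing and child.alleles == (1,)):
            out.append(rec)
    return out


def apply_score_threshold(
    candidates: Iterable[TrioVariantRecord],
    score_label: str,
    threshold: float,
    direction: str = "ge",
) -> list[TrioVariantRecord]:
    """Filter candidates on an external caller score (DQ/PP/GL/PL).

    ``direction`` is ``"ge"`` (keep if score >= threshold) or ``"le"``.
    Candidates lacking the score are kept and counted in a logged tally,
    mirroring how external candidate lists mix scored and unscored rows.
    """
    if score_label not in VALID_SCORE_LABELS:
        raise ValueError(f"unknown score label {score_label!r}")
    if direction not in ("ge", "le"):
        raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")
    kept, unscored = [], 0
    for rec in candidates:
        score = rec.child.score if rec.child.score_label == score_label else None
        if score is None:
            unscored += 1
            kept.append(rec)
        elif (direction == "ge" and score >= threshold) or (
            direction == "le" and score <= threshold
        ):
            kept.append(rec)
    if unscored:
        logger.info("%d candidate(s) lacked %s and were kept", unscored, score_label)
    return kept


def _strip_namespace(phase_set: Optional[str]) -> Optional[str]:
    if phase_set is None:
        return None
    return phase_set.split(":", 1)[-1]


def write_trio_vcf(
    records: Iterable[TrioVariantRecord],
    path: str,
    contigs: Mapping[str, int],
    sample_names: Sequence[str] = ("FATHER", "MOTHER", "CHILD"),
) -> str:
    """Write trio records as a multi-sample VCF 4.2 file.

    Phased genotypes use ``|`` with the integer PS phase-set field (role
    namespaces are stripped on output; the sample column carries them
    implicitly).
    """
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("PS", 1, "Integer", "Phase set identifier")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in sample_names:
        header.add_sample(s)
    ps_codes: dict[str, int] = {}

    def _ps_int(ps: Optional[str]) -> Optional[int]:
        raw = _strip_namespace(ps)
        if raw is None:
            return None
        try:
            return int(raw)
        except ValueError:
            return ps_codes.setdefault(raw, len(ps_codes) + 1)

    with pysam.VariantFile(path, "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.site.chrom,
                start=rec.site.pos - 1,
                alleles=(rec.site.ref, rec.site.alt),
            )
            for name, call in zip(sample_names, (rec.father, rec.mother, rec.child)):
                fmt = vrec.samples[name]
                if call.alleles is None:
                    fmt["GT"] = (None, None)
                else:
                    fmt["GT"] = tuple(call.alleles)
                    fmt.phased = call.phased
                ps = _ps_int(call.phase_set)
                if ps is not None:
                    fmt["PS"] = ps
                if call.depth is not None:
                    fmt["DP"] = call.depth
            out.write(vrec)
    return path
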