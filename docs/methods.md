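# Methods

## Model and procedure

The package filters candidate de novo mutations (DNMs) in a trio by
re-genotyping every candidate site *per haplotype* instead of per
diploid genome. The chain of reasoning:

1. **Candidates.** From a multi-sample VCF (any caller), a candidate is
   a biallelic SNV with both parents 0/0 and the child 0/1 (hemizygous
   1 on a male's X). Multiallelic records are decomposed first; a
   genotype index pointing at a different alt allele becomes missing in
   the decomposed record, never reference, so decomposition cannot
   fabricate a hom-ref parent. Records with any missing parental
   genotype are not candidates.
2. **Molecules.** Coordinate-sorted reads sharing a `BX` barcode are
   chained into molecules while consecutive read starts are within a
   gap threshold (default 50 kb, standard practice for linked-read
   molecule reconstruction; true molecules rarely have internal read
   gaps that large, and distinct molecules re-using a barcode are
   almost always much farther apart).
3. **Haplotype assignment.** Each molecule votes with its read bases at
   the owner's phased heterozygous sites (phase blocks come from the
   per-individual phased VCFs; namespaced per individual because phase
   sets are never comparable across individuals). Bases below phred 13
   are excluded. The block holding the majority of informative
   observations is used; the majority allele match assigns HP1 or HP2;
   any tie — between blocks or between haplotypes — and any molecule
   with zero informative observations is HP0. All reads of a molecule
   inherit its tag. A per-read voting mode exists behind a flag for
   comparison, and pre-computed HP tags can be trusted instead of
   recomputed.
4. **Haploid genotyping.** For each (individual, haplotype) partition a
   quality-filtered pileup is built at every candidate site (base
   quality ≥ 13, mapping quality ≥ 20) and a deterministic rule calls
   one haploid genotype; see below.
5. **Classification and phasing.** The six (or five/two on X) haploid
   calls plus the child's phasing status produce H / L / REMOVED with a
   fixed reason-code precedence (`parental-alt-haplotype` →
   `haploid-conflict` → `child-not-0-1` → `unphased` /
   `uncovered-haplotype`), so reports are deterministic.
   Parent-of-origin is a transmission vote over the child's phase
   block: each inherited het site where exactly one parent carries the
   allele on the DNM-bearing child haplotype casts one vote; majority
   decides, ties and empty evidence return unknown.

## The haploid genotype rule

The original workflow re-runs a diploid caller on haplotype-split
alignment files and reads haploid genotypes off the result. We instead
define the rule explicitly so the stage is deterministic, testable and
caller-independent:

* depth (ref + alt reads) < `min_depth` → `UNCOVERED`;
* both alleles with count ≥ `min_minor_count` (2) and minor fraction
  ≥ `min_minor_fraction` (0.15) → `CONFLICT`;
* an exact ref/alt tie → `CONFLICT` (neither allele has a majority; any
  directional tie-break would violate ref/alt exchange symmetry — the
  only reachable case under the defaults is 1 ref + 1 alt read);
* otherwise the majority allele (`REF`/`ALT`).

`min_depth` defaults to 2 ("more than 1×"); depth 1 is folded into
`UNCOVERED` (the raw depth is retained in the report so the distinction
is recoverable). The minor-evidence thresholds tolerate one sequencing
error at typical per-haplotype depths (a single stray base among ≥ 7
reads never triggers `CONFLICT`; two concordant bases at ≥ 15 % do).
Bases matching neither allele are counted (`other_count`) but never
vote. All three knobs are exposed on the CLI.

"The DNM is phased" is operationalised as: the child's diploid call
carries a phase set *and* the child's two haploid calls disagree (one
`REF`, one `ALT`), which identifies the alt-bearing haplotype. A
candidate with the full high-confidence pattern except phasing is kept
as `L` — absent phasing is missing information, not counter-evidence —
unless the child's haploids are callable but identical, which
contradicts the diploid het call and removes the candidate.

HP0 reads are piled up identically and used two ways: on X-nonPAR the
naturally phased haploids (father's X; a male child's X) are called
from all of the individual's reads, and for autosomal candidates with
an uncovered child haplotype the child's HP0 pileup is recorded as
`hp0_support` when it shows both alleles. HP0 evidence annotates but
never upgrades a candidate to `H` and never removes one; the exact role
of undetermined reads in the original tool is not recoverable, so we
chose the conservative reading (retention support only).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `--depth` (`min_depth`) | 2 reads | per-haplotype callable minimum |
| `min_minor_count` / `min_minor_fraction` | 2 / 0.15 | CONFLICT evidence rule |
| `--gap-threshold` | 50 000 bp | molecule chaining gap |
| `--min-baseq` / `--min-mapq` | 13 / 20 phred | pileup and voting filters |
| `--par-bed` | hg19 PARs (chrX:60001–2,699,520; 154,931,044–155,260,560) | PAR intervals, analysed with autosomal rules |
| `--child-sex` | required for X-nonPAR sites | selects the five- vs two-haploid X rule |

## The simulator

The simulator generates the study conditions the tests and the
acceptance evaluation run under. It models:

* abstract allele-vector genomes — variant positions carry ref/alt
  bases on a constant filler sequence. Alignment is out of scope, so
  reads are emitted pre-placed; this exercises the real VCF/SAM I/O
  while testing the method's logic rather than a mapper;
* Mendelian transmission of one whole haplotype per parent (no
  recombination at sub-megabase scale), planted child DNMs with known
  parent-of-origin, and human-like heterozygosity (~1 het / 1.3 kb);
* long molecules with exponential lengths (mean 40 kb) and stationary
  uniform starts at ~40× molecule coverage per haplotype; reads
  scattered along molecules with Poisson counts calibrated on the
  realised spans so mean read depth per haplotype is unbiased for the
  target (8× by default); independent per-base substitution errors
  (0.5 % by default);
* **artifact sites** — the false-positive mechanism: inherited parental
  hets whose alt allele lies on the transmitted haplotype; each
  alt-bearing parental molecule covering the site loses its reads *at
  that locus* with probability `dropout_severity` (0.9 by default), and
  the multi-sample VCF reports the parent as 0/0 (the miscall such
  dropout produces upstream). Dropout is local: deleting whole
  molecules would erase the haplotype genome-wide here, because without
  recombination every artifact shares the one transmitted haplotype —
  a concentration real genomes don't exhibit;
* phase blocks derived from molecule co-coverage connectivity
  (union–find over het sites spanned by a common molecule), giving
  realistic block structure without implementing a phasing algorithm;
  singleton blocks are emitted unphased;
* an X mode: hemizygous father, sexed child, maternal-only artifacts,
  haploid genotypes in the emitted VCF.

Identical configurations (including the seed) produce byte-identical
output files.

What the simulator does **not** model — and therefore what passing
tests do not demonstrate about real data: alignment and mapping errors,
repetitive sequence, barcode collisions and whitelist errors, chimeric
molecules, GC and quality-score structure, indels, switch errors in
phasing, and recombination. In particular the emitted phasing is exact,
so real-world switch errors would add a parent-of-origin and
classification error channel this package does not see in testing.

## Problem sizes and observed behaviour

Default simulations use a 400 kb contig with 300 het sites per
individual, 20 DNMs and 200 artifact sites (~43 k reads per
individual); the test suite uses 60–200 kb configurations. At the
default severe-dropout conditions the pipeline retains every true DNM
and removes the artifact candidates whose parental alt haplotype
remains callable. Removal is sharply severity-dependent: the residual
alt-haplotype depth is `target_depth × (1 − severity)`, so at 8× and
severity 0.9 the expectation (0.8×) sits below the 2-read callable
minimum and most artifacts are retained as `L` (uncovered haplotype)
rather than removed — by the explicit rule that an uncovered haplotype
is insufficient information. At severity 0.5 the residual 4× makes the
parental alt haploid visible and nearly all artifacts are removed.
This is the expected behaviour of the method, not a tuning target: a
read-level filter cannot remove what left no reads behind.

## Known limitations

* Only biallelic SNVs by default; indels can be enabled but are
  untested territory.
* External caller scores (DQ/PP/GL/PL) are ingested and thresholded,
  never recomputed; vector-valued GL/PL are scalarised by their
  maximum entry.
* Reads spanning two phase blocks are assigned by the block with the
  majority of informative sites (ties → HP0); the behaviour of
  upstream tools in this situation is unspecified.
* Trios only; no extended pedigrees or tumour–normal mode.
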