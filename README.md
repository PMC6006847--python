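# haplodenovo

Haplotype-based filtering and phasing of **de novo mutations (DNMs)** in
parent–parent–child trios sequenced with **linked reads** (e.g. 10X
Chromium), plus a synthetic linked-read trio simulator so the whole
pipeline can be exercised and validated without external data.

## The problem

A candidate DNM is a site where the child is heterozygous (0/1) and both
parents are called homozygous reference (0/0). Trio callers emit
thousands of such candidates per genome, and most are false positives.
A dominant failure mode is **allele-specific coverage dropout**: at an
inherited parental heterozygous site, reads from the alt-bearing
parental haplotype are depleted, the diploid caller reports the parent
as 0/0, and the inherited variant masquerades as a DNM in the child.

Linked reads solve this. Short reads sharing a barcode (`BX` tag)
derive from one long DNA molecule, hence from one haplotype. Within
each phase block every molecule — and all of its reads — can be
assigned to haplotype 1 (`HP1`), haplotype 2 (`HP2`) or left
undetermined (`HP0`), and a **haploid genotype** can be called for each
of the six trio haplotypes at every candidate site:

* `REF` / `ALT` — the haplotype carries allele 0 / 1,
* `CONFLICT` — both alleles credibly supported on one haplotype,
* `UNCOVERED` — fewer than `--depth` reads (default 2, i.e. > 1×).

Each candidate is then classified:

| label | rule |
|---|---|
| `H` (high-confidence) | all six haploids callable, all four parental haploids `REF`, child haploids exactly one `REF` + one `ALT`, child variant phased |
| `REMOVED` | any parental haploid `ALT`, any haploid `CONFLICT`, or child haploids callable but not {`REF`,`ALT`} — positive evidence of an inherited variant or artifact |
| `L` (low-confidence) | a required haplotype `UNCOVERED` (or the child unphased) with no disqualifying evidence; kept for further consideration |

On the X chromosome outside the pseudoautosomal regions, a male's X is
naturally phased: a female child is judged on five haploids (including
the father's single X), a male child on the mother's two haploids plus
his single X haploid. PAR sites follow the autosomal rules.

The phased child haplotype also yields **parent-of-origin**: inherited
het sites in the same phase block where only one parent carries the
allele on the DNM-bearing haplotype vote for the transmitting parent.

## Worked example

Simulate a 400 kb trio (20 true DNMs, 200 dropout artifact sites, 8×
per-haplotype depth, 0.5 % base error) and run the full pipeline:

```bash
haplodenovo simulate --out-dir demo --seed 1
haplodenovo full \
    --phased-vcf-father demo/father.phased.vcf \
    --phased-vcf-mother demo/mother.phased.vcf \
    --phased-vcf-child  demo/child.phased.vcf \
    --bam-father demo/father.sam --bam-mother demo/mother.sam \
    --bam-child  demo/child.sam \
    --candidates-vcf demo/trio.vcf --father FATHER --mother MOTHER --child CHILD \
    --out demo/run
```

The log summarises each stage:

```
INFO haplodenovo.pipeline: 220 candidate DNM(s) after extraction and thresholds
INFO haplodenovo.pipeline: father: reads tagged HP1/HP2/HP0 = 19895/20843/1273
INFO haplodenovo.pipeline: mother: reads tagged HP1/HP2/HP0 = 20217/20743/1254
INFO haplodenovo.pipeline: child:  reads tagged HP1/HP2/HP0 = 21114/21051/374
INFO haplodenovo.dnm_classifier: classification tally: {'H': 19, 'L': 158, 'REMOVED': 43}
```

220 candidates came in (20 true DNMs + 200 injected artifacts).
`demo/run.dnm.tsv` is the flat file of retained candidates annotated
`H` or `L` with parent-of-origin, the six haploid states and their
depths; `demo/run.removed.tsv` holds the 43 removed candidates with
machine-readable reasons (here all `parental-alt-haplotype`: the
parent's alt haplotype was directly observed). Against the simulator's
truth tables, all 20 true DNMs are retained (19 as `H`; one haplotype
fell below 2× for the other) with parent-of-origin recovered for all of
them (13 paternal, 7 maternal), and every removed site is a genuine
artifact. The remaining artifacts stay `L` because severe dropout left
their parental alt haplotype without callable reads — exactly the
"insufficient information" case the low-confidence tier exists for.

Each stage is also available separately (`simulate`, `tag`, `genotype`,
`classify`); `classify` accepts a hand-written haploid-profile TSV, and
candidate VCFs from external DNM callers (GATK, FreeBayes, TrioDeNovo,
DeNovoGear) enter through `--candidates-vcf` with optional
`--score-filter DQ:7:ge`-style thresholds on DQ/PP/GL/PL.

## Layout

```
src/haplodenovo/
  model.py                 domain types (sites, calls, blocks, profiles)
  variant_io.py            VCF reading/merging/writing, candidate extraction
  haplotype_assignment.py  molecule grouping, HP1/HP2/HP0 voting, splitting
  haploid_genotyping.py    per-haplotype pileups and haploid calls
  dnm_classifier.py        H/L/REMOVED rules, chrX, parent-of-origin, reports
  simulate.py              linked-read trio simulator with ground truth
  pipeline.py              end-to-end orchestration + run manifest
  evaluation.py            truth-based scoring of pipeline runs
  cli.py                   haplodenovo {full,simulate,tag,genotype,classify}
```
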