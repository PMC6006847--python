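"""Molecule grouping and haplotype voting against brute-force oracles."""

import random

from hypothesis import given, settings, strategies as st

from haplodenovo.haplotype_assignment import (
    _BlockIndex,
    assign_reads,
    collect_observations,
    group_reads_into_molecules,
    split_by_tag,
    vote_haplotype,
)
from haplodenovo.model import (
    AlleleObservation,
    Haplotype,
    PhaseBlock,
    PhasedHetSite,
    Role,
)

from conftest import make_read


def _block(sites, owner=Role.CHILD, block_id="1", chrom="chr1"):
    return PhaseBlock(owner=owner, block_id=block_id, chrom=chrom, sites=sites)


# ---------------------------------------------------------------- grouping


def test_same_barcode_within_gap_is_one_molecule():
    reads = [
        make_read("r1", 10_000, "A" * 100),
        make_read("r2", 20_000, "A" * 100),
    ]
    mols = group_reads_into_molecules(reads, gap_threshold=50_000)
    assert len(mols) == 1 and mols[0].read_names == ["r1", "r2"]


def test_same_barcode_beyond_gap_splits_molecules():
    reads = [
        make_read("r1", 10_000, "A" * 100),
        make_read("r2", 260_000, "A" * 100),
    ]
    mols = group_reads_into_molecules(reads, gap_threshold=50_000)
    assert len(mols) == 2


def test_unbarcoded_reads_become_singletons():
    reads = [make_read("r1", 100, "A" * 50, barcode=None),
             make_read("r2", 120, "A" * 50, barcode=None)]
    mols = group_reads_into_molecules(reads, gap_threshold=50_000)
    assert len(mols) == 2 and all(len(m.reads) == 1 for m in mols)


def _chain_oracle(positions, gap):
    """Brute-force transitive chaining of sorted read starts."""
    groups = []
    for p in positions:
        if groups and p - groups[-1][-1] <= gap:
            groups[-1].append(p)
        else:
            groups.append([p])
    return [len(g) for g in groups]


def test_grouping_matches_transitive_chaining_oracle():
    rng = random.Random(1)
    for _ in range(50):
        n = rng.randint(1, 30)
        starts = sorted(rng.randrange(0, 500_000) for _ in range(n))
        gap = rng.choice([1_000, 20_000, 50_000])
        reads = [make_read(f"r{i}", s, "A" * 10) for i, s in enumerate(starts)]
        mols = group_reads_into_molecules(reads, gap_threshold=gap)
        assert sorted(len(m.reads) for m in mols) == sorted(_chain_oracle(starts, gap))


# ---------------------------------------------------------------- voting


def _vote_oracle(obs, block):
    site = {s.pos: s for s in block.sites}
    n1 = sum(1 for o in obs if o.allele_index == site[o.pos].hap1 and o.allele_index >= 0)
    n2 = sum(1 for o in obs if o.allele_index == site[o.pos].hap2 and o.allele_index >= 0)
    if n1 > n2:
        return Haplotype.HP1
    if n2 > n1:
        return Haplotype.HP2
    return Haplotype.HP0


def test_unanimous_vote_and_tie():
    sites = [PhasedHetSite(100, "A", "G", 0, 1), PhasedHetSite(200, "A", "G", 1, 0),
             PhasedHetSite(300, "A", "G", 0, 1)]
    block = _block(sites)
    unanimous = [AlleleObservation(100, 0, 30), AlleleObservation(200, 1, 30),
                 AlleleObservation(300, 0, 30)]
    assert vote_haplotype({block: unanimous}) is Haplotype.HP1
    tied = [AlleleObservation(100, 0, 30), AlleleObservation(100, 1, 30),
            AlleleObservation(200, 1, 30), AlleleObservation(200, 0, 30)]
    assert vote_haplotype({block: tied}) is Haplotype.HP0
    assert vote_haplotype({block: []}) is Haplotype.HP0
    assert vote_haplotype({}) is Haplotype.HP0


@settings(max_examples=300, derandomize=True)
@given(st.data())
def test_vote_matches_exhaustive_counting_oracle(data):
    n_sites = data.draw(st.integers(1, 10))
    positions = sorted(
        data.draw(
            st.lists(st.integers(1, 10_000), min_size=n_sites, max_size=n_sites, unique=True)
        )
    )
    sites = []
    for pos in positions:
        h1 = data.draw(st.integers(0, 1))
        sites.append(PhasedHetSite(pos, "A", "G", h1, 1 - h1))
    block = _block(sites)
    obs = data.draw(
        st.lists(
            st.builds(
                AlleleObservation,
                pos=st.sampled_from(positions),
                allele_index=st.sampled_from([0, 1, -1]),
                base_quality=st.just(30),
            ),
            max_size=20,
        )
    )
    assert vote_haplotype({block: obs}) is _vote_oracle(obs, block)


def test_label_swap_symmetry():
    """Exchanging hap1/hap2 alleles maps HP1 <-> HP2 and fixes HP0."""
    rng = random.Random(3)
    for _ in range(100):
        positions = sorted(rng.sample(range(1, 5_000), rng.randint(1, 8)))
        sites = [PhasedHetSite(p, "A", "G", h, 1 - h)
                 for p in positions for h in [rng.randint(0, 1)]]
        swapped = [PhasedHetSite(s.pos, s.ref, s.alt, s.hap2, s.hap1) for s in sites]
        block, block_sw = _block(sites), _block(swapped)
        obs = [AlleleObservation(rng.choice(positions), rng.choice([0, 1, -1]), 30)
               for _ in range(rng.randint(0, 12))]
        tag = vote_haplotype({block: obs})
        tag_sw = vote_haplotype({block_sw: obs})
        expected = {Haplotype.HP1: Haplotype.HP2, Haplotype.HP2: Haplotype.HP1,
                    Haplotype.HP0: Haplotype.HP0}[tag]
        assert tag_sw is expected


def test_low_quality_bases_do_not_vote():
    block = _block([PhasedHetSite(101, "A", "G", 0, 1)])
    index = _BlockIndex([block])
    read = make_read("r1", 90, "A" * 30, qual=5)  # base quality below threshold
    obs = collect_observations([read], index, min_base_quality=13)
    assert not obs.get(block)


# ---------------------------------------------------------------- partition


def test_split_by_tag_partitions_input():
    reads = [make_read(f"r{i}", 100 + i, "A" * 10) for i in range(100)]
    tags = [Haplotype.HP1] * 40 + [Haplotype.HP2] * 35 + [Haplotype.HP0] * 25
    parts = split_by_tag(zip(reads, tags))
    assert [len(parts[h]) for h in (Haplotype.HP1, Haplotype.HP2, Haplotype.HP0)] == [40, 35, 25]
    assert sum(len(v) for v in parts.values()) == len(reads)


def test_partition_conservation_on_simulation(clean_sim):
    """|HP1| + |HP2| + |HP0| equals the read count for each individual."""
    from haplodenovo.haplotype_assignment import build_phase_blocks, read_alignments
    from haplodenovo.variant_io import merge_phased_vcfs

    truth, paths, _ = clean_sim
    merged = list(merge_phased_vcfs(
        paths["father_phased_vcf"], paths["mother_phased_vcf"], paths["child_phased_vcf"]
    ))
    blocks = build_phase_blocks(merged)
    for role in Role:
        reads, _ = read_alignments(paths[f"{role.value}_sam"])
        parts = split_by_tag(assign_reads(reads, blocks[role]))
        assert sum(len(v) for v in parts.values()) == len(reads)


def test_error_free_reads_tagged_with_true_haplotype(clean_sim):
    """Without base errors, every informative read recovers its source
    haplotype up to the block's arbitrary hap1/hap2 orientation."""
    from haplodenovo.haplotype_assignment import build_phase_blocks, read_alignments
    from haplodenovo.variant_io import merge_phased_vcfs

    truth, paths, _ = clean_sim
    merged = list(merge_phased_vcfs(
        paths["father_phased_vcf"], paths["mother_phased_vcf"], paths["child_phased_vcf"]
    ))
    blocks = build_phase_blocks(merged)
    truth_hap = {r.name: r.hap_index for r in truth.reads}
    for role in Role:
        reads, _ = read_alignments(paths[f"{role.value}_sam"])
        tagged = assign_reads(reads, blocks[role])
        # orientation between emitted hap order and tag is fixed per role here
        # because the simulator writes GT in haplotype order: HP1 == hap 0
        for read, tag in tagged:
            if tag is Haplotype.HP0:
                continue
            expect = Haplotype.HP1 if truth_hap[read.query_name] == 0 else Haplotype.HP2
            assert tag is expect


def test_trust_existing_tags_matches_recompute_on_clean_data(tmp_path, tmp_path_factory):
    """Pre-tagged input (truth tags) partitions like recomputed tags for
    every read the voter can place."""
    from haplodenovo.haplotype_assignment import build_phase_blocks, read_alignments
    from haplodenovo.simulate import simulate
    from haplodenovo.variant_io import merge_phased_vcfs
    from conftest import small_config

    out = tmp_path_factory.mktemp("truthtag")
    cfg = small_config(emit_truth_tags=True, base_error_rate=0.0, seed=5)
    truth, paths = simulate(cfg, str(out))
    merged = list(merge_phased_vcfs(
        paths["father_phased_vcf"], paths["mother_phased_vcf"], paths["child_phased_vcf"]
    ))
    blocks = build_phase_blocks(merged)
    reads, _ = read_alignments(paths["child_sam"])
    trusted = dict((r.query_name, t) for r, t in assign_reads(reads, blocks[Role.CHILD],
                                                             trust_existing_tags=True))
    recomputed = assign_reads(reads, blocks[Role.CHILD])
    for read, tag in recomputed:
        if tag is not Haplotype.HP0:
            assert trusted[read.query_name] is tag
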