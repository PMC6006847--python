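"""Shared fixtures: hand-built alignments/VCFs and small simulated trios."""

from __future__ import annotations

import pysam
import pytest

from haplodenovo.pipeline import PipelineConfig, run_full
from haplodenovo.simulate import SimulationConfig, simulate

SAM_HEADER = pysam.AlignmentHeader.from_dict(
    {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": "chr1", "LN": 1_000_000},
            {"SN": "chrX", "LN": 1_000_000},
        ],
    }
)


def make_read(
    name: str,
    start: int,
    seq: str,
    barcode: str | None = "BC0001-1",
    chrom: str = "chr1",
    mapq: int = 60,
    qual: int = 30,
) -> pysam.AlignedSegment:
    """Build a mapped single-end read (0-based start, full-match CIGAR)."""
    read = pysam.AlignedSegment(SAM_HEADER)
    read.query_name = name
    read.flag = 0
    read.reference_id = 0 if chrom == "chr1" else 1
    read.reference_start = start
    read.mapping_quality = mapq
    read.cigarstring = f"{len(seq)}M"
    read.query_sequence = seq
    read.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
    if barcode is not None:
        read.set_tag("BX", barcode)
    return read


def small_config(**overrides) -> SimulationConfig:
    """A fast desk-top simulation: ~15k reads, runs in about a second."""
    defaults = dict(
        genome_length=150_000,
        n_het_sites_per_individual=120,
        n_dnms=8,
        n_artifact_sites=20,
        mean_molecule_length=30_000,
        molecules_per_haplotype=180,
        target_depth_per_haplotype=10.0,
        base_error_rate=0.0,
        dropout_severity=0.9,
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def pipeline_config_for(sim_dir: str, out_prefix: str, **overrides) -> PipelineConfig:
    defaults = dict(
        father_phased_vcf=f"{sim_dir}/father.phased.vcf",
        mother_phased_vcf=f"{sim_dir}/mother.phased.vcf",
        child_phased_vcf=f"{sim_dir}/child.phased.vcf",
        father_bam=f"{sim_dir}/father.sam",
        mother_bam=f"{sim_dir}/mother.sam",
        child_bam=f"{sim_dir}/child.sam",
        candidates_vcf=f"{sim_dir}/trio.vcf",
        out_prefix=out_prefix,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Error-free simulated trio with moderate dropout, plus its file set."""
    out = tmp_path_factory.mktemp("clean_sim")
    cfg = small_config(base_error_rate=0.0, dropout_severity=0.5,
                       target_depth_per_haplotype=16.0)
    truth, paths = simulate(cfg, str(out))
    return truth, paths, str(out)


@pytest.fixture(scope="session")
def noisy_sim(tmp_path_factory):
    """Simulated trio at the default (noisy, severe-dropout) conditions."""
    out = tmp_path_factory.mktemp("noisy_sim")
    cfg = small_config(base_error_rate=0.005, seed=11)
    truth, paths = simulate(cfg, str(out))
    return truth, paths, str(out)


@pytest.fixture(scope="session")
def clean_pipeline_result(clean_sim, tmp_path_factory):
    truth, paths, sim_dir = clean_sim
    out = tmp_path_factory.mktemp("clean_out")
    cfg = pipeline_config_for(sim_dir, str(out / "run"))
    return truth, run_full(cfg)
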