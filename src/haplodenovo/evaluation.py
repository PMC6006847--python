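"""Truth-based evaluation of pipeline runs on simulated trios.

Utilities that run the full pipeline on a simulator output directory and
score the classifications against the ground truth: artifact removal
rate (the false-positive elimination the haplotype filter exists for),
true-DNM retention, and parent-of-origin accuracy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .model import Label
from .pipeline import PipelineConfig, PipelineResult, run_full
from .simulate import SimulationConfig, TruthSet, simulate


def run_pipeline_on_simulation(
    sim_config: SimulationConfig, workdir: str, **pipeline_overrides
) -> tuple[TruthSet, PipelineResult]:
    """Simulate a trio into ``workdir`` and run the full pipeline on it."""
    sim_dir = os.path.join(workdir, f"sim_seed{sim_config.seed}")
    truth, paths = simulate(sim_config, sim_dir)
    cfg = PipelineConfig(
        father_phased_vcf=paths["father_phased_vcf"],
        mother_phased_vcf=paths["mother_phased_vcf"],
        child_phased_vcf=paths["child_phased_vcf"],
        father_bam=paths["father_sam"],
        mother_bam=paths["mother_sam"],
        child_bam=paths["child_sam"],
        candidates_vcf=paths["trio_vcf"],
        out_prefix=os.path.join(sim_dir, "run"),
        **pipeline_overrides,
    )
    return truth, run_full(cfg)


@dataclass
class RemovalStats:
    n_artifact_candidates: int
    n_artifacts_removed: int
    n_true_dnms: int
    n_true_dnms_covered: int
    n_true_dnms_retained: int

    @property
    def removal_percent(self) -> float:
        if self.n_artifact_candidates == 0:
            return 0.0
        return 100.0 * self.n_artifacts_removed / self.n_artifact_candidates

    @property
    def all_covered_dnms_retained(self) -> bool:
        return self.n_true_dnms_retained == self.n_true_dnms_covered


def score_artifact_removal(truth: TruthSet, result: PipelineResult) -> RemovalStats:
    """How many injected artifact candidates were removed, and whether
    every true DNM with called evidence was retained (H or L).

    A true DNM counts as *covered* when its candidate record exists and
    was not dropped for lack of any read evidence -- every candidate is
    classified, so coverage here simply means presence in the candidate
    set; retention means a label of H or L.
    """
    by_pos = {c.site.pos: c for c in result.classifications}
    artifacts = [p for p in truth.artifact_positions if p in by_pos]
    removed = [p for p in artifacts if by_pos[p].label is Label.REMOVED]
    dnms = truth.dnm_positions
    covered = [p for p in dnms if p in by_pos]
    retained = [p for p in covered if by_pos[p].label in (Label.HIGH, Label.LOW)]
    return RemovalStats(
        n_artifact_candidates=len(artifacts),
        n_artifacts_removed=len(removed),
        n_true_dnms=len(dnms),
        n_true_dnms_covered=len(covered),
        n_true_dnms_retained=len(retained),
    )


def score_parent_of_origin(truth: TruthSet, result: PipelineResult) -> tuple[int, int]:
    """(matches, phased DNMs) for parent-of-origin inference."""
    by_pos = {c.site.pos: c for c in result.classifications}
    n_phased = n_match = 0
    for pos in truth.dnm_positions:
        cls = by_pos.get(pos)
        if cls is None or cls.profile is None:
            continue
        if cls.profile.child_alt_haplotype is None and cls.profile.chrom_class.value != "X-nonPAR":
            continue
        n_phased += 1
        if cls.parent_of_origin is truth.sites[pos].origin:
            n_match += 1
    return n_match, n_phased
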