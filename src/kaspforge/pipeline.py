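"""End-to-end pipeline driver: panel filters -> designs -> placement -> effects.

Chains the sequential stages in their fixed order (rare-allele, target
coverage, flank coverage, flank variation, tandem repeat, GC window,
alignment uniqueness), records one final verdict per candidate site, and
keeps a run manifest whose per-rule counts must sum back to the number of
candidates — the conservation check the tests assert.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

from . import __version__
from .annotation import GeneModel, annotate_designs
from .design import KASPDesign, build_designs
from .io_formats import ReferenceGenome
from .panel import FilterRule, GenomePanel, run_panel_filters
from .mapping import map_designs


@dataclasses.dataclass
class PipelineConfig:
    """Every threshold of the design pipeline, at its published default."""

    min_call_depth: int = 5
    max_other_frac: float = 0.10
    low_depth_frac: float = 0.1
    max_low_genomes_frac: float = 0.10
    flank_bp: int = 50
    het_carries_alt: bool = True
    strict_flank: bool = False
    max_flank_snps: int = 5
    per_flank: bool = True
    max_indel_len: int = 10
    min_indel_offset: int = 5
    repeat_max_copies: int = 5
    gc_lo: float = 35.0
    gc_hi: float = 65.0
    gc_window: int = 55
    seed_len: int = 15
    min_identity_legacy: float = 90.0


@dataclasses.dataclass
class RunManifest:
    version: str
    n_candidates: int
    failures_by_rule: dict[str, int]
    n_designs: int

    def conserved(self) -> bool:
        return self.n_candidates == self.n_designs + sum(self.failures_by_rule.values())


@dataclasses.dataclass
class PipelineResult:
    designs: list[KASPDesign]
    verdicts: dict[tuple[str, int], str]  # site -> failed rule name, "none" = survivor
    manifest: RunManifest


def run_pipeline(
    panel: GenomePanel,
    config: PipelineConfig | None = None,
    gene_models: Optional[list[GeneModel]] = None,
    secondary: Optional[ReferenceGenome] = None,
    legacy: Optional[ReferenceGenome] = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    verdicts: dict[tuple[str, int], str] = {}

    targets, outcomes = run_panel_filters(
        panel,
        max_other_frac=cfg.max_other_frac,
        low_depth_frac=cfg.low_depth_frac,
        max_low_genomes_frac=cfg.max_low_genomes_frac,
        flank_bp=cfg.flank_bp,
        het_carries_alt=cfg.het_carries_alt,
        strict_flank=cfg.strict_flank,
    )
    for oc in outcomes:
        if not oc.passed:
            verdicts[oc.site] = oc.failed_rule.value

    designs, outcomes = build_designs(
        targets,
        panel,
        flank_bp=cfg.flank_bp,
        max_flank_snps=cfg.max_flank_snps,
        per_flank=cfg.per_flank,
        max_indel_len=cfg.max_indel_len,
        min_indel_offset=cfg.min_indel_offset,
        repeat_max_copies=cfg.repeat_max_copies,
        gc_lo=cfg.gc_lo,
        gc_hi=cfg.gc_hi,
        gc_window=cfg.gc_window,
    )
    for oc in outcomes:
        if not oc.passed:
            verdicts[oc.site] = oc.failed_rule.value

    survivors, outcomes = map_designs(
        designs,
        panel.reference,
        secondary=secondary,
        legacy=legacy,
        min_identity_legacy=cfg.min_identity_legacy,
        seed_len=cfg.seed_len,
    )
    for oc in outcomes:
        if not oc.passed:
            verdicts[oc.site] = oc.failed_rule.value
    for d in survivors:
        verdicts[d.target.site] = "none"

    if gene_models is not None:
        refs = {panel.reference.assembly_id: panel.reference}
        annotate_designs(survivors, {panel.reference.assembly_id: gene_models}, refs)

    failures: dict[str, int] = {}
    for rule in verdicts.values():
        if rule != "none":
            failures[rule] = failures.get(rule, 0) + 1
    manifest = RunManifest(
        version=__version__,
        n_candidates=len(verdicts),
        failures_by_rule=failures,
        n_designs=len(survivors),
    )
    return PipelineResult(designs=survivors, verdicts=verdicts, manifest=manifest)
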