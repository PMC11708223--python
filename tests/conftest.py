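"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from kaspforge.annotation import load_gene_models
from kaspforge.io_formats import (
    DepthTrack,
    ReferenceGenome,
    VariantCall,
    VariantClass,
    Zygosity,
    filter_calls,
)
from kaspforge.panel import GenomePanel
from kaspforge.pipeline import run_pipeline
from kaspforge.simulate import PanelSpec, generate_scenario, write_gene_models_gff3

SCENARIO_SEED = 20_2409  # fixed study seed for the default synthetic scenario


@pytest.fixture(scope="session")
def default_scenario():
    """The default desk-scale study: 20 genomes x 200 kb, ~1,800 sites."""
    return generate_scenario(SCENARIO_SEED)


@pytest.fixture(scope="session")
def small_scenario():
    """A 30 kb mini-study for fast end-to-end checks."""
    spec = PanelSpec(
        chrom_length=30_000, n_genes=6, n_repeat_tracts=3, n_at_tracts=3,
        n_duplicated_sites=2,
    )
    return generate_scenario(SCENARIO_SEED + 1, spec)


def build_panel(scenario) -> GenomePanel:
    return GenomePanel(
        scenario.reference,
        {g: filter_calls(c) for g, c in scenario.calls_by_genome.items()},
        scenario.depth_tracks,
    )


@pytest.fixture(scope="session")
def small_panel(small_scenario):
    return build_panel(small_scenario)


@pytest.fixture(scope="session")
def small_result(small_scenario, small_panel):
    return run_pipeline(small_panel)


@pytest.fixture(scope="session")
def small_gene_models(small_scenario, tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "genes.gff3"
    write_gene_models_gff3(small_scenario.genes, path)
    return load_gene_models(path)


def make_reference(seq: str, chrom: str = "chr1", assembly: str = "test") -> ReferenceGenome:
    return ReferenceGenome(assembly, {chrom: seq})


def uniform_track(genome: str, mean: float, length: int, chrom: str = "chr1") -> DepthTrack:
    return DepthTrack(genome, mean, {chrom: [(1, length, int(round(mean)))]})


def snp_call(genome: str, pos: int, ref: str, alt: str, depth: int = 30,
             het: bool = False, chrom: str = "chr1") -> VariantCall:
    return VariantCall(
        genome_id=genome, chromosome=chrom, position=pos, ref_allele=ref,
        alt_allele=alt, variant_class=VariantClass.SNP, read_depth=depth,
        zygosity=Zygosity.HET if het else Zygosity.HOM_ALT,
    )


def random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
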