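"""Multi-genome variant panel and the first three design filters.

A candidate assay site is an aligned position where at least one
resequenced genome differs from the reference.  Sites pass through a fixed
sequence of rejection rules:

1. *Rare alleles* — at least 90% of panel lines must carry either the
   reference allele or the single most common alternative ("target")
   allele; sites where every line is homozygous for the same alternative
   are monomorphic within the panel and useless as assays.
2. *Target coverage* — a genome supports the site poorly when its read
   depth there is below 0.1x its genome-wide mean; sites poorly supported
   in more than 10% of genomes are rejected.
3. *Flank coverage* — the same 0.1x/10% criterion applied independently to
   every one of the 50 bases either side of the target; a single failing
   flank base rejects the site.

Rules about the *content* of the flanking variation (filter 4 onward) live
in :mod:`kaspforge.design`.
"""

from __future__ import annotations

import bisect
import dataclasses
import enum
from typing import Iterable, Mapping

import numpy as np

from .io_formats import DepthTrack, ReferenceGenome, VariantCall, VariantClass, Zygosity

SiteKey = tuple[str, int]


class FilterRule(enum.Enum):
    RARE_ALLELE = "rare_allele"
    MONOMORPHIC = "monomorphic"
    TARGET_COVERAGE = "target_coverage"
    FLANK_COVERAGE = "flank_coverage"
    FLANK_VARIATION = "flank_variation"
    REPEAT = "repeat"
    ALIGNMENT = "alignment"
    GC = "gc"
    NONE = "none"


@dataclasses.dataclass
class FilterOutcome:
    site: SiteKey
    verdict: str  # "pass" | "fail"
    failed_rule: FilterRule = FilterRule.NONE
    detail: str = ""

    def __post_init__(self) -> None:
        assert (self.verdict == "fail") == (self.failed_rule is not FilterRule.NONE)

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


@dataclasses.dataclass
class TargetVariant:
    """The modal non-reference allele at a surviving candidate site."""

    chromosome: str
    position: int
    ref_allele: str
    target_allele: str
    variant_class: VariantClass
    alt_counts: dict[tuple[str, str], float]  # (ref, alt) -> carrier count
    carrier_set: frozenset[str]

    @property
    def site(self) -> SiteKey:
        return (self.chromosome, self.position)


class GenomePanel:
    """Reference plus per-genome calls and depth tracks for N genomes."""

    def __init__(
        self,
        reference: ReferenceGenome,
        calls_by_genome: Mapping[str, Iterable[VariantCall]],
        depth_tracks: Mapping[str, DepthTrack],
    ) -> None:
        self.reference = reference
        self.genomes = sorted(calls_by_genome)
        if len(self.genomes) < 2:
            raise ValueError("a panel needs at least two genomes")
        missing = [g for g in self.genomes if g not in depth_tracks]
        if missing:
            raise ValueError(f"no depth track for genomes {missing}")
        self.depth_tracks = dict(depth_tracks)
        # (chrom, pos) -> genome -> [VariantCall]
        self.site_calls: dict[SiteKey, dict[str, list[VariantCall]]] = {}
        for genome, calls in calls_by_genome.items():
            for c in calls:
                self.site_calls.setdefault((c.chromosome, c.position), {}).setdefault(
                    genome, []
                ).append(c)
        # sorted per-chromosome position index for fast range queries
        self._positions: dict[str, list[int]] = {}
        for chrom, pos in self.site_calls:
            self._positions.setdefault(chrom, []).append(pos)
        for positions in self._positions.values():
            positions.sort()

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def sites(self) -> list[SiteKey]:
        chrom_order = {name: i for i, name in enumerate(self.reference.chromosomes)}
        return sorted(self.site_calls, key=lambda s: (chrom_order.get(s[0], 1 << 30), s[1]))

    def calls_in_range(self, chrom: str, start: int, end: int) -> dict[SiteKey, dict[str, list[VariantCall]]]:
        """Site calls whose anchor position lies in a 1-based inclusive range."""
        positions = self._positions.get(chrom, [])
        lo = bisect.bisect_left(positions, start)
        hi = bisect.bisect_right(positions, end)
        return {
            (chrom, p): self.site_calls[(chrom, p)] for p in positions[lo:hi]
        }


# ---------------------------------------------------------------------------
# Filter 1: rare-allele / monomorphism


def select_target_allele(
    site: SiteKey,
    site_calls: Mapping[str, list[VariantCall]],
    n_genomes: int,
    max_other_frac: float = 0.10,
    het_carries_alt: bool = True,
) -> TargetVariant | FilterOutcome:
    """Pick the modal alternative allele, or reject the site.

    A line carrying any alternative allele other than the modal one counts
    against the ``max_other_frac`` budget (strictly more than 10% of lines
    rejects).  A site where every line is homozygous for the same
    alternative shows no polymorphism within the panel and is rejected as
    monomorphic.  Ties between equally common alternatives are broken
    lexicographically on (alt, ref) allele strings.
    """
    if not site_calls:
        raise ValueError(f"site {site} has no alternative allele (caller bug)")
    weight = 1.0 if het_carries_alt else 0.5
    counts: dict[tuple[str, str], float] = {}
    hom_counts: dict[tuple[str, str], int] = {}
    carriers: dict[tuple[str, str], set[str]] = {}
    for genome, calls in site_calls.items():
        for c in calls:
            key = (c.ref_allele, c.alt_allele)
            w = 1.0 if c.zygosity is Zygosity.HOM_ALT else weight
            counts[key] = counts.get(key, 0.0) + w
            carriers.setdefault(key, set()).add(genome)
            if c.zygosity is Zygosity.HOM_ALT:
                hom_counts[key] = hom_counts.get(key, 0) + 1
    # modal allele; ties broken lexicographically on (alt, ref)
    modal = min(counts, key=lambda k: (-counts[k], k[1], k[0]))
    if hom_counts.get(modal, 0) == n_genomes:
        return FilterOutcome(site, "fail", FilterRule.MONOMORPHIC, "all lines homozygous for the alternative allele")
    other_lines = {
        g for key, gs in carriers.items() if key != modal for g in gs
    } - carriers[modal]
    if len(other_lines) / n_genomes > max_other_frac:
        return FilterOutcome(
            site,
            "fail",
            FilterRule.RARE_ALLELE,
            f"{len(other_lines)}/{n_genomes} lines carry another alternative allele",
        )
    ref, alt = modal
    return TargetVariant(
        chromosome=site[0],
        position=site[1],
        ref_allele=ref,
        target_allele=alt,
        variant_class=_classify(ref, alt),
        alt_counts=counts,
        carrier_set=frozenset(carriers[modal]),
    )


def _classify(ref: str, alt: str) -> VariantClass:
    if len(ref) == len(alt) == 1:
        return VariantClass.SNP
    return VariantClass.INS if len(alt) > len(ref) else VariantClass.DEL


# ---------------------------------------------------------------------------
# Filters 2-3: fractional depth coverage


def _low_genomes_at(
    panel: GenomePanel, chrom: str, pos: int, low_depth_frac: float
) -> list[str]:
    out = []
    for genome in panel.genomes:
        track = panel.depth_tracks[genome]
        if track.depth_at(chrom, pos) < low_depth_frac * track.mean_depth:
            out.append(genome)
    return out


def check_target_coverage(
    site: SiteKey,
    panel: GenomePanel,
    low_depth_frac: float = 0.1,
    max_low_genomes_frac: float = 0.10,
) -> FilterOutcome:
    """Reject when the target base is low-coverage in >10% of genomes."""
    low = _low_genomes_at(panel, site[0], site[1], low_depth_frac)
    if len(low) / panel.n_genomes > max_low_genomes_frac:
        return FilterOutcome(
            site,
            "fail",
            FilterRule.TARGET_COVERAGE,
            f"low coverage in {len(low)}/{panel.n_genomes} genomes",
        )
    return FilterOutcome(site, "pass")


def check_flank_coverage(
    site: SiteKey,
    panel: GenomePanel,
    flank_bp: int = 50,
    low_depth_frac: float = 0.1,
    max_low_genomes_frac: float = 0.10,
    any_genome_fails: bool = False,
) -> FilterOutcome:
    """Apply the target-coverage criterion to every flank base.

    One failing flank position rejects the whole site.  With
    ``any_genome_fails`` the stricter reading applies: a single genome
    low at a single flank base suffices.  Sites closer than ``flank_bp``
    to a chromosome end cannot host a full design and are rejected.
    """
    chrom, pos = site
    if pos - flank_bp < 1 or pos + flank_bp > panel.reference.length(chrom):
        return FilterOutcome(site, "fail", FilterRule.FLANK_COVERAGE, "truncated flank")
    n = panel.n_genomes
    lows = np.zeros(2 * flank_bp + 1, dtype=np.int64)
    for genome in panel.genomes:
        track = panel.depth_tracks[genome]
        depths = track.depths_in_range(chrom, pos - flank_bp, pos + flank_bp)
        lows += depths < low_depth_frac * track.mean_depth
    lows[flank_bp] = 0  # centre base is filter 2's job
    threshold = 0 if any_genome_fails else max_low_genomes_frac * n
    bad = np.nonzero(lows > threshold)[0]
    if bad.size:
        offset = int(bad[0]) - flank_bp
        return FilterOutcome(
            site,
            "fail",
            FilterRule.FLANK_COVERAGE,
            f"flank base at offset {offset:+d} low in {int(lows[bad[0]])}/{n} genomes",
        )
    return FilterOutcome(site, "pass")


# ---------------------------------------------------------------------------
# Stage driver


def run_panel_filters(
    panel: GenomePanel,
    max_other_frac: float = 0.10,
    low_depth_frac: float = 0.1,
    max_low_genomes_frac: float = 0.10,
    flank_bp: int = 50,
    het_carries_alt: bool = True,
    strict_flank: bool = False,
) -> tuple[list[TargetVariant], list[FilterOutcome]]:
    """Run filters 1-3 over every candidate site.

    Returns the surviving targets and one outcome per site (pass outcomes
    included), in genomic order.
    """
    survivors: list[TargetVariant] = []
    outcomes: list[FilterOutcome] = []
    for site in panel.sites():
        result = select_target_allele(
            site, panel.site_calls[site], panel.n_genomes, max_other_frac, het_carries_alt
        )
        if isinstance(result, FilterOutcome):
            outcomes.append(result)
            continue
        target = result
        oc = check_target_coverage(site, panel, low_depth_frac, max_low_genomes_frac)
        if not oc.passed:
            outcomes.append(oc)
            continue
        oc = check_flank_coverage(
            site, panel, flank_bp, low_depth_frac, max_low_genomes_frac, strict_flank
        )
        if not oc.passed:
            outcomes.append(oc)
            continue
        outcomes.append(FilterOutcome(site, "pass"))
        survivors.append(target)
    return survivors, outcomes
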