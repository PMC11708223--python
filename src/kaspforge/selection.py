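"""Trait-targeted panel selection and the design query surface.

Breeders name trait loci (genes, SSR markers, array SNPs); the pipeline
offers every placed design within 20 kb of such a locus as a candidate,
keeps up to five per locus (protein-altering designs first, then nearest
first, never two mutually redundant designs within 100 bp carrying
identical predicted genotypes across all panel lines), and finally trims
the union down to a fixed assay quota by repeatedly removing the farthest
nonfunctional marker from whichever locus currently holds the most.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional

from .design import KASPDesign


@dataclasses.dataclass
class TraitTarget:
    target_id: str
    name: str
    assembly: str
    chromosome: str
    start: int
    end: int
    kind: str = "gene"  # gene | SSR | array_snp
    aliases: tuple[str, ...] = ()

    def distance_to(self, pos: int) -> int:
        if pos < self.start:
            return self.start - pos
        if pos > self.end:
            return pos - self.end
        return 0


@dataclasses.dataclass
class Candidate:
    design: KASPDesign
    distance: int


@dataclasses.dataclass
class PanelSelection:
    target: TraitTarget
    candidates: list[Candidate]
    selected: list[Candidate] = dataclasses.field(default_factory=list)
    removal_log: list[tuple[str, int]] = dataclasses.field(default_factory=list)  # (rule, pKey)


def _design_position(design: KASPDesign, assembly: str) -> Optional[tuple[str, int]]:
    pos = design.positions.get(assembly)
    if pos is not None:
        return pos
    if assembly not in design.positions:
        # unmapped assembly: fall back to the design's native coordinates
        return (design.target.chromosome, design.target.position)
    return None


def find_candidates(
    targets: Iterable[TraitTarget],
    designs: Iterable[KASPDesign],
    max_dist: int = 20_000,
) -> dict[str, PanelSelection]:
    """Per-target candidate lists: placed designs within ``max_dist`` bp.

    Distance runs from the design's target-variant base to the nearest
    edge of the trait-target interval; candidates are sorted by distance
    then pKey.
    """
    designs = list(designs)
    out: dict[str, PanelSelection] = {}
    for t in targets:
        cands: list[Candidate] = []
        for d in designs:
            pos = _design_position(d, t.assembly)
            if pos is None or pos[0] != t.chromosome:
                continue
            dist = t.distance_to(pos[1])
            if dist <= max_dist:
                cands.append(Candidate(d, dist))
        cands.sort(key=lambda c: (c.distance, c.design.pKey))
        out[t.target_id] = PanelSelection(t, cands)
    return out


def _redundant(a: KASPDesign, b: KASPDesign, assembly: str, dedup_bp: int) -> bool:
    pa = _design_position(a, assembly)
    pb = _design_position(b, assembly)
    if pa is None or pb is None or pa[0] != pb[0]:
        return False
    return abs(pa[1] - pb[1]) <= dedup_bp and a.predicted_genotypes == b.predicted_genotypes


def select_per_target(
    selection: PanelSelection,
    k: int = 5,
    dedup_bp: int = 100,
) -> PanelSelection:
    """Choose up to k candidates: functional nearest-first, then the rest.

    A candidate redundant with an already chosen one (within ``dedup_bp``
    and identical predicted genotypes across all lines) is skipped and the
    next candidate takes its slot; targets with fewer than k candidates
    keep everything admissible.
    """
    order = sorted(
        selection.candidates,
        key=lambda c: (not c.design.functional, c.distance, c.design.pKey),
    )
    chosen: list[Candidate] = []
    for cand in order:
        if len(chosen) >= k:
            break
        if any(
            _redundant(cand.design, c.design, selection.target.assembly, dedup_bp)
            for c in chosen
        ):
            selection.removal_log.append(("redundant_within_100bp", cand.design.pKey))
            continue
        chosen.append(cand)
    chosen.sort(key=lambda c: (c.distance, c.design.pKey))
    selection.selected = chosen
    return selection


def trim_to_quota(
    selections: Mapping[str, PanelSelection],
    quota: int,
) -> set[int]:
    """Trim the union of per-target selections down to ``quota`` designs.

    Repeatedly, among the targets currently holding the most selected
    markers (ties: lexicographic target id), remove the nonfunctional
    marker farthest from its target (ties: highest pKey).  If no
    max-count target holds a nonfunctional marker the search widens to
    all targets; if none exists anywhere the farthest functional marker
    goes instead (logged as a deviation).
    """

    def union() -> set[int]:
        return {c.design.pKey for sel in selections.values() for c in sel.selected}

    while len(union()) > quota:
        active = sorted(
            (sel for sel in selections.values() if sel.selected),
            key=lambda s: (-len(s.selected), s.target.target_id),
        )
        if not active:
            break
        sel = victim = None
        rule = "quota_nonfunctional_farthest"
        for s in active:
            nonfunc = [c for c in s.selected if not c.design.functional]
            if nonfunc:
                sel = s
                victim = max(nonfunc, key=lambda c: (c.distance, c.design.pKey))
                break
        if victim is None:  # only functional markers remain: logged deviation
            sel = active[0]
            victim = max(sel.selected, key=lambda c: (c.distance, c.design.pKey))
            rule = "quota_functional_farthest"
        sel.selected.remove(victim)
        sel.removal_log.append((rule, victim.design.pKey))
    return union()


def build_panel(
    targets: Iterable[TraitTarget],
    designs: Iterable[KASPDesign],
    k: int = 5,
    max_dist: int = 20_000,
    dedup_bp: int = 100,
    quota: int | None = None,
) -> dict[str, PanelSelection]:
    """Full two-stage selection: per-target pick, then global quota trim."""
    selections = find_candidates(targets, designs, max_dist)
    for sel in selections.values():
        select_per_target(sel, k, dedup_bp)
    if quota is not None:
        trim_to_quota(selections, quota)
    return selections


def query_designs(
    designs: Iterable[KASPDesign],
    assembly: str,
    region: tuple[str, int, int] | None = None,
    anchor: str | None = None,
    targets: Iterable[TraitTarget] = (),
    distance: int = 10_000,
) -> list[KASPDesign]:
    """Search-tool query: designs in a region, or near a named trait locus.

    ``anchor`` matches a trait target's id, name or alias; unknown names
    raise ``KeyError``.
    """
    designs = list(designs)
    if region is not None:
        chrom, start, end = region
        out = []
        for d in designs:
            pos = _design_position(d, assembly)
            if pos is not None and pos[0] == chrom and start <= pos[1] <= end:
                out.append(d)
        return sorted(out, key=lambda d: d.pKey)
    if anchor is None:
        raise ValueError("either region or anchor must be given")
    for t in targets:
        if anchor in (t.target_id, t.name) or anchor in t.aliases:
            sel = find_candidates([t], designs, distance)[t.target_id]
            return [c.design for c in sel.candidates]
    raise KeyError(f"unknown anchor name {anchor!r}")
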