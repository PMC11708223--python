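"""Synthetic study generator: genomes, variant panels, gene models,
genotyping runs — each with analytically derived ground truth.

The generator emulates the structure of a multi-genome resequencing panel
compared against one reference assembly: a panel of N genomes with
site-wise alternative alleles at controlled frequencies, per-genome read
depth with planted low-coverage patches, flanking SNP/indel structure
spanning both sides of every design rule, genes with valid coding
sequence for effect prediction, and a genotyping run with configurable
call-failure and discordance rates.

Every planted candidate site carries a :class:`TruthRecord` stating which
filter (if any) should reject it and, for survivors, the exact degenerate
design sequence.  Truth verdicts are computed here by straight-line
reimplementations of the rules (including an independent IUPAC table, a
regex-based tandem-repeat detector and a direct GC counter), never by
calling the pipeline modules — the agreement test between the two is the
repository's central double-entry check.
"""

from __future__ import annotations

import dataclasses
import itertools
import re
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    DepthTrack,
    ReferenceGenome,
    VariantCall,
    VariantClass,
    Zygosity,
)

_COMP = str.maketrans("ACGT", "TGCA")
_STOPS = ("TAA", "TAG", "TGA")
_CODONS_NO_STOP = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# independent IUPAC table for truth-side design construction
_TRUTH_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "AC": "M", "AG": "R", "AT": "W", "CG": "S", "CT": "Y", "GT": "K",
    "ACG": "V", "ACT": "H", "AGT": "D", "CGT": "B", "ACGT": "N",
}
_TRUTH_SETS = {v: k for k, v in _TRUTH_IUPAC.items()}
_REPEAT_RE = re.compile(r"(.{1,5})\1{5,}")


@dataclasses.dataclass
class PanelSpec:
    """Shape of the synthetic study (desk-scale by default).

    The default scenario — 20 genomes, one 200 kb chromosome, candidate
    sites every 110 bp (~1,800 sites) — runs the whole pipeline end to
    end in well under a minute while planting cases on both sides of
    every filter boundary.
    """

    n_genomes: int = 20
    chrom_length: int = 200_000
    chrom_name: str = "chr1"
    gc: float = 0.43
    site_stride: int = 110
    margin: int = 60
    dup_zone: int = 3_000  # trailing bases reserved for duplicated contexts
    n_genes: int = 30
    n_duplicated_sites: int = 8
    n_repeat_tracts: int = 12
    n_at_tracts: int = 12
    mean_depth_range: tuple[float, float] = (6.2, 90.3)
    call_depth_range: tuple[int, int] = (5, 60)
    het_rate: float = 0.15


@dataclasses.dataclass
class TruthRecord:
    """Analytic expectation for one planted candidate site."""

    site: tuple[str, int]
    failed_rule: str  # "none" for an expected pass
    design_sequence: Optional[str] = None
    region: Optional[str] = None
    effect: Optional[str] = None
    functional: Optional[bool] = None
    scenario: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class TruthTable:
    records: dict[tuple[str, int], TruthRecord]

    def counts_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records.values():
            out[rec.failed_rule] = out.get(rec.failed_rule, 0) + 1
        return out


@dataclasses.dataclass
class SyntheticGene:
    gene_id: str
    chromosome: str
    strand: str
    start: int  # 1-based inclusive genomic span
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, phase)
    cds_seq: str  # spliced, transcription orientation
    # genomic position (1-based) -> ("utr5"|"cds"|"intron"|"utr3", cds offset or -1)
    role: dict[int, tuple[str, int]]


# ---------------------------------------------------------------------------
# Reference + genes


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str, start: int, strand: str) -> tuple[str, SyntheticGene]:
    """Build one gene's genomic segment plus its model and role map."""
    n_exons = int(rng.integers(1, 4))
    n_codons = int(rng.integers(40, 120))
    codons = (
        ["ATG"]
        + [ _CODONS_NO_STOP[i] for i in rng.integers(0, len(_CODONS_NO_STOP), n_codons - 2) ]
        + [_STOPS[int(rng.integers(0, 3))]]
    )
    cds_seq = "".join(codons)
    # split the CDS across exons (each piece >= 3 bp)
    if n_exons == 1:
        pieces = [cds_seq]
    else:
        cuts = sorted(rng.choice(np.arange(3, len(cds_seq) - 3), size=n_exons - 1, replace=False))
        pieces, prev = [], 0
        for cut in cuts:
            pieces.append(cds_seq[prev:cut])
            prev = cut
        pieces.append(cds_seq[prev:])
    utr5 = _random_seq(rng, int(rng.integers(10, 40)), 0.45)
    utr3 = _random_seq(rng, int(rng.integers(10, 40)), 0.45)
    introns = [_random_seq(rng, int(rng.integers(50, 200)), 0.40) for _ in range(n_exons - 1)]

    # transcription-order blocks
    blocks: list[tuple[str, str]] = [("utr5", utr5)]
    for i, piece in enumerate(pieces):
        blocks.append(("cds", piece))
        if i < len(introns):
            blocks.append(("intron", introns[i]))
    blocks.append(("utr3", utr3))
    tx_seq = "".join(seq for _, seq in blocks)
    seg_len = len(tx_seq)

    # transcription-order offsets -> genomic offsets within the segment
    def genomic_off(tx_off: int) -> int:
        return tx_off if strand == "+" else seg_len - 1 - tx_off

    role: dict[int, tuple[str, int]] = {}
    tx_off = 0
    cds_off = 0
    tx_intervals: dict[str, list[tuple[int, int, int]]] = {"cds": [], "exon": []}
    exon_open: Optional[int] = None
    for kind, seq in blocks:
        for j in range(len(seq)):
            g = start + genomic_off(tx_off + j)
            role[g] = (kind, cds_off + j if kind == "cds" else -1)
        if kind == "cds":
            tx_intervals["cds"].append((tx_off, tx_off + len(seq) - 1, cds_off))
            cds_off += len(seq)
        if kind != "intron":
            if exon_open is None:
                exon_open = tx_off
        else:
            tx_intervals["exon"].append((exon_open, tx_off - 1, -1))
            exon_open = None
        tx_off += len(seq)
    tx_intervals["exon"].append((exon_open, tx_off - 1, -1))

    def to_genomic(a: int, b: int) -> tuple[int, int]:
        lo, hi = sorted((start + genomic_off(a), start + genomic_off(b)))
        return lo, hi

    exons = sorted(to_genomic(a, b) for a, b, _ in tx_intervals["exon"])
    cds = []
    for a, b, coff in tx_intervals["cds"]:
        lo, hi = to_genomic(a, b)
        phase = (3 - coff % 3) % 3
        cds.append((lo, hi, phase))
    cds.sort()
    seg = tx_seq if strand == "+" else tx_seq.translate(_COMP)[::-1]
    gene = SyntheticGene(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        start=start,
        end=start + seg_len - 1,
        exons=exons,
        cds=cds,
        cds_seq=cds_seq,
        role=role,
    )
    return seg, gene


def site_positions(spec: PanelSpec) -> list[int]:
    """The deterministic candidate-site grid (1-based positions)."""
    hi = spec.chrom_length - spec.dup_zone - spec.margin
    return list(range(spec.margin, hi, spec.site_stride))


def generate_reference(
    spec: PanelSpec, seed: int
) -> tuple[ReferenceGenome, list[SyntheticGene], dict]:
    """Random assembly with planted genes, repeat/AT tracts and duplications.

    Returns the reference, the gene models, and a layout dict recording
    which candidate sites sit on a repeat tract, a low-GC tract or a
    duplicated context (consumed by :func:`generate_panel` truth).
    """
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, spec.chrom_length, spec.gc))
    chrom = spec.chrom_name

    # genes, non-overlapping, clear of the duplication zone
    genes: list[SyntheticGene] = []
    occupied: list[tuple[int, int]] = []
    attempts = 0
    while len(genes) < spec.n_genes and attempts < spec.n_genes * 30:
        attempts += 1
        start = int(rng.integers(spec.margin, spec.chrom_length - spec.dup_zone - 2500))
        strand = "+" if rng.random() < 0.5 else "-"
        seg, gene = _make_gene(rng, f"gene{len(genes) + 1:03d}", chrom, start, strand)
        if gene.end >= spec.chrom_length - spec.dup_zone:
            continue
        if any(not (gene.end < s or gene.start > e) for s, e in occupied):
            continue
        seq[gene.start - 1 : gene.end] = list(seg)
        occupied.append((gene.start, gene.end))
        genes.append(gene)

    sites = site_positions(spec)
    in_gene = lambda p: any(s <= p <= e for s, e in occupied)
    free_sites = [p for p in sites if not any(in_gene(p + o) for o in (-55, 0, 55))]
    rng.shuffle(free_sites)
    layout = {"repeat_sites": set(), "at_sites": set(), "dup_sites": set()}

    k = 0
    for _ in range(spec.n_repeat_tracts):
        if k >= len(free_sites):
            break
        p = free_sites[k]; k += 1
        unit = ["AC", "AG", "CT", "TG"][int(rng.integers(0, 4))]
        tract = unit * 7  # 7 copies: fails the >5-copy rule in every resolution
        off = int(rng.integers(6, 30))
        seq[p + off - 1 : p + off - 1 + len(tract)] = list(tract)
        layout["repeat_sites"].add(p)
    for _ in range(spec.n_at_tracts):
        if k >= len(free_sites):
            break
        p = free_sites[k]; k += 1
        tract = _repeat_free_at_tract(rng, 55)
        seq[p - 28 : p + 27] = list(tract)  # the 55 bp window centred on p
        layout["at_sites"].add(p)

    ref_seq = "".join(seq)
    # duplicated contexts: copy the 101 bp window of selected sites into the dup zone
    dup_candidates = [p for p in free_sites[k:] if p not in layout["repeat_sites"]]
    dup_cursor = spec.chrom_length - spec.dup_zone + 50
    for p in dup_candidates[: spec.n_duplicated_sites]:
        window = ref_seq[p - 51 : p + 50]
        if dup_cursor + 101 > spec.chrom_length:
            break
        ref_seq = ref_seq[: dup_cursor - 1] + window + ref_seq[dup_cursor - 1 + 101 :]
        layout["dup_sites"].add(p)
        dup_cursor += 140

    reference = ReferenceGenome("synthref", {chrom: ref_seq})
    return reference, genes, layout


def _repeat_free_at_tract(rng: np.random.Generator, length: int) -> str:
    """An A/T-only string (GC 0%) free of >5-copy short tandem runs."""
    while True:
        s = "".join("AT"[i] for i in rng.integers(0, 2, length))
        if not _REPEAT_RE.search(s):
            return s


# ---------------------------------------------------------------------------
# GFF3 writing for the planted gene models


def write_gene_models_gff3(genes: list[SyntheticGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chromosome}\tsynth\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chromosome}\tsynth\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chromosome}\tsynth\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e, phase) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chromosome}\tsynth\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# Panel generation with analytic truth


@dataclasses.dataclass
class _SitePlan:
    pos: int
    ref_allele: str
    target_allele: str
    variant_class: str  # "SNP" | "INS" | "DEL"
    target_carriers: dict[str, tuple[str, int]]  # genome -> (zygosity, call depth)
    other_allele: Optional[tuple[str, str]] = None  # (ref, alt) of the competing allele
    other_carriers: dict[str, tuple[str, int]] = dataclasses.field(default_factory=dict)
    low_target_genomes: list[str] = dataclasses.field(default_factory=list)
    low_flank: Optional[tuple[int, list[str]]] = None  # (offset, genomes)
    # (offset, {alt base -> carrier genomes})
    flank_snps: list[tuple[int, dict[str, list[str]]]] = dataclasses.field(default_factory=list)
    # (offset, kind, length, carriers); several entries may share an offset
    flank_indels: list[tuple[int, str, int, list[str]]] = dataclasses.field(default_factory=list)
    scenario: dict = dataclasses.field(default_factory=dict)


def _plan_site(
    rng: np.random.Generator,
    reference: ReferenceGenome,
    chrom: str,
    pos: int,
    genomes: list[str],
    spec: PanelSpec,
    forced_coverage: str | None = None,
    plant_flanks: bool = True,
) -> _SitePlan:
    n = len(genomes)
    boundary = int(np.floor(0.10 * n))  # largest count that still passes ">10%"
    ref_base = reference.base(chrom, pos)

    vtype = rng.choice(["SNP", "INS", "DEL"], p=[0.8, 0.1, 0.1])
    if vtype == "SNP":
        ref_allele = ref_base
        target_allele = rng.choice([b for b in "ACGT" if b != ref_base])
    elif vtype == "INS":
        ref_allele = ref_base
        target_allele = ref_base + _random_seq(rng, int(rng.integers(1, 8)), 0.5)
    else:
        length = int(rng.integers(1, 8))
        ref_allele = reference.slice(chrom, pos, pos + length)
        target_allele = ref_base

    def depth() -> int:
        return int(rng.integers(*spec.call_depth_range))

    def pick(k: int, exclude: set[str] = frozenset()) -> list[str]:
        pool = [g for g in genomes if g not in exclude]
        return [str(g) for g in rng.choice(pool, size=min(k, len(pool)), replace=False)]

    def carriers(names: list[str], low_depth: bool = False) -> dict[str, tuple[str, int]]:
        out = {}
        for g in names:
            zyg = "het" if rng.random() < spec.het_rate else "hom"
            out[g] = (zyg, int(rng.integers(1, 5)) if low_depth else depth())
        return out

    allele_scn = rng.choice(
        ["clean", "boundary_other", "rare_fail", "mono", "tie", "lowdepth"],
        p=[0.55, 0.10, 0.10, 0.05, 0.05, 0.15],
    )
    plan = _SitePlan(
        pos=pos,
        ref_allele=ref_allele,
        target_allele=target_allele,
        variant_class=vtype,
        target_carriers={},
        scenario={"allele": str(allele_scn), "vtype": str(vtype)},
    )
    other_base = None
    if vtype == "SNP":
        choices = [b for b in "ACGT" if b not in (ref_base, target_allele)]
        other_base = str(rng.choice(choices))

    if allele_scn == "mono":
        plan.target_carriers = {g: ("hom", depth()) for g in genomes}
    elif allele_scn == "tie" and other_base is not None:
        c = max(1, boundary)
        named = pick(2 * c)
        plan.target_carriers = carriers(named[:c])
        plan.other_allele = (ref_base, other_base)
        plan.other_carriers = carriers(named[c:])
    else:
        m = int(rng.integers(1, n))
        named = pick(m)
        plan.scenario["n_carriers"] = m
        if allele_scn == "lowdepth":
            # some carrier calls fall under the depth-5 load cut (never all)
            n_low = int(rng.integers(1, len(named) + 1)) if len(named) > 1 else 0
            plan.target_carriers = {
                **carriers(named[n_low:]),
                **carriers(named[:n_low], low_depth=True),
            }
            plan.scenario["n_lowdepth_calls"] = n_low
        else:
            plan.target_carriers = carriers(named)
        if allele_scn in ("boundary_other", "rare_fail") and other_base is not None:
            k = boundary if allele_scn == "boundary_other" else boundary + 1
            plan.other_allele = (ref_base, other_base)
            plan.other_carriers = carriers(pick(k, exclude=set(named)))

    cov_scn = forced_coverage or rng.choice(
        ["ok", "target_low_pass", "target_low_fail", "flank_low_pass", "flank_low_fail"],
        p=[0.72, 0.06, 0.08, 0.06, 0.08],
    )
    plan.scenario["coverage"] = str(cov_scn)
    if cov_scn == "target_low_pass":
        plan.low_target_genomes = pick(boundary)
    elif cov_scn == "target_low_fail":
        plan.low_target_genomes = pick(int(rng.integers(boundary + 1, n + 1)))
    elif cov_scn in ("flank_low_pass", "flank_low_fail"):
        off = int(rng.integers(1, 51)) * (1 if rng.random() < 0.5 else -1)
        k = boundary if cov_scn == "flank_low_pass" else boundary + 1
        plan.low_flank = (off, pick(k))

    if plant_flanks:
        _plan_flank_variation(rng, plan, reference, chrom, genomes, spec)
    return plan


def _plan_flank_variation(rng, plan: _SitePlan, reference, chrom, genomes, spec: PanelSpec):
    n = len(genomes)
    chrom_len = reference.length(chrom)
    taken: set[int] = {0}
    if plan.variant_class == "DEL":
        taken |= set(range(1, len(plan.ref_allele)))

    indel_scn = rng.choice(
        ["none", "ok", "near", "long", "two", "unequal"],
        p=[0.70, 0.12, 0.05, 0.05, 0.04, 0.04],
    )
    plan.scenario["flank_indel"] = str(indel_scn)

    def free_offset(lo_abs: int, hi_abs: int, span: int = 0, sign: int = 0) -> Optional[int]:
        for _ in range(40):
            s = sign or (1 if rng.random() < 0.5 else -1)
            off = int(rng.integers(lo_abs, hi_abs + 1)) * s
            span_offsets = set(range(off, off + span + 1))
            if span_offsets & taken:
                continue
            lo_pos = plan.pos + min(span_offsets)
            hi_pos = plan.pos + max(span_offsets)
            if lo_pos < 1 or hi_pos > chrom_len:
                continue
            taken.update(span_offsets)
            return off
        return None

    def some_carriers() -> list[str]:
        size = int(rng.integers(1, max(2, n // 2)))
        return [str(g) for g in rng.choice(genomes, size=size, replace=False)]

    def plant_indel(off_lo: int, off_hi: int, length: int, kind: str | None = None):
        kind = kind or ("INS" if rng.random() < 0.5 else "DEL")
        span = length if kind == "DEL" else 0
        off = free_offset(off_lo, off_hi, span)
        if off is None:
            return
        plan.flank_indels.append((off, kind, length, some_carriers()))

    if indel_scn == "ok":
        plant_indel(7, 38, int(rng.integers(1, 11)))
    elif indel_scn == "near":
        plant_indel(2, 5, int(rng.integers(1, 6)), kind="INS")
    elif indel_scn == "long":
        plant_indel(7, 35, int(rng.integers(11, 13)))
    elif indel_scn == "two":
        plant_indel(7, 25, int(rng.integers(1, 6)))
        plant_indel(26, 40, int(rng.integers(1, 6)))
    elif indel_scn == "unequal":
        off = free_offset(7, 35, 3)
        if off is not None:
            plan.flank_indels.append((off, "DEL", 2, some_carriers()))
            plan.flank_indels.append((off, "DEL", 3, some_carriers()))

    counts = [0, 1, 2, 3, 4, 5, 6]
    probs = [0.38, 0.24, 0.15, 0.08, 0.05, 0.05, 0.05]
    for side in (-1, 1):
        k = int(rng.choice(counts, p=probs))
        for _ in range(k):
            off = free_offset(1, 50, sign=side)
            if off is None:
                continue
            ref_b = reference.base(chrom, plan.pos + off)
            cs = some_carriers()
            n_alts = min(len(cs), 1 if rng.random() < 0.8 else 2)
            alt_pool = [b for b in "ACGT" if b != ref_b]
            alts = [str(a) for a in rng.choice(alt_pool, size=n_alts, replace=False)]
            # split carriers across the alternative bases at this site
            per_alt = {a: cs[i::n_alts] for i, a in enumerate(alts)}
            plan.flank_snps.append((off, per_alt))


def _emit_calls(plan: _SitePlan, chrom: str, calls_by_genome: dict[str, list[VariantCall]]):
    def emit(genome, pos, ref, alt, vclass, dp, zyg):
        calls_by_genome[genome].append(
            VariantCall(
                genome_id=genome,
                chromosome=chrom,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                variant_class=VariantClass[vclass],
                read_depth=dp,
                zygosity=Zygosity.HOM_ALT if zyg == "hom" else Zygosity.HET,
            )
        )

    for g, (zyg, dp) in plan.target_carriers.items():
        emit(g, plan.pos, plan.ref_allele, plan.target_allele, plan.variant_class, dp, zyg)
    if plan.other_allele is not None:
        ref, alt = plan.other_allele
        for g, (zyg, dp) in plan.other_carriers.items():
            emit(g, plan.pos, ref, alt, "SNP", dp, zyg)
    for off, per_alt in plan.flank_snps:
        for alt in sorted(per_alt):
            for g in per_alt[alt]:
                emit(g, plan.pos + off, _flank_ref_base(plan, off), alt, "SNP", 30, "hom")
    for off, kind, length, carriers in plan.flank_indels:
        p = plan.pos + off
        anchor = _flank_ref_base(plan, off)
        if kind == "INS":
            ref, alt = anchor, anchor + "A" * length
        else:
            ref, alt = anchor + plan.flank_del_seqs[(off, length)], anchor
        for g in carriers:
            emit(g, p, ref, alt, kind, 30, "hom")


def _flank_ref_base(plan: _SitePlan, off: int) -> str:
    return plan.flank_ref_bases[off]


def _build_track(genome: str, mean_depth: float, spec: PanelSpec, low_positions: list[int]) -> DepthTrack:
    base = max(int(round(mean_depth)), 1)
    rows: list[tuple[int, int, int]] = []
    prev = 1
    for p in low_positions:
        if p > prev:
            rows.append((prev, p - 1, base))
        rows.append((p, p, 0))
        prev = p + 1
    if prev <= spec.chrom_length:
        rows.append((prev, spec.chrom_length, base))
    return DepthTrack(genome, mean_depth, {spec.chrom_name: rows})


# attach reference-dependent lookups to plans lazily
def _prepare_plan_sequences(plan: _SitePlan, reference: ReferenceGenome, chrom: str) -> None:
    plan.flank_ref_bases = {
        off: reference.base(chrom, plan.pos + off)
        for off in range(-55, 56)
        if 1 <= plan.pos + off <= reference.length(chrom)
    }
    plan.flank_del_seqs = {}
    for off, kind, length, _ in plan.flank_indels:
        if kind == "DEL":
            plan.flank_del_seqs[(off, length)] = reference.slice(
                chrom, plan.pos + off + 1, plan.pos + off + length
            )


# ---------------------------------------------------------------------------
# Truth computation (straight-line, independent of the pipeline modules)


def _truth_for_site(
    plan: _SitePlan,
    reference: ReferenceGenome,
    genes: list[SyntheticGene],
    layout: dict,
    spec: PanelSpec,
) -> TruthRecord:
    chrom = spec.chrom_name
    n = spec.n_genomes
    rec = TruthRecord(site=(chrom, plan.pos), failed_rule="none", scenario=dict(plan.scenario))

    # --- load filter: SNP/INS calls with depth < 5 are never seen
    def surviving(carriers: dict[str, tuple[str, int]], vclass: str) -> dict[str, str]:
        out = {}
        for g, (zyg, dp) in carriers.items():
            if vclass in ("SNP", "INS") and dp < 5:
                continue
            out[g] = zyg
        return out

    target_lines = surviving(plan.target_carriers, plan.variant_class)
    other_lines = surviving(plan.other_carriers, "SNP") if plan.other_allele else {}

    if not target_lines and not other_lines:
        rec.failed_rule = "not_a_site"  # every call fell under the load cut
        return rec

    # --- filter 1: modal allele, rare alternatives, monomorphism
    alleles: dict[tuple[str, str], dict[str, str]] = {}
    if target_lines:
        alleles[(plan.ref_allele, plan.target_allele)] = target_lines
    if other_lines:
        alleles[plan.other_allele] = other_lines
    modal = min(alleles, key=lambda k: (-len(alleles[k]), k[1], k[0]))
    modal_lines = alleles[modal]
    if sum(1 for z in modal_lines.values() if z == "hom") == n:
        rec.failed_rule = "monomorphic"
        return rec
    others = set().union(*(set(v) for k, v in alleles.items() if k != modal)) - set(modal_lines) \
        if len(alleles) > 1 else set()
    if len(others) / n > 0.10:
        rec.failed_rule = "rare_allele"
        return rec
    modal_ref, modal_alt = modal

    # --- filter 2: target coverage
    if len(plan.low_target_genomes) / n > 0.10:
        rec.failed_rule = "target_coverage"
        return rec

    # --- filter 3: flank coverage (planted patches; truncated flanks)
    if plan.pos - 50 < 1 or plan.pos + 50 > reference.length(chrom):
        rec.failed_rule = "flank_coverage"
        return rec
    if plan.low_flank is not None and len(plan.low_flank[1]) / n > 0.10:
        rec.failed_rule = "flank_coverage"
        return rec

    # --- filter 4: flank variation admissibility
    # flank calls are planted at depth 30 (> 5): all survive loading
    snp_sites = [(off, set(per_alt)) for off, per_alt in plan.flank_snps]
    indel_entries = plan.flank_indels
    indel_offsets = {off for off, *_ in indel_entries}
    if len(indel_offsets) > 1:
        rec.failed_rule = "flank_variation"
        return rec
    if indel_entries:
        kinds_lengths = {(kind, length) for _, kind, length, _ in indel_entries}
        if len(kinds_lengths) > 1:
            rec.failed_rule = "flank_variation"
            return rec
        off = next(iter(indel_offsets))
        kind, length = next(iter(kinds_lengths))
        if length > 10 or abs(off) <= 5:
            rec.failed_rule = "flank_variation"
            return rec
        if kind == "DEL":
            span_end = off + length
            if (off < 0 and span_end > -6) or span_end > 50:
                rec.failed_rule = "flank_variation"
                return rec
    n_left = sum(1 for off, _ in snp_sites if off < 0)
    n_right = sum(1 for off, _ in snp_sites if off > 0)
    if max(n_left, n_right) > 5:
        rec.failed_rule = "flank_variation"
        return rec

    # --- design sequence (independent construction)
    letters = list(reference.slice(chrom, plan.pos - 50, plan.pos + 50))
    for off, alts in snp_sites:
        bases = {reference.base(chrom, plan.pos + off)} | alts
        letters[50 + off] = _TRUTH_IUPAC["".join(sorted(bases))]
    target_index = 50
    if indel_entries:
        off, kind, length, _ = indel_entries[0]
        if kind == "DEL":
            for o in range(off + 1, off + length + 1):
                letters[50 + o] = "N"
        else:
            at = 50 + off + 1
            letters[at:at] = ["N"] * length
            if off < 0:
                target_index += length
    design_seq = "".join(letters)

    # --- repeat screen: regex over every SNP resolution, Ns removed
    stripped = design_seq.replace("N", "")
    options = [sorted(_TRUTH_SETS.get(ch, ch)) for ch in stripped]
    for resolution in itertools.product(*options):
        if _REPEAT_RE.search("".join(resolution)):
            rec.failed_rule = "repeat"
            return rec

    # --- GC window centred on the target
    start = min(max(target_index - 27, 0), len(design_seq) - 55)
    window = design_seq[start : start + 55]
    num = den = 0.0
    for ch in window:
        if ch == "N":
            continue
        s = _TRUTH_SETS[ch]
        num += sum(b in "GC" for b in s) / len(s)
        den += 1
    gc_pct = 100.0 * num / den
    if not (35.0 <= gc_pct <= 65.0):
        rec.failed_rule = "gc"
        return rec

    # --- alignment uniqueness: only planted duplications break it
    if plan.pos in layout["dup_sites"]:
        rec.failed_rule = "alignment"
        return rec

    rec.design_sequence = design_seq
    rec.region, rec.effect, rec.functional = _truth_effect(
        plan, modal_ref, modal_alt, genes
    )
    return rec


def _truth_effect(plan: _SitePlan, ref_allele: str, alt_allele: str, genes: list[SyntheticGene]):
    """Region/effect expectation from the generator's own gene bookkeeping."""
    from Bio.Seq import Seq

    pos = plan.pos
    is_indel = len(ref_allele) != len(alt_allele)
    if is_indel:
        length = abs(len(ref_allele) - len(alt_allele))
        lo, hi = (pos + 1, pos + length) if len(ref_allele) > len(alt_allele) else (pos, pos + 1)
    else:
        lo = hi = pos
    gene = next((g for g in genes if not (hi < g.start or lo > g.end)), None)
    if gene is None:
        return "intergenic", "none", False
    if is_indel:
        cds_offsets = [
            gene.role[p][1] for p in range(lo, hi + 1)
            if p in gene.role and gene.role[p][0] == "cds"
        ]
        if not cds_offsets:
            return _region_of(gene, pos), "none", False
        total = len(gene.cds_seq)
        if any(o < 3 for o in cds_offsets):
            return "CDS", "start_loss", True
        if any(o >= total - 3 for o in cds_offsets):
            return "CDS", "stop_loss", True
        effect = "frameshift" if length % 3 else "nonframeshift"
        return "CDS", effect, True
    region = _region_of(gene, pos)
    if region != "CDS":
        return region, "none", False
    off = gene.role[pos][1]
    alt_tx = alt_allele if gene.strand == "+" else alt_allele.translate(_COMP)
    ci = off // 3
    codon = gene.cds_seq[ci * 3 : ci * 3 + 3]
    mut = codon[: off % 3] + alt_tx + codon[off % 3 + 1 :]
    if ci == 0 and codon == "ATG" and mut != "ATG":
        return "CDS", "start_loss", True
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mut).translate())
    if alt_aa == ref_aa:
        return "CDS", "synonymous", False
    if ref_aa == "*":
        return "CDS", "stop_loss", True
    if alt_aa == "*":
        return "CDS", "premature_stop", True
    return "CDS", "nonsynonymous", True


def _region_of(gene: SyntheticGene, pos: int) -> str:
    kind = gene.role.get(pos, ("intergenic", -1))[0]
    return {"utr5": "UTR5", "utr3": "UTR3", "cds": "CDS", "intron": "intron"}.get(kind, kind)


# ---------------------------------------------------------------------------
# Whole-scenario convenience


@dataclasses.dataclass
class SyntheticScenario:
    spec: PanelSpec
    reference: ReferenceGenome
    genes: list[SyntheticGene]
    layout: dict
    calls_by_genome: dict[str, list[VariantCall]]
    depth_tracks: dict[str, DepthTrack]
    truth: TruthTable


def generate_scenario(seed: int, spec: PanelSpec | None = None) -> SyntheticScenario:
    """Reference + panel + truth in one deterministic call."""
    spec = spec or PanelSpec()
    reference, genes, layout = generate_reference(spec, seed)
    calls, tracks, truth = generate_panel(reference, genes, layout, spec, seed)
    return SyntheticScenario(spec, reference, genes, layout, calls, tracks, truth)


def generate_panel(reference, genes, layout, spec, seed):
    """Plant per-genome calls and depth patches; derive truth analytically.

    Returns ``(calls_by_genome, depth_tracks, truth)``.  The calls are
    unfiltered (the call-depth rule is the loader's job); the truth
    applies every rule — including that load filter — by independent code.
    """
    rng = np.random.default_rng(seed + 1)
    chrom = spec.chrom_name
    genomes = [f"g{i:03d}" for i in range(1, spec.n_genomes + 1)]
    mean_depths = {g: float(rng.uniform(*spec.mean_depth_range)) for g in genomes}

    plans: list[_SitePlan] = []
    for pos in site_positions(spec):
        plans.append(_plan_site(rng, reference, chrom, pos, genomes, spec))
    # truncated-flank specials near the chromosome ends; kept clear of the
    # first grid site's flank and planted without flank variation so they
    # cannot contaminate neighbouring truth records
    for pos in (max(1, spec.margin - 51), reference.length(chrom) - 25):
        plan = _plan_site(
            rng, reference, chrom, pos, genomes, spec,
            forced_coverage="ok", plant_flanks=False,
        )
        plan.scenario["truncated"] = True
        plans.append(plan)

    calls_by_genome: dict[str, list[VariantCall]] = {g: [] for g in genomes}
    low_patches: dict[str, list[int]] = {g: [] for g in genomes}
    for plan in plans:
        _prepare_plan_sequences(plan, reference, chrom)
        _emit_calls(plan, chrom, calls_by_genome)
        for g in plan.low_target_genomes:
            low_patches[g].append(plan.pos)
        if plan.low_flank is not None:
            off, gs = plan.low_flank
            for g in gs:
                low_patches[g].append(plan.pos + off)

    depth_tracks = {
        g: _build_track(g, mean_depths[g], spec, sorted(set(low_patches[g])))
        for g in genomes
    }
    truth = TruthTable(
        {
            (chrom, plan.pos): _truth_for_site(plan, reference, genes, layout, spec)
            for plan in plans
        }
    )
    return calls_by_genome, depth_tracks, truth


def write_scenario(sc: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Emit the scenario as plain-text files (FASTA, VCF, TSV, GFF3).

    Returns the paths written; reloading them through
    :mod:`kaspforge.io_formats` reproduces the in-memory objects.
    """
    from .io_formats import write_depth_track, write_reference, write_variant_calls

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "vcf": out / "panel.vcf",
        "gff": out / "genes.gff3",
        "truth": out / "truth.tsv",
    }
    write_reference(sc.reference, paths["reference"])
    write_variant_calls(sc.calls_by_genome, sc.reference, paths["vcf"])
    write_gene_models_gff3(sc.genes, paths["gff"])
    depth_dir = out / "depth"
    depth_dir.mkdir(exist_ok=True)
    for g, track in sc.depth_tracks.items():
        write_depth_track(track, depth_dir / f"{g}.depth.tsv")
    paths["depth_dir"] = depth_dir
    with open(paths["truth"], "w") as fh:
        fh.write("# chrom\tpos\tfailed_rule\tregion\teffect\tfunctional\tdesign_sequence\n")
        for (chrom, pos), rec in sorted(sc.truth.records.items()):
            fh.write(
                f"{chrom}\t{pos}\t{rec.failed_rule}\t{rec.region or '.'}\t"
                f"{rec.effect or '.'}\t{rec.functional if rec.functional is not None else '.'}\t"
                f"{rec.design_sequence or '.'}\n"
            )
    return paths


# ---------------------------------------------------------------------------
# Genotyping-run generator


@dataclasses.dataclass
class GenotypingTruth:
    group_of_sample: dict[str, int]
    dead_markers: list[str]
    monomorphic_markers: list[str]
    drifted_lines: dict[str, float]
    named_lines: list[str]


def generate_genotyping_run(
    designs,
    seed: int,
    n_samples: int = 60,
    k_groups: int = 4,
    cell_fail_rate: float = 0.03,
    dead_marker_frac: float = 0.15,
    monomorphic_frac: float = 0.005,
    named_lines: list[str] | None = None,
    drifted_lines: dict[str, float] | None = None,
):
    """Simulate a diversity-panel genotyping run over the given designs.

    Samples come from ``k_groups`` planted subpopulations with divergent
    marker allele frequencies; a fraction of markers is dead (fails in all
    samples), individual calls fail at ``cell_fail_rate`` (split between
    "?", "Bad" and "Uncallable"), and samples listed in ``named_lines``
    reproduce the design-time predicted genotypes of the same-named panel
    genome, except for ``drifted_lines`` whose calls are flipped at the
    given discordance rate (emulating seed-lot drift).

    Returns ``(GenotypeMatrix, GenotypingTruth)``.
    """
    import pandas as pd

    from .genotypes import GenotypeMatrix

    rng = np.random.default_rng(seed + 2)
    named_lines = list(named_lines or [])
    drifted_lines = dict(drifted_lines or {})
    markers = [str(d.pKey) for d in designs]
    n_markers = len(markers)
    if n_markers == 0:
        raise ValueError("no designs to genotype")

    anon = [f"S{i:03d}" for i in range(1, n_samples - len(named_lines) + 1)]
    samples = anon + named_lines
    groups = {s: int(i % k_groups) + 1 for i, s in enumerate(anon)}

    n_dead = int(round(dead_marker_frac * n_markers))
    dead = set(rng.choice(markers, size=n_dead, replace=False))
    mono_pool = [m for m in markers if m not in dead]
    n_mono = max(1, int(round(monomorphic_frac * n_markers))) if mono_pool else 0
    mono = set(rng.choice(mono_pool, size=min(n_mono, len(mono_pool)), replace=False))

    # per-group reference-allele frequencies, strongly diverged
    freqs = {
        m: {g: float(rng.choice([0.1, 0.9])) for g in range(1, k_groups + 1)}
        for m in markers
    }
    for m in mono:
        for g in range(1, k_groups + 1):
            freqs[m][g] = 1.0

    fail_codes = np.array(["?", "Bad", "Uncallable"])
    predicted_by_design = {str(d.pKey): d.predicted_genotypes for d in designs}

    calls = pd.DataFrame("NA", index=samples, columns=markers)
    for m in markers:
        if m in dead:
            calls[m] = rng.choice(fail_codes, size=len(samples))
            continue
        col = []
        for s in samples:
            if s in groups:
                p_ref = freqs[m][groups[s]]
                n_ref = int(rng.binomial(2, p_ref))
                call = ("alt_hom", "het", "ref_hom")[n_ref]
            else:  # named line: start from the design-time prediction
                pred = predicted_by_design[m].get(s, "reference")
                call = {"reference": "ref_hom", "target": "alt_hom", "het": "het"}.get(
                    pred, "ref_hom"
                )
                rate = drifted_lines.get(s, 0.0)
                if rate and rng.random() < rate:
                    call = str(rng.choice([c for c in ("ref_hom", "alt_hom", "het") if c != call]))
            if rng.random() < cell_fail_rate:
                call = str(rng.choice(fail_codes))
            col.append(call)
        calls[m] = col

    truth = GenotypingTruth(
        group_of_sample=groups,
        dead_markers=sorted(dead),
        monomorphic_markers=sorted(mono),
        drifted_lines=drifted_lines,
        named_lines=named_lines,
    )
    return GenotypeMatrix(calls), truth
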