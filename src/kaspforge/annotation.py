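"""Predicted functional effect of target variants against gene models.

Each target variant is located relative to every annotated transcript
isoform (intergenic / UTR / intron / CDS) and, inside coding sequence,
its consequence is predicted on the spliced, strand-oriented CDS: SNPs are
re-translated codon-wise (synonymous, nonsynonymous, premature stop, stop
loss, start loss) and indels are classified by whether their length is a
multiple of three (nonframeshift) or not (frameshift), with start/stop
codon disruption taking precedence.  A design counts as *functional* when
any isoform in any annotated assembly predicts a protein-altering effect —
the property the panel-selection stage prefers.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import gffutils

from .io_formats import ReferenceGenome, VariantClass
from .panel import TargetVariant
from .sequence import revcomp, translate_cds


class Region(enum.Enum):
    INTERGENIC = "intergenic"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRON = "intron"
    CDS = "CDS"


class Effect(enum.Enum):
    NONE = "none"
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    PREMATURE_STOP = "premature_stop"
    STOP_LOSS = "stop_loss"
    START_LOSS = "start_loss"
    FRAMESHIFT = "frameshift"
    NONFRAMESHIFT = "nonframeshift"


FUNCTIONAL_EFFECTS = frozenset(
    {
        Effect.NONSYNONYMOUS,
        Effect.PREMATURE_STOP,
        Effect.STOP_LOSS,
        Effect.START_LOSS,
        Effect.FRAMESHIFT,
        Effect.NONFRAMESHIFT,
    }
)


@dataclasses.dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, sorted ascending
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]


@dataclasses.dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript]


@dataclasses.dataclass
class TranscriptEffect:
    assembly_id: str
    gene_id: str
    transcript_id: str
    region: Region
    effect: Effect

    @property
    def functional(self) -> bool:
        return self.effect in FUNCTIONAL_EFFECTS


@dataclasses.dataclass
class EffectAnnotation:
    records: list[TranscriptEffect]

    @property
    def functional(self) -> bool:
        return any(r.functional for r in self.records)

    @property
    def regions(self) -> set[Region]:
        return {r.region for r in self.records} or {Region.INTERGENIC}


# ---------------------------------------------------------------------------
# GFF3 loading


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Assemble hierarchical gene models from a GFF3 file.

    UTRs are derived as exon-minus-CDS when not annotated explicitly.
    Orphan CDS/exon features and CDS outside exons raise ``ValueError``.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    for feat in db.features_of_type(("CDS", "exon")):
        parents = list(db.parents(feat, featuretype=("mRNA", "transcript")))
        if not parents:
            raise ValueError(f"{feat.featuretype} at {feat.seqid}:{feat.start} has no mRNA parent")

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts: list[Transcript] = []
        for mrna in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
            cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
            for c in cds:
                if not any(e[0] <= c[0] and c[1] <= e[1] for e in exons):
                    raise ValueError(f"CDS {c} outside exons of {mrna.id}")
            utr5, utr3 = _derive_utrs(exons, cds, mrna.strand)
            transcripts.append(
                Transcript(mrna.id, mrna.strand, exons, cds, utr5, utr3)
            )
        genes.append(
            GeneModel(gene.id, gene.seqid, gene.strand, gene.start, gene.end, transcripts)
        )
    return genes


def _derive_utrs(exons, cds, strand):
    if not cds:
        return [], []
    cds_lo, cds_hi = cds[0][0], cds[-1][1]
    before, after = [], []
    for s, e in exons:
        if s < cds_lo:
            before.append((s, min(e, cds_lo - 1)))
        if e > cds_hi:
            after.append((max(s, cds_hi + 1), e))
    return (before, after) if strand == "+" else (after, before)


# ---------------------------------------------------------------------------
# Effect prediction


def _in_intervals(pos: int, intervals) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def _spliced_cds(tx: Transcript, chrom_seq: str) -> str:
    seq = "".join(chrom_seq[s - 1 : e] for s, e in tx.cds)
    return revcomp(seq) if tx.strand == "-" else seq


def _cds_offset(tx: Transcript, pos: int) -> int:
    """0-based offset of a genomic position within the spliced CDS."""
    off = 0
    for s, e in tx.cds:
        if s <= pos <= e:
            off += pos - s
            break
        off += e - s + 1
    if tx.strand == "-":
        total = sum(e - s + 1 for s, e in tx.cds)
        off = total - off - 1
    return off


def _classify_cds_snp(tx: Transcript, chrom_seq: str, pos: int, alt: str) -> Effect:
    cds_seq = _spliced_cds(tx, chrom_seq)
    off = _cds_offset(tx, pos)
    alt_base = alt if tx.strand == "+" else revcomp(alt)
    ci = off // 3
    codon = cds_seq[ci * 3 : ci * 3 + 3]
    if len(codon) < 3:  # trailing partial codon of an incomplete model
        return Effect.NONE
    mut = list(codon)
    mut[off % 3] = alt_base
    mut_codon = "".join(mut)
    ref_aa = translate_cds(codon)
    alt_aa = translate_cds(mut_codon)
    if ci == 0 and codon == "ATG" and mut_codon != "ATG":
        return Effect.START_LOSS
    if alt_aa == ref_aa:
        return Effect.SYNONYMOUS
    if ref_aa == "*":
        return Effect.STOP_LOSS
    if alt_aa == "*":
        return Effect.PREMATURE_STOP
    return Effect.NONSYNONYMOUS


def _indel_span(variant: TargetVariant) -> tuple[int, int]:
    """Genomic bases affected by an indel (deleted run, or insertion anchor)."""
    pos = variant.position
    if variant.variant_class is VariantClass.DEL:
        length = len(variant.ref_allele) - len(variant.target_allele)
        return pos + 1, pos + length
    return pos, pos + 1


def _classify_cds_indel(tx: Transcript, variant: TargetVariant) -> Effect:
    length = abs(len(variant.target_allele) - len(variant.ref_allele))
    lo, hi = _indel_span(variant)
    # start / stop codon disruption takes precedence
    cds_positions_start = _terminal_codon_positions(tx, first=tx.strand == "+")
    cds_positions_stop = _terminal_codon_positions(tx, first=tx.strand == "-")
    span = set(range(lo, hi + 1))
    if span & cds_positions_start:
        return Effect.START_LOSS
    if span & cds_positions_stop:
        return Effect.STOP_LOSS
    return Effect.FRAMESHIFT if length % 3 else Effect.NONFRAMESHIFT


def _terminal_codon_positions(tx: Transcript, first: bool) -> set[int]:
    """Genomic positions of the left-most (first=True) or right-most codon."""
    flat = [p for s, e in tx.cds for p in range(s, e + 1)]
    return set(flat[:3]) if first else set(flat[-3:])


def annotate_variant(
    variant: TargetVariant,
    models: Iterable[GeneModel],
    reference: ReferenceGenome,
    assembly_id: str | None = None,
) -> EffectAnnotation:
    """Region and predicted effect of one variant on every overlapping isoform."""
    assembly = assembly_id or reference.assembly_id
    chrom, pos = variant.chromosome, variant.position
    if chrom not in reference.chromosomes or pos > reference.length(chrom):
        raise ValueError(f"variant at {chrom}:{pos} outside reference bounds")
    chrom_seq = reference.chromosomes[chrom]
    # an indel's affected span may reach into a gene even when the anchor
    # base sits just outside it
    if variant.variant_class is VariantClass.SNP:
        lo = hi = pos
    else:
        lo, hi = _indel_span(variant)
    records: list[TranscriptEffect] = []
    for gene in models:
        if gene.chromosome != chrom or hi < gene.start or lo > gene.end:
            continue
        for tx in gene.transcripts:
            region, effect = _tx_region_effect(tx, chrom_seq, variant)
            records.append(TranscriptEffect(assembly, gene.gene_id, tx.transcript_id, region, effect))
    return EffectAnnotation(records)


def _tx_region_effect(tx: Transcript, chrom_seq: str, variant: TargetVariant):
    pos = variant.position
    is_indel = variant.variant_class is not VariantClass.SNP
    if is_indel:
        lo, hi = _indel_span(variant)
        overlaps_cds = any(not (hi < s or lo > e) for s, e in tx.cds)
    else:
        overlaps_cds = _in_intervals(pos, tx.cds)
    if overlaps_cds:
        if is_indel:
            return Region.CDS, _classify_cds_indel(tx, variant)
        return Region.CDS, _classify_cds_snp(tx, chrom_seq, pos, variant.target_allele)
    if _in_intervals(pos, tx.utr5):
        return Region.UTR5, Effect.NONE
    if _in_intervals(pos, tx.utr3):
        return Region.UTR3, Effect.NONE
    if _in_intervals(pos, tx.exons):
        return Region.CDS, Effect.NONE  # exonic in a model without CDS
    if tx.exons and tx.exons[0][0] <= pos <= tx.exons[-1][1]:
        return Region.INTRON, Effect.NONE
    return Region.INTERGENIC, Effect.NONE


def annotate_designs(
    designs,
    models_by_assembly: Mapping[str, Iterable[GeneModel]],
    references: Mapping[str, ReferenceGenome],
):
    """Attach effect annotations and the any-isoform functional flag in place."""
    for d in designs:
        records: list[TranscriptEffect] = []
        for assembly, models in models_by_assembly.items():
            ann = annotate_variant(d.target, models, references[assembly], assembly)
            records.extend(ann.records)
        d.effect = EffectAnnotation(records)
        d.functional = d.effect.functional
    return designs
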