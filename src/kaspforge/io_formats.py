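"""Readers and writers for the external formats the pipeline consumes.

Reference assemblies arrive as FASTA, per-genome variant calls as VCF, and
per-base read-depth tracks as run-length-encoded TSV (the output of a
coverage tool such as BEDTools genomecov).  External files keep their
native 1-based inclusive coordinates; the loaders validate and normalise,
and every writer emits plain tab-separated text so that a written file
reloads to an identical object.

The one piece of filtering applied at load time is the call-level read
depth cut: SNP and insertion calls supported by fewer than ``min_depth``
reads are discarded as likely artefacts.  Deletion calls are exempt by
default (their supporting depth is not comparable) but the threshold can
be applied to them too via ``filter_deletions``.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = frozenset("ACGTN")


class VariantClass(enum.Enum):
    SNP = "SNP"
    INS = "INS"
    DEL = "DEL"


class Zygosity(enum.Enum):
    HOM_ALT = "hom_alt"
    HET = "het"


@dataclasses.dataclass
class ReferenceGenome:
    """A reference assembly held fully in memory.

    ``chromosomes`` maps name -> uppercase A/C/G/T/N string.  Positions in
    the public API are 1-based inclusive; helpers convert to Python string
    indices internally.
    """

    assembly_id: str
    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"chromosome {name!r} has illegal characters {sorted(bad)}")

    def length(self, chrom: str) -> int:
        return len(self.chromosomes[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.chromosomes[chrom][pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Substring over a 1-based inclusive interval."""
        if start < 1 or end > self.length(chrom):
            raise ValueError(f"{chrom}:{start}-{end} outside chromosome bounds")
        return self.chromosomes[chrom][start - 1 : end]


@dataclasses.dataclass
class VariantCall:
    """One allele observed in one resequenced genome (VCF-style, left-anchored)."""

    genome_id: str
    chromosome: str
    position: int  # 1-based; for indels, the shared anchor base
    ref_allele: str
    alt_allele: str
    variant_class: VariantClass
    read_depth: int
    zygosity: Zygosity

    def __post_init__(self) -> None:
        r, a = self.ref_allele, self.alt_allele
        if self.variant_class is VariantClass.SNP and not (len(r) == len(a) == 1 and r != a):
            raise ValueError(f"malformed SNP {r}>{a}")
        if self.variant_class is VariantClass.INS and len(a) <= len(r):
            raise ValueError(f"malformed insertion {r}>{a}")
        if self.variant_class is VariantClass.DEL and len(r) <= len(a):
            raise ValueError(f"malformed deletion {r}>{a}")
        if self.read_depth < 0:
            raise ValueError("negative read depth")

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))


class DepthTrack:
    """Run-length encoded per-base read depth for one genome.

    Intervals are 1-based inclusive, sorted, non-overlapping.  Positions
    not covered by any interval have depth 0.  ``mean_depth`` is the
    genome-wide average read depth reported by the aligner and is the
    denominator of the fractional (0.1x) coverage rule downstream.
    """

    def __init__(
        self,
        genome_id: str,
        mean_depth: float,
        intervals: Mapping[str, Iterable[tuple[int, int, int]]],
    ) -> None:
        if mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        self.genome_id = genome_id
        self.mean_depth = float(mean_depth)
        self._tracks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivals in intervals.items():
            rows = sorted(ivals)
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            depths = np.array([r[2] for r in rows], dtype=np.int64)
            if np.any(depths < 0):
                raise ValueError("negative depth")
            if np.any(ends < starts):
                raise ValueError("interval end before start")
            if np.any(starts[1:] <= ends[:-1]):
                raise ValueError(f"overlapping depth intervals on {chrom}")
            self._tracks[chrom] = (starts, ends, depths)

    def depth_at(self, chrom: str, pos: int) -> int:
        track = self._tracks.get(chrom)
        if track is None:
            return 0
        starts, ends, depths = track
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos <= ends[i]:
            return int(depths[i])
        return 0

    def depths_in_range(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-position depths over a 1-based inclusive range (vectorised)."""
        positions = np.arange(start, end + 1, dtype=np.int64)
        track = self._tracks.get(chrom)
        if track is None or track[0].size == 0:
            return np.zeros(positions.size, dtype=np.int64)
        starts, ends, depths = track
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = (idx >= 0) & (positions <= ends[np.clip(idx, 0, len(ends) - 1)])
        out = np.zeros(positions.size, dtype=np.int64)
        out[valid] = depths[idx[valid]]
        return out

    def intervals(self) -> dict[str, list[tuple[int, int, int]]]:
        return {
            chrom: [(int(s), int(e), int(d)) for s, e, d in zip(*track)]
            for chrom, track in self._tracks.items()
        }


# ---------------------------------------------------------------------------
# FASTA


def load_reference(path: str | Path, assembly_id: str | None = None) -> ReferenceGenome:
    """Load a FASTA assembly, upper-casing and validating the alphabet."""
    path = Path(path)
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(assembly_id or path.stem, chroms)


def write_reference(genome: ReferenceGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF


def _classify(ref: str, alt: str) -> VariantClass:
    if len(ref) == len(alt) == 1:
        return VariantClass.SNP
    if len(alt) > len(ref):
        return VariantClass.INS
    if len(ref) > len(alt):
        return VariantClass.DEL
    raise ValueError(f"unsupported allele pair {ref}>{alt} (MNPs not handled)")


def filter_calls(
    calls: Iterable[VariantCall],
    min_depth: int = 5,
    filter_deletions: bool = False,
) -> list[VariantCall]:
    """The call-level depth cut: drop SNP/INS calls below ``min_depth``.

    Shared by the VCF loader and in-memory pipelines so both paths apply
    the identical rule.
    """
    out = []
    for c in calls:
        applies = c.variant_class in (VariantClass.SNP, VariantClass.INS) or filter_deletions
        if applies and c.read_depth < min_depth:
            continue
        out.append(c)
    return out


def load_variant_calls(
    path: str | Path,
    min_depth: int = 5,
    reference: ReferenceGenome | None = None,
    filter_deletions: bool = False,
) -> dict[str, list[VariantCall]]:
    """Read a VCF into per-genome call lists, applying the depth-<5 cut.

    Multi-allelic records are split into one :class:`VariantCall` per
    carried alternative allele per sample.  SNP and insertion calls with
    read depth below ``min_depth`` are dropped; deletions are retained
    unless ``filter_deletions`` is set.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    out: dict[str, list[VariantCall]] = {s: [] for s in samples}
    for rec in vf:
        if rec.alts is None:
            continue
        if reference is not None:
            if rec.chrom not in reference.chromosomes:
                raise ValueError(f"unknown chromosome {rec.chrom!r} in {path}")
            if rec.pos > reference.length(rec.chrom):
                raise ValueError(
                    f"position {rec.chrom}:{rec.pos} beyond chromosome end"
                )
        for sample in samples:
            sdata = rec.samples[sample]
            gt = sdata.get("GT")
            if gt is None or all(a in (None, 0) for a in gt):
                continue
            depth = sdata.get("DP")
            if depth is None:
                depth = rec.info.get("DP", 0)
            depth = int(depth or 0)
            carried = [a for a in gt if a not in (None, 0)]
            for alt_index in sorted(set(carried)):
                alt = rec.alts[alt_index - 1]
                vclass = _classify(rec.ref, alt)
                zyg = (
                    Zygosity.HOM_ALT
                    if all(a == alt_index for a in gt if a is not None)
                    else Zygosity.HET
                )
                out[sample].append(
                    VariantCall(
                        genome_id=sample,
                        chromosome=rec.chrom,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        variant_class=vclass,
                        read_depth=depth,
                        zygosity=zyg,
                    )
                )
    return {
        sample: filter_calls(calls, min_depth, filter_deletions)
        for sample, calls in out.items()
    }


def write_variant_calls(
    calls_by_genome: Mapping[str, Iterable[VariantCall]],
    reference: ReferenceGenome,
    path: str | Path,
) -> None:
    """Write per-genome calls as a multi-sample VCF 4.2 text file.

    Calls at the same site in different genomes are merged into one record
    with the union of alternative alleles.
    """
    samples = list(calls_by_genome)
    # (chrom, pos, ref) -> {alt: {genome: zygosity}}, plus per-genome depth
    sites: dict[tuple[str, int, str], dict] = {}
    for genome, calls in calls_by_genome.items():
        for c in calls:
            key = (c.chromosome, c.position, c.ref_allele)
            entry = sites.setdefault(key, {"alts": [], "gt": {}, "dp": {}})
            if c.alt_allele not in entry["alts"]:
                entry["alts"].append(c.alt_allele)
            entry["gt"].setdefault(genome, []).append((c.alt_allele, c.zygosity))
            entry["dp"][genome] = c.read_depth

    chrom_order = {name: i for i, name in enumerate(reference.chromosomes)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for name, seq in reference.chromosomes.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for (chrom, pos, ref), entry in sorted(
            sites.items(), key=lambda kv: (chrom_order[kv[0][0]], kv[0][1], kv[0][2])
        ):
            alts = entry["alts"]
            alt_index = {a: i + 1 for i, a in enumerate(alts)}
            cols = [chrom, str(pos), ".", ref, ",".join(alts), ".", "PASS", ".", "GT:DP"]
            for genome in samples:
                carried = entry["gt"].get(genome)
                if not carried:
                    cols.append("0/0:.")
                    continue
                if len(carried) >= 2:
                    # two alternative alleles in one genome: het across alts
                    i, j = sorted(alt_index[a] for a, _ in carried[:2])
                    gt = f"{i}/{j}"
                else:
                    alt, zyg = carried[0]
                    i = alt_index[alt]
                    gt = f"{i}/{i}" if zyg is Zygosity.HOM_ALT else f"0/{i}"
                cols.append(f"{gt}:{entry['dp'][genome]}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Depth TSV


def load_depth_track(
    path: str | Path,
    genome_id: str | None = None,
    mean_depth: float | None = None,
) -> DepthTrack:
    """Read a `chrom<TAB>start<TAB>end<TAB>depth` track (1-based inclusive).

    The header comment written by :func:`write_depth_track` carries the
    genome id and mean depth; explicit arguments override it.
    """
    intervals: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line.lstrip("#").split():
                    if token.startswith("genome=") and genome_id is None:
                        genome_id = token.split("=", 1)[1]
                    elif token.startswith("mean_depth=") and mean_depth is None:
                        mean_depth = float(token.split("=", 1)[1])
                continue
            chrom, start, end, depth = line.split("\t")
            intervals.setdefault(chrom, []).append((int(start), int(end), int(depth)))
    if genome_id is None or mean_depth is None:
        raise ValueError(f"{path}: genome id / mean depth missing (no header, no arguments)")
    return DepthTrack(genome_id, mean_depth, intervals)


def write_depth_track(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genome={track.genome_id} mean_depth={track.mean_depth:g}\n")
        fh.write("# chrom\tstart\tend\tdepth (1-based inclusive)\n")
        for chrom, rows in track.intervals().items():
            for start, end, depth in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{depth}\n")
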