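"""Placement of design and primer sequences in reference assemblies.

Degenerate design sequences are located with a deterministic exact-seed /
ungapped-extension search: every unambiguous 15-mer of the query (both
strands) seeds candidate loci, each candidate is scored over the full
query length (match +1, mismatch -1; an ambiguity letter matches any base
in its set, N matches anything), and the unique best-scoring locus wins.
Two or more loci tying for best score means the design cannot be placed
unambiguously and it is reported unplaced — the uniqueness requirement
that keeps an assay locus-specific.

The same engine drives the legacy-assembly cross-reference (unique best
hit with >= 90% full-length identity), array-SNP context placement, and
SSR primer-pair positioning (each primer >= 95% identity, both primers of
exactly one surviving pair within 10 kb on one chromosome).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Optional

from .design import KASPDesign
from .io_formats import ReferenceGenome
from .sequence import SET_FOR_IUPAC, revcomp

DEFAULT_SEED_LEN = 15


@dataclasses.dataclass(frozen=True)
class AlignmentHit:
    assembly_id: str
    chromosome: str
    start: int  # 1-based start of the aligned window on the forward strand
    strand: str  # "+" | "-"
    identity_pct: float  # matches / query length * 100
    score: int  # matches - mismatches

    @property
    def locus(self) -> tuple[str, int, str]:
        return (self.chromosome, self.start, self.strand)


@dataclasses.dataclass
class SSRMarker:
    name: str
    forward: str
    reverse: str
    positions: dict[str, tuple[str, int, int] | None] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError(f"SSR {self.name}: primers must be >= 15 bp")


def _seed_offsets(query: str, seed_len: int) -> list[int]:
    """Offsets of non-overlapping unambiguous seed k-mers covering the query."""
    offsets: list[int] = []
    i = 0
    n = len(query)
    plain = frozenset("ACGT")
    while i + seed_len <= n:
        window = query[i : i + seed_len]
        if set(window) <= plain:
            offsets.append(i)
            i += seed_len
        else:
            i += 1
    # a trailing unambiguous window improves sensitivity near the 3' end
    if n >= seed_len:
        tail_off = n - seed_len
        if set(query[tail_off:]) <= plain and (not offsets or offsets[-1] != tail_off):
            offsets.append(tail_off)
    return offsets


def _score_at(query: str, ref_seq: str, start0: int) -> tuple[int, int]:
    """(matches, score) of the full ungapped alignment at a 0-based start."""
    matches = 0
    for qc, rc in zip(query, ref_seq[start0 : start0 + len(query)]):
        if rc in SET_FOR_IUPAC[qc]:
            matches += 1
    return matches, 2 * matches - len(query)


class SeedIndex:
    """Exact k-mer index of one assembly, shared across many queries."""

    def __init__(self, reference: ReferenceGenome, seed_len: int = DEFAULT_SEED_LEN) -> None:
        self.reference = reference
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in reference.chromosomes.items():
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i : i + seed_len], []).append((chrom, i))

    def occurrences(self, seed: str) -> list[tuple[str, int]]:
        return self._index.get(seed, [])


def _seed_occurrences(reference: ReferenceGenome, seed: str) -> list[tuple[str, int]]:
    out = []
    for chrom, seq in reference.chromosomes.items():
        pos = seq.find(seed)
        while pos != -1:
            out.append((chrom, pos))
            pos = seq.find(seed, pos + 1)
    return out


def best_hits(
    query: str,
    reference: ReferenceGenome,
    seed_len: int = DEFAULT_SEED_LEN,
    index: SeedIndex | None = None,
) -> list[AlignmentHit]:
    """All loci tying for the best full-length ungapped score.

    Candidate loci are those sharing at least one exact unambiguous
    ``seed_len``-mer with the query on either strand; only windows fully
    inside a chromosome are scored.  Passing a prebuilt :class:`SeedIndex`
    amortises the seed lookup across many queries.
    """
    if len(query) < seed_len:
        raise ValueError(f"query shorter than seed length {seed_len}")
    qlen = len(query)
    candidates: set[tuple[str, int, str]] = set()
    for strand, oriented in (("+", query), ("-", revcomp(query))):
        for off in _seed_offsets(oriented, seed_len):
            seed = oriented[off : off + seed_len]
            occurrences = (
                index.occurrences(seed) if index is not None
                else _seed_occurrences(reference, seed)
            )
            for chrom, pos in occurrences:
                start0 = pos - off
                if 0 <= start0 and start0 + qlen <= len(reference.chromosomes[chrom]):
                    candidates.add((chrom, start0, strand))
    hits: list[AlignmentHit] = []
    for chrom, start0, strand in candidates:
        oriented = query if strand == "+" else revcomp(query)
        matches, score = _score_at(oriented, reference.chromosomes[chrom], start0)
        hits.append(
            AlignmentHit(
                assembly_id=reference.assembly_id,
                chromosome=chrom,
                start=start0 + 1,
                strand=strand,
                identity_pct=100.0 * matches / qlen,
                score=score,
            )
        )
    if not hits:
        return []
    best = max(h.score for h in hits)
    return sorted(
        (h for h in hits if h.score == best),
        key=lambda h: (h.chromosome, h.start, h.strand),
    )


def locate_design(
    design: KASPDesign | str,
    reference: ReferenceGenome,
    seed_len: int = DEFAULT_SEED_LEN,
    index: SeedIndex | None = None,
) -> Optional[AlignmentHit]:
    """Unique best placement of a design sequence, or None on tie/no hit."""
    seq = design if isinstance(design, str) else design.alignment_query
    hits = best_hits(seq, reference, seed_len, index)
    if len(hits) != 1:
        return None
    return hits[0]


def crossref_legacy(
    design: KASPDesign | str,
    legacy_reference: ReferenceGenome,
    min_identity: float = 90.0,
    seed_len: int = DEFAULT_SEED_LEN,
    index: SeedIndex | None = None,
) -> Optional[AlignmentHit]:
    """Position in an older assembly; informational, never rejects a design.

    Unknown (None) when there is no hit, several tied best hits, or the
    unique best hit has full-length identity below ``min_identity``.
    """
    seq = design if isinstance(design, str) else design.alignment_query
    hits = best_hits(seq, legacy_reference, seed_len, index)
    if len(hits) != 1 or hits[0].identity_pct < min_identity:
        return None
    return hits[0]


def position_array_snp(
    context_sequence: str,
    assemblies: Mapping[str, ReferenceGenome],
    min_identity: float = 90.0,
    seed_len: int = DEFAULT_SEED_LEN,
) -> dict[str, Optional[AlignmentHit]]:
    """Place a fixed-array SNP context in each assembly (crossref contract)."""
    return {
        name: crossref_legacy(context_sequence, ref, min_identity, seed_len)
        for name, ref in assemblies.items()
    }


def position_ssr(
    marker: SSRMarker,
    assemblies: Mapping[str, ReferenceGenome],
    min_identity: float = 95.0,
    max_pair_span: int = 10_000,
    seed_len: int = DEFAULT_SEED_LEN,
) -> dict[str, tuple[str, int, int] | None]:
    """Resolve an SSR marker per assembly from its primer pair.

    Each primer's tied-best hits with full-length identity >= 95% survive;
    the marker gets a position in an assembly iff exactly one surviving
    forward/reverse combination lies within ``max_pair_span`` on one
    chromosome there.  The position is the interval spanned by the pair.
    """
    out: dict[str, tuple[str, int, int] | None] = {}
    for name, ref in assemblies.items():
        fwd = [h for h in best_hits(marker.forward, ref, seed_len) if h.identity_pct >= min_identity]
        rev = [h for h in best_hits(marker.reverse, ref, seed_len) if h.identity_pct >= min_identity]
        pairs = []
        for f in fwd:
            for r in rev:
                if f.chromosome != r.chromosome:
                    continue
                lo = min(f.start, r.start)
                hi = max(f.start + len(marker.forward) - 1, r.start + len(marker.reverse) - 1)
                if hi - lo + 1 <= max_pair_span:
                    pairs.append((f.chromosome, lo, hi))
        out[name] = pairs[0] if len(set(pairs)) == 1 and pairs else None
    marker.positions.update(out)
    return out


def map_designs(
    designs: Iterable[KASPDesign],
    primary: ReferenceGenome,
    secondary: ReferenceGenome | None = None,
    legacy: ReferenceGenome | None = None,
    min_identity_legacy: float = 90.0,
    seed_len: int = DEFAULT_SEED_LEN,
) -> tuple[list[KASPDesign], list]:
    """Uniqueness stage: keep designs placing uniquely in every required assembly.

    A design must have a single best alignment in the primary assembly and
    (when given) the secondary assembly; the legacy assembly is annotated
    only.  Returns survivors and per-design outcomes.
    """
    from .panel import FilterOutcome, FilterRule

    survivors: list[KASPDesign] = []
    outcomes: list[FilterOutcome] = []
    indices = {
        ref.assembly_id: SeedIndex(ref, seed_len)
        for ref in (primary, secondary, legacy)
        if ref is not None
    }
    for d in designs:
        ok = True
        for ref in (primary, secondary):
            if ref is None:
                continue
            hit = locate_design(d, ref, seed_len, indices[ref.assembly_id])
            d.positions[ref.assembly_id] = (hit.chromosome, hit.start) if hit else None
            if hit is None:
                ok = False
        if legacy is not None:
            hit = crossref_legacy(d, legacy, min_identity_legacy, seed_len, indices[legacy.assembly_id])
            d.positions[legacy.assembly_id] = (hit.chromosome, hit.start) if hit else None
        if ok:
            survivors.append(d)
            outcomes.append(FilterOutcome(d.target.site, "pass"))
        else:
            outcomes.append(
                FilterOutcome(d.target.site, "fail", FilterRule.ALIGNMENT, "no single best alignment")
            )
    return survivors, outcomes
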