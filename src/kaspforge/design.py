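"""Degenerate design-sequence construction (filter 4 and sequence checks).

A design sequence is the target variant plus 50 bp of flank either side.
Flanking polymorphism observed anywhere in the panel is folded into the
sequence: flanking SNPs become IUPAC ambiguity letters covering reference
plus observed alternatives, and a single admissible flanking indel becomes
a run of Ns.  Admissibility (filter 4):

* at most one indel site among both flanks, all alleles there of one kind
  and one length, length <= 10 bp, and more than 5 bp away from the target
  (a deleted run must keep that clearance and stay inside its flank);
* no flank site may mix SNP and indel alleles;
* at most 5 SNP sites per flank (a strict total-of-5 mode is available).

Designs that survive are then screened for tandem repeats (no resolution
of the ambiguity letters may contain more than 5 consecutive copies of any
1-5 nt unit, Ns ignored) and for GC content (the 55 bp window centred on
the target must fall in [35%, 65%], ambiguity letters contributing the
mean GC of their base set).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Mapping, Optional

from .io_formats import ReferenceGenome, VariantCall, VariantClass, Zygosity
from .panel import FilterOutcome, FilterRule, GenomePanel, TargetVariant
from .sequence import AMBIGUITY_LETTERS, gc_percent, iupac_code, iupac_set

MAX_REPEAT_RESOLUTIONS = 4**10


@dataclasses.dataclass
class FlankSNP:
    offset: int  # signed bp from target, in [-50,-1] U [1,50]
    ref_base: str
    alt_bases: frozenset[str]


@dataclasses.dataclass
class FlankIndel:
    offset: int  # signed anchor offset from target
    length: int
    kind: VariantClass  # INS or DEL


@dataclasses.dataclass
class FlankProfile:
    left_flank: str
    right_flank: str
    snp_sites: list[FlankSNP]
    indel_site: Optional[FlankIndel]


@dataclasses.dataclass
class KASPDesign:
    """A finished (or in-progress) degenerate assay design."""

    pKey: int
    target: TargetVariant
    design_sequence: str
    target_index: int  # 0-based index of the target base within design_sequence
    flank_profile: FlankProfile
    positions: dict[str, tuple[str, int] | None] = dataclasses.field(default_factory=dict)
    predicted_genotypes: dict[str, str] = dataclasses.field(default_factory=dict)
    effect: object | None = None  # EffectSummary from kaspforge.annotation
    functional: bool = False
    gc_window_pct: float | None = None

    @property
    def n_ambiguous_left(self) -> int:
        return sum(1 for s in self.flank_profile.snp_sites if s.offset < 0)

    @property
    def n_ambiguous_right(self) -> int:
        return sum(1 for s in self.flank_profile.snp_sites if s.offset > 0)

    @property
    def alignment_query(self) -> str:
        """The sequence used for genome placement.

        An insertion's N-run has no counterpart in the reference and would
        shift everything downstream under ungapped alignment, so it is
        excised; a deletion's Ns substitute reference bases in place and
        stay (N matches any base).
        """
        indel = self.flank_profile.indel_site
        if indel is None or indel.kind is not VariantClass.INS:
            return self.design_sequence
        flank_bp = len(self.flank_profile.left_flank)
        at = flank_bp + indel.offset + 1
        return self.design_sequence[:at] + self.design_sequence[at + indel.length :]


# ---------------------------------------------------------------------------
# Filter 4


def assess_flank_variation(
    target: TargetVariant,
    panel: GenomePanel,
    flank_bp: int = 50,
    max_flank_snps: int = 5,
    per_flank: bool = True,
    max_indel_len: int = 10,
    min_indel_offset: int = 5,
) -> FlankProfile | FilterOutcome:
    """Collect panel-wide flanking variation and test admissibility.

    ``per_flank`` applies the SNP cap to each flank separately (default);
    otherwise it caps the total across both flanks.
    """
    chrom, pos = target.site
    site_calls = panel.calls_in_range(chrom, pos - flank_bp, pos + flank_bp)
    site_calls.pop((chrom, pos), None)

    snp_sites: list[FlankSNP] = []
    indel_sites: list[FlankIndel] = []
    for (c, p), per_genome in sorted(site_calls.items(), key=lambda kv: kv[0]):
        offset = p - pos
        snp_alts: set[str] = set()
        indel_alleles: set[tuple[VariantClass, int]] = set()
        ref_base = panel.reference.base(c, p)
        for calls in per_genome.values():
            for call in calls:
                if call.variant_class is VariantClass.SNP:
                    snp_alts.add(call.alt_allele)
                else:
                    indel_alleles.add((call.variant_class, call.indel_length))
        if snp_alts and indel_alleles:
            return _fail(target, f"flank site {offset:+d} mixes SNP and indel alleles")
        if indel_alleles:
            if len(indel_alleles) > 1:
                return _fail(target, f"unequal indel alleles at flank offset {offset:+d}")
            kind, length = next(iter(indel_alleles))
            indel_sites.append(FlankIndel(offset=offset, length=length, kind=kind))
        elif snp_alts:
            snp_sites.append(FlankSNP(offset=offset, ref_base=ref_base, alt_bases=frozenset(snp_alts)))

    if len(indel_sites) > 1:
        return _fail(target, f"{len(indel_sites)} flanking indel sites (max 1)")
    indel = indel_sites[0] if indel_sites else None
    if indel is not None:
        if indel.length > max_indel_len:
            return _fail(target, f"flanking indel of {indel.length} bp (max {max_indel_len})")
        if abs(indel.offset) <= min_indel_offset:
            return _fail(target, f"flanking indel {abs(indel.offset)} bp from target (min {min_indel_offset + 1})")
        if indel.kind is VariantClass.DEL:
            # deleted run occupies offsets offset+1 .. offset+length
            span_end = indel.offset + indel.length
            if indel.offset < 0 and span_end > -(min_indel_offset + 1):
                return _fail(target, "deleted run reaches within 5 bp of target")
            if span_end > flank_bp:
                return _fail(target, "deleted run extends beyond the flank")

    n_left = sum(1 for s in snp_sites if s.offset < 0)
    n_right = sum(1 for s in snp_sites if s.offset > 0)
    if per_flank:
        if max(n_left, n_right) > max_flank_snps:
            return _fail(target, f"{max(n_left, n_right)} SNP sites in one flank (max {max_flank_snps})")
    elif n_left + n_right > max_flank_snps:
        return _fail(target, f"{n_left + n_right} SNP sites in total (max {max_flank_snps})")

    return FlankProfile(
        left_flank=panel.reference.slice(chrom, pos - flank_bp, pos - 1),
        right_flank=panel.reference.slice(chrom, pos + 1, pos + flank_bp),
        snp_sites=snp_sites,
        indel_site=indel,
    )


def _fail(target: TargetVariant, detail: str) -> FilterOutcome:
    return FilterOutcome(target.site, "fail", FilterRule.FLANK_VARIATION, detail)


# ---------------------------------------------------------------------------
# Sequence construction


def build_design_sequence(
    target: TargetVariant,
    profile: FlankProfile,
    reference: ReferenceGenome,
    pkey: int = 0,
    flank_bp: int = 50,
) -> KASPDesign:
    """Render the degenerate design sequence from an admissible profile.

    The target base is written as the reference allele (the assay
    interrogates reference vs target).  Flanking SNP sites get the minimal
    IUPAC letter covering reference plus alternatives; the flanking indel,
    if any, becomes Ns — inserted after the anchor for insertions, or
    substituted for the deleted reference bases for deletions (keeping
    design coordinates aligned to the reference).
    """
    chrom, pos = target.site
    letters = list(reference.slice(chrom, pos - flank_bp, pos + flank_bp))
    for s in profile.snp_sites:
        i = flank_bp + s.offset
        letters[i] = iupac_code({s.ref_base} | set(s.alt_bases))
    target_index = flank_bp
    indel = profile.indel_site
    if indel is not None:
        if indel.kind is VariantClass.DEL:
            for off in range(indel.offset + 1, indel.offset + indel.length + 1):
                letters[flank_bp + off] = "N"
        else:
            insert_at = flank_bp + indel.offset + 1
            letters[insert_at:insert_at] = ["N"] * indel.length
            if indel.offset < 0:
                target_index += indel.length
    return KASPDesign(
        pKey=pkey,
        target=target,
        design_sequence="".join(letters),
        target_index=target_index,
        flank_profile=profile,
    )


# ---------------------------------------------------------------------------
# Tandem-repeat screen


def _has_long_repeat(s: str, max_copies: int, max_unit: int) -> bool:
    """More than ``max_copies`` consecutive copies of any short unit?

    A string contains > c copies of a length-u unit iff it is u-periodic
    over a span of (c+1)*u bases, i.e. iff s[i] == s[i+u] holds for c*u
    consecutive positions.
    """
    n = len(s)
    for u in range(1, max_unit + 1):
        need = max_copies * u
        run = 0
        for i in range(n - u):
            if s[i] == s[i + u]:
                run += 1
                if run >= need:
                    return True
            else:
                run = 0
    return False


_COMPATIBLE = {
    (a, b): bool(iupac_set(a) & iupac_set(b))
    for a in "ACGTRYSWKMBDHV"
    for b in "ACGTRYSWKMBDHV"
}


def _optimistic_long_repeat(s: str, max_copies: int, max_unit: int) -> bool:
    """Periodicity scan where ambiguity letters match on any shared base.

    Necessary but not sufficient for a repeat in some resolution (each
    pairing is judged independently, ignoring consistency of choices), so
    a negative answer proves every resolution clean and skips expansion.
    """
    n = len(s)
    compat = _COMPATIBLE
    for u in range(1, max_unit + 1):
        need = max_copies * u
        run = 0
        for i in range(n - u):
            if compat[(s[i], s[i + u])]:
                run += 1
                if run >= need:
                    return True
            else:
                run = 0
    return False


def _any_resolution_has_repeat(stripped: str, max_copies: int, max_unit: int) -> bool:
    """Equivalent to scanning every cartesian resolution, but local.

    A minimal failing run — ``max_copies + 1`` copies of a unit of length
    <= ``max_unit`` — spans at most ``(max_copies + 1) * max_unit`` bases,
    so a run either lies wholly in unambiguous sequence (found by a single
    scan with each ambiguity position replaced by a unique sentinel that
    matches nothing) or passes through an ambiguity letter (found by
    expanding only the window of that radius around each such letter).
    Window resolutions are substrings of genuine full resolutions, so no
    false positives arise.
    """
    if not _optimistic_long_repeat(stripped, max_copies, max_unit):
        return False
    radius = (max_copies + 1) * max_unit - 1
    ambig_positions = [i for i, ch in enumerate(stripped) if ch in AMBIGUITY_LETTERS]
    sentinelized = "".join(
        chr(256 + i) if ch in AMBIGUITY_LETTERS else ch for i, ch in enumerate(stripped)
    )
    if _has_long_repeat(sentinelized, max_copies, max_unit):
        return True
    for i in ambig_positions:
        lo = max(0, i - radius)
        window = stripped[lo : i + radius + 1]
        options = [
            sorted(iupac_set(ch)) if ch in AMBIGUITY_LETTERS else [ch] for ch in window
        ]
        n_res = 1
        for opt in options:
            n_res *= len(opt)
            if n_res > MAX_REPEAT_RESOLUTIONS:
                raise RuntimeError("ambiguity expansion exceeds the 4^10 resolution cap")
        for resolution in itertools.product(*options):
            if _has_long_repeat("".join(resolution), max_copies, max_unit):
                return True
    return False


def check_tandem_repeats(
    design: KASPDesign | str,
    max_copies: int = 5,
    max_unit: int = 5,
) -> FilterOutcome:
    """Reject when any SNP resolution contains a >5-copy short tandem run.

    Ns are removed first; the test set is every resolution of every
    ambiguity letter into its constituent bases (cartesian product, capped
    at 4^10 resolutions per expanded window), each scanned for more than
    ``max_copies`` consecutive exact copies of any 1..``max_unit`` nt
    unit.
    """
    seq = design if isinstance(design, str) else design.design_sequence
    site = ("design", 0) if isinstance(design, str) else design.target.site
    stripped = seq.replace("N", "")
    if _any_resolution_has_repeat(stripped, max_copies, max_unit):
        return FilterOutcome(
            site, "fail", FilterRule.REPEAT,
            f"a resolution contains >{max_copies} copies of a <= {max_unit} nt unit",
        )
    return FilterOutcome(site, "pass")


# ---------------------------------------------------------------------------
# GC window


def check_gc_window(
    design: KASPDesign,
    lo: float = 35.0,
    hi: float = 65.0,
    window: int = 55,
) -> FilterOutcome:
    """GC of the 55 bp window centred on the target must lie in [lo, hi]."""
    seq = design.design_sequence
    if len(seq) < window:
        raise ValueError("design shorter than GC window")
    half = window // 2
    start = min(max(design.target_index - half, 0), len(seq) - window)
    pct = gc_percent(seq[start : start + window])
    design.gc_window_pct = pct
    if lo <= pct <= hi:
        return FilterOutcome(design.target.site, "pass", detail=f"{pct:.1f}%")
    return FilterOutcome(
        design.target.site, "fail", FilterRule.GC, f"GC {pct:.1f}% outside [{lo}, {hi}]"
    )


# ---------------------------------------------------------------------------
# Stage driver


def predict_genotypes(target: TargetVariant, panel: GenomePanel) -> dict[str, str]:
    """Design-time genotype expectation per panel line at the target site."""
    out: dict[str, str] = {}
    per_genome = panel.site_calls.get(target.site, {})
    for genome in panel.genomes:
        state = "reference"
        for call in per_genome.get(genome, []):
            if (call.ref_allele, call.alt_allele) == (target.ref_allele, target.target_allele):
                state = "target" if call.zygosity is Zygosity.HOM_ALT else "het"
                break
            state = "unknown"  # carries a different alternative allele
        out[genome] = state
    return out


def build_designs(
    targets: Iterable[TargetVariant],
    panel: GenomePanel,
    flank_bp: int = 50,
    max_flank_snps: int = 5,
    per_flank: bool = True,
    max_indel_len: int = 10,
    min_indel_offset: int = 5,
    repeat_max_copies: int = 5,
    gc_lo: float = 35.0,
    gc_hi: float = 65.0,
    gc_window: int = 55,
    first_pkey: int = 1,
) -> tuple[list[KASPDesign], list[FilterOutcome]]:
    """Filter 4 + sequence construction + repeat and GC screens.

    Returns surviving designs (pKeys assigned in genomic order) and one
    outcome per input target.
    """
    designs: list[KASPDesign] = []
    outcomes: list[FilterOutcome] = []
    pkey = first_pkey
    for target in targets:
        profile = assess_flank_variation(
            target, panel, flank_bp, max_flank_snps, per_flank, max_indel_len, min_indel_offset
        )
        if isinstance(profile, FilterOutcome):
            outcomes.append(profile)
            continue
        design = build_design_sequence(target, profile, panel.reference, pkey, flank_bp)
        oc = check_tandem_repeats(design, repeat_max_copies)
        if not oc.passed:
            outcomes.append(oc)
            continue
        oc = check_gc_window(design, gc_lo, gc_hi, gc_window)
        if not oc.passed:
            outcomes.append(oc)
            continue
        design.predicted_genotypes = predict_genotypes(target, panel)
        designs.append(design)
        outcomes.append(FilterOutcome(target.site, "pass"))
        pkey += 1
    return designs, outcomes
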