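"""Filter 4, degenerate sequence construction, repeat and GC screens."""

import itertools

import numpy as np
import pytest

from conftest import make_reference, random_genome, snp_call, uniform_track
from kaspforge.design import (
    KASPDesign,
    assess_flank_variation,
    build_design_sequence,
    check_gc_window,
    check_tandem_repeats,
    build_designs,
)
from kaspforge.io_formats import VariantCall, VariantClass, Zygosity
from kaspforge.panel import FilterOutcome, FilterRule, GenomePanel, TargetVariant, select_target_allele
from kaspforge.sequence import AMBIGUITY_LETTERS, iupac_code, iupac_set

POS = 101  # target position in a 201 bp toy chromosome


def indel_call(genome, pos, ref, alt, chrom="chr1"):
    vclass = VariantClass.INS if len(alt) > len(ref) else VariantClass.DEL
    return VariantCall(genome, chrom, pos, ref, alt, vclass, 30, Zygosity.HOM_ALT)


def toy_panel(flank_calls, seq=None, seed=0):
    """Ten-genome panel with a SNP target at POS plus given flank calls."""
    rng = np.random.default_rng(seed)
    seq = seq or random_genome(rng, 201)
    ref = make_reference(seq)
    genomes = [f"g{i}" for i in range(10)]
    target_alt = next(b for b in "ACGT" if b != seq[POS - 1])
    calls = {g: [] for g in genomes}
    for g in genomes[:4]:
        calls[g].append(snp_call(g, POS, seq[POS - 1], target_alt))
    for c in flank_calls:
        calls[c.genome_id].append(c)
    tracks = {g: uniform_track(g, 30.0, 201) for g in genomes}
    panel = GenomePanel(ref, calls, tracks)
    target = select_target_allele(("chr1", POS), panel.site_calls[("chr1", POS)], 10)
    assert isinstance(target, TargetVariant)
    return panel, target


class TestFlankVariationFilter:
    def test_admissible_indel_plus_snps(self):
        # one 3 bp deletion at +10, two SNP sites: conditions (i) and (ii) hold together
        rng = np.random.default_rng(1)
        seq = random_genome(rng, 201)
        del_ref = seq[POS + 9 : POS + 13]  # anchor + 3 deleted bases
        calls = [
            indel_call("g1", POS + 10, del_ref, del_ref[0]),
            snp_call("g2", POS - 8, seq[POS - 9], next(b for b in "ACGT" if b != seq[POS - 9])),
            snp_call("g3", POS + 20, seq[POS + 19], next(b for b in "ACGT" if b != seq[POS + 19])),
        ]
        panel, target = toy_panel(calls, seq=seq)
        profile = assess_flank_variation(target, panel)
        assert not isinstance(profile, FilterOutcome)
        assert profile.indel_site.length == 3
        assert len(profile.snp_sites) == 2

    @pytest.mark.parametrize(
        "offset,length,ok",
        [(4, 3, False), (5, 3, False), (6, 3, True),  # 5 bp clearance boundary
         (10, 10, True), (10, 11, False), (10, 12, False)],  # 10 bp length cap
    )
    def test_indel_offset_and_length_boundaries(self, offset, length, ok):
        rng = np.random.default_rng(2)
        seq = random_genome(rng, 201)
        anchor = seq[POS + offset - 1]
        calls = [indel_call("g1", POS + offset, anchor, anchor + "A" * length)]
        panel, target = toy_panel(calls, seq=seq)
        result = assess_flank_variation(target, panel)
        assert isinstance(result, FilterOutcome) != ok

    def test_two_indel_sites_fail(self):
        rng = np.random.default_rng(3)
        seq = random_genome(rng, 201)
        calls = [
            indel_call("g1", POS + 10, seq[POS + 9], seq[POS + 9] + "AA"),
            indel_call("g2", POS - 20, seq[POS - 21], seq[POS - 21] + "T"),
        ]
        panel, target = toy_panel(calls, seq=seq)
        result = assess_flank_variation(target, panel)
        assert isinstance(result, FilterOutcome)
        assert result.failed_rule is FilterRule.FLANK_VARIATION

    def test_unequal_deletion_lengths_fail(self):
        rng = np.random.default_rng(4)
        seq = random_genome(rng, 201)
        anchor_pos = POS + 12
        a = seq[anchor_pos - 1]
        calls = [
            indel_call("g1", anchor_pos, seq[anchor_pos - 1 : anchor_pos + 2], a),
            indel_call("g2", anchor_pos, seq[anchor_pos - 1 : anchor_pos + 3], a),
        ]
        panel, target = toy_panel(calls, seq=seq)
        result = assess_flank_variation(target, panel)
        assert isinstance(result, FilterOutcome)

    @pytest.mark.parametrize("n_snps,ok", [(5, True), (6, False)])
    def test_per_flank_snp_cap(self, n_snps, ok):
        rng = np.random.default_rng(5)
        seq = random_genome(rng, 201)
        calls = [
            snp_call(f"g{i % 9 + 1}", POS + 2 + 3 * i, seq[POS + 1 + 3 * i],
                     next(b for b in "ACGT" if b != seq[POS + 1 + 3 * i]))
            for i in range(n_snps)
        ]
        panel, target = toy_panel(calls, seq=seq)
        result = assess_flank_variation(target, panel)
        assert isinstance(result, FilterOutcome) != ok

    def test_total_mode_counts_both_flanks(self):
        rng = np.random.default_rng(6)
        seq = random_genome(rng, 201)
        offsets = [-20, -10, -4, 8, 15, 30]  # 3 left + 3 right
        calls = [
            snp_call(f"g{i + 1}", POS + off, seq[POS + off - 1],
                     next(b for b in "ACGT" if b != seq[POS + off - 1]))
            for i, off in enumerate(offsets)
        ]
        panel, target = toy_panel(calls, seq=seq)
        assert not isinstance(assess_flank_variation(target, panel), FilterOutcome)
        strict = assess_flank_variation(target, panel, per_flank=False)
        assert isinstance(strict, FilterOutcome)


class TestDesignSequence:
    def test_no_flank_variants_gives_reference_window(self):
        panel, target = toy_panel([])
        profile = assess_flank_variation(target, panel)
        design = build_design_sequence(target, profile, panel.reference)
        assert design.design_sequence == panel.reference.slice("chr1", POS - 50, POS + 50)
        assert len(design.design_sequence) == 101
        assert design.target_index == 50

    def test_snp_site_becomes_iupac_letter(self):
        rng = np.random.default_rng(8)
        seq = "".join("C" if i == POS + 6 else c for i, c in enumerate(random_genome(rng, 201), 1))
        calls = [snp_call("g1", POS + 6, "C", "T")]
        panel, target = toy_panel(calls, seq=seq)
        profile = assess_flank_variation(target, panel)
        design = build_design_sequence(target, profile, panel.reference)
        assert design.design_sequence[50 + 6] == "Y"  # C/T

    def test_two_alts_minimal_code(self):
        assert iupac_code({"A", "C", "G"}) == "V"
        rng = np.random.default_rng(9)
        seq = "".join("A" if i == POS - 9 else c for i, c in enumerate(random_genome(rng, 201), 1))
        calls = [snp_call("g1", POS - 9, "A", "C"), snp_call("g2", POS - 9, "A", "G")]
        panel, target = toy_panel(calls, seq=seq)
        design = build_design_sequence(target, assess_flank_variation(target, panel), panel.reference)
        assert design.design_sequence[50 - 9] == "V"

    def test_deletion_rendered_as_in_place_ns(self):
        rng = np.random.default_rng(10)
        seq = random_genome(rng, 201)
        del_ref = seq[POS + 9 : POS + 13]
        calls = [indel_call("g1", POS + 10, del_ref, del_ref[0])]
        panel, target = toy_panel(calls, seq=seq)
        design = build_design_sequence(target, assess_flank_variation(target, panel), panel.reference)
        assert len(design.design_sequence) == 101
        assert design.design_sequence[50 + 11 : 50 + 14] == "NNN"

    def test_insertion_ns_extend_design(self):
        rng = np.random.default_rng(11)
        seq = random_genome(rng, 201)
        anchor = seq[POS - 21]
        calls = [indel_call("g1", POS - 20, anchor, anchor + "GT")]
        panel, target = toy_panel(calls, seq=seq)
        design = build_design_sequence(target, assess_flank_variation(target, panel), panel.reference)
        assert len(design.design_sequence) == 103
        assert design.design_sequence[50 - 20 + 1 : 50 - 20 + 3] == "NN"
        assert design.target_index == 52  # left-flank insertion shifts the target
        # the alignment query excises the inserted Ns back to the reference window
        assert design.alignment_query == panel.reference.slice("chr1", POS - 50, POS + 50)

    def test_target_base_is_reference_allele(self, small_scenario, small_result):
        for d in small_result.designs:
            assert d.design_sequence[d.target_index] == d.target.ref_allele[0]

    def test_degenerate_count_equals_snp_sites(self, small_result):
        for d in small_result.designs:
            n_letters = sum(ch in AMBIGUITY_LETTERS for ch in d.design_sequence)
            assert n_letters == len(d.flank_profile.snp_sites)

    def test_reference_resolution_recovers_reference(self, small_scenario, small_result):
        """Replacing ambiguity letters by the reference base (and undoing the
        indel rendering) must give back the reference substring exactly."""
        ref = small_scenario.reference
        for d in small_result.designs:
            expected = ref.slice(d.target.chromosome, d.target.position - 50, d.target.position + 50)
            seq = list(d.alignment_query)  # insertion Ns already excised
            for s in d.flank_profile.snp_sites:
                i = 50 + s.offset
                assert s.ref_base in iupac_set(seq[i])
                seq[i] = s.ref_base
            resolved = "".join(seq)
            # deletion Ns stand for reference bases: N positions must match there
            assert all(a == b or a == "N" for a, b in zip(resolved, expected))


def naive_repeat_oracle(seq: str, max_copies: int = 5, max_unit: int = 5) -> bool:
    """O(L^2 * 4^k) oracle: full expansion, quadratic scan per resolution."""
    stripped = seq.replace("N", "")
    options = [sorted(iupac_set(c)) if c in AMBIGUITY_LETTERS else [c] for c in stripped]
    for res in itertools.product(*options):
        s = "".join(res)
        for unit in range(1, max_unit + 1):
            for i in range(len(s) - unit):
                copies = 1
                while s[i + copies * unit : i + (copies + 1) * unit] == s[i : i + unit]:
                    copies += 1
                if copies > max_copies:
                    return True
    return False


class TestTandemRepeats:
    @pytest.mark.parametrize(
        "seq,fails",
        [
            ("GGCT" + "AT" * 6 + "CGGT", True),  # 6 copies of AT
            ("GGCT" + "A" * 5 + "CGGT", False),  # 5 copies: boundary passes
            ("GGCT" + "A" * 6 + "CGGT", True),
            ("GCGCA" + "CTGAC" * 6 + "TT", True),  # 5-mer unit
        ],
    )
    def test_plain_boundaries(self, seq, fails):
        assert (not check_tandem_repeats(seq).passed) == fails

    def test_resolution_dependent_repeat(self):
        # R between two AAAAA blocks: resolution A gives an 11-A run
        seq = "GCTGC" + "AAAAA" + "R" + "AAAAA" + "GCTGC"
        assert not check_tandem_repeats(seq).passed
        # Y (C/T) between the blocks can never bridge the run
        seq = "GCTGC" + "AAAAA" + "Y" + "AAAAA" + "GCTGC"
        assert check_tandem_repeats(seq).passed

    def test_ns_removed_before_scan(self):
        # 3 + 3 copies of AT separated by Ns fuse into 6 after N removal
        seq = "GCGTC" + "AT" * 3 + "NN" + "AT" * 3 + "GCGTC"
        assert not check_tandem_repeats(seq).passed

    def test_agrees_with_naive_oracle(self):
        rng = np.random.default_rng(12)
        letters = list("ACGT") * 6 + list("RYSWKM")
        for _ in range(1000):
            n = int(rng.integers(10, 40))
            seq = "".join(rng.choice(letters, size=n))
            got = not check_tandem_repeats(seq).passed
            assert got == naive_repeat_oracle(seq), seq


class TestGcWindow:
    def make_design(self, seq: str, target_index: int = 50) -> KASPDesign:
        target = TargetVariant("chr1", POS, seq[target_index], "A", VariantClass.SNP, {}, frozenset({"g1"}))
        from kaspforge.design import FlankProfile

        profile = FlankProfile(seq[:target_index], seq[target_index + 1 :], [], None)
        return KASPDesign(1, target, seq, target_index, profile)

    def test_all_at_window_fails(self):
        assert not check_gc_window(self.make_design("AT" * 50 + "A")).passed

    def test_balanced_window_passes(self):
        # 27 G/C of 55 in the window -> 49.1%
        window = "GC" * 13 + "A" + "G" + "AT" * 14  # contrived but in range
        seq = ("AT" * 11 + window + "TA" * 12)[:101]
        design = self.make_design(seq)
        oc = check_gc_window(design)
        assert oc.passed
        assert 35 <= design.gc_window_pct <= 65

    def test_boundary_percentages_inclusive(self):
        # "between 35% and 65%" is inclusive: a 40 bp window with exactly
        # 14 G/C bases sits at 35.0% and passes; 26/40 = 65.0% passes too.
        lo_seq = ("G" * 14 + "A" * 26) * 3
        lo = self.make_design(lo_seq[:101])
        assert check_gc_window(lo, window=40).passed
        assert lo.gc_window_pct == pytest.approx(35.0)
        hi_seq = ("G" * 26 + "A" * 14) * 3
        hi = self.make_design(hi_seq[:101])
        assert check_gc_window(hi, window=40).passed
        assert hi.gc_window_pct == pytest.approx(65.0)

    def test_ambiguity_contributes_mean_gc(self):
        # a window of 55 'S' letters (G/C) is 100% GC; 55 'W' (A/T) is 0%
        s_design = self.make_design("S" * 101)
        check_gc_window(s_design)
        assert s_design.gc_window_pct == pytest.approx(100.0)
        w_design = self.make_design("W" * 101)
        check_gc_window(w_design)
        assert w_design.gc_window_pct == pytest.approx(0.0)


class TestEmittedDesignInvariants:
    def test_every_design_satisfies_all_rules(self, small_result):
        """Joint invariant over the full synthetic-pipeline output."""
        for d in small_result.designs:
            assert d.n_ambiguous_left <= 5 and d.n_ambiguous_right <= 5
            indel = d.flank_profile.indel_site
            if indel is not None:
                assert indel.length <= 10
                assert abs(indel.offset) > 5
            assert check_tandem_repeats(d).passed
            assert 35 <= d.gc_window_pct <= 65
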