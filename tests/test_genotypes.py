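"""Call rates, numeric coding, clustering, concordance, design properties."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kaspforge.design import FlankIndel, FlankProfile, FlankSNP, KASPDesign
from kaspforge.genotypes import (
    GenotypeMatrix,
    call_rate_summary,
    compare_properties,
    concordance,
    cutoff_sweep,
    design_properties,
    hierarchical_clusters,
    to_numeric_matrix,
)
from kaspforge.io_formats import VariantClass
from kaspforge.panel import TargetVariant


def matrix(rows: dict[str, list[str]], markers: list[str]) -> GenotypeMatrix:
    return GenotypeMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=markers))


class TestCallRates:
    def test_validation_threshold_strict(self):
        # 170/178 samples called = 95.5% -> validated; 160/178 = 89.9% -> not
        calls = {}
        for i in range(178):
            calls[f"s{i}"] = [
                "ref_hom" if i < 170 else "?",
                "alt_hom" if i < 160 else "Bad",
            ]
        gm = matrix(calls, ["m1", "m2"])
        summary = call_rate_summary(gm, threshold=0.90)
        assert summary.validated == ["m1"]
        assert summary.per_marker["m1"] == pytest.approx(170 / 178)

    def test_exactly_at_threshold_not_validated(self):
        calls = {f"s{i}": ["ref_hom" if i < 9 else "Uncallable"] for i in range(10)}
        summary = call_rate_summary(matrix(calls, ["m1"]), threshold=0.90)
        assert summary.validated == []  # 90% is not > 90%

    def test_failed_in_all_and_monomorphic(self):
        calls = {f"s{i}": ["?", "ref_hom", "ref_hom" if i % 2 else "het"] for i in range(10)}
        summary = call_rate_summary(matrix(calls, ["dead", "mono", "poly"]))
        assert summary.failed_in_all == ["dead"]
        assert summary.monomorphic == ["mono"]
        assert summary.polymorphic_validated == ["poly"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(pd.DataFrame())


class TestNumericMatrix:
    def test_codings(self):
        gm = matrix(
            {"s1": ["ref_hom", "het"], "s2": ["ref_hom", "ref_hom"],
             "s3": ["alt_hom", "ref_hom"], "s4": ["ref_hom", "?"]},
            ["m1", "m2"],
        )
        half = to_numeric_matrix(gm, het_mode="half")
        assert half.loc["s1", "m2"] == 0.5
        assert half.loc["s3", "m1"] == 0.0
        # failed call imputed with the marker mean of (0.5, 1, 1)
        assert half.loc["s4", "m2"] == pytest.approx(np.mean([0.5, 1.0, 1.0]))
        majority = to_numeric_matrix(gm, het_mode="majority")
        assert majority.loc["s1", "m2"] == 1.0  # ref majority in m2

    def test_all_reference_column(self):
        gm = matrix({f"s{i}": ["ref_hom"] for i in range(4)}, ["m1"])
        assert (to_numeric_matrix(gm)["m1"] == 1.0).all()

    def test_marker_without_calls_rejected(self):
        gm = matrix({"s1": ["?"], "s2": ["Bad"]}, ["m1"])
        with pytest.raises(ValueError, match="no successful calls"):
            to_numeric_matrix(gm)


class TestClustering:
    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        block = lambda v: v + rng.normal(0, 0.01, size=(10, 30))
        data = np.vstack([block(0.0), block(1.0)])
        df = pd.DataFrame(data, index=[f"s{i}" for i in range(20)])
        result = hierarchical_clusters(df, k=2)
        left = set(result.labels.iloc[:10])
        right = set(result.labels.iloc[10:])
        assert len(left) == len(right) == 1 and left != right

    def test_identical_rows_single_cluster(self):
        df = pd.DataFrame(np.ones((5, 8)), index=[f"s{i}" for i in range(5)])
        result = hierarchical_clusters(df, k=1)
        assert set(result.labels) == {1}
        assert result.linkage[:, 2].max() == 0.0  # all merge heights zero

    def test_newick_contains_all_samples(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.random((6, 5)), index=[f"s{i}" for i in range(6)])
        nwk = hierarchical_clusters(df, k=2).to_newick()
        assert nwk.endswith(";") and all(f"s{i}" in nwk for i in range(6))

    def test_fewer_samples_than_k_rejected(self):
        df = pd.DataFrame(np.ones((2, 3)))
        with pytest.raises(ValueError):
            hierarchical_clusters(df, k=5)


class TestConcordance:
    def test_self_agreement_is_100(self):
        gm = matrix({"L1": ["ref_hom", "alt_hom"], "L2": ["het", "ref_hom"]}, ["1", "2"])
        predicted = {
            "L1": {"1": "reference", "2": "target"},
            "L2": {"1": "het", "2": "reference"},
        }
        report = concordance(gm, predicted)
        assert report.n_nonmatching == 0
        assert (report.per_line_pct == 100.0).all()
        assert report.markers_complete_agreement == 2

    def test_failure_codes_count_as_nonmatching(self):
        gm = matrix({"L1": ["ref_hom", "Bad"]}, ["1", "2"])
        predicted = {"L1": {"1": "reference", "2": "target"}}
        report = concordance(gm, predicted)
        assert report.n_nonmatching == 1
        assert report.per_line_pct["L1"] == 50.0

    def test_injected_failure_fraction_lowers_match_exactly(self):
        rng = np.random.default_rng(9)
        markers = [str(i) for i in range(200)]
        calls = {"L1": ["ref_hom"] * 200}
        predicted = {"L1": {m: "reference" for m in markers}}
        flip = rng.choice(200, size=50, replace=False)  # f = 0.25
        for i in flip:
            calls["L1"][i] = "?"
        report = concordance(matrix(calls, markers), predicted)
        assert report.per_line_pct["L1"] == pytest.approx(75.0)

    def test_datapoint_dimensions(self):
        lines = [f"L{i}" for i in range(13)]
        markers = [str(i) for i in range(40)]
        gm = matrix({ln: ["ref_hom"] * 40 for ln in lines}, markers)
        predicted = {ln: {m: "reference" for m in markers} for ln in lines}
        report = concordance(gm, predicted)
        assert report.n_datapoints == 13 * 40


def make_design(snp_offsets=(), indel=None, seq=None, pkey=1, pos=1000):
    target = TargetVariant("chr1", pos, "A", "G", VariantClass.SNP, {}, frozenset({"g1"}))
    snps = [FlankSNP(off, "A", frozenset({"C"})) for off in snp_offsets]
    profile = FlankProfile("A" * 50, "A" * 50, snps, indel)
    seq = seq or ("AT" * 51)[:101]
    return KASPDesign(pkey, target, seq, 50, profile, positions={"R498": ("chr1", pos)})


class TestDesignProperties:
    def test_enumeration_example(self):
        props = design_properties(make_design(snp_offsets=(-12, 7)))
        assert props["n_ambiguous"] == 2
        assert props["n_ambiguous_left"] == 1
        assert props["n_ambiguous_right"] == 1
        assert props["n_ambiguous_least_flank"] == 1
        assert props["n_ambiguous_most_flank"] == 1
        assert props["dist1_left"] == 12
        assert props["dist1_right"] == 7
        assert props["dist1_shortest"] == 7
        assert props["dist1_longest"] == 12
        assert props["dist2_left"] is None  # fewer than 2 in the flank

    def test_no_ambiguity_design(self):
        props = design_properties(make_design())
        assert props["n_ambiguous"] == 0
        for n in range(1, 6):
            assert props[f"dist{n}_left"] is None
            assert props[f"dist{n}_shortest"] is None

    def test_longest_requires_both_flanks(self):
        props = design_properties(make_design(snp_offsets=(-10, -20, 8)))
        assert props["dist2_left"] == 20
        assert props["dist2_right"] is None
        assert props["dist2_shortest"] == 20
        assert props["dist2_longest"] is None  # right flank lacks a second site

    def test_indel_properties(self):
        indel = FlankIndel(offset=-31, length=4, kind=VariantClass.DEL)
        props = design_properties(make_design(indel=indel))
        assert props["n_indel_bases"] == 4
        assert props["indel_distance"] == 31

    def test_gc_flank_split(self):
        seq = "G" * 50 + "A" + "T" * 50
        props = design_properties(make_design(seq=seq))
        assert props["gc_left"] == pytest.approx(100.0)
        assert props["gc_right"] == pytest.approx(0.0)
        assert props["gc_lowest"] == 0.0 and props["gc_highest"] == 100.0


def rank_sum_permutation_oracle(a, b):
    """Exact two-sided p-value by full enumeration of group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    observed = ranks[:n_a].sum()
    mean = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-9:
            count += 1
    return count / total


class TestPropertyComparison:
    def test_identical_groups_p_near_one(self):
        designs = [make_design(snp_offsets=(-10, 5), pkey=i) for i in range(6)]
        comps = compare_properties(designs, designs)
        for c in comps:
            assert c.p_value > 0.9

    def test_shifted_counts_significant(self):
        """Ambiguous-base counts ~Poisson(1.8) vs ~Poisson(2.5) at n=500
        should separate decisively, mirroring the success/failure contrast."""
        rng = np.random.default_rng(13)

        def group(lam, n):
            out = []
            for i in range(n):
                k = min(int(rng.poisson(lam)), 10)
                left = min(k // 2 + k % 2, 5)
                right = min(k // 2, 5)
                offsets = tuple(-(o + 1) for o in range(left)) + tuple(o + 1 for o in range(right))
                out.append(make_design(snp_offsets=offsets, pkey=i))
            return out

        comps = compare_properties(group(1.8, 500), group(2.5, 500))
        by_name = {c.property_name: c for c in comps}
        c = by_name["n_ambiguous"]
        assert c.p_value < 0.001 and c.stars == "***"
        assert c.mean_success < c.mean_failure

    def test_degenerate_group_skipped(self):
        good = [make_design(snp_offsets=(-10,), pkey=i) for i in range(5)]
        lone = [make_design(snp_offsets=(5,), pkey=99)]
        comps = compare_properties(good, lone)
        assert comps == []  # one design in the failure group: skipped

    def test_exact_method_matches_permutation_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            n_a, n_b = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            a = [make_design(snp_offsets=tuple(-(o + 1) for o in range(int(rng.integers(0, 5)))), pkey=i)
                 for i, _ in enumerate(range(n_a))]
            b = [make_design(snp_offsets=tuple(-(o + 1) for o in range(int(rng.integers(0, 5)))), pkey=i)
                 for i, _ in enumerate(range(n_b))]
            comps = compare_properties(a, b)
            by_name = {c.property_name: c for c in comps}
            if "n_ambiguous_left" not in by_name:
                continue
            got = by_name["n_ambiguous_left"].p_value
            expected = rank_sum_permutation_oracle(
                [design_properties(d)["n_ambiguous_left"] for d in a],
                [design_properties(d)["n_ambiguous_left"] for d in b],
            )
            assert got == pytest.approx(expected, abs=0.02)


class TestCutoffSweep:
    def make_designs(self, rng, n=60):
        designs = []
        for i in range(n):
            left = int(rng.integers(0, 6))
            right = int(rng.integers(0, 6))
            offsets = tuple(-(o + 1) for o in range(left)) + tuple(o + 1 for o in range(right))
            designs.append(make_design(snp_offsets=offsets, pkey=i, pos=1000 + 97 * i))
        return designs

    def test_monotone_counts_and_spacing(self):
        rng = np.random.default_rng(15)
        designs = self.make_designs(rng)
        sweep = cutoff_sweep(designs, "R498", cutoffs=(5, 4, 3, 2, 1, 0))
        counts = sweep["n_designs"].tolist()
        assert counts == sorted(counts, reverse=True)
        spacing = sweep["median_spacing_bp"].dropna().tolist()
        assert spacing == sorted(spacing)

    def test_success_rates_within_subset(self):
        rng = np.random.default_rng(16)
        designs = self.make_designs(rng, n=40)
        # genotyping: markers with more ambiguity fail more often
        samples = [f"s{i}" for i in range(20)]
        calls = {}
        for s in samples:
            row = []
            for d in designs:
                heavy = max(d.n_ambiguous_left, d.n_ambiguous_right) >= 4
                row.append("?" if heavy else "ref_hom" if rng.random() < 0.6 else "alt_hom")
            calls[s] = row
        gm = matrix(calls, [str(d.pKey) for d in designs])
        sweep = cutoff_sweep(designs, "R498", gm=gm, cutoffs=(5, 3))
        full = sweep[sweep.max_ambiguous == 5].iloc[0]
        trimmed = sweep[sweep.max_ambiguous == 3].iloc[0]
        assert trimmed.pct_successful >= full.pct_successful
        assert trimmed.n_markers_tested <= full.n_markers_tested
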