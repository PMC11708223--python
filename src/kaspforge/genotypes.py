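"""Genotyping-run QC, concordance, clustering and design-property statistics.

A genotyping run is a sample x marker table of calls; besides the three
genotype classes (reference homozygote, target-allele homozygote,
heterozygote) a cell may hold one of the failure codes the chemistry
reports ("?", "Bad", "Uncallable") or be missing entirely.  A marker is
*validated* when it calls successfully in strictly more than 90% of
samples.  Downstream analyses: concordance of calls against design-time
predicted genotypes (failed calls count as nonmatching), UPGMA clustering
of the numeric genotype matrix for population structure, Wilcoxon
rank-sum comparison of 29 per-design sequence properties between
successful and failing assays, and the ambiguous-base cutoff sweep
trading design density against success rate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .design import KASPDesign
from .sequence import gc_percent

SUCCESS_CODES = ("ref_hom", "alt_hom", "het")
FAILURE_CODES = ("?", "Bad", "Uncallable", "NA")
ALL_CODES = SUCCESS_CODES + FAILURE_CODES

_PREDICTION_TO_CALL = {"reference": "ref_hom", "target": "alt_hom", "het": "het"}


class GenotypeMatrix:
    """Sample x marker call table with failure codes."""

    def __init__(self, calls: pd.DataFrame) -> None:
        bad = set(np.unique(calls.values.astype(str))) - set(ALL_CODES)
        if bad:
            raise ValueError(f"unknown call codes {sorted(bad)}")
        if calls.empty:
            raise ValueError("empty genotype matrix")
        self.calls = calls.astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    def is_success(self) -> pd.DataFrame:
        return self.calls.isin(SUCCESS_CODES)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeMatrix":
        """Read long-format `sample<TAB>marker<TAB>call` (with header)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        wide = df.pivot(index="sample", columns="marker", values="call").fillna("NA")
        return cls(wide)

    def to_tsv(self, path: str | Path) -> None:
        long = self.calls.stack().rename("call").rename_axis(["sample", "marker"]).reset_index()
        long.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class CallRateSummary:
    per_marker: pd.Series  # fraction of samples successfully called
    per_sample: pd.Series
    validated: list[str]
    failed_in_all: list[str]
    monomorphic: list[str]  # validated markers whose successful calls are all identical

    @property
    def polymorphic_validated(self) -> list[str]:
        mono = set(self.monomorphic)
        return [m for m in self.validated if m not in mono]


def call_rate_summary(gm: GenotypeMatrix, threshold: float = 0.90) -> CallRateSummary:
    """Per-marker/per-sample call rates and the validated marker set.

    Validation requires a call rate strictly above ``threshold``.
    """
    ok = gm.is_success()
    per_marker = ok.mean(axis=0)
    per_sample = ok.mean(axis=1)
    validated = [m for m in gm.markers if per_marker[m] > threshold]
    failed_in_all = [m for m in gm.markers if not ok[m].any()]
    monomorphic = [
        m for m in validated if gm.calls.loc[ok[m], m].nunique() == 1
    ]
    return CallRateSummary(per_marker, per_sample, validated, failed_in_all, monomorphic)


def to_numeric_matrix(
    gm: GenotypeMatrix,
    het_mode: str = "half",
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Numeric coding: reference allele 1, target allele 0.

    Heterozygotes become 0.5 (``het_mode="half"``) or the marker's most
    common homozygous coding (``"majority"``).  Failed calls are imputed
    with the marker mean.
    """
    if het_mode not in ("half", "majority"):
        raise ValueError(f"unknown het_mode {het_mode!r}")
    calls = gm.calls if markers is None else gm.calls[list(markers)]
    num = pd.DataFrame(np.nan, index=calls.index, columns=calls.columns)
    num[calls == "ref_hom"] = 1.0
    num[calls == "alt_hom"] = 0.0
    for m in calls.columns:
        col = calls[m]
        n_ref = int((col == "ref_hom").sum())
        n_alt = int((col == "alt_hom").sum())
        n_het = int((col == "het").sum())
        if n_ref + n_alt + n_het == 0:
            raise ValueError(f"marker {m} has no successful calls")
        het_value = 0.5 if het_mode == "half" else (1.0 if n_ref >= n_alt else 0.0)
        num.loc[col == "het", m] = het_value
        num[m] = num[m].fillna(num[m].mean())
    return num


@dataclasses.dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: pd.Series  # sample -> 1..k

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        names = list(self.labels.index)

        def rec(node) -> str:
            if node.is_leaf():
                return names[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def hierarchical_clusters(numeric: pd.DataFrame, k: int) -> ClusterResult:
    """Euclidean distances + average-linkage (UPGMA) agglomeration, cut at k."""
    if len(numeric) < k:
        raise ValueError(f"fewer samples ({len(numeric)}) than requested clusters ({k})")
    dist = pdist(numeric.values, metric="euclidean")
    link = hierarchy.linkage(dist, method="average")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return ClusterResult(link, pd.Series(labels, index=numeric.index))


@dataclasses.dataclass
class ConcordanceReport:
    per_line_pct: pd.Series  # % datapoints matching per line
    n_datapoints: int
    n_nonmatching: int
    markers_complete_agreement: int
    nonmatch_distribution: pd.Series  # n nonmatching lines -> marker count

    @property
    def overall_pct(self) -> float:
        return 100.0 * (1 - self.n_nonmatching / self.n_datapoints)


def concordance(
    gm: GenotypeMatrix,
    predicted: Mapping[str, Mapping[str, str]],
    markers: Sequence[str] | None = None,
) -> ConcordanceReport:
    """Compare genotyping calls with design-time predictions, line by line.

    ``predicted`` maps line id -> marker -> predicted state
    ("reference"/"target"/"het").  A datapoint matches iff the call equals
    the prediction; any failure code is a nonmatch.
    """
    lines = [s for s in gm.samples if s in predicted]
    if not lines:
        raise ValueError("no genotyped samples match predicted lines")
    marker_list = list(markers) if markers is not None else gm.markers
    match = pd.DataFrame(False, index=lines, columns=marker_list)
    for line in lines:
        preds = predicted[line]
        for m in marker_list:
            expected = _PREDICTION_TO_CALL.get(preds.get(m, ""), None)
            match.loc[line, m] = expected is not None and gm.calls.loc[line, m] == expected
    n_total = match.size
    n_nonmatch = int((~match).values.sum())
    nonmatch_per_marker = (~match).sum(axis=0)
    dist = nonmatch_per_marker.value_counts().sort_index()
    return ConcordanceReport(
        per_line_pct=100.0 * match.mean(axis=1),
        n_datapoints=n_total,
        n_nonmatching=n_nonmatch,
        markers_complete_agreement=int((nonmatch_per_marker == 0).sum()),
        nonmatch_distribution=dist,
    )


# ---------------------------------------------------------------------------
# Design properties (the 29-property set)

PROPERTY_NAMES = [
    "n_indel_bases",
    "indel_distance",
    "n_ambiguous",
    "n_ambiguous_left",
    "n_ambiguous_right",
    "n_ambiguous_least_flank",
    "n_ambiguous_most_flank",
    "dist1_left", "dist1_right", "dist1_shortest", "dist1_longest",
    "dist2_left", "dist2_right", "dist2_shortest", "dist2_longest",
    "dist3_left", "dist3_right", "dist3_shortest",
    "dist4_left", "dist4_right", "dist4_shortest",
    "dist5_left", "dist5_right", "dist5_shortest",
    "gc_pct", "gc_left", "gc_right", "gc_lowest", "gc_highest",
]


def design_properties(design: KASPDesign) -> dict[str, float | None]:
    """The per-design sequence properties tested against assay success.

    Distance properties to the nth ambiguous base are undefined (None)
    when the relevant flank has fewer than n ambiguous sites; the
    "longest in either flank" variants additionally require n sites in
    both flanks.
    """
    profile = design.flank_profile
    left = sorted(abs(s.offset) for s in profile.snp_sites if s.offset < 0)
    right = sorted(s.offset for s in profile.snp_sites if s.offset > 0)
    indel = profile.indel_site
    props: dict[str, float | None] = {
        "n_indel_bases": float(indel.length) if indel else None,
        "indel_distance": float(abs(indel.offset)) if indel else None,
        "n_ambiguous": float(len(left) + len(right)),
        "n_ambiguous_left": float(len(left)),
        "n_ambiguous_right": float(len(right)),
        "n_ambiguous_least_flank": float(min(len(left), len(right))),
        "n_ambiguous_most_flank": float(max(len(left), len(right))),
    }
    for n in range(1, 6):
        dl = float(left[n - 1]) if len(left) >= n else None
        dr = float(right[n - 1]) if len(right) >= n else None
        props[f"dist{n}_left"] = dl
        props[f"dist{n}_right"] = dr
        defined = [d for d in (dl, dr) if d is not None]
        props[f"dist{n}_shortest"] = min(defined) if defined else None
        if n <= 2:
            props[f"dist{n}_longest"] = max(dl, dr) if (dl is not None and dr is not None) else None
    seq = design.design_sequence
    t = design.target_index
    props["gc_pct"] = gc_percent(seq)
    props["gc_left"] = gc_percent(seq[:t])
    props["gc_right"] = gc_percent(seq[t + 1 :])
    props["gc_lowest"] = min(props["gc_left"], props["gc_right"])
    props["gc_highest"] = max(props["gc_left"], props["gc_right"])
    return props


def _exact_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Tie-safe exact two-sided rank-sum test by exhaustive enumeration.

    p is the fraction of group assignments whose rank sum deviates from
    its null mean at least as far as the observed one; W is the U
    statistic of the first group (R's convention).
    """
    import itertools

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    observed = ranks[:n_a].sum()
    mean = n_a * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n_a):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mean) >= abs(observed - mean) - 1e-9:
            count += 1
    W = observed - n_a * (n_a + 1) / 2
    return float(W), count / total


@dataclasses.dataclass
class PropertyComparison:
    property_name: str
    W: float
    p_value: float
    mean_success: float
    mean_failure: float
    n_success: int
    n_failure: int

    @property
    def stars(self) -> str:
        p = self.p_value
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def compare_properties(
    success: Iterable[KASPDesign],
    failure: Iterable[KASPDesign],
) -> list[PropertyComparison]:
    """Two-sided Wilcoxon rank-sum per property between assay outcomes.

    W follows the R convention (rank-sum based U of the success group).
    For group sizes <= 8 the null distribution is evaluated exactly by
    exhaustive permutation (tie-safe); larger groups use the normal
    approximation with tie correction.  Properties with fewer than two
    defined values in either group are skipped.
    """
    succ_props = [design_properties(d) for d in success]
    fail_props = [design_properties(d) for d in failure]
    out: list[PropertyComparison] = []
    for name in PROPERTY_NAMES:
        a = np.array([p[name] for p in succ_props if p[name] is not None], dtype=float)
        b = np.array([p[name] for p in fail_props if p[name] is not None], dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        if max(len(a), len(b)) <= 8:
            W, p = _exact_rank_sum(a, b)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            W, p = float(res.statistic), float(res.pvalue)
        out.append(
            PropertyComparison(
                property_name=name,
                W=W,
                p_value=p,
                mean_success=float(a.mean()),
                mean_failure=float(b.mean()),
                n_success=len(a),
                n_failure=len(b),
            )
        )
    return out


def comparisons_to_frame(comparisons: list[PropertyComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "property": c.property_name,
                "W": c.W,
                "p_value": c.p_value,
                "mean_success": c.mean_success,
                "mean_failure": c.mean_failure,
                "n_success": c.n_success,
                "n_failure": c.n_failure,
                "significance": c.stars,
            }
            for c in comparisons
        ]
    )


# ---------------------------------------------------------------------------
# Ambiguous-base cutoff sweep


def cutoff_sweep(
    designs: Sequence[KASPDesign],
    assembly: str,
    gm: GenotypeMatrix | None = None,
    cutoffs: Sequence[int] = (4, 3, 2, 1, 0),
    threshold: float = 0.90,
    marker_id=lambda d: str(d.pKey),
) -> pd.DataFrame:
    """Design availability and success rates under ambiguous-base caps.

    For each cutoff c the design set is restricted to those whose busier
    flank holds at most c ambiguous bases; the sweep reports the subset
    size, the median distance between consecutive retained designs on the
    assembly, and — when a genotyping run is supplied — the percentage of
    tested markers producing any calls and the percentage validated.
    """
    summary = call_rate_summary(gm, threshold) if gm is not None else None
    rows = []
    for c in cutoffs:
        subset = [
            d for d in designs if max(d.n_ambiguous_left, d.n_ambiguous_right) <= c
        ]
        positions = sorted(
            d.positions.get(assembly) or (d.target.chromosome, d.target.position)
            for d in subset
        )
        diffs = np.array(
            [
                b[1] - a[1]
                for a, b in zip(positions, positions[1:])
                if a[0] == b[0]
            ]
        )
        row = {
            "max_ambiguous": c,
            "n_designs": len(subset),
            "median_spacing_bp": float(np.median(diffs)) if diffs.size else np.nan,
        }
        if summary is not None:
            tested = [d for d in subset if marker_id(d) in summary.per_marker.index]
            n = len(tested)
            if n:
                producing = sum(
                    1 for d in tested if marker_id(d) not in set(summary.failed_in_all)
                )
                successful = sum(1 for d in tested if marker_id(d) in set(summary.validated))
                row.update(
                    n_markers_tested=n,
                    pct_producing_results=100.0 * producing / n,
                    pct_successful=100.0 * successful / n,
                )
            else:
                row.update(n_markers_tested=0, pct_producing_results=np.nan, pct_successful=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
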