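# Methods

## Model and assumptions

The package models allele-specific PCR assay design as a sequence of
rejection rules over candidate variant sites in a panel of N resequenced
genomes aligned to one reference assembly. Coordinates are 1-based
inclusive at every file boundary (VCF, GFF3, depth TSV) and converted to
0-based string indices only inside sequence arithmetic. Indels are
VCF-style left-anchored: reference and alternative allele share their
first base, and the indel's "position" is that anchor.

Assumptions worth stating explicitly:

- **Reference-based calling.** A genome with no call at a site is assumed
  to carry the reference allele there (the coverage filters exist
  precisely to reject sites where that assumption is unsafe).
- **Heterozygous lines carry the alternative.** For carrier counting a
  het line counts fully toward the alternative allele (an allele-specific
  assay detects it); a 0.5-weight mode is available
  (`het_carries_alt=False`). A site is monomorphic — and rejected — only
  when *all* N lines are homozygous for the same alternative, since a het
  line still carries the reference allele and the assay stays
  informative.
- **Rare-allele counting** follows "identified in more than 10% of
  lines": any line carrying a non-modal alternative counts (het or hom),
  except lines that also carry the modal allele.
- **Depth semantics.** "Low coverage" is strict: depth < 0.1 × the
  genome's global mean depth (taken from the depth-track metadata, not
  recomputed locally). Depth exactly at 0.1 × the mean is not low; a
  count of low genomes exactly at 10% of N passes. The call-level filter
  drops SNP and insertion calls with supporting depth < 5 at load time;
  deletion calls are exempt (their sentence-level rule names only SNPs
  and insertions) but `filter_deletions=True` extends it.

## The filters, and choices made where the rules were open

**Filter 3 aggregation.** Each flank base is tested with the same
>10%-of-genomes aggregation as the target base; one failing flank base
rejects the site. The stricter reading — any single genome low at any
flank base — is exposed as `strict_flank`. Sites closer than 50 bp to a
chromosome end cannot host a full design and fail here ("truncated
flank").

**Filter 4 semantics.** The SNP cap (≤ 5) applies per flank by default
(`per_flank=False` gives the total-of-5 reading). A flank site mixing SNP
and indel alleles fails; indel alleles at one site must share kind *and*
length. The indel clearance rule is anchored: |anchor offset| > 5 and
length ≤ 10; additionally a deleted run must itself stay > 5 bp from the
target and inside its flank, since the anchor-offset rule alone would let
a left-flank deletion overlap the target base.

**Rendering.** Flanking SNP sites become the minimal IUPAC letter
covering {reference base} ∪ observed alternatives. A deletion becomes L
Ns substituted in place (design coordinates stay aligned to the
reference); an insertion becomes L Ns inserted after the anchor (design
length 101 + L, target index shifted for left-flank insertions). The
target base itself is stored as the reference allele.

**Repeat screen.** The defined semantics is: strip Ns, expand every
ambiguity letter over its base set (cartesian product, capped at 4^10
resolutions), fail if any resolution contains more than 5 consecutive
copies of any 1–5 nt unit (maximal runs, all phases). The implementation
short-circuits equivalently: a minimal failing run (6 copies of a ≤ 5-mer)
spans ≤ 30 bp, so a run either lies wholly in unambiguous sequence (found
by one scan with per-position sentinels) or passes through an ambiguity
letter (found by expanding only a 59 bp window around it); an optimistic
periodicity prescan, where letters match on base-set intersection, proves
most designs clean without any expansion. Equivalence is tested against a
naive full-expansion oracle on 1,000 random degenerate sequences.

**GC window.** Centred on the target base (placement was unspecified;
centring is the symmetric choice), clamped to the design when an
insertion shifts the target off-centre. Bounds are inclusive. Ambiguity
letters contribute the mean GC of their base set; Ns are excluded from
numerator and denominator.

**Placement.** BLAST is replaced by a deterministic engine: exact
unambiguous 15-mer seeds (both strands; the seed length is a config
default, not a published value) propose candidate loci, each scored
ungapped over the full query (match +1 / mismatch −1; ambiguity letters
match any base of their set, N matches anything). The unique
best-scoring locus wins; exact ties mean "unplaced". Identity is
matches / query length, ambiguity-compatible positions counting as
matches. One consequence of ungapped scoring: an *inserted* N-run has no
reference counterpart and would shift everything downstream, so placement
uses the design with inserted Ns excised (deletion Ns stay). Gapped
alignment, e-values and a full local-alignment search are out of scope;
the engine's best-hit sets are tested against an exhaustive
sliding-window oracle.

**Effect annotation.** Region (UTR5/UTR3/intron/CDS/intergenic) is
assigned per transcript isoform; UTRs are derived as exon-minus-CDS when
absent. CDS SNPs are classified by strand- and phase-aware codon
mutation under the standard nuclear code; CDS-overlapping indels are
frameshift iff length mod 3 ≠ 0, with start/stop-codon disruption taking
precedence; an indel anchored just outside a gene still annotates if its
affected span reaches in. A design is *functional* when any isoform in
any annotated assembly predicts a protein-altering effect — the
any-isoform rule is this package's collapse choice.

**Panel selection.** Candidates are designs within 20,000 bp of a trait
locus (the round bound inferred from an observed 0–19,913 bp realised
range), distance measured from the design's target base to the nearest
interval edge. Per locus, functional designs are taken nearest-first,
then nonfunctional nearest-first, up to 5; a candidate within 100 bp of
an already chosen design with identical predicted genotypes across all
lines is skipped and the next candidate takes its slot (the same
redundancy rule the quota stage states, applied in both stages). The
quota trim repeatedly removes the farthest nonfunctional marker from
whichever locus currently holds the most (ties: lexicographic locus id,
then highest pKey); functional markers are removed only when nothing
nonfunctional remains, and such removals are logged.

**Genotyping analysis.** Validation requires call rate strictly > 0.90;
`?`, `Bad`, `Uncallable` and missing cells all count as failed calls, and
as nonmatching datapoints in concordance. For clustering, failed calls
are imputed with the marker mean (the handling of missing cells was
unspecified; mean imputation is neutral for Euclidean distances);
distances are Euclidean, linkage is average (UPGMA), and cutting at k
gives group labels. "Success vs failure" for the design-property
comparison is validated vs all others (including failed-in-all); the
partition is exposed as a parameter because other readings are possible.
The Wilcoxon rank-sum test reports W in the R convention (U of the
success group); groups of ≤ 8 use an exact exhaustive permutation null
(tie-safe, two-sided by symmetric deviation of the rank sum) and larger
groups the normal approximation with tie correction. The 29 design
properties are: flanking-indel length and distance; ambiguous-base counts
(total, left, right, min-flank, max-flank); distances to the 1st–5th
ambiguous base in the left flank, right flank, and the shortest in
either (defined only when the relevant flank holds ≥ n sites), plus the
longest in either for n = 1, 2 (requiring ≥ n in both flanks); and GC
percent (whole design, left flank, right flank, min, max). The cutoff
sweep restricts designs by the busier flank's ambiguous count and
reports subset size, median spacing between consecutive retained designs
per chromosome, and — within the genotyped subset — the percentage
producing any calls and the percentage validated.

## The synthetic-data generator

The generator emulates the structure of a resequencing-panel study: one
random chromosome (background GC 0.43) carrying non-overlapping
multi-exon genes with valid CDS (start codon, in-frame stop, no internal
stops, short UTRs, 1–3 exons, both strands), a candidate-site grid every
110 bp (adjacent sites' 50 bp flanks stay disjoint, so truth stays
local), per-genome mean depths uniform on 6.2–90.3 reads/base, and
per-site scenarios drawn to put mass on both sides of every filter
boundary: carrier counts uniform on 1..N−1, boundary and failing
rare-allele configurations, monomorphic sites, modal ties, calls planted
below the depth-5 load cut, low-coverage patches at targets and single
flank bases, flank SNP counts 0–6 per flank, flanking indels with
offsets and lengths straddling the clearance and length rules, repeat
tracts, AT-rich (GC-failing) windows, and duplicated 101 bp contexts in a
reserved zone to break placement uniqueness. Defaults: 20 genomes ×
200 kb ≈ 1,800 planted sites; the full pipeline over them runs in a few
seconds on one CPU, which is why tests and the acceptance script use
this scale.

Ground truth is computed at generation time by straight-line,
independent reimplementations of every rule — a separate IUPAC table, a
regex-backreference tandem-repeat detector, a direct GC counter, and
block-bookkeeping effect logic — never by calling pipeline code. The
agreement test (every verdict and every surviving design sequence, site
for site) is the repository's central double-entry check.

The genotyping-run generator draws samples from k planted subpopulations
whose per-marker reference-allele frequencies come from {0.1, 0.9}, kills
a configurable fraction of markers outright (default 0.15 failed-in-all),
injects cell-level failure codes (default 0.03, split between `?`, `Bad`
and `Uncallable`), and lets named samples reproduce a panel genome's
predicted genotypes with a configurable discordance rate (emulating
seed-lot drift in one variety).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: read-level error and mapping bias (depth is
run-length truth, not alignment output), linkage between nearby sites
(scenarios are independent per site), population structure in the
*design* panel (carriers are drawn independently), multi-chromosome
assemblies, gene overlap and alternative isoforms (one transcript per
gene), and realistic allele-frequency spectra (counts are uniform, not
mutation–drift shaped).

## Numerical and degenerate-input choices

- All thresholds are strict or inclusive exactly as stated above;
  boundary tests pin each one.
- Ties: modal-allele ties break lexicographically on (alt, ref) allele
  strings; placement ties are detected exactly and mean "unplaced";
  selection ties break on distance then pKey; quota ties on locus id then
  pKey. Identical inputs give byte-identical outputs.
- A marker with no successful calls cannot be numerically coded
  (error); a property with fewer than two defined values in either group
  is skipped in the comparison table; an empty candidate list selects
  nothing and is logged.
- The ambiguity-expansion cap (4^10) can only bind on inputs that
  already violate the flank-SNP caps; exceeding it raises rather than
  silently truncating.

## Known limitations

- The placement engine is ungapped; designs that would only align with
  internal gaps in a *different* assembly can be reported unplaced where
  a gapped aligner would place them. Cross-assembly positioning of
  indel-dense designs is therefore conservative.
- Filter 4 inspects variant anchors within ±50 bp; a deletion anchored
  outside the flank whose run reaches into it is not seen (such calls do
  not arise from the generator and are rare in left-anchored call sets).
- Only the standard nuclear genetic code is supported; organellar
  targets are out of scope.
- The quota trim is greedy, matching the stated procedure; it does not
  globally optimise panel spacing.
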