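# kaspforge

Design of **degenerate-base KASP assays** (Kompetitive Allele-Specific
PCR) from a multi-genome resequencing panel, for marker-assisted rice
breeding and similar crop-genomics settings.

A KASP assay interrogates one biallelic SNP or indel with two
allele-specific primers plus a common primer. When the assay must work
across *diverse* germplasm, polymorphism in the primer-binding flanks can
break it; the remedy implemented here is to fold panel-wide flanking
variation into the design sequence as IUPAC ambiguity letters (flanking
SNPs) and runs of `N` (one admissible flanking indel), so primers can be
synthesised with degenerate bases.

## The pipeline

For every candidate site — a position where at least one panel genome
carries a non-reference allele — the package applies a fixed sequence of
filters. With N panel genomes, the site's **target allele** is the most
common alternative, and the site survives iff:

1. **Rare alleles** — lines carrying neither the reference nor the target
   allele make up ≤ 10% of N, and the panel is not monomorphic for the
   alternative (all N lines homozygous-alt).
2. **Target coverage** — genomes whose read depth at the site is
   < 0.1 × their genome-wide mean depth make up ≤ 10% of N.
3. **Flank coverage** — the same criterion holds at *every one* of the 50
   bases either side; a single failing flank base rejects the site.
4. **Flank variation** — at most 5 SNP sites per flank; at most one
   flanking indel, of one length ≤ 10 bp, more than 5 bp from the target.

The design sequence is then the 101 bp window (target base kept as the
reference allele; flanking SNPs as minimal IUPAC codes; the indel as
`N…N`), screened further for:

5. **Tandem repeats** — no resolution of the ambiguity letters (Ns
   removed) may contain more than 5 consecutive copies of any 1–5 nt
   unit;
6. **GC content** — the 55 bp window centred on the target must lie in
   [35%, 65%] (ambiguity letters contribute the mean GC of their base
   set);
7. **Placement uniqueness** — a deterministic exact-seed / ungapped
   extension search must find a single best locus in every required
   assembly (ties ⇒ rejected). Legacy assemblies are cross-referenced
   with a ≥ 90% full-length-identity rule; SSR markers are positioned
   from their primer pairs (≥ 95% identity, unique pair within 10 kb).

Surviving designs are annotated against gene models (synonymous /
nonsynonymous / premature stop / stop loss / start loss for CDS SNPs;
frameshift / nonframeshift for CDS indels), and trait-targeted panels are
selected: up to 5 designs within 20 kb of each named locus, functional
designs first, never two mutually redundant designs within 100 bp with
identical predicted genotypes, trimmed to a global quota.

Genotyping runs (sample × marker calls with `?`/`Bad`/`Uncallable`
failure codes) are analysed for call rates (validation requires > 90%),
concordance with design-time predictions, UPGMA population structure
(1 = reference allele, 0 = target, heterozygotes 0.5 or majority-coded),
Wilcoxon rank-sum comparison of 29 per-design sequence properties between
successful and failing assays, and an ambiguous-base cutoff sweep.

All inputs are standard formats: FASTA, VCF 4.x (per-sample `DP`
honoured; SNP/insertion calls with depth < 5 dropped on load), GFF3,
run-length depth TSV, and long-format genotype TSV.

## Worked example

Generate a fully synthetic study (reference + 20-genome variant panel +
depth tracks + gene models, with analytic per-site ground truth), then
run the pipeline on the files:

```sh
kaspforge simulate --seed 7 --out-dir demo --length 30000
kaspforge run --reference demo/reference.fasta --vcf demo/panel.vcf \
    --depth-dir demo/depth --gff demo/genes.gff3 --out-dir demo/out
```

which prints

```
1077 candidates -> 394 designs (demo/out/designs.tsv)
```

meaning 1,077 candidate variant sites entered the filters and 394
degenerate design sequences survived all seven. `demo/out/manifest.json`
accounts for every rejection (the counts sum back to 1,077):

```json
"failures_by_rule": {
  "flank_coverage": 172, "target_coverage": 25, "rare_allele": 96,
  "monomorphic": 11, "repeat": 95, "flank_variation": 215,
  "gc": 66, "alignment": 3
}
```

`demo/out/designs.tsv` holds one row per design, e.g.

```
2  chr1  469  C  CAAAAAAAAAAA  INS  0  2  INS:+31:1  61.82  False  GAGT…CCANCTT…CGACRTRTTCAGA
```

— an 11 bp insertion target whose design sequence carries one flanking
insertion rendered as `N` at +31 and two right-flank SNPs rendered as
`R`; the 55 bp GC window is 61.8%. Because `demo/truth.tsv` records the
generator's analytic verdict for every planted site, you can check the
pipeline against it: every verdict in `demo/out/verdicts.tsv` matches.

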