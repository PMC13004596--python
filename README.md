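# bscomp — branch-site competition analysis

`bscomp` is a toolkit for the downstream statistics of studies in which two
RNA-binding proteins compete for intron branch sites — the splicing
activator SF1, which recognizes the branch-point sequence during E-complex
assembly, and Quaking (QKI), a dimeric STAR-family repressor whose
high-affinity binding site (an ACUAAY core plus a YAAY "half site" within
~20 nt, the Quaking response element) mirrors the branch-site consensus.
It is written for computational biologists who already have quantifier
output in hand — splicing event tables (VAST-tools/rMATS-style), transcript
count tables from an intron-aware annotation, and proteomics abundance
tables — and need the bespoke analyses that sit on top:

* **Co-regulation quadrants** — events significant under two perturbation
  contrasts (|ΔΨ| > 10 percentage points in either, MVdPSI95 > 0 in both)
  classified by their pair of ΔΨ signs, plus seeded sampling of unchanged,
  expressed control events (|ΔΨ| < 1, MVdPSI95 = 0, base mean > 100).
* **3'ss-proximal motif scanning** — strand-resolved extraction of windows
  upstream of the 3' splice site (defaults (60, 20) nt for mammalian scans,
  (80, 1) for yeast introns), IUPAC motif scanning with overlapping
  ("tandem-embedded") occurrences, QRE classification
  (dual-core / bipartite / core-only / none), and foreground-vs-background
  dual-motif enrichment by Pearson chi-squared (χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))),
  Yates-corrected chi-squared, or Fisher's exact test.
* **Percent unspliced** — per gene and sample, PU = 100·u/(u+s) from raw
  unspliced/spliced counts; treatment-vs-control shifts tested by Student's
  t (significant at p < 0.1 and median-of-ratios base mean > 100); and
  class-level log2-fold-change comparisons (unspliced vs spliced vs
  intronless) by Mann-Whitney U.
* **RAC proteomics scoring** — background-corrected enrichment
  (NSC_RAC − NSC_APT)/NSC_NE per bait substrate, early-spliceosome/17S U2
  (E/U2) inclusion and sign counts, row z-scores with average-linkage
  clustering, and DIA differential analysis with an empirical-Bayes
  moderated t and Benjamini-Hochberg correction (loose |log2FC| > 0.2 /
  strict > 0.7, p < 0.01).
* **Synthetic data** — seeded generators for all four input types with
  planted ground truth (quadrant membership, motif category and offsets,
  percent-unspliced shifts, binder status, log2 fold changes), used by the
  test suite and the end-to-end demo.

## Worked example

Simulate a genome of single-intron contigs with dual ACUAA-like motifs
planted at 18% in a foreground arm (introns whose retention responds to the
perturbation) and 6% in a background arm, extract the final 80 intron
nucleotides, scan, and test enrichment:

```sh
bscomp simulate introns --n-fg 60 --n-bg 150 --seed 2 --out-prefix sim
bscomp windows --genome sim.genome.fa --introns sim.introns.bed \
    --from-up 80 --to-up 1 --out w.fa
bscomp scan --windows w.fa --out scan.tsv
# split scan.tsv into fg.tsv / bg.tsv using sim.truth.json groups, then:
bscomp enrich --fg fg.tsv --bg bg.tsv --out enrich.json
```

which prints

```
wrote 210 windows to w.fa
scanned 210 windows
chi2: statistic=7.024 p=0.008041
```

and writes `enrich.json` with the 2×2 table `[[10, 50], [8, 142]]`: 10 of
60 foreground windows (16.7%) carry two or more ACUAA cores against 8 of
150 (5.3%) in the background, an enrichment the uncorrected chi-squared
test rejects at p ≈ 0.008. The per-window `scan.tsv` lists each window's
core count, hit offsets, half-site offsets and QRE category, which match
the generator's planted truth exactly (the generator rejection-samples
motif-free backgrounds before planting, so scanner truth is exact).

The end-to-end demo simulates all four data types, runs every stage, and
verifies each recovered quantity against planted truth:

```
$ bscomp demo --seed 1 --out demo.json
[PASS] quadrant_counts_recovered: {'planted': {'A_up_B_up': 30, ...}, 'recovered': {'A_up_B_up': 30, ...}}
[PASS] control_sample_size: 1000
[PASS] motif_categories_exact: {'mismatches': 0}
[PASS] pu_planted_recall: {'recall': 1.0}
[PASS] pu_null_fp_rate: {'fp_rate': 0.1}
[PASS] class_l2fc_ordering: {'unspliced': 0.190..., 'spliced': 0.065..., 'intronless': -0.888...}
[PASS] eu2_sign_counts_exact: {'WT': {'n_pos': 18, 'n_neg': 22}, ...}
[PASS] dia_strict_recall: {'recall': 1.0}
all recovery checks passed
```

Reports are deterministic: two runs with the same seed are byte-identical.

## Applying the proteomics scoring to deposited tables

The DDA scoring path (`bscomp rac`) consumes any TSV with `protein_id`,
the `NE`/`WT`/`upDEL`/`dnDEL`/`2xDEL`/`APT` normalized-spectral-count
columns and an E/U2 membership list (`--eu2-list`), so a deposited
supplementary spectral-count table exported to TSV can be scored directly
to reproduce published per-substrate sign counts; see `docs/methods.md`
for the exact inclusion and sign-count rules.

## Layout

```
src/bscomp/
  io_formats.py   FASTA/BED6/GFF3/TSV/JSON readers and writers, coordinate conventions
  coregulation.py quadrant classification and control sampling
  windows.py      strand-resolved 3'ss-proximal window extraction
  motifs.py       IUPAC scanning, QRE categories, 2x2 enrichment tests
  splicing.py     size factors, percent unspliced, class abundance shifts
  proteomics.py   RAC enrichment, sign counts, z-scores/clustering, DIA tests
  simulate.py     seeded generators with planted ground truth
  config.py       run configuration (YAML), every threshold with its default
  demo.py, cli.py end-to-end demo and the `bscomp` command-line interface
```

`docs/methods.md` documents the models, defaults, numerical choices and
known limitations.
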