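# Methods

`bscomp` implements the downstream, bespoke computations of a branch-site
competition analysis: given the outputs of standard splicing quantifiers,
RNA-seq pseudoaligners and proteomics search engines (which are explicitly
out of scope), it classifies co-regulated splicing events, scans intron 3'ss
regions for branch-site-like motifs, quantifies intron retention as percent
unspliced, and scores RNA-affinity-chromatography (RAC) proteomics. Every
stage can be exercised on synthetic data with planted, machine-readable
ground truth.

## Co-regulation quadrants

An alternatively spliced event is characterized per perturbation contrast by
dPSI (change in percent spliced in, percentage points) and MVdPSI95 (the
minimum |dPSI| supported at 95% confidence; > 0 means the confidence
interval excludes zero). Significance within one contrast requires |dPSI| >
10 and MVdPSI95 > 0 — both strict inequalities, mirroring the ">" wording
of the cutoffs. An event is co-regulated by two contrasts when it clears the
dPSI cutoff in **either** contrast and has MVdPSI95 > 0 in **both**; it is
assigned to one of four quadrants by its pair of dPSI signs. An event with
dPSI exactly 0 in a contrast has no sign and is dropped with a log message
(only reachable when the dPSI cutoff is set to 0).

Control events must satisfy, in both contrasts, |dPSI| < 1 and MVdPSI95 ≤ 0
(the unchanged set is defined by "MVdPSI = 0", hence the inclusive
comparison), and have base mean > 100. The reference analysis does not state
how its 1,000 controls were chosen from the eligible pool; we sample
uniformly without replacement with an explicit seed, so the control set is
reproducible.

## 3'ss-proximal windows

Window bounds are distances upstream of the 3' splice site, inclusive on
both ends: position −1 is the last intron nucleotide, and a (60, 20) window
covers −60..−20 (41 nt). Two presets reflect the two study configurations:
(60, 20) for mammalian scans, chosen to include the branch site while
excluding the polypyrimidine tract and 3'ss (an alternative 63-nt upper
bound appears in some descriptions of the same analysis; both are
configurable, neither is silently mixed), and (80, 1) for yeast introns,
read as the final 80 intron nucleotides. Minus-strand windows are
reverse-complemented so sequences always read 5'→3' on the transcript.
Introns shorter than the window are errors unless clipping is requested;
clipped windows record their effective extent. Windows with more than 50%
N are flagged and excluded from enrichment by default.

## Motif scanning and QRE categories

The core motif defaults to the 5-mer ACTAA (DNA alphabet; RNA input is
normalized U→T), with ACTAAC and TACTAAC as named presets. Occurrences are
counted with overlaps because tandem-embedded configurations such as
UACUAACUAAC contain two cores sharing sequence; a dual-core window is one
with ≥ 2 occurrences. A single core accompanied by a YAAY half-site within
20 nt (edge-to-edge gap, either side of the core) is a bipartite
configuration — the SELEX-defined high-affinity Quaking response element.
Half-sites overlapping a core are discarded, since every ACUAAC core
trivially contains a YAAY. Precedence: dual_core > bipartite > core_only >
none.

Enrichment of dual-core windows in a foreground set (e.g. introns whose
retention increases under the perturbation) versus a background set uses
the 2×2 table [dual, not-dual] × [foreground, background]. The default is
the uncorrected Pearson chi-squared (the reference analysis names a
"Chi-squared test" without stating a correction); the Yates-corrected
variant and Fisher's exact test are exposed, and the method used is
recorded in the output. Zero margins are an error for the chi-squared
variants; Fisher returns its exact p.

## Percent unspliced

For a transcriptome annotated as unspliced / spliced / intronless, percent
unspliced for one gene in one sample is 100·u/(u+s) computed from **raw**
counts — a within-library ratio needs no normalization — and is missing
when u+s = 0. Expression filtering follows the DESeq2 convention: size
factors by median-of-ratios (reference = per-transcript geometric mean over
samples, transcripts with any zero excluded), base mean = mean over all
samples of the normalized u+s. A gene's treatment-vs-control shift is
tested with a two-sided pooled-variance Student's t-test on per-sample pu
values (the reference names "Student's t-test" without specifying the
flavor; Welch is available by flag), and called significant when p < 0.1
and base mean > 100. Zero-variance genes have no defined t statistic: p is
reported missing and the gene is excluded from the significant set, logged.

A useful consequence of median-of-ratios worth stating precisely: scaling
one library by c rescales the geometric-mean reference by c^(1/m) (m
samples), so size-factor *ratios* gain exactly c while the normalized
matrix — and hence base mean — rescales globally by c^(1/m). Percent
unspliced, delta-pu and the t-test are exactly invariant.

Class-level abundance shifts are per-transcript L2FC = log2((mean
normalized treatment + 0.5) / (mean normalized control + 0.5)), filtered at
mean TPM > 0.2 when TPM is supplied, compared between classes by two-sided
Mann-Whitney U. Full negative-binomial shrinkage machinery is deliberately
not reimplemented: the claim of interest is the class-level distribution
comparison, so the printed per-transcript effect sizes are a documented,
simpler substitute and class comparisons are treated qualitatively.

## RAC proteomics

DDA arm: background-corrected enrichment relative to nuclear-extract input
is (NSC_substrate − NSC_APT)/NSC_NE per substrate, missing when any needed
value is missing or NSC_NE = 0. Missing is distinct from zero everywhere.
The included set is E/U2 proteins (membership supplied as an input list)
with a positive score in ≥ 1 of the four substrates; per-substrate sign
counts tally strictly positive and strictly negative scores among included
proteins — zeros and missing in neither, which is consistent with
per-substrate totals differing in the reference figures. Heatmap support:
per-row z-scores with sample (n−1) standard deviation, constant rows
dropped; agglomerative clustering with Euclidean distance and average
linkage, missing imputed as 0 with a logged count.

DIA arm: per-replicate log2 intensities, missing never imputed, proteins
with fewer than two usable replicates in a group dropped. The default test
is an empirical-Bayes moderated t: per-protein pooled variances are
squeezed toward a scaled inverse-chi-square prior fitted across proteins by
the method of moments on log variances (trigamma inversion by Newton's
method), and the moderated statistic is referred to a t distribution with
residual-plus-prior degrees of freedom. This mirrors the standard
linear-models-plus-empirical-Bayes proteomics workflow and is the package's
own choice over a per-protein Welch t, which at 3 replicates and realistic
noise has too little power to make threshold-filter memberships meaningful;
a Welch t remains available (`method="welch"`). The moderated p-values are
cross-checked against the reference R implementation (limma::eBayes) in the
test suite. P-values are Benjamini-Hochberg adjusted across tested
proteins; loose/strict flags are |l2fc| > 0.2 / 0.7 with p < 0.01.

## Synthetic data

All generators are pure functions of (parameters, seed). One global seed
expands into fixed per-generator substreams (`SeedSequence` spawn keys), so
adding a generator never perturbs existing outputs.

* **Contrast tables** — co-regulated events get |dPSI| ~ U(15, 35) in both
  contrasts (clear of the 10-point threshold by ≥ 5 points) with signs per
  planted quadrant and MVdPSI95 ~ U(0.5, 5); surplus events are significant
  in one contrast only; null events move < 1 point with MVdPSI95 = 0 and
  base mean ~ U(150, 3000).
* **Intron genomes** — each intron sits on its own contig with random exon
  flanks and strand. Window backgrounds are rejection-sampled until they
  contain neither a core nor a half-site match, motifs are planted
  (dual-core windows are tandem-embedded with probability 0.5, otherwise
  two separated cores; bipartite plants a concrete YAAY instance at a gap
  of 1–20 nt on a random side), and the planted window is re-verified with
  the production scanner — so per-window truth is exact by construction,
  not approximate. Category rates default to 18% dual in the foreground
  arm vs 6% in the background, with 15% bipartite and 25% single-core in
  the remainder (the latter two are this package's choice of plausible
  composition). GC content defaults to 0.4.
* **Count matrices** — per gene, total counts are negative binomial with
  variance μ + φμ² (φ = 0.05), mean 500 scaled by lognormal library
  factors (CV 0.2) and a lognormal gene-level spread (σ = 0.3); the
  unspliced share is a binomial split at the group's true percent
  unspliced (baseline 10%, planted shift +30 points, n = 3 per group).
  This is the standard RNA-seq count model; it emulates depth, dispersion
  and library-size variation but not positional coverage, multimapping or
  annotation error, so passing recovery tests demonstrates the statistics,
  not robustness to quantifier artifacts.
* **Proteomics** — planted substrate binders receive NSC strictly above the
  aptamer background, non-binders strictly below, so enrichment signs equal
  binder status exactly whenever NE > 0; DIA intensities are normal on the
  log2 scale (σ = 0.3) around planted group means (|l2fc| = 1.5 for 24 of
  120 proteins, 3 replicates). Peptide-level noise, shared peptides and
  intensity-dependent missingness are not modeled.

## Problem sizes and numerical choices

The shipped statistical checks use: 1,000 random 60-mers for
scanner-vs-oracle equivalence; 2,260 events (60 co-regulated, 2,000 null)
for quadrant recovery and control sampling; 1,000 null genes and 50 planted
genes for percent-unspliced error rates and power; 200 simulation seeds at
400 introns per arm for motif-enrichment operating characteristics; and 120
proteins for proteomics recovery. These sizes give stable estimates
(binomial standard error ≤ ~2 points on every reported rate) while keeping
a full run around two minutes on one CPU.

Ties and degenerate inputs: boundary events (|dPSI| exactly at a cutoff)
are excluded by the strict inequalities; Mann-Whitney uses scipy's exact
null for small groups without ties and normal approximation with tie
correction otherwise; hierarchical-clustering leaf order is deterministic
given input order (scipy's convention); BH adjustment is the step-up
formula, monotone by construction.

## Known limitations

The package consumes quantifier outputs; PSI estimation, alignment and MS
search are upstream. The L2FC used for class comparisons is a pseudocounted
ratio of normalized means, not a shrunken estimator, so per-transcript
effect sizes are not comparable to shrinkage-based pipelines. The moderated
DIA test assumes a common variance prior across proteins and equal residual
df; proteins with heterogeneous missingness are squeezed within
residual-df strata. Motif truth exactness in simulations relies on
rejection sampling of an 80-nt window; at much higher GC or with very
degenerate patterns rejection may fail, in which case the generator raises
with a suggestion rather than silently degrading truth quality.
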