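# Methods

## Scope and conventions

The package analyses a called 6mA methylome against a genome and its
annotation; it does not call modifications from raw kinetics. All internal
coordinates are 0-based half-open on the forward strand. Strand-aware logic
flips *windows and offsets*, never sequences, except where flank sequence
itself is reported (motif contexts), which is reverse-complemented so that
contexts always read 5′→3′ on the site strand. A site's adenine is at the
stored position: forward-strand `A` for + sites, forward-strand `T` for −
sites; records violating this are rejected on input and counted in a
rejection report. Duplicate records on (chrom, pos, strand) keep the
maximum methylated fraction. The minimum-methylated-fraction filter
defaults to 0 and is an explicit flag (`--min-fraction`); it is applied
with an inclusive boundary (fraction ≥ threshold kept). Genotype-comparison
runs default to 0.1, the standard choice for replicate mutant methylomes;
whether any such filter belongs on a deep single-sample map is left to the
caller rather than guessed.

## Feature geography

Gene models take one transcript per gene (the first mRNA by file order when
several exist, with a warning — no isoform policy is imposed). Introns are
the inter-exon gaps; TSS/TTS are the first/last transcribed base in
transcription order. The promoter is the 2 kb immediately 5′ of the TSS on
the gene strand, clipped at chromosome edges; `Genes*` is gene body ∪
promoter and `Intergenic` is its unstranded genome complement, so Genes*
and Intergenic tile the genome exactly once. All other classes may overlap
one another and are scored independently — per-class twin statistics
(fragment-methylated proportion; 6mA/A density) are only consistent with
non-exclusive accounting. A gene is TE-associated (TEG) when its scope
interval overlaps ≥1 TE by ≥1 bp on half-open intervals; scope defaults to
Genes* with gene-body scope available, since the distinction is real but
underdetermined by the usual phrasing "TE-associated".

## Landscape statistics

Density is 6mA/A: sites divided by adenines of the same strand within the
class intervals; unstranded classes (intergenic, repeats) pool strands.
Class contrasts use the pooled two-proportion z-test, two-sided normal p.
Inter-site intervals are successive position differences within a
chromosome, strands pooled — positional clustering is a regional property —
and never span chromosomes.

Hotspots are maximal runs of ≥10 sites in which every adjacent gap is
strictly <100 bp, strands pooled; the interval spans first to last member
site (half-open). The TE-association test relocates each hotspot to a
uniform random start on its own chromosome, preserving length and allowing
overlaps among relocated hotspots, 1000 permutations by default, with the
one-sided add-one empirical p-value (1 + #{null ≥ observed}) / (n + 1). The
permutation scheme is this package's choice of null; its type-I behaviour
is verified by calibration (uniformly placed hotspots reject at ≤5% + 2 s.e.
at α = 0.05) and its mean against a closed-form overlap probability.

Motif-context statistics count IUPAC motif matches anchored at the
methylated adenine among site contexts, against the fraction of *all*
genomic adenine contexts (both strands) matching the same motif;
enrichment is the ratio. Sites closer than the flank (default 4 bp) to a
chromosome edge are skipped and counted. De novo motif discovery is out of
scope; the default motifs are AGGYV (adenine at index 0) and GAGG (index 1).

## Metagene profiles

Occupancy at a grid point or window offset is the fraction of units (genes
or anchors) carrying a site there, so unsmoothed values are exact rationals
k/n. Gene bodies are consolidated to 1000 points and introns to 200: for
unit length L ≥ grid, uniform sampling (`out[j] = x[⌊(j+0.5)·L/grid⌋]`);
for L < grid, each base is spread to its two nearest grid points by linear
interpolation, preserving the vector sum. Profiles are strand-specific on
the unit's own 5′→3′ axis. Window profiles use transcription-oriented
offsets (positive = downstream in transcription direction); windows
extending past a chromosome edge are dropped and counted. TE profiles are
paired with same-length uniform random regions as a baseline. Smoothing is
LOWESS with span f = 0.05 and zero robustifying iterations — robust
iterations would down-weight exactly the sparse occupancy spikes the
profiles exist to show.

Splice-donor offsets are counted per exon|intron junction on the host gene
strand: offset −1 is the last exonic base, +1 the first intronic base, and
"1–2 bp upstream of the donor site" is reported at offsets −2/−1.
The alternative reading (first two intronic bases) remains directly
readable from the same profile; no conclusion is hard-coded on either.
Per-offset enrichment is count divided by the window mean (default
w = 10 on each side).

## Expression association

Per-gene summaries count sites in the body, promoter, TSS window (−300 to
+100, inclusive ends, transcription-oriented), TTS window (±500), CDS,
introns, UTRs, and in TEs overlapping the gene (TE counts pool strands —
repeats are unstranded). The default strand policy counts gene-strand sites
only (`both` available). Gene classes: Gene+/− (≥1 body site), TSS+/−,
TTS+/−, and the promoter/body partition {None, Promoter, Body, Both}.
TPM replicates are averaged before any analysis. Bins are [0,1], (1,5],
(5,10], (10,∞); "active" means TPM > 1 strictly and "highly expressed"
TPM > 100. Group contrasts are Mann–Whitney rank-sum: exact null
distribution when min(n) ≤ 8 with no ties, normal approximation with tie
correction otherwise; Benjamini–Hochberg adjusted p-values are reported
alongside raw ones across each comparison family. The high/low contrast
reports the relative excess of mean per-gene body site count,
mean(high)/mean(low) − 1.

## Differential methylation

A gene is *marked* in a genotype only if it has ≥1 body site in every
replicate of that genotype; the union of genes marked in ≥1 genotype is the
denominator for shared and state-change fractions (denominators are always
reported explicitly). Gene 6mA level is body 6mA/A on the gene strand,
averaged over replicates; fold change is defined only when the WT level is
positive — a 0 → positive transition is a `from_none` state change, not an
infinite fold change. The global shift is the ratio of mean global
densities minus one, in percent; its one-tailed rank-sum test runs on
per-chromosome densities pooled across replicates by default, because with
two replicates per genotype a rank-sum on whole samples cannot reach
p < 0.05 (`--unit sample` is available). The DEG overlay cross-tabulates
DEG direction against the 6mA fold-change category; DEG calling itself is
upstream (contract: FDR ≤ 0.001, |fold change| > 2).

## Category enrichment

Per COG-style category: methylated-gene fraction against the background of
all genes with a category assignment, one-sided exact binomial p (the
directionality of "enrichment" argues for one-sided; two-sided is
available), BH-adjusted across categories. The cross-category Pearson
correlation of mean gene length with methylated fraction carries the usual
t-test p. The density outlier screen is the two-sided single-outlier Grubbs
test at α = 0.05, critical value from the t-distribution with n−2 df.
DEG-ratio tests are one-sided binomial tests of a subset's DEG fraction
against the overall fraction as p₀.

## Synthetic data generator

The generator emulates the observed landscape of a compact ~30-Mb
chromosome-scale algal genome at roughly 1/15 scale: 20 chromosomes ×
100 kb, 600 genes, i.i.d. uniform bases. Gene models are intron-rich (7–9
exons of 80–130 bp, introns 50–100 bp, 50/80-bp UTRs) — deliberately at
the intron-dense end of the plausible range so that splice-junction
statistics rest on ~4000 junctions and are measurable at this genome size.
Genes are packed greedily with strand-aware 2-kb promoter clearance.
Repeats cover 8% (TE; superfamily mix 60% DNA/CMC-EnSpm, 20% LTR/Gypsy,
10% LINE/L1, 10% DNA/hAT) plus 0.5% each of simple repeats and
low-complexity runs.

Each adenine (either strand) gets a multiplicative relative hazard:
×10 in AGGYV contexts, a linear 0.5→1.5 5′→3′ ramp over gene bodies, a
Gaussian TTS bump (height ×5, sd 150 bp), ×6 at donor offsets −2/−1, and
×5 inside TEs. `base_rate` (default 0.001, i.e. 0.1% 6mA/A) is the target
*global* density: hazards are normalized so the expected site count —
including the hotspot sites planted next — equals base_rate × #adenines,
with per-site probabilities capped at 1 (a warning fires if >1% of
adenines cap). Sites are independent Bernoulli draws per strand; methylated
fractions are Uniform(0.1, 0.8) and coverages Poisson(100). Hotspots
(default 5 runs of 20 sites, spacing 40–80 bp) are planted afterwards at
well-separated intergenic loci so their ground-truth intervals are exact
and they cannot distort the gene-anchored profiles. Expression follows
log2(TPM+1) = 3.0 + 0.5 × body-site-count + N(0, 2.0), truncated at zero,
three i.i.d. replicates.

Mutants: the demethylase-KO model keeps all WT sites and adds new draws at
(factor − 1)× the calibrated hazard (default factor 1.213) — a lost eraser
accumulates marks on the WT pattern, and at this genome size the additive
form gives the global shift a sampling s.d. of ~2 percentage points where
an independent redraw would have ~5. The methylase-KO model removes each
gene's body sites with the configured probability and redraws the
remaining genes' sites from the hazard, producing marked/unmarked churn.
Replicates (default 2 per genotype) are independent Bernoulli thinnings at
95% retention. All randomness flows from one seed through fixed-offset
child seeds, so stages are independently reproducible and outputs are
byte-identical across reruns.

What the generator does **not** emulate: realistic sequence composition
(GC skew, codon structure, splice-site consensus), repeat sequence
similarity, kinetic-signal noise or coverage-dependent miscalls,
correlated methylation between neighbouring adenines outside planted
hotspots, hotspot–TE coupling, isoform diversity, and replicate batch
effects beyond thinning. Tests passing on synthetic data therefore
demonstrate the correctness of the computations and the recoverability of
planted effects at desk scale, not caller-level robustness on real SMRT
data.

## Numerical and scale choices

Default analysis sizes (the 2-Mb default dataset, 1000 permutations, 200
calibration trials, LOWESS over 1000–2000-point vectors) keep a full
pipeline run in seconds on one CPU. Degenerate inputs are contracts, not
crashes: empty hotspot sets write header-only tables; classes with zero
adenines report an absent density; genes without introns are skipped by
donor profiling; empty expression strata skip the high/low contrast with a
warning. Hard errors are reserved for malformed records, unknown
chromosomes, infeasible packing, and empty required inputs. Exactness is
preferred where attainable: exact binomial tails, exact small-sample
rank-sum, add-one permutation p-values (never zero), and occupancy values
that are exact unit fractions before smoothing.

## Known limitations

Per-site methylated fractions are carried through I/O but not modelled —
site presence is binary in all statistics, matching the fragment and
density definitions. One transcript per gene. The hotspot definition reads
the run rule literally (≥ for the count, strict < for the gap); a
`--stranded-hotspots` variant exists because strand pooling, while the
natural reading for regional clusters, is not the only one. The TE
permutation preserves hotspot lengths and chromosome assignment but not
inter-hotspot spacing. COG assignments are an input table; no annotation
pipeline is bundled.
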