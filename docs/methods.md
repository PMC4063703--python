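# Methods

This note documents the statistical procedures `termsig` implements, the
choices made where a procedure admits more than one reasonable reading, and
what the bundled simulator does and does not emulate.

## Coordinates and gene models

Internally all intervals are 0-based half-open; GFF3 I/O converts at the
boundary (GFF3 is 1-based inclusive).  Every base-pair distance the package
reports is therefore a convention-independent integer: abutting features
have distance 0, overlapping features a negative distance equal to minus
the overlap length.  One model per gene (no isoforms): an ORF, optional
5'/3' UTRs abutting it, and the span as their union.  Genes without an
annotated 3'UTR stay in the expression analyses (via the ORF/span) but are
excluded from the read-through universe and from UTR-based distances.

### Neighbour definitions

* *Upstream same-strand neighbour*: the nearest gene on the same strand
  whose 3' end lies 5' of the focal gene's 5' end, orientation-aware (for a
  minus-strand gene "upstream" means larger coordinates).  Opposite-strand
  genes lying between the pair are ignored by default; a flag
  (`allow_intervening_antisense=False`) suppresses the pairing instead,
  since either reading of "directly upstream" is defensible.  Ties resolve
  to the lexicographically smaller gene id.
* *First downstream reverse-orientation gene*: among opposite-strand genes
  whose span extends past the focal gene's 3' end, the one with the nearest
  facing boundary.  Convergent overlapping partners qualify and give a
  negative distance.
* *Antisense coverage*: bases of the focal span covered by the union (not
  the sum) of opposite-strand gene spans; F_as divides by span length.

## Signal model and summarization

Tracks are linear-scale, background-corrected intensities, one per
(genotype x replicate x strand).  Quantile normalization maps every track's
value multiset to the across-track mean of order statistics; tied values
receive the mean of their tied quantile values, which preserves ranks and
makes the operation idempotent.  A floor of 1e-6 is applied afterwards so
that every downstream ratio is defined.  Note the textbook caveat: with
ties present, a track's post-normalization multiset can deviate from the
shared reference at the tied entries; on continuous array data ties do not
occur and all sorted track vectors are exactly equal.

Probes belong to a region when their midpoint falls inside it (half-open).
Gene expression is the median of in-span probes per replicate, averaged
over replicates, on the gene's own strand.  The read-through index uses the
mean (not median) of in-region probes — the natural reading of "average
signal" for a short region with few probes — per replicate, then averages
the per-replicate UTR/ORF ratios; the median is available as an option.

## Differential expression

The signed fold change is mut/wt when mut >= wt, else -(wt/mut), so |FC|
is always >= 1 and the under-expression threshold reads FC <= -1.9.
Significance comes from a t-test on log2 per-replicate gene values.  The
default is Student's (equal-variance) t: the two genotypes are hybridized
and summarized identically, and at n = 3 per group the equal-variance test
is the one whose type-I error matches its nominal level (Monte Carlo size
0.010 at alpha = 0.01, versus ~0.0055 for Welch, whose Satterthwaite
degrees of freedom are conservative at such small n).  Welch and a
Wilcoxon rank-sum variant are selectable.  Calls: *under* if
FC <= -threshold and p < alpha, *over* if FC >= +threshold and p < alpha
(fold thresholds inclusive, significance strict); defaults 1.9 and 0.01.
No multiple-testing correction by default — calls are FC-gated raw-p, the
convention for triplicate arrays — with Benjamini-Hochberg behind a flag.

## Read-through calls

A gene with an annotated 3'UTR is flagged gTERM when the mutant/wild-type
ratio of UTR/ORF ratios is >= 1.5 ("at least 1.5 greater" is read as
inclusive) AND its coding region shows no differential-expression call
(the DE machinery run on ORF intervals with the same thresholds).  The ORF
gate can alternatively be a |log2 FC| cap.  No minimum UTR signal or
minimum mutant ratio is required — no such gate is part of the procedure —
so very low-signal genes are controlled only by the intensity floor.

## Empirical nulls and rank tests

The permutation test compares the median of a quantity over a flagged gene
set with medians of `n` random same-size sets drawn (without replacement
within a set, independently across sets) from the universe of genes where
the quantity is defined.  Ties count toward both exceedance sides
(conservative).  Sampled mode stores add-one p-values, p = (k+1)/(n+1),
which cannot be zero; when k = 0 the result additionally carries the
bound-style report "< 1/n" (e.g. "< 1/10,000").  Exhaustive mode
enumerates all subsets (guarded to <= 10^6) and stores the exact
enumeration probability k/n; the observed set is itself one of the
enumerated subsets, so its own side has k >= 1.  Sampling is vectorized
(each row of uniform keys yields one subset via partial argsort) and
bit-reproducible given a seed.

The Wilcoxon departure-from-zero test drops zeros, then uses an exact null
for n <= 25: the sign-flip distribution is convolved over doubled midranks,
so ties in |x| are handled exactly; beyond 25 a tie-corrected normal
approximation (scipy) is used.  The Mann-Whitney rank-sum comparison is
exact when the smaller group has <= 8 observations — scipy's exact network
distribution when tie-free, direct group-assignment enumeration when ties
are present — and asymptotic with tie correction otherwise; `method="exact"`
forces the exact null regardless of size (within an enumeration guard).
Both exact paths use the two-sided convention p = min(1, 2 min(P<=, P>=)).
The KS comparison of a set's F_as values against the pooled values of the
random null sets uses the asymptotic two-sample test.

## AP-MS dependency inference

Unique-peptide counts are keyed by (bait, background, prey).  Preys with
>= 1 peptide in the no-tag control purification are discarded everywhere
(idempotent).  A prey *requires* gene g for association with a bait when it
has >= `min_peptides` (default 2 — one peptide is weak evidence) unique
peptides in the wild-type purification and 0 in the gΔ background;
"absent", not "reduced", because the phenomenon modelled is dissociation.
A fold-drop alternative (count_del <= count_wt / r) is available.  The
deleted gene's own protein is never an edge source for its own deletion.
Module candidates are connected components (>= 2 proteins) of the mutual
dependency graph (a requires b AND b requires a, matching deletion labels
to prey names case-insensitively, ignoring dots and delta suffixes).

## The synthetic-data generator

The generator realizes, with known labels, exactly the structures the
statistics assume: per chromosome a chain of non-overlapping same-strand
genes with UTRs (strand alternates per chromosome so both orientations are
exercised), into which it plants (i) convergent overlapping partners
(`*_rv` genes, overlap 50-250 bp), (ii) a set of genes with deliberately
short upstream gaps (5-40 bp versus the ordinary 150-700 bp), and (iii)
genes exactly covered by an antisense gene (`*_as`, F_as = 1).

Signal per probe is 2^(gene baseline + probe affinity + effect + noise):
gene baselines ~ N(9, 1) log2, a fixed per-probe affinity ~ N(0, 0.5)
shared by all arrays, background probes ~ N(6, 1.5), and per-array noise
~ N(0, 0.1) log2 by default.  The fixed affinity/background terms emulate
sequence-dependent hybridization efficiency; they cancel exactly from fold
changes and UTR/ORF ratios but make the intensity distribution continuous,
which is the regime quantile normalization assumes (without them the
distribution is bimodal with an empty gap, and rank-mapping across the gap
attenuates injected folds — a QN artifact of unrealistic input, not a
property of the method).  Effects: +-log2(3) over the whole span for DE
genes, +log2(3) on 3'UTR probes only for read-through genes, mutant
genotype only; in the noise-free limit both are recovered exactly.
Defaults describe a compact fission-yeast-like study: 3 chromosomes, 500
genes, 20 bp probe spacing, triplicates, 47 short-gap genes, 50
read-through genes, 20 + 10 DE genes.

What the simulator does **not** emulate: probe cross-hybridization and GC
affinity structure, RMA-style background (signal is generated
background-free; a pass-through hook accepts pre-corrected data),
transcript isoforms, snoRNA-specific termination, and — deliberately — any
coupling between the injected read-through set and the convergent-pair
structure, or between the DE set and the short-gap set.  Passing recovery
tests therefore show that the statistics recover the effects they define
under realistic array noise, not that real termination defects are this
cleanly separable; on real data the gates (ORF unchanged, annotated 3'UTR)
and the context statistics carry the inferential weight.

## Problem sizes and numerical choices

The test suite and acceptance script run the study defaults: 500-gene
genomes across 10 seeds for read-through recovery, a 2,000-gene null study
for DE calibration, 10,000-set permutation nulls, 50,000-draw sampled-vs-
exhaustive comparisons on 10-gene universes, and 200 random cases per
exact rank test; these sizes give stable estimates while keeping a full
run in well under a minute per block.  Degenerate inputs are handled
explicitly: all-zero vectors give p = 1 with a warning; zero-variance
t-tests give p = 1 ("unchanged"); regions without probes yield flagged
missing values (NaN) and exclusion, never exceptions; empty flagged sets
skip their context tests.  Floats written to TSV use %.17g and are parsed
round-trip, so staged CLI invocations are byte-identical to the combined
pipeline.

## Known limitations

Single-isoform gene models; mean-based region summaries are sensitive to
within-UTR probe outliers (median option available); the permutation
universe treats genes as exchangeable (no matching on length or
expression); the rank-sum exact mode refuses tied inputs too large to
enumerate; and the co-purification module logic is presence/absence —
quantitative dissociation (partial loss) requires the fold-drop rule.
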