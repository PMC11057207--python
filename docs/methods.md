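# Methods

This note records the models, conventions and design choices behind each
analysis stage, what the synthetic data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Coordinates and formats

All internal coordinates are 0-based half-open, so `len = end − start`
with no exceptions; GFF3 and VCF 1-based inclusive coordinates are
converted only at the I/O boundary (`sexchrom.io`). Region labels
(PAR1, oldSLR, newSLR, PAR2, autosome) are a closed vocabulary assigned
through a `RegionMap`; lookups return exactly one label or "unlabeled".

## Fixed sex-linked variants

A site qualifies when every male is heterozygous and every female is
homozygous for one shared allele. Sites are pre-filtered to biallelic
calls with genotype quality strictly greater than 30 (a call at GQ = 30
is set missing). Any missing call among the focal samples makes the site
ineligible: the pattern is defined over *all* individuals of each sex,
and a site that cannot be verified in all of them is excluded rather than
scored on the remainder. ZW systems are supported by a flag that swaps
the sex roles. Percentages in the assignment summary are rounded
half-up to one decimal and always carry an explicit denominator, because
concordance fractions are routinely quoted against either the full or the
mapped variant set and the two differ.

The sex-linked span on a chromosome is the smallest interval containing
at least 99 % of its fixed sex-variants (robust to isolated mismapped
variants), snapped outward to gene boundaries. Tips with at least 20
consecutive variant-free genes are flagged as pseudoautosomal candidates.
The 99 % core and 20-gene flank are tunable; no principled value exists,
so both are exposed and defaulted to values that tolerate ~1 % mismapping
without truncating a real span.

Coverage validation normalizes each sample by its autosomal median
depth. A region is flagged Y-linked when the female/male normalized
ratio falls below 0.1, and hemizygous when the male normalized depth
falls in [0.35, 0.65]. These thresholds encode qualitative expectations
(females carry no Y; males carry one copy of each sex-linked region);
the band is wide because 10–20 % depth noise is typical. Note that
pseudoautosomal regions assembled in both haplotypes also show ~0.5×
male depth in a merged reference, since reads split between the two
copies — the female/male ratio (≈ 1 on PARs, ≈ 2 on the X-SLR, ≪ 1 on
the Y) is what separates the cases.

## Gene-loss triangulation and classification

Candidates are orthogroups with a syntenic, array-representative member
in the outgroup and the non-focal haplotype but no member in the focal
assembly. Orthogroups with any nonsyntenic or non-representative member
are excluded up front, because movement and tandem-array ambiguity
confound presence/absence calls.

Classification uses the candidate transcript's hits against the focal
genome. The top hit is selected by percent identity with deterministic
tie-breaks (larger query coverage, then smaller subject start). A
candidate is *present* only when the top hit lies on the corresponding
chromosome (an explicit source-chromosome → focal-chromosome-set map,
since X↔Y correspondence can be many-to-many after fusions) **and**
covers at least half the query; exactly 0.5 counts as present, reading
"less than 50 %" strictly. Secondary hits on the corresponding
chromosome never rescue presence when the top hit is elsewhere; they are
used only to separate partial from full loss. A candidate absent from
the hit table is fully lost (logged).

Per-region proportions are lost/(lost + present) over all triangulable
genes; the autosomal proportion is treated as a baseline for
presence–absence polymorphism and technical error, and the excess over
that baseline is reported alongside the raw proportion. Windowed
profiles use non-overlapping 20-gene windows in either the X order or
the outgroup order (the outgroup order approximating the ancestral
arrangement); the trailing remainder window is kept but flagged so edge
effects are visible yet excludable.

## Synonymous divergence (NG86)

The estimator is the Nei–Gojobori (1986) counting method. Synonymous
site counts are fractional — each codon position contributes
(synonymous single changes)/3, with changes creating a stop codon
counted as nonsynonymous — and are averaged over the two sequences.
Multi-difference codons average their synonymous/nonsynonymous step
counts over all orderings of the differing positions; pathways passing
through a stop codon are excluded unless every pathway does. The
Jukes–Cantor correction Ks = −¾ ln(1 − 4·ps/3) is undefined at
ps ≥ 3/4 and reported as such rather than clamped. Codons containing
gaps or ambiguity codes are dropped pairwise; only the standard genetic
code is supported. A counting method was chosen over maximum-likelihood
codon models because the pipeline's Ks consumers (window medians, a
young/old dichotomy at 0.03) need rank stability, not branch-model
accuracy; the estimator choice is recorded in output metadata.

Sliding windows use 100 genes with step 1 by default, genes with
Ks ≥ 0.2 excluded first; the window "center" is the median x-position
of its members (a documented convention — the mean or the midpoint of
the span would also be defensible). Even-sized medians are the mean of
the middle two values.

The strata test counts young (Ks strictly below 0.03) versus old
(strictly above) genes by ancestral origin chromosome and applies a
Pearson chi-square with df = 1 and no continuity correction (a flag
enables it; the choice is logged because published statistics rarely say
which was used). Genes with Ks exactly at the threshold fall in neither
class and are excluded with a logged count.

## TE statistics

Window occupancy and near-gene proximity merge overlapping TE intervals
before measuring coverage (the quantity is "fraction occupied");
per-region repeat ratios sum clipped lengths without merging (the
quantity is repeat load, and nesting legitimately pushes it above 1).
This merged-versus-summed split is deliberate and mirrored in the tests.
Upstream/downstream 1-kb flanks are strand-aware and clipped at
chromosome ends with the denominator adjusted; introns are the exon
complement within the gene body; per-region means weight genes equally,
never by length. Family clustering implements the 80–80–80 rule with
single-linkage components (the field's family semantics; complete
linkage is available behind a flag), coverage denominator the shorter
sequence of the pair. The X/Y copy chi-square takes expectation
proportional to region lengths in bp — the defensible null when the
compared regions differ in size.

## Anchor chaining and inversions

Anchors are gene pairs with ordinal ranks per chromosome. Chaining
grows maximal runs with monotone B-ranks (increasing = same orientation,
decreasing = reversed), allowing rank gaps up to 5 in both genomes and
discarding runs shorter than 3 anchors; blocks partition the retained
anchors. These defaults were tuned on simulated fixtures and are
exposed in configuration. A reversed block is called a heterozygous
inversion when every existing neighbour block on the chromosome pair is
same-orientation (chromosome ends count as context). Orientation alone
cannot distinguish an inversion from a translocation-with-reversal
within a chromosome; this is a known limitation, logged rather than
modelled.

## The synthetic trio generator

The generator emulates the statistical structure the analyses assume,
at roughly 1/1000 the scale of a real ~1.5 Gb genome so a full run takes
under a second: a 720-kb sex chromosome (PAR1 60 kb, old SLR 300 kb with
2,000 genes, new SLR 300 kb, PAR2 60 kb) and two autosomes, in three
genomes (X-haplotype, Y-haplotype, outgroup). Defaults are the study
conditions the pipeline is meant to recover: 30 % Y loss on the old SLR
with 38 % of losses partial, a 4 % baseline loss elsewhere (a realistic
allowance for presence–absence polymorphism and annotation error, so
that excess-over-baseline is a meaningful quantity), a 2 % annotation
miss rate (genes present in the genome but absent from the annotation,
exercising the "present" classification path), 6 males and 6 females
with 50 fixed sex-linked and 450 autosomal Hardy–Weinberg sites
(female-homozygous-reference probability 0.993), TE totals targeted at
3× on the old Y, 1.09× on the new X and 1.02× on the A-haplotype PARs,
near-gene TE insertion probabilities 3× higher on the old Y than the
old X (background scatter is compensated so the *total* region counts
still hit the multipliers), an old-SLR Ks mixture (45 % young below
0.03, 50 % between 0.03 and 0.2, 5 % tail above 0.2, identical on both
ancestral origin scaffolds) with Ks ≈ 0 elsewhere, and planted
inversions: 4 covering 31 % of the new SLR and 2 per autosome covering
10 %. Inversions are realized by reversing gene-index runs, so they
appear to the caller exactly as reversed anchor runs; planted fractions
are measured midpoint-to-midpoint, the same convention the anchor-based
caller sees, making ±2 % recovery checks fair.

Partial losses draw hit coverage strictly below 0.5 so truth labels are
unambiguous at the classifier boundary; fully lost genes either have no
hit or a spurious off-chromosome hit (both paths exercised). Gene
"sequences" for Ks work are codon strings built from 4-fold degenerate
codons and diverged by third-position changes, which makes the achieved
ps exact and the target Ks recoverable to rounding; hit tables are
emitted directly rather than produced by a search tool, because the
pipeline consumes tables.

What the generator does **not** emulate: linkage disequilibrium and
realistic allele-frequency spectra (autosomal sites are independent
Hardy–Weinberg draws), sequencing error in genotypes (GQ is uniformly
high; filter behaviour is tested with dedicated fixtures), mapping
artefacts, nested/fragmented TE annotations beyond random overlap,
gene-order evolution other than the planted inversions, and any
population-genetic dynamics of degeneration (losses are independent
Bernoulli draws, not a forward process). Passing tests therefore show
that the statistics recover what they define on data meeting their
assumptions — not that those assumptions hold in any particular real
dataset.

All stochastic draws flow from one seeded `numpy` generator; identical
configurations produce byte-identical emitted fixtures (checksummed in a
manifest). The pipeline derives per-stage child seeds from the top seed
by hashing, so stages can be rerun in isolation.

## Problem sizes and determinism

Default test and acceptance runs use the scaled genome above: 2,980 annotated genes on the X
haplotype, ~11,000 TEs, 500 variant sites, ~1,900
anchors, 400 coverage windows, 1,000-replicate null calibration of the
strata test, and 100 random 300-codon pairs for estimator/oracle
agreement. These sizes keep the full suite under half a minute while
leaving every recovery check enough statistical resolution (binomial
99 % intervals at n = 2,000; ±0.3 on a ratio estimated from ~4,400
Poisson counts).

## Known limitations

- The fixed-variant scan is exact for the pattern it defines; truly
  sex-linked sites with even one genotyping error or missing call are
  not recovered (no fuzzy matching), which is conservative.
- Chance Hardy–Weinberg sites can match the all-het/all-hom pattern
  (probability ≈ (2pq)⁶(p¹² + q¹²) per site); with 12 samples this is
  rare but nonzero, and precision below 1.0 on simulated data reflects
  it honestly.
- The Ks estimator ignores transition/transversion bias and codon usage
  (NG86 assumptions); absolute values at high divergence are
  underestimates, though the young/old dichotomy at 0.03 is robust.
- Inversion calls require at least 3 anchors; inversions smaller than
  the local anchor spacing are invisible.
- `cluster_families` is O(n²) in the number of elements and is meant
  for exemplar sequences, not full-genome TE complements.
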