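# Methods

This note documents the statistical procedures, sequence-comparison
conventions, simulator design and numerical choices behind
`prophagekit`, and what the test battery does and does not demonstrate.

## Catalog model and filtering

A catalog is a host table (one row per replicon; taxonomy phylum →
class → order → family → genus, genus mandatory) plus a prophage table
(1-based inclusive coordinates on a named replicon, predictor confidence
category, plasmid flag). Validation enforces coordinate bounds and
taxonomic *nestedness* — a genus name may not appear under two different
families, and so on up the ranks — because every downstream host-range
and enrichment computation silently assumes it.

Filtering keeps predictions with category ∈ {1, 2} (the predictor's
high-confidence classes), on replicons ≥ 10 kb, and without a plasmid
tag. All three cutoffs are parameters; the defaults reflect common
practice for prophage mining from complete genomes. The filter is
idempotent and monotone in its thresholds (property-tested).

Summary statistics use **lysogens** (hosts with ≥ 1 retained prophage)
as the denominator of the mean; a per-all-genomes variant is an option.
The per-lysogen count mode resolves ties to the smallest count, and the
coefficient of variation uses the sample standard deviation (ddof = 1),
both for deterministic, conventional output. The length histogram
reports the two highest local maxima (plateau-tolerant) rather than a
formal bimodality test — prophage length distributions typically show a
short (~30 kb) and a long (~70 kb) population and the modal bins make
that visible without extra assumptions.

## Enrichment testing

All group comparisons are one-sided Wilcoxon rank-sum tests
(H1: the focal group's per-genome counts are larger). Prophage counts
are small integers, so ties dominate; the implementation uses mid-ranks
throughout and switches regimes:

* both groups ≤ 8 observations → exact permutation enumeration over all
  C(n+m, n) assignments of the pooled mid-ranks (agrees with brute-force
  enumeration by construction and by test);
* otherwise → the tie-corrected normal approximation, *without*
  continuity correction. Under the exchangeable null this choice holds
  the empirical type-I rate near the nominal α (0.05 ± 0.02 at desk
  scale, verified in the acceptance suite); adding continuity correction
  makes the heavily tied test conservative.

Per rank, every taxon with ≥ 5 genomes is tested against the background;
the background **excludes the focal taxon's genomes** by default (an
`'all'` option includes them). Rationale: comparing a group against a
pool containing itself dilutes the very signal under test; exclusion is
standard enrichment practice. Bonferroni correction multiplies by the
number of taxa actually tested at that rank.

Two database-imbalance guards:

* **cap rule** — taxa with more than `cap_trigger` (50) genomes are
  first downsampled to `cap_sample` (10) genomes, deterministically
  under the run seed;
* **bootstrap** — per iteration, draw `n_genomes` (10) genomes *without
  replacement* from every eligible genus (≥ 50 genomes by default), test
  each genus against the pooled remainder of that iteration's sample,
  and record p; 100 iterations give the per-genus p-value distribution.
  Sampling without replacement matches the subsampling character of the
  scheme (each iteration is a balanced sub-catalog, not a resample).
  Iterations use independent, named substreams of the master seed, so
  any single iteration is reproducible in isolation.

## Pathogen classification and LOO

Biosample free text cannot be curated reproducibly by hand, so the
pathogen rule is an explicit keyword engine over six fields (general
description, isolation source, isolation site, host, environmental
medium, sample type), scanned in fixed order; the first match is
recorded as the trigger. The shipped keyword list ("pathogen",
"patient with", "diseased", "infection", "lesion", "clinical isolate")
is a documented approximation of disease-association phrasing and is
configuration, not code. Genera with more than 100 genomes are capped by
uniform subsampling before the group comparison.

The LOO sweep recomputes the pathogen-vs-unassigned test with one genus
removed at a time; a removal that empties either group yields an
explicit undefined result. The shared-genus table tests only genera
present in both groups and Bonferroni-corrects by the number of shared
genera — that is the family of tests actually performed.

## Sequence comparison conventions

The delegating tools in this space do not state their denominators, so
the package fixes them explicitly:

* **identity** = matches / aligned columns, internal gaps counted,
  terminal gaps excluded (alignments are local);
* **coverage** = aligned span of the *shorter* sequence / its length;
* nucleotide scoring 2 / −3, gap open 5, gap extend 2 (a length-k gap
  costs 5 + 2k); protein scoring BLOSUM62, gap 11 / 1.

Nucleotide pairs whose length product is ≤ 4·10⁶ are aligned with an
exact affine-gap Smith-Waterman; longer pairs go through `blastn -task
blastn` with identical scoring, taking the best HSP. The exact path is
tested against a quadratic-space textbook DP oracle; on ≥ 90 %-identical
long sequences the heuristic's best HSP realizes the same full-length
alignment.

ANI follows the classic fragment recipe: chop the query into
non-overlapping 1 kb windows, align each to the subject, keep fragments
with identity ≥ 30 % and fragment coverage ≥ 70 %, and average the kept
identities (undefined if none pass). Fragment thresholds are
configuration.

ORF calling is deliberately simple and stated: all six frames, first ATG
after each in-frame stop through that stop, ≥ 33 aa, translation table
11 (GTG/TTG starts available by option). A dedicated gene finder would
differ at the margins; AAI values therefore carry this method caveat.

Reciprocal best hits use exact protein Smith-Waterman for every pair
that shares at least one 4-residue word (a seed-and-extend screen; pairs
passing the 30 % identity / 70 % coverage homology filters essentially
always share many such words, while unrelated short ORFs rarely share
one). Best hits are by score, ties broken by higher identity then
lexicographic ORF id, making the pairing deterministic and symmetric.
AAI = 100 × mean RBH identity; it is computed on cluster representatives
(the dereplicated set) by default.

## Viral clustering and host range

Clustering is greedy and representative-based (cd-hit semantics):
sequences in order of decreasing length (ties by id) join the first
cluster whose representative they match at ≥ 90 % identity and ≥ 80 %
coverage, else found a new cluster. A sampled 15-mer containment screen
(threshold 0.02) skips alignments against unrelated representatives; at
90 % identity ~21 % of 15-mers survive, two orders of magnitude above
the screen. Membership evidence (the member-vs-representative alignment
stats) is stored and re-verifiable.

Host range of a cluster = the highest rank at which member host lineages
differ, named by the level *below* it: hosts in different genera of one
family → "genus", different families of one order → "family", …,
different phyla → "phylum"; "same-genus" when all members share the
genus. The headline narrow-host-range fraction is the fraction of
clusters that are same-genus; a member-weighted variant is reported
alongside because both readings are defensible.

## AAI network and co-structure

Edges with AAI ≥ 80 (a conventional genus-level relatedness threshold
for phages) form the network; per-rank "differ-at" edge fractions are
non-increasing from genus to phylum under nested taxonomy (a theorem,
and a property test). A node-level variant (fraction of prophages with
≥ 1 cross-rank edge) is available since an edge-based and a node-based
reading of such fractions are both in circulation; the edge fraction is
the default.

ANI-vs-AAI co-structure clusters the host 1−ANI and prophage 1−AAI
matrices (average linkage, cut heights 0.05 and 0.20 by default) and
scores congruence as the fraction of prophage pairs whose AAI-cluster
comembership matches their hosts' ANI-cluster comembership. The
permutation behavior (shuffled phage-host assignment → congruence drops
toward chance) is what elevates the visual heat-map comparison into a
testable statistic.

## k-mer usage bias

B(w) = f_obs(w)/f_exp(w) on overlapping windows (windows containing
non-ACGT symbols are skipped and the denominator reduced). Two
expectation models are implemented because the sub-k-mer composition
rule is stated ambiguously in the literature this follows:

* `markov_max` (default): f_exp(w) = Π f((k−1)-subwords) / Π f(interior
  (k−2)-subwords) — the maximal-order Markov / contrast-word statistic;
* `literal_product`: the plain product of (k−1)-subword frequencies.

They coincide exactly at k = 2 (both reduce to f(x)·f(y)), which is
where the di-/tri-nucleotide analyses operate; k = 1 stores raw
frequencies (no sub-k-mers exist). Counting is single-strand by default
(prophages are extracted in reported orientation) with a both-strand
option, under which bias profiles are reverse-complement invariant.
K-mers with zero expectation are reported as undefined rather than
dropped. Distances are Euclidean over the shared defined log-biases;
co-clustering is average-linkage, and per-phage host rankings sort
candidate hosts by ascending distance.

Calibration: on a 100 kb i.i.d. sequence the binomial standard error of
B(w) near 1 is ≈ √(4ᵏ/L) — about 0.6 % at k = 2 but ≈ 5 % at k = 4 — so
the "all biases within ±0.05" check is asserted at k = 2 and as a
5-standard-error bound at k = 3, 4, where ±0.05 is statistically
unattainable at this length.

## Synthetic data: what it emulates, and what not

The generator plants exactly the structure the analyses are supposed to
recover, under one master seed with named substreams (byte-identical
reruns):

* taxonomy: a balanced phylum/order/family/genus tree, nested by
  construction;
* genome sizes: log-normal around 4 Mb, clipped to 1–10 Mb;
* counts: negative binomial (mean 2, dispersion 1) per genome; planted
  genera get a fold-multiplied mean, pathogen-labelled genomes a 1.5×
  multiplier, pathogen fraction 0.3 — values chosen once as realistic
  study conditions;
* lengths: 0.7·N(30 kb, 5 kb²) + 0.3·N(70 kb, 10 kb²), floored at 5 kb;
* predictor noise: categories drawn 0.6/0.3/0.1, 3 % plasmid flags, 10 %
  of genomes carry a small extra replicon — exercising every filter;
* sequence families: a family ancestor plus members carrying exactly
  round(d·L) substitutions (always to a different base), so
  member-to-ancestor identity is 1−d analytically and member-to-member
  identity ≈ 1−2d(1−d); substitution-only by default (indels optional)
  to keep identities oracle-predictable;
* composition: each phylum owns a random order-1 Markov (dinucleotide)
  transition matrix; host windows descend from the phylum ancestor via a
  genus (15 %) and genome (2 %) mutation ladder, giving within-genus ANI
  structure; prophage sequences are emitted from the transition mixture
  w·host-clade + (1−w)·phage-background with w = 0.8 by default — the
  planted, tunable signal the k-mer stage recovers (w = 0 yields
  chance-level host assignment);
* Biosample text: pathogen rows contain at least one trigger phrase,
  unassigned rows none, by construction.

What the simulator does **not** emulate: real gene content and operon
structure (ORFs in simulated sequences are random short ORFs),
attachment sites, GC skew, horizontal transfer between families,
incomplete or misassembled genomes, and the real correlation structure
of public databases. Passing tests therefore demonstrate that the
*procedures* are implemented correctly and are well-calibrated under
stated models — not that any biological conclusion transfers to a
particular real dataset.

## Problem sizes and determinism

Test and demo scales are chosen for single-CPU desk runs: enrichment and
bootstrap calibration at 20 genera × 20–30 genomes (the bootstrap
p-matrix is 20 × 100), cluster recovery at 2 families × 10 members of
~30 kb, AAI recovery on proteomes of ~10 proteins, k-mer calibration at
100 kb. With negative-binomial dispersion 1 the planted-genus signal is
strong but stochastic draw to draw; tests pin seeds, and the
planted-recovery battery is a fixed-seed regression of a
high-probability event rather than a claim of certain detection.

All pipeline randomness flows from one master seed through named
substreams (`SeedSequence([seed, stream, …])`); reruns with identical
config and inputs are byte-identical, which is also how the "rerun is a
no-op" guarantee is delivered.

## Known limitations

* The keyword pathogen rule inherits every limitation of free-text
  metadata; its unassigned group certainly contains unlabelled
  pathogens.
* blastn's best-HSP statistics are a heuristic stand-in for the exact
  optimum on long, highly diverged pairs; at the 90 %/80 % clustering
  operating point the discrepancy is negligible, far below threshold it
  is not quantified.
* The ORF caller is not a gene finder; AAI magnitudes depend on it.
* The 4-residue-word RBH screen can miss homolog pairs very near the
  30 % identity floor (weak-signal pairs with no exact 4-mer run);
  AAI ≥ 80 network edges are unaffected.
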