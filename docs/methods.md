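# Methods

This note documents the models and procedures `scatdiet` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that were genuinely
open.

## The assay being modelled

A scat contains DNA from everything the predator recently ate, plus its
parasites, gut microbiota and environmental contaminants.  A universal
eukaryote primer pair amplifies a ~140–170 bp fragment of the 3′ end of
the nuclear small-subunit ribosomal RNA gene (SSU rDNA); a 3′-blocked
oligo suppresses amplification of tetrapod (i.e. predator) DNA.  Each
PCR uses fusion primers carrying a 10 nt sample tag between the
sequencer adapter and the universal primer — one of six forward and one
of eight reverse tags — so up to 48 scats share a sequencing run and
reads are assigned back to scats by their tag pair.  The pipeline turns
the pooled reads into per-scat taxonomic profiles and population-level
diet summaries.

## Read filtering and demultiplexing

* Whole-read mean Phred quality ≥ 30 keeps a read (boundary inclusive);
  there is no quality trimming — reads are kept or discarded whole.
* Minimum length 120 bp (inclusive) removes partial reads and
  primer-dimer.
* Demultiplexing anchors the forward tag exactly at position 0 followed
  by the forward primer with ≤ 1 mismatch; the read's 3′ end must match
  `revcomp(reverse_primer) + revcomp(reverse_tag)` with ≤ 1 mismatch in
  the primer and a configurable number (default 0) in the tag.  The
  asymmetry is deliberate: the 5′ end of a single-direction
  semiconductor read is high quality, the 3′ end is not, and the strict
  default reproduces the characteristic loss of reads whose reverse tag
  was corrupted.  Rejection reasons are assigned in the order
  `no_forward_tag`, `no_reverse_tag`, `unknown_pair`, and every input
  read lands in exactly one of assigned/rejected.
* Tags *and* primers are trimmed before clustering.  The primers are
  conserved across all taxa by design; leaving them in place would add
  ~47 identical bases to every read and inflate inter-taxon identity
  toward the clustering threshold.
* Reads are used in sequencing orientation only; the fusion-primer
  design fixes amplicon orientation, so there is no reverse-complement
  rescue pass.

## Sequence identity

Both clustering and database matching use the same measure: the fraction
of matching columns in an optimal semi-global alignment with unit match
score and unit mismatch/gap penalties, computed by exhaustive dynamic
programming (no heuristics; exact at desk scale, and cached since the
same pairs recur).

The exact boundary conditions matter and were an open design choice.
Allowing free terminal gaps on *both* sequences at the same end
degenerates into local alignment — two unrelated sequences then reach
identity 1.0 over a short lucky overlap, which is useless as a
clustering criterion.  `scatdiet` therefore uses containment-style
semi-global alignment: the shorter sequence must be consumed end to end,
only the longer sequence's terminal overhangs are gap-free, and those
overhang columns are excluded from the identity denominator.
Consequences: equal-length sequences align globally ("AAAA" vs "AAAT" is
0.75); a sequence and a ragged-ended fragment of it (what the length
filter leaves behind) reach 1.0; unrelated random amplicons sit around
0.55.  Ties are broken deterministically (rightmost best end cell;
diagonal > vertical > horizontal in traceback), and arguments are
canonically ordered so identity is exactly symmetric.

## Clustering

Per-scat reads are dereplicated; unique sequences are processed in
decreasing abundance (ties: decreasing length, then lexicographic) and
joined to the *first* existing centroid, in creation order, with
identity **≥ 0.90** to its seed — otherwise they found a new cluster.
This mirrors the greedy semantics of the standard centroid-based OTU
tools; first-fit (rather than best-fit) and the deterministic ordering
make the output independent of input order, which the test suite pins
against an independent restatement of the rule.  `threshold = 1.0`
degenerates to exact dereplication.

## Classification and aggregation

Each cluster seed is aligned against every reference record (the
reference is a FASTA whose record names are full semicolon-delimited
lineages; RNA is converted to DNA on load).  A record qualifies as a
match when the normalized alignment score — score divided by seed
length, 1.0 for a perfect full-length match — is at least
`min_hit_coverage` (default 0.7).  This is the operational analogue of
"no BLAST match": random sequences score ~0.13 against any record and
single-breakpoint chimaeras ~0.5, so both fall below the floor and are
discarded, while a genuine hit at exactly 90% identity (~0.8) still
qualifies.  Among qualifying records the highest identity wins, ties
going to the earlier database record.

Assignment then requires identity **strictly greater than 0.90** — a
deliberate asymmetry with the ≥ 0.90 clustering rule, matching the
respective phrasings of the assay's protocol.  The hit's lineage is
scanned from species upward and the *most specific* rank present in the
aggregation list determines the (taxon, category) of the cluster; every
member read inherits it.  Lineages containing no listed rank are
collected into a training report (closest species, cluster and read
counts) for a curator to convert into new rules; growing the list never
changes already-assigned clusters.

The packaged aggregation table carries 60 taxa across the four
categories (food / parasite / contaminant / unicellular eukaryote) used
by the Adélie penguin scat assay, e.g. Euphausiidae (krill) and
Scyphozoa (jellyfish) as food, Cestoda (tapeworms) as parasite,
Primates as contaminant.

## Diet profiles and population summaries

Scats with fewer than 50 food reads are removed before any summary
(boundary: 50 retained, 49 dropped).  Proportions are computed within a
category — food proportions among food reads, parasite proportions among
parasite reads — and population summaries are **means of per-scat
proportions**, never pooled counts, with SE = sample SD/√n (n = 1
reports SE 0 with a logged warning).  For non-food categories, scats
with zero reads of the category have no defined proportion vector and
are excluded from that category's mean (the retained-scat set still
forms the FOC denominator).  Frequency of occurrence counts a taxon
present at ≥ 1 read; co-occurrence is the percentage of retained scats
containing both taxa of a pair (its diagonal equals FOC, and
cooccurrence(i,j) ≤ min(FOC(i), FOC(j)) always); the single-item
percentage is the share of retained scats containing exactly one food
taxon.  Summaries can be stratified by any metadata key (e.g. sex);
stratum means recombine exactly to the unstratified mean when weighted
by stratum sizes.

## Population comparison

Two populations are compared over the food groups present at mean
proportion ≥ 0.1% in both (inclusive boundary; taxa absent from either
are excluded).  Each population yields a symmetric matrix of pairwise
absolute differences |p_i − p_j| among its mean proportions — absolute
rather than signed, since a dissimilarity-style matrix is the standard
Mantel input and signed entries would make the result depend on
arbitrary group orientation.  Proportions are *not* renormalized over
the shared groups: the comparison targets ratios of prey items, which
renormalization would not preserve any better and would couple to the
excluded groups.  The Mantel statistic r is the Pearson correlation of
the strictly-upper-triangle entries; the null distribution comes from
uniformly random simultaneous row/column permutations of one matrix,
and the one-sided (greater) p uses the add-one correction,
p = (1 + #{r_perm ≥ r_obs}) / (1 + n_permutations), so with the default
9999 permutations the smallest attainable p is 0.0001.  At least three
shared groups are required; a self-comparison gives r = 1 exactly.

A calibration subtlety: the permutation p is uniform under an
*exchangeable* null.  Two populations sampled from the same
*non-uniform* composition produce strongly correlated difference
matrices — r near 1 and p at the floor is then the correct behaviour
(that is the "identical diets" outcome, not a false positive).  The
package's null-calibration check therefore simulates pairs of
populations from an equal-proportion composition, where group labels
are exchangeable and the p-value distribution should be (and is)
approximately uniform.

## The synthetic-data generator

`build_mock_reference` draws taxon names from the packaged aggregation
table, gives each a multi-rank lineage whose aggregation-level rank is
the taxon itself, and generates random amplicon templates (default
140–170 bp) flanked by the real primer-binding sites, rejecting any
template within 90% identity of an existing one (error if impossible).
`simulate_scat_reads` builds reads as
`forward_tag + forward_primer + template + revcomp(reverse_primer) +
revcomp(reverse_tag)` — instrument adapters are assumed already removed
by base-calling — and corrupts them with the error model; a truth table
records every read's scat and source taxon.

The error model has a flat per-base substitution rate that ramps up
linearly beyond a start position (non-decreasing by construction,
capped at 0.75), independent insertion/deletion noise, and per-read
single-breakpoint chimaeras spliced from two same-scat templates (PCR
chimaeras form within a reaction).  Phred scores are derived
deterministically from the same per-position probabilities,
Q = −10·log₁₀(p) clipped to [2, 40], so the mean-quality filter
interacts realistically with the 3′ ramp.  The defaults
(base 2×10⁻⁴, ramp 2×10⁻³ per base from position 170, indel 5×10⁻⁴,
chimaera 1%) were calibrated once so that a typical ~220 bp tagged read
keeps a mean Q just above 30 while the ramp corrupts a large fraction
of reverse tags: about 80% of simulated reads survive quality
filtering but only ~15–20% are assignable, reproducing the qualitative
read-loss behaviour of the original chemistry without claiming its
(unpublished) quantitative rates.

Default community composition mirrors the category-level structure of
the real survey: ~51% food reads (krill-dominated: 45% Euphausiidae,
20% Actinopterygii, 15% Calanoida, 10% Amphipoda, 7% Scyphozoa, 3%
Ctenophora within food), ~11% parasite, ~15% contaminant, ~13%
unicellular and ~10% reads from taxa absent from the reference.
`make_population` can add between-scat Dirichlet heterogeneity around
the base composition.

What the generator does **not** emulate: flow-space (ionogram) signal
and homopolymer-specific errors, run-to-run bias, PCR amplification
bias among taxa, the blocking primer's chemistry (predator DNA appears
only as a configurable contaminant fraction), and real SSU sequence
structure (templates are random DNA, far more separable than real
lineages).  Passing tests therefore demonstrate the correctness of the
pipeline's logic and statistics under the assay's assumptions — not
classification accuracy on real, phylogenetically structured
references.

## Problem sizes and numerical conventions

The end-to-end validation uses 60 scats × 500 noise-free reads across
two simulated runs (the scale at which exhaustive alignment is exact
and fast, with alignment caching); the clustering oracle uses 50 random
instances of ≤ 20 unique 30 bp sequences; Mantel oracle checks
enumerate all 24 permutations of 4×4 matrices; null calibration uses
200 replicate pairs of 15-scat populations at 999 permutations each.
Percentages in bookkeeping reports round half away from zero.  All
randomness flows through explicit integer seeds (NumPy `SeedSequence`
spawning for independent per-scat streams), and identical inputs,
configuration and seed reproduce output files byte for byte.

## Known limitations

* Exhaustive O(nm) alignment is intended for desk-scale references
  (thousands of records would be slow without indexing heuristics).
* Single best hit only — no lowest-common-ancestor voting, no E-values.
* The 0.1% shared-group floor is applied to mean proportions (the
  alternative — pooled sequence counts — is ambiguous in the source
  protocol); the difference matters only for taxa at the floor's edge.
* DNA proportions are not biomass: the summaries quantify sequence
  composition, and cross-population *change*, not grams of prey.
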