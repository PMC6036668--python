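# Methods

`htscan` detects horizontal transfer (HT) of retrotransposon families
(exemplified by BovB and L1) from genome assemblies. This note documents the
models, the synthetic data the package is validated on, the numerical
choices, and the known limitations.

## The detection procedure

The pipeline follows the strategy used in large multi-genome TE surveys:

1. **Mining.** TE copies are located by a nucleotide seed-and-extend search:
   exact 11-mer seeds on both strands, ungapped x-drop extension under
   match +2 / mismatch −3 (the match reward suited to divergent sequences),
   chaining of consistent segments, and gapped refinement of each candidate
   region. Hits to the same family within 500 bp on one strand merge into
   loci. Family labels are verified by a reciprocal best-hit (RBH) check
   against the reference repeat library; a locus whose best library hit
   belongs to a different family is relabelled and marked unconfirmed.
2. **Full-length filtering.** Nucleotide analyses use family length windows
   (BovB: ≥ 2400 and < 4000 bp; L1: ≥ 3000 and < 9000 bp). "Intact"
   additionally requires at least one ORF of ≥ 200 aa; this operational
   definition is configurable because intactness has no single standard
   definition.
3. **Clustering.** Two all-against-all engines. The greedy centroid engine
   (UCLUST/VSEARCH style) processes sequences longest-first and assigns each
   to the first centroid it matches at or above the identity threshold —
   appropriate for ancient transfers, where the centroid is ideally the
   transferred element. The single-linkage engine (BLAST+SiLiX style)
   connects any pair with an above-threshold local hit covering at least
   half of the shorter sequence and takes connected components — sensitive
   for recent transfers but prone to chaining degraded copies. The default
   analysis threshold is 0.6, at the low end of the 50–90% range, to retain
   sensitivity for older events.
4. **Cross-rank filter.** Clusters whose members span at least two classes
   (or phyla) are HT candidates; within-rank clusters are consistent with
   vertical inheritance and are dropped.
5. **Validation.** Each candidate's closest cross-rank copy pair is checked
   four ways: *flank contrast* (identity of the 1 kb flanks must stay at or
   below 0.6 on both sides; flanks nearly as similar as the elements mark
   the candidate `likely_contamination`); *reciprocal best hit* (each copy's
   best hit in the partner species must lie in the partner's cluster);
   *scaffold quality* (copies whose flanks are truncated by scaffold ends
   cannot be validated: `likely_artefact`); and *phylogenetic discordance*
   (below). `confirmed` requires all four.
6. **Divergence landscapes.** Copy coverage binned by Kimura two-parameter
   (K2P) distance to the family reference in 1% bins; amplification bursts
   appear as modes at the burst age.

## Distances and trees

The K2P model separates transitions (observed fraction P) from
transversions (Q): K = −½·ln((1−2P−Q)·√(1−2Q)). Gap and N columns are
excluded; saturated pairs raise an error rather than returning infinity.
Plain K2P is computed (no CpG adjustment, which some repeat-annotation
utilities apply in certain modes).

Trees are built by neighbour joining on K2P distance matrices, with
negative branch-length estimates clamped to zero and the deficit moved to
the sibling branch. On additive matrices NJ is exact: topology and branch
lengths are recovered to 1e-9 (verified on random 8-leaf trees). Bootstrap
support resamples alignment columns (default 1000 replicates; tests use
fewer) and reports the fraction of replicate trees containing each split.
Within bootstrap replicates only, saturated distances are capped at K = 5
so a replicate cannot abort the resampling.

Multiple alignment is progressive: a UPGMA guide tree on 8-mer distances,
then profile–profile alignment under an affine-gap, end-gap-free scheme
(match +2, mismatch −3, gap open −5, extend −2), deterministic given input
order. Conserved blocks are maximal runs of ≥ 5 columns whose most frequent
non-gap character reaches 50% of the sequences, with gaps allowed in kept
columns — the two block parameters mirror common practice for conserved
block extraction; the remaining behaviour of full Gblocks is intentionally
not reproduced.

## Identity definitions

Identity is used in two roles, and two definitions are deliberate:

* **Global identity** (clustering kernel, flank contrast, RBH confirmation)
  is the Levenshtein ratio `1 − d/max(|a|, |b|)` with `d` the optimal global
  edit distance. For substitution-only differences it equals matches over
  alignment columns exactly. A matches-over-columns count along one optimal
  edit path was rejected after it proved inflatable: between divergent
  sequences, co-optimal paths trade mismatches for match-creating shifts,
  pushing the apparent identity of unrelated DNA to ~0.55 and destroying
  threshold discrimination. The Levenshtein ratio keeps unrelated 3.2 kb
  sequences near 0.48.
* **Local/hit identity** (mining, single-linkage hits) is matches over
  alignment columns of the refined hit alignment, internal gaps counted,
  terminal gaps excluded — the convention of alignment-based search tools.
  It is verified to stay within 0.02 of a score-based full-DP oracle.

Score-based global alignment (gaps dearer than mismatches) backs all
absolute distance estimates (`k2p_pair`, divergence landscapes), because
edit-distance paths bias K2P downward by ~15% at 10–20% divergence.
Within-cluster support scores use the fast edit-distance route; the bias
largely cancels in the ratio.

## The HT support score and discordance rule

For the closest cross-rank pair (a ∈ species A, b ∈ species B):

* `support_score` = K2P(a, b) / median K2P among within-rank,
  cross-species pairs of the older (more internally diverged) rank group in
  the cluster. A transferred element sits closer to its donor than the
  donor's own within-rank background, so scores < 1 support HT; vertical
  cross-rank clusters score ≈ 1 or above.
* `tree_discordant` is true when, in the NJ tree of cluster members, the
  minimal clade spanning a and b contains copies of those two species only,
  while same-rank copies — from species closer in the species tree than A
  and B are to each other — sit outside it. This operationalises the
  "species appear too closely related on the TE tree" criterion; the NJ
  root trifurcation is rerooted away from the pair when it would otherwise
  split the clade. Clusters of fewer than 4 copies leave the verdict
  undefined (and hence unconfirmed).

Both rules are heuristics for a criterion that published analyses apply by
expert inspection; the thresholds (support < 1, flank maximum 0.6,
contamination margin 0.1) are configurable.

## The synthetic-data generator

The simulator provides ground truth where real multi-genome data cannot:

* **Species tree**: ultrametric Yule tree, leaves `sp1..spN`, rescaled to a
  root-to-tip height in expected substitutions/site. The default study
  condition is 12 species at height 0.35, giving cross-class copy identity
  ≈ 0.55–0.72 (old TE lineages straddling the root remain recognisable,
  exactly the regime that makes the cross-rank filter non-trivial).
* **Copies** evolve by a K2P process (κ = 2 by default) along each branch;
  active copies replicate as a Gillespie birth process (default 1 new copy
  per active copy per unit branch length, from 4 ancestral copies of a
  3.2 kb master element — the canonical BovB length); each new copy is born
  inactive with probability 0.3, matching the observation that TE lineages
  go extinct. The master element carries one long stop-free ORF so ORF/RT
  analyses have signal.
* **Decay**: segmental deletions with sizes uniform on 31 bp–10 kb, the
  range reported for TE removal from genomes, applied at a configurable
  expected number of events per copy (default 0 so that mining statistics
  are interpretable; decay is exercised explicitly in tests).
* **Horizontal transfer** is an explicit list of events, not a rate
  process (no quantitative HT rate is established for these families). An
  event copies one active-copy sequence from the donor branch at a
  fractional position along it into the recipient branch at the same
  fraction, then lets the founder amplify down the recipient subtree. All
  descendants carry `horizontal = True` in the truth table.
* **Genomes** are i.i.d. uniform random DNA (60 kb by default) with copies
  inserted at random non-overlapping positions and strands — the simplest
  non-homologous context, which makes flank tests exact: true HT pairs have
  unrelated flanks by construction.

What the generator does **not** emulate: repetitive or compositionally
biased genomic background (mining precision on real genomes will be lower),
insertions within copies other than by nesting, target-site duplications,
rate variation across sites or lineages, and selection. Passing tests
demonstrate the machinery recovers planted signal under the stated model,
not performance on real assemblies.

## Problem sizes

Validation uses 12-species simulations with ~50–80 copies total and 60 kb
backgrounds, 100-tree NJ exactness batches, 50-instance clustering-oracle
batches, and 40-copy amplification bursts at 2 kb — sizes chosen so the
full suite and the acceptance script each complete in minutes on one core
while keeping estimator noise (e.g. K2P standard error ≈ √(K/L)) well
inside the asserted tolerances.

## Numerical and degenerate-input choices

* Ambiguity codes other than N collapse to N on read; N columns score 0 in
  alignment and are excluded from distance counts.
* Greedy clustering order is length-descending with ties by id; all stages
  sort outputs, so reruns are bit-identical for a fixed seed.
* Centroid selection ties break by lexicographically smallest copy id.
* Consensus columns: a gap wins only by strict majority; base ties go to
  the first-seen base. Consensus sequences longer than every supporting
  copy are flagged (`overlong`), the known failure mode for degraded
  families.
* The PSSM is log-odds (bits) over a uniform 1/20 background with unit
  pseudocounts; gap-majority seed columns are dropped. The RT envelope is
  the maximal-scoring gapless window of ≥ 200 aa at ≥ 50 bits — on shuffled
  sequences the expected per-column score is negative (minus the relative
  entropy), so the null stays far below threshold. No insert states are
  modelled; a profile HMM would tolerate indels inside the domain better.
* An HT candidate whose flanks are truncated by scaffold ends is demoted to
  `likely_artefact` before any other verdict except contamination.

## Known limitations

* The seed-and-extend searcher requires an exact word match; families more
  diverged than ~40% from every library entry can fall below seeding
  sensitivity (mitigated in practice by lowering `word_size`).
* Protein-space search is not implemented; the RT-domain PSSM covers the
  conserved-protein role for already-mined copies only.
* Maximum-likelihood tree inference is out of scope; NJ with bootstrap is
  the implemented arm, sufficient for the discordance test.
* The discordance rule needs the cluster to contain at least one same-rank
  species besides the candidate pair; two-species clusters cannot be
  confirmed, a deliberate conservative choice.
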