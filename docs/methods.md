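# Methods

This note documents the models and procedures implemented in `hsp70evo`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Localization classification

Two evidence streams are combined per protein sequence.

**C-terminal motif.** The final four residues are matched exactly against
EEVD (cytosol) and HDEL/KDEL (ER retention). Mitochondrial members carry
none of these. RARFEEL is searched anywhere in the sequence and reported as
a boolean, but deliberately never contributes to the label: the motif also
occurs in ER-clade members, so treating it as cytosol evidence would
mislabel exactly the cases where extra evidence is needed.

**N-terminal signature.** A 23-position window holds the diagnostic
residues; the shipped table (`data/signatures.tsv`, editable TSV of
position / localization / allowed residues) encodes the cytosolic consensus
at 16 positions, the four ER variants (K8, N9, R11, I23) and the fifteen
mitochondrial variants. Position 23 discriminates ER from everything else,
so I23 votes ER only. Because the window's absolute position varies with
signal peptides and N-terminal annotation noise, it is located by best-match
scan over the first 90 residues (`locate_nterm_window`), scoring matches to
the union of all three consensi; a placement matching fewer than 50% of
scored positions is rejected. Each signature position then casts one vote
for every localization whose allowed set contains the observed residue.

**Combination rule.** A C-terminal motif, when found, sets the label. With
no motif, the vote winner sets the label if it leads by at least 2 votes
(`vote_margin`, configurable); conflicts between the streams resolve in
favor of the motif and are recorded in the call's note; otherwise the call
is `unknown`. The margin is an artifact decision — the biological claim is
only that the window discriminates — so it is exposed as a parameter.

**Serine insertion.** The Lineage-A-diagnostic serine in the ATPase domain
is read off a protein alignment against a reference row known to lack the
insertion (any Lineage-B member). The diagnostic column is a reference-gap
column whose 5 flanking columns on each side match the query exactly
(`flank` configurable); the query's residue there yields
present / substituted(residue) / absent, and `undetermined` when no such
column anchors. Exact flank matching is justified by the strong
conservation of the surrounding ATPase-domain context; raising `flank`
trades sensitivity for specificity.

**Logo arithmetic.** Positional profiles are per-column frequencies over
observed residues (gaps and X ignored) with information content
IC = log2(20) − H in bits; an all-gap column has undefined IC and is
reported as missing. Discriminating positions between two profiles are
those where the majority residues differ and both majority frequencies
exceed 0.7 (configurable); on the consensus profiles this recovers exactly
the four ER-diagnostic positions {8, 9, 11, 23}.

## Ka/Ks estimation

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor multiple-hit
correction, implemented from first principles and verified against a
brute-force enumeration oracle in the test suite.

* **Sites.** For each codon position, the synonymous fraction is the number
  of synonymous single-nucleotide changes divided by the number of changes
  that do not create a stop codon (renormalization over non-stop changes),
  so each position contributes exactly one site and S + N = 3 for every
  sense codon. Stop codons and N-containing codons contribute nothing.
* **Differences.** Only codon columns where both cells are gap-free, N-free
  and non-stop are compared. Codons differing at k positions are averaged
  over all k! substitution orderings; orderings passing through a stop
  codon are excluded and the remainder reweighted. In the rare case where
  every ordering is blocked, the column is excluded from both the site and
  difference totals (the pair's comparable-codon count drops accordingly).
* **Correction.** pS = Sd/S̄ and pN = Nd/N̄ (site counts averaged over the
  two sequences) are corrected with d = −(3/4)·ln(1 − 4p/3). A proportion
  at or above 3/4 cannot be corrected: the pair is invalid
  (`undefined_correction`). Fewer than 10 comparable codons (`min_codons`)
  also invalidates a pair.
* **Saturation filter.** Retained pairs are valid with 0 < Ks ≤ 3.0
  (`ks_max` configurable). Ks beyond the threshold is treated as saturated;
  Ks = 0 with any Ka leaves the ratio undefined and the pair is excluded
  from pools as the conservative choice.
* **Pooling.** An inter-clade pair contributes its ratio to both endpoint
  clades' pools; intra-clade pairs are excluded. The alternative reading —
  pooling per-clade means rather than raw per-pair ratios — would discard
  the within-clade distribution the rank tests need, so raw ratios are
  pooled.

The estimator choice itself is a design decision: a from-scratch NG86 with
an exhaustively tested counting core is preferred over mimicking any
particular library routine, because clade-level contrasts in the strongly
purifying regime are robust to the estimator family.

## Clade statistics

All comparisons are rank-based; pooled ratios are bounded, skewed and
unequal in sample size.

* **Kruskal–Wallis.** H = 12/(n(n+1)) · Σ R_g²/n_g − 3(n+1) over pooled
  ranks, divided by the tie correction 1 − Σ(t³−t)/(n³−n); a vanishing tie
  divisor (all observations equal) yields H = 0. The p-value uses the χ²
  approximation with k − 1 df, which is well calibrated for the group sizes
  used here (type-I error ≈ 0.05 at three groups of twenty).
* **Pairwise rank-sum tests.** Two-sided; exact enumeration of the rank-sum
  null distribution when both groups have ≤ 10 observations and the pooled
  sample is tie-free, otherwise the normal approximation with tie-corrected
  variance and a 0.5 continuity correction. Groups smaller than 2 yield a
  missing p-value.
* **Holm adjustment.** Sorted raw p multiplied by (m − rank + 1), made
  monotone along the sorted order, capped at 1; order-invariant.
* **Effect size.** |Cohen's d| with the pooled sample standard deviation;
  zero variance with equal means gives 0, with unequal means is flagged
  infinite. Values above 0.8 are labelled large.
* **Compact letter display.** Letters are the maximal cliques of the graph
  whose edges join clades with adjusted p ≥ 0.05, so two clades share a
  letter exactly when they are not significantly different. This is a
  presentation layer; the adjusted p matrix is the inference. Outlying
  ratios are retained in all statistics (trimming, if any, is left to
  plotting).

## Trees and clade assignment

Neighbor joining (Saitou–Nei agglomeration with the Studier–Keppler Q
matrix) is provided for desk-scale grouping; heavy Bayesian/ML inference is
intentionally out of scope and published trees can be supplied as newick
instead. Q-ties break on the lexicographically smallest id pair, making the
topology deterministic; negative branch-length estimates are clamped to
zero with the deficit moved to the sister branch; the result is unrooted.
On additive matrices NJ is exact (verified down to branch lengths).
Distances come from pairwise ungapped columns as p-distance or Poisson
−ln(1−p); a pair with no shared columns is an error, and p = 1 under
Poisson is reported as missing.

Clade assignment takes a rooted tree (unrooted trees are midpoint-rooted
first; midpoint rooting is implemented via an explicit longest-path walk so
a midpoint landing exactly on a node is handled) plus seed labels, and
gives each unlabeled leaf the label of the smallest clade containing it and
seeds of exactly one class; leaves whose every seeded clade mixes classes
stay unassigned. The operation never overwrites seeds and is idempotent.

## Nomenclature

`HSP70 + code + lineage + copy + suffix` with codes {c, m, er}, one
uppercase lineage letter, copy ≥ 1 and suffix i/c only when inducibility is
known; gene symbols are lowercased protein names. Parsing is
case-insensitive and consumes `er` greedily before the single-letter codes
(so `hsp70era1` is ER/A/1, per the scheme's own example). Copy numbers are
assigned per (species × localization × lineage) in input order — the scheme
specifies no ordering, so a deterministic, stable choice is used. Organelle
members default to lineage A: only one mitochondrial and one ER lineage are
known, and reserving the letter leaves room for novel ones. The suffix `c`
for constitutive genes extrapolates the grammar symmetrically from the `i`
example; no explicit constitutive example exists in the scheme's
description.

## Synthetic families

The simulator emulates the assumed family structure: ancient duplications
produce cytosolic Lineages A and B plus mitochondrial and ER lineages, each
then tracking a random ultrametric species tree. Defaults are the study
conditions used throughout the tests: 3 species × 4 lineages × 200 codons;
ω = 0.2 for Lineage A versus 0.05 for Lineage B, the organelle lineages and
the backbone (inducible lineages under weaker purifying selection, all well
below 1); stem branches of expected synonymous divergence 0.15 and crown
root-to-tip 0.25, so typical inter-lineage pairs accumulate path Ks near
1 — informative but below the saturation threshold.

Coding sequences evolve by a two-class per-site scheme: at each codon
position, a synonymous change occurs with probability t times the
position's synonymous site fraction (t = expected synonymous
substitutions/site on the branch) and a nonsynonymous, stop-avoiding change
with ω times the complementary mass. This is deliberately simpler than a
full codon-model sampler: it gives directly controllable pN/pS ≈ ω (the
realized ratio converges to ω on long branches; verified within ±20% at
5000 codons) at the cost of ignoring transition/transversion bias and codon
usage. Diagnostic features (C-terminal motifs, N-terminal signature
variants, the Lineage-A serine insertion with its conserved flanks) are
written at lineage ancestors and masked from mutation, mirroring the
conservation of real diagnostic residues — which is exactly the premise the
classifier rests on. Optional post-hoc noise substitutes whole codons to a
different amino acid at a per-residue probability (motif sites included, so
noise genuinely degrades classification), and frame-shift injection inserts
one nucleotide mid-CDS; both are recorded in a ledger that exactly predicts
which records CDS validation rejects.

What passing on these families shows: the estimation and classification
machinery recovers known truth under the generative assumptions. What it
does not show: performance under real HSP70 base composition, codon usage,
alignment error, gene conversion between paralogs, or signal-peptide
variability — none of which the generator models.

## Problem sizes and determinism

The benchmark sizes are chosen to make every property sharply decidable at
desk scale: 20 simulated families for recovery rates, 2000 null simulations
for test calibration, 1000 random short codon pairs for oracle equivalence,
200-codon sequences (5000 for the convergence check). All randomness flows
through explicit seeds; identical configurations produce byte-identical
output files, and the pipeline writes a manifest (versions, seed, per-stage
counts) alongside every run.

## Known limitations

* NG86 with JC correction underestimates ω when pS is large (Ks is
  corrected more than Ka), so pooled ratios are comparative, not absolute,
  measures of selection pressure; clade orderings are what the pipeline is
  designed to recover.
* The saturation threshold (Ks > 3) is a convention; results near the
  threshold deserve a sensitivity check via `ks_max`.
* The N-terminal window scan assumes the signature lies within the first
  90 residues; proteins with unusually long signal peptides or N-terminal
  extensions would need a larger `search_limit`.
* Compact letters are a greedy presentation of the pairwise test matrix and
  can obscure borderline structure; read the adjusted p matrix when it
  matters.
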