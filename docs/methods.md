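# Methods

This note documents the models, algorithms, numerical choices and
limitations behind the package. It is written for someone who wants to
understand or modify the pipeline, not to re-derive it.

## The question the pipeline answers

Animal mitochondrial genomes carry 13 protein-coding genes and 2 rRNAs
on one circular molecule. Although the genes are physically linked and
share one genealogy in expectation, their phylogenetic signals often
disagree. The pipeline quantifies that disagreement: it infers a
maximum-likelihood tree per gene partition, asks — for every pair of
partitions — whether each partition's data can statistically reject the
other partition's tree, and aggregates the three-state outcomes
(congruent / incongruent / ambiguous) into summary matrices. Downstream
analyses relate a gene's incongruence count to its functional category
and to its distance from the origin of replication (OR) on its strand.

## Substitution model

All likelihoods use TIM2+G+I: the GTR submodel with exchangeability
constraints AC = AT and CG = GT (two free transversion classes, two
free transition classes), discrete-gamma rate heterogeneity, and a
proportion of invariant sites.

* Generator: `q_ij = s_ij * pi_j`, rows sum to zero, scaled so the
  expected substitution rate at stationarity is 1 per unit time over
  the variable fraction. No extra `1/(1-pinv)` rescale is applied, so
  simulated and inferred branch lengths share one convention: a branch
  of length `t` carries `(1-pinv)*t` expected substitutions per site.
* Base frequencies are empirical counts from the evaluation alignment,
  floored at 1e-4 and renormalized; they are not ML-optimized (a
  config switch away if ever needed).
* Gamma rates use the mean-of-quartile rule with `ncat = 4`:
  category boundaries at the quartiles of Gamma(alpha, alpha),
  category rate = conditional mean within the band, so the weighted
  mean rate is exactly 1.
* Ambiguity codes are partial tip observations (ones for every
  compatible base); gaps are fully missing. A site can belong to the
  invariant class only if some single base is compatible with every
  taxon, and the invariant-class mass is the stationary probability of
  those bases.

Transition probabilities come from the symmetrized eigendecomposition
`B = D^{1/2} Q D^{-1/2}` (real spectrum, stable), evaluated in batch
for all (edge, rate-category) pairs at once.

## Likelihood engine

Felsenstein pruning over pattern-compressed alignments, with per-node
max-rescaling and per-(category, pattern) log-scale accumulators.
Per-site log-likelihood vectors — the common currency of the RELL
tests — are exposed directly.

Branch lengths are optimized by a batched Newton iteration on
`x = log t`, using analytic first and second derivatives obtained from
the eigendecomposition (`P'(s) = U (Lambda e^{Lambda s}) U^{-1}`).
All edges of a round move simultaneously against the partials frozen
at the round start; a guard compares the joint likelihood before and
after the round and, in the rare event it decreased, reverts and
re-runs the round with partials refreshed before every edge (exact
conditional maximization, hence monotone). Model parameters are fitted
by coordinate ascent: bounded 1-D line searches for alpha, pinv and
the three free rate classes, plus a joint Nelder-Mead refinement of
(alpha, pinv, global branch scale). The joint step matters: those
three quantities trade off along a likelihood ridge that 1-D sweeps
traverse extremely slowly, and without it the invariant fraction is
systematically underestimated.

## Tree search

Maximum-likelihood search follows the random-start hill-climbing
recipe: a uniform random topology (sequential addition), NNI
neighborhoods, accept the best improving neighbor, stop when none
improves. Neighbor scoring is exact but lazy — every NNI neighbor's
log-likelihood at current branch lengths is computed in place from the
stored partials (two small matrix products per neighbor, no tree
copies); the top four screened neighbors are then re-optimized with a
full branch-length round before acceptance. On a stall the current
tree gets a deeper branch pass, then every neighbor is re-scored with
two full rounds (trees of at most 25 taxa; larger trees stop at the
stall, where strong concatenated signal makes deep local optima rare).
Restarts are available (`restarts`, default 3 in the desk profile;
the experiment profile uses 1).

Parsimony search is the same hill climb minimizing the Fitch length,
computed on bitmask patterns; ambiguity codes contribute their
compatible-state sets. Ties among equally scoring neighbors break
toward the lexicographically smallest Newick string.

## Topology-test battery

All seven likelihood statistics are computed from per-site
log-likelihood vectors of the candidate topologies, each topology's
branch lengths re-optimized on the evaluation alignment first (the
alignment's own search tree is reused as-is). One RELL replicate set
(B draws of n sites with replacement, shared across candidates) feeds
bp-RELL, KH, wKH, SH, wSH and c-ELW, the usual convention of tree-test
batteries; the AU test draws its own replicates at ten scales
(0.5–1.4). Because sites sharing a log-likelihood column are
interchangeable, the bootstrap reduces to a multinomial over unique
columns.

* KH is one-sided: `delta = L_best − L_m` against the centered
  bootstrap differences; the weighted variant standardizes both sides
  by the difference's standard deviation (for two candidate trees this
  scaling cancels, so wKH = KH there; with more candidates the
  best-tree reference makes them differ).
* SH centers each tree's replicate totals by its own mean and compares
  `max_k centered_k − centered_m` with the observed `L_max − L_m`,
  which dominates the KH null, so `p_SH >= p_KH` holds by
  construction.
* AU fits `Phi^{-1}(1 − bp_r) = d sqrt(r) + c / sqrt(r)` by weighted
  least squares (binomial weights) and reports `1 − Phi(d − c)`.
  Bootstrap proportions split ties evenly among co-leaders, so
  identical vectors give bp = 1/2 and p = 1/2 rather than an arbitrary
  argmax artifact. Trees degenerate at every scale fall back to the
  bp-RELL call (0 or 1) and are flagged.
* ILD: `D = L(combined) − [L(A) + L(B)]` in parsimony steps with
  identical search effort for all three matrices;
  `p = (1 + #{D* >= D}) / (R + 1)` over R site-reassignment
  permutations. Both the observed and permuted differences are clamped
  at zero — heuristic search can leave them marginally negative, and
  clamping is conservative (it can only raise p).

A gene pair's call combines the two rejection directions: incongruent
iff both alignments reject the other's topology at alpha (default
0.05), congruent iff neither does, ambiguous otherwise. Two searches
returning the same topology short-circuit to congruent, the exact
limit of the identical-vector case. The pipeline never aggregates
across the seven tests; every output table carries a test column.

## Workflows

* **Pairwise**: all unordered partition pairs, each evaluated once
  with a seed derived from the pair's sorted names and mirrored, so
  the matrix is symmetric by construction and its diagonal congruent
  by definition.
* **Antigene**: for each gene g, the concatenation of the other 14
  genes is tested reciprocally against every single gene h != g
  (15 rows x 14 comparisons). Comparison RNG streams are keyed by the
  partner gene only, so leave-one-out rows are paired (common random
  numbers) and row contrasts are not drowned by seed noise.
* **Categories**: CO = {COX1-3, CYTB}, ND = {ND1-6, ND4L},
  AT = {ATP6, ATP8}, rRNA = {12S, 16S}, concatenated and compared
  pairwise.
* **Subsampling**: random taxon culling without replacement at each
  fraction (independent draws across fractions), full pairwise
  recomputation on the reduced matrix; fractions leaving fewer than 4
  taxa are skipped with a warning.
* Congruent proportions use unordered pairs; ambiguous cells count in
  the denominator but never the numerator, and are also reported
  separately.

## OR-distance gradient

A gene's replication distance is the circular arc from its strand's OR
to the gene's 5' end (midpoint available via config), measured along
the strand's replication direction, modulo genome length. The unscaled
congruence measure is the per-gene count of pairwise comparisons
flagged in a chosen orientation; both orientations (incongruent-count
and congruent-count) are emitted in reports since either convention
appears in practice. Ordinary least squares of count on distance is
done per strand; strands with fewer than three genes produce an NA row
with a reason, and slopes below 1e-12 counts/bp are classed "0".

## Synthetic mitogenomes

The generator emulates a partitioned mitogenome matrix: 15 named gene
partitions with realistic lengths on a circular map, a vertebrate
(human-like; ND6 the sole minority-strand gene) or derived-insect
strand layout (rRNAs at the minority-strand OR, the ND1/ND4/ND4L/ND5
block opposite it), an OR per strand, and per-gene true trees that are
identical, block-discordant, or increasingly discordant with OR
distance. Layout templates are editable TSV data bundled with the
package, not code. The insect template is a deliberately stretched
caricature — a 21 kb circle with an enlarged control region and a
large intergenic spacer placing the ND block truly opposite the OR —
so the replication-distance range is wide enough for a planted
gradient to be resolvable at desk scale; real derived-insect genomes
are nearer 16 kb with the same qualitative geometry.

* Species trees are Yule (unit birth rate), rescaled so the median
  tip-to-tip path is 0.5 expected substitutions per site — informative
  but unsaturated at mitochondrial rates. Every branch is floored at
  1e-6.
* Discordance is planted by NNI moves by default; SPR is available for
  strong rearrangements. All genes of a `block_discordant` subset
  share one perturbed topology (a shared discordant history — what the
  category analysis looks for); under `or_gradient`, gene g draws
  `Poisson(lam * d_g / d_max(strand))` moves, so the most distant gene
  on each strand sees the full intensity `lam`.
* The default sequence model is mitochondria-like: strong transition
  bias (AG = 6, CT = 10 against transversions 1 and 0.7), AT-rich
  composition (0.32/0.27/0.12/0.29), alpha = 0.45, pinv = 0.25.
* `length_scale` compresses gene lengths proportionally for desk-scale
  runs, flooring every gene at 100 sites so tests stay informative.
* Everything is a pure function of (scenario, seed) through named
  `SeedSequence` children; regenerating a dataset is byte-identical.

What the generator does **not** emulate: indels and alignment error
(synthetic data are gap-free), tRNAs and the control region,
within-gene rate variation fitted to any real taxon (per-gene rate
multipliers default to 1), codon structure, and base-compositional
strand asymmetry. Passing tests therefore demonstrate that the
machinery recovers planted topological structure under the analysis
model — not that real mitogenome incongruence has the planted form.

## Experiment designs and problem sizes

The replicated experiments in `mitocongruence.experiments` (driven by
the numbered scripts in `analysis/`) run at sizes chosen for a single
desk CPU:

* Engine checks: exhaustive-enumeration oracle on 4–6-taxon fixtures;
  JC closed form at the bottom of the model-nesting chain.
* Null calibration: 200 replicates of two 350-bp genes on one 10-taxon
  tree, B = 1000, alpha = 0.05; ILD separately with 100 replicates of
  two 200-bp genes on 6 taxa, R = 99.
* Power: 50 replicates, 10 taxa, 900-bp genes on topologies five SPR
  moves apart; also yields the AU-vs-SH sensitivity ordering.
* Antigene culprit: 6 taxa, half-length genes, ND5 on a strongly
  rearranged topology (10 SPR moves) at 3x rate; anti-ND5 vs anti-COX1
  congruent fractions contrasted per replicate under SH, whose
  conservative behavior gives the steadiest fractions.
* rRNA category: 8 taxa, half-length genes, both rRNAs sharing a
  6-SPR-move topology; detection = rRNA incongruent with CO, ND and
  AT under AU.
* Subsampling: 40 taxa, quarter-length COX1/ND4/ND5 with a discordant
  ND4+ND5 block (lam = 3), fractions 100% and 10%, 20 draws, SH.
* Gradient: insect layout at 0.4 length scale, 8 taxa, lam = 8,
  pairwise matrix over the six minority-strand genes plus the two
  nearest-OR majority genes (ND2, COX1) so incongruence counts have
  congruent partners to grade against; weighted-SH counts (the
  conservative tests give the steadiest count profiles); OLS on the
  minority strand; the congruent scenario serves as the no-gradient
  null.

## Known limitations

* NNI-only search can stop in local optima on very weak single-gene
  data; the reciprocal design then produces one-sided rejections
  (ambiguous calls), not spurious incongruence, but power suffers.
  Restarts mitigate this at linear cost.
* The wKH implementation equals KH for two-tree comparisons (see
  above); the distinction only matters for larger candidate sets.
* The AU curve fit uses a fixed scale grid; very one-sided datasets
  fall back to bp-RELL calls (flagged in output).
* Coordinate ascent does not guarantee a global model-parameter
  optimum; the joint (alpha, pinv, scale) step removes the dominant
  ridge but extremely short alignments still leave the pair weakly
  identified.
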