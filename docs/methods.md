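# Methods

This note records the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic test systems do and
do not establish.

## Co-regulated gene set estimation

**Model.** A gene co-regulated with the TF is assumed to satisfy
x_g = a_g·x_TF + b_g + ε on an unknown subset of conditions (the
conditions where the regulatory program is active) and to be unrelated to
the TF elsewhere. Repression is expected as well as activation, so
membership uses |r|; the sign of each member's correlation is recorded.

**Algorithm.** Alternating optimisation seeded at the TF gene:

- *Gene step*: select, from all genes in the matrix, those with
  |Pearson r| ≥ `r_init` (default 0.7) against the TF over the current
  condition set. Selection is from the full gene universe each iteration
  rather than a shrinking filter, so genes whose full-matrix correlation
  is attenuated by inactive conditions are recovered once the condition
  set tightens. On the first iteration only, if fewer than `seed_top_k`
  (default 20) genes clear `r_init`, the top-`seed_top_k` genes by |r|
  above 0.7·`r_init` are admitted as a seed: with a strict threshold the
  alternation cannot bootstrap when the active conditions are a minority
  of the matrix, because every true member's full-matrix |r| then sits
  just under the threshold. Final membership always requires |r| ≥
  `r_init` on the final condition set.
- *Condition step*: fit x_g = a·x_TF + b per member gene by least squares
  over the current conditions, average the squared residuals per
  condition across genes, and keep conditions at or below the
  `residual_quantile` (default 0.9) quantile, never dropping below
  `min_conditions_frac` (default 0.5) of all conditions. Dropping uses a
  strict inequality so a flat residual profile is a fixed point.

Iteration stops at a joint fixed point or after `max_iter` (20) rounds.
Correlations are computed pairwise-complete over missing values and
require at least 10 shared observations; zero-variance genes are flagged
and excluded.

**Fitness veto.** When knockout-fitness data are supplied, a gene is kept
only if the |Pearson r| between its fitness profile and the TF's is at
least `r_fit_min` (default 0.5). A veto rather than a weighted score: the
fitness compendium measures a different quantity on different conditions,
so it is used only to discard genes whose organism-level phenotype is
inconsistent with co-regulation.

## Operon-head filtering

Input genes are grouped into maximal runs of genomically adjacent genes
that share strand, have intergenic gaps ≤ `operon_gap` (default 200 bp, a
standard bacterial operon heuristic), have no other annotated gene in
between, and whose consecutive pairs correlate at ≥ `r_adj` (default 0.8).
Only the 5′-most gene of each run is kept (the shared promoter lies
upstream of it); isolated genes pass through. The filter is idempotent
and its output is a subset of its input.

## Motif discovery

**Generative model.** Each upstream sequence carries at most one motif
instance with presence probability `pi` (default 0.8 — the input set is
pre-filtered to likely targets). Given presence, the placement is uniform
over offsets and strands. Instance columns follow an unknown PWM θ with
a symmetric Dirichlet(α=0.5) prior per column; non-instance positions
follow the 0-order genome background. Sequences enter one at a time in
feeding order (descending |r| with the TF), so the cleanest promoters
shape the posterior first; a seeded scrambled order is available for
rerun-based robustness checks.

**Sampler.** A particle is the set of placements made so far plus the
aligned-base counts they imply. For each new sequence, every particle
enumerates {absent} ∪ {(offset, strand)}; a candidate's weight is

  prior(candidate) × DM(word | counts, α)/bg(word) × exp(−λ·D_min(θ̂)),

where DM is the Dirichlet-multinomial predictive of the aligned w-mer,
the background ratio makes weights comparable across widths and sequence
lengths, and D_min(θ̂) is the two-block dissimilarity (below) of the
posterior-mean PWM after tentatively adding the word. The presence mass
`pi` is split uniformly over the 2(L−w+1) placements. One candidate is
sampled per particle; the particle weight multiplies by the candidate
normalising constant (which also accumulates the marginal-likelihood
estimate); systematic resampling triggers when the effective sample size
drops below half the population. With λ = 0 the sampler reduces to
symmetry-agnostic motif discovery, which the tests exploit.

The per-candidate symmetry factor is computed exactly by an incremental
identity: the symmetrised KL between two discrete distributions equals
Σ(p−q)(log p − log q), and adding one site changes at most one count per
column, so per-pair increment tables give every candidate's D_min without
re-forming the PWM. This matches direct recomputation to 1e-9 and is
what makes the per-placement prior affordable.

**Two-block symmetry.** Bacterial TFBS half-sites are typically related
by one of three transforms: reverse complement (palindromic), identity
(direct repeat), or reversal without complement (inverted repeat). The
dissimilarity between core blocks B1 and B2 under a transform T is

  D = (1/c) Σ_j [KL(p_j‖q_j) + KL(q_j‖p_j)]/2,  q = T(B2), in bits,

which is 0 iff the transformed blocks agree exactly — a raw cross-entropy
would not reach 0 and could not serve as a minimised dissimilarity.
During sampling the blocks are the two half-sites [0, c) and [w−c, w)
with c = ⌊w/2⌋; on the final PWM, block location and length are found by
exhaustive search maximising (information content of both blocks) − λ·
(min-over-transforms D), ties to smaller c then leftmost. The symmetry
class is the argmin transform, reported as `none` above a 1.0-bit
threshold; ties break palindromic > direct repeat > inverted repeat.

**Width selection.** One independent SMC family per candidate width
(default 12–24), each with RNG stream `seed + w`. Score = Σ log
normalising constants − (3w/2)·log(n_sites) — a BIC-style penalty with
three free parameters per PWM column, n_sites from the maximum-weight
particle. Ties prefer the smaller width. With 1000 particles the
marginal-likelihood noise is small enough to separate adjacent widths
even for internally periodic palindromes; at a few hundred particles the
selection can wobble by ±1–2 positions, which is why 1000 is the default.

**Failure mode.** If the winning family's maximum-weight particle placed
no sites, the result is the explicit status "no motif found" rather than
a degenerate PWM.

## Genome scanning

Scores are log₂ likelihood ratios against the 0-order genome background
(computed from A/C/G/T counts only; entries below 1e-3 are floored and
the vector renormalised, with a warning). The null score distribution is
obtained exactly by discretising each column's contributions onto a
common grid (default step: score range / 10 000) and convolving the
per-column point masses; site p-values are looked up as the survival
function at the site's discretised score, so a word's p-value is exactly
the background mass of words at or above its grid score. Windows
containing N are skipped and counted. Overlapping +/− hits on the same
window — the normal case for palindromes — collapse to the higher-scoring
strand, ties to +.

Two thresholds gate acceptance: p ≤ 0.001, and a raw-score threshold.
With reference sites available the threshold is the largest value that
still recovers 90% of them; the pipeline uses the discovery stage's own
confident site calls (posterior ≥ 0.5) as that reference, floored at
0 bits (below 0 bits a window is likelier background than motif). Without
any reference the default is 60% of the maximum achievable score. The
p-value filter alone is deliberately loose — on a 50-kb toy genome it
admits ~100 chance windows — and the score threshold does the real work,
which mirrors how the two metrics divide labour at genome scale.

## Regulon assembly

Binding sites are double-stranded objects: each accepted site searches
downstream along the + strand for the nearest + gene and downstream along
the − strand for the nearest − gene, pairing when the gene's start lies
within `max_upstream` (default 300 bp, matching the discovery window) and
the site does not overlap the gene. A site inside an ORF pairs with that
gene as intragenic when enabled (default on — intragenic sites are real
and routinely discarded by ortholog-based methods). A site in a shared
divergent promoter may legitimately pair with both flanking genes. A
`strand_restricted` option searches only the called strand's direction;
it is off by default because the called strand of a palindromic site is
arbitrary. Operon extension appends each paired head gene's downstream
co-operonic genes, sharing the head's site, flagged `via_operon`.
Offsets are reported as the site's 5′ end minus the gene's translation
start, in gene orientation (negative = upstream).

Evaluation against a reference gene set uses TPR = TP/(TP+FN) and
FPR = FP/(FP+TN) over the annotated gene universe, and a ROC utility
re-runs scan+assembly over a descending score-threshold grid.

## Synthetic study systems

The generators are pure functions of (parameters, seed) and write a
ground-truth record beside every fixture.

- `make_pwm`: cores at a given conservation (dominant base probability,
  default 0.85) whose second block is exactly the requested transform of
  the first. The core consensus is rejection-sampled so the three
  transforms differ pairwise at ≥ 2 consensus positions; without this, a
  block that happens to be self-reverse-complementary makes two symmetry
  classes coincide and the classification ill-posed.
- `make_genome`: i.i.d. background sequence; transcription units
  (singletons and operon runs) alternate strand with 600 bp between units
  and 100 bp inside runs, head gene 5′-most. Planted sites are
  PWM-sampled (per-position consensus identity, default 0.9) and placed
  uniformly in the head's 300-bp upstream window, in gene orientation.
  The 600-bp unit spacing guarantees a planted site can pair with only
  its own gene under the 300-bp bidirectional rule, keeping the truth
  assignment unambiguous even for divergent neighbours.
- `make_expression`: TF profile standard normal; members a_g·x_TF + b_g +
  σ·N(0,1) on the active conditions with |a_g| ∈ (1, 2), random sign,
  σ = 0.3 by default; all other cells N(0, 0.3) — log-scale expression of
  unregulated genes and conditions varies modestly. Operon-run members
  copy their head's profile plus N(0, 0.05) noise.
- `make_fitness`: coherent genes share a latent condition response plus
  N(0, 0.1); others independent; condition ids are disjoint from
  expression condition ids.
- The default end-to-end bundle: 50 genes, TF `g000` autoregulating,
  planted regulon = TF + three operons (3+2+2) + five singletons =
  13 genes behind 9 sites, 16-bp palindromic motif at identity 0.9,
  200 expression conditions with the program active on 120, 30 fitness
  conditions.

**What passing on these systems shows — and does not.** The fixtures
have i.i.d. background (no repeats, no GC skew, no codon structure),
exactly one motif per promoter, genuinely linear co-expression, and
operons that perfectly obey the adjacency heuristic. Success here
demonstrates the algorithms are correct and well-calibrated on their own
generative assumptions; it does not certify recovery rates on real
compendia, where background structure, condition-dependent regulation,
and overlapping regulons all degrade the signal.

## Numerical and reproducibility choices

- All randomness flows from one integer seed; per-width SMC streams use
  `seed + w`. Same config + seed reproduces site lists and regulon tables
  byte for byte (fixed float formatting, canonical sort orders).
- Ties everywhere resolve deterministically: consensus ties alphabetical,
  block ties smallest-c/leftmost, symmetry ties in fixed order, site
  strand ties to +, feeding-order ties lexicographic.
- Degenerate inputs: sequences shorter than w force `absent`; an all-N
  genome falls back to a uniform background; an empty reference set makes
  TPR undefined (NaN) rather than zero.
- Problem sizes in the test suite (20×300 bp discovery fixtures,
  2000×200 expression, 50-gene bundles) are desk-scale choices that
  exercise every stage while keeping the whole suite around two minutes.

## Known limitations

- At most one motif instance per sequence; tandem sites in one promoter
  are not modelled.
- One motif per run; co-occurring motifs of other TFs are background.
- 0-order background only; an intergenic-only or higher-order null is not
  implemented.
- The SMC has no rejuvenation move: placements of early sequences are
  fixed once made, so a badly misleading first sequence can bias the
  posterior (mitigated by the feeding order and the particle count).
- The score-threshold chooser assumes the discovery site calls are mostly
  correct; on a failed discovery the 0-bit floor is the only guard.
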