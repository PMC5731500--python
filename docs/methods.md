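# Methods

## Problem and model

chronosite estimates divergence times (node ages) on a **fixed, rooted,
binary species tree** from multi-gene DNA alignments and fossil
calibrations. The unnormalized posterior is the product of four blocks:

1. **Phylogenetic likelihood.** Per gene, Felsenstein's pruning algorithm
   under HKY85 with K discrete gamma rate categories (mean-of-category
   discretization, Yang-style, of a Gamma(α, α) density into K
   equal-probability classes). The generator is scaled to one expected
   substitution per site per distance unit, so a branch's distance is
   `(parent_age − child_age) × branch_rate × category_rate`. Base
   frequencies default to the weighted empirical frequencies of the
   concatenated genes.
2. **Prior of node ages.** Conditional on the root age t_R and n tips, the
   n−2 free internal ages behave as i.i.d. draws from the
   birth-death-sampling (BDS) kernel g(t) with cdf G(t) (parameters: birth
   rate λ, death rate μ, sampling fraction ρ). Calibrated nodes instead
   carry soft-uniform fossil densities, and the remaining ages are
   distributed as the conditional order statistics given the calibration
   ages and their ranks: per inter-calibration segment a factorial term
   h(i) (count of free ages in the segment) and a power term G′(i) (the
   segment's G-mass raised to that count), normalized by (n−2−c)!. With no
   internal calibrations this collapses exactly to Σ ln g. We include the
   (n−2−c)! normalization so the conditional density is properly
   normalized; it is constant during a run.
3. **Rate prior.** Independent-rates relaxed clock: per gene g and branch
   b, ln r_bg ~ Normal(ln μ_g − σ²_g/2, σ²_g), mean-corrected so
   E[r] = μ_g.
4. **Hyperpriors.** Gamma(2, rate 2/m) on κ, α and each μ_g (m = the
   configured initial value, acting as prior mean); Exponential(1) on each
   σ²_g. λ, μ, ρ are fixed from configuration.

Tips are contemporaneous (age 0); ages are in abstract units with the
documented convention 1 unit = 100 Myr. The root **must** carry a
calibration — the BDS density is conditional on t_R and would otherwise be
unanchored.

### BDS kernel in closed form

With r = λ−μ and D(t) = ρλ + (λ(1−ρ)−μ)e^{−rt}:

    g(t) = r² e^{−rt} D(t_R) / (D(t)² (1 − e^{−r t_R}))
    G(t) = (1 − e^{−rt}) D(t_R) / ((1 − e^{−r t_R}) D(t))

computed with `expm1` so the near-critical regime is stable; the λ=μ case
uses its own closed form `G(t) = (1+ρλt_R) t / (t_R (1+ρλt))`, selected
when |λ−μ|·t_R < 1e−12. G is inverted analytically, which is also how
synthetic trees are drawn.

### Calibration densities

One family is supported: soft-uniform bounds. Mass 1−2p is uniform on
[t_L, t_U]; each side carries mass p in an exponential tail with rate
chosen for continuity at the bound. Calibration densities are **not**
truncated to (0, t_R) or renormalized (the tail mass below zero is
negligible for realistic bounds); the prior-of-ages term and the
calibration term are kept as separate factors.

## Subtree site compression

Full-site compression (duplicate columns collapsed with counts) is the
baseline. Because the topology is fixed, each inner node additionally keeps
only the **distinct projections** of the columns onto its own leaf set: a
site lookup table whose row stores, per child, either the leaf's code (a
TPM row index) or the child's own pattern-row index. The root's rows also
carry repeat counts aggregating the full-site weights of all columns
mapping to that root pattern. Partial likelihoods are computed once per
unique subtree pattern instead of once per column.

Implementation notes:

- Construction is one vectorized unique-key pass per node over the pairs
  (left child row, right child row); since child rows are in bijection with
  child subtree patterns, the pair uniquely identifies the concatenated
  leaf-code key. The per-node "hash table" therefore exists only during
  construction; afterwards the lookup tables and row counts are retained
  and the hashes are dropped (they are never queried again).
- Pattern counts obey n_patterns ≤ min(5^(leaves below), s′) with s′ the
  kept full-site-compressed columns, and are monotone up the tree; a cherry
  saturates at (4+1)² = 25 rows (4 bases + 1 unknown/missing code; all
  IUPAC ambiguity codes and gaps map to unknown, U maps to T).
- Tables depend only on data and topology: they are built once and never
  touched by MCMC. Age/rate proposals refresh only the affected branch TPMs
  (computed from a cached symmetric eigendecomposition of the HKY
  generator) and the partials on the path from the changed node to the
  root, with an undo log for exact restoration on rejection.
- **Numerical scaling:** per (pattern, category), whenever the maximum
  partial drops below 1e−100 the vector is rescaled by its maximum and the
  log accumulated; the root combines categories in log space. Verified
  finite and oracle-consistent on 64-taxon balanced trees.
- Taxa absent from a gene get all-unknown rows (probability-one factors)
  rather than per-gene pruned topologies, keeping one compression layout
  per gene.
- The independent oracle (`plain_pruning_log_likelihood`) runs
  column-by-column with no subtree sharing; the two paths agree to 1e−10
  relative on randomized instances including the balanced (best) and
  caterpillar (worst) shapes.

## Incremental prior of ages

The Age Pointer Vector (APV) keeps the n−2 free prior nodes sorted by age
(ties broken by node id; the root is excluded), so rank queries are index
look-ups. Per segment the Conditional Density Vector (CDV) caches ln h(i)
and ln G′(i); the evaluators are position-specialized (first / middle /
last) and static. A proposed age triggers one of four transactions:

1. free node, no calibration rank change → Δ ln g only;
2. free node crossing calibrations → plus the CDV entries bordering each
   crossed calibration (a move past two calibrations touches exactly 3
   entries);
3. calibration node, no rank change → its calibration density, one new CDF
   evaluation, and the two bordering G′ entries (h is untouched);
4. calibration node changing rank → bordering h and G′ entries at both old
   and new positions.

Repositioning is by adjacent swaps. A root-age proposal refreshes every
kernel cache (all g and G depend on t_R); the root is one node, so this
stays cheap. Every transaction keeps an undo snapshot so rejection restores
the state exactly (bitwise, including the cached total). `full_log_prior`
recomputes everything from scratch and is the oracle: after 10,000
randomized transactions the cached value stays within 1e−9 of it.

Index conventions: calibration ranks are 1-based among the n−2 sorted ages;
the last segment's count is n−2−R_{c−1}, which is the only reading under
which the segment counts partition n−2−c and the h-arguments match the
G′-exponents.

## MCMC

Single-parameter Metropolis-Hastings, one step = one full sweep (all
internal ages, all branch rates per gene, per-gene μ_g and σ²_g, then κ and
α). Age proposals are uniform sliding windows reflected into (max child
age, parent age) — reflection keeps the kernel symmetric; the root reflects
only at its lower bound. Positive scalars use log-scale multiplicative
windows with the log Jacobian in the acceptance ratio. Widths are tuned
every 50 sweeps during burn-in toward ~30% acceptance and frozen
afterwards. A `fix_root_age` switch conditions the chain on t_R, used by
the prior-only distributional check (the order-statistics density is
conditional on the root age). Chains are bit-reproducible from the seed.

## Synthetic data

`simulate_tree` draws the n−2 free ages i.i.d. from G⁻¹(uniform) with the
root at 1.0 and merges uniformly chosen lineage pairs in age order — i.e.
exactly the prior the inference assumes, which makes prior-only sampling
and recovery experiments coherent. `simulate_alignment` evolves each site
from a root state drawn from π down every branch by categorical draws from
the TPM rows, with a per-site gamma category; sequence simulation is native
(no external simulator). What this does **not** emulate about real data:
alignment error, indels, ambiguity codes, heterotachy, model
misspecification, per-gene topology conflict — passing recovery tests
therefore demonstrate correctness of the implementation under its own
model, not robustness to violations.

Defaults (the study conditions): HKY κ=2, K=4 gamma categories; α=0.5
(typical empirical heterogeneity); λ=2, μ=1, ρ=0.5 (a moderately sampled
supercritical regime); independent lognormal clock with mean 0.5
substitutions/site/unit (root-to-tip divergence ≈ 0.5) and σ²=0.01
(strict-ish); 20 taxa, 10 genes × 2,000 sites as the reference dataset
size, with recovery runs at 10 taxa, 2 genes × 1,000 sites and a ±5% soft
root bound.

## Problem sizes and tolerances

The checked-in tests and the acceptance script use desk-scale problem
sizes, chosen as the package's own verification protocol: 100 randomized
likelihood instances (4–20 taxa, 10–1,000 sites), 10,000 prior
transactions (5–40 taxa, 0–5 calibrations), 50,000 prior-only sweeps on a
6-leaf caterpillar (per-rank KS < 0.05 against direct simulation), and a
4,000-sweep recovery run. Oracle equivalences are asserted at 1e−10
(relative, likelihood) and 1e−9 (absolute log, prior); distributional and
recovery checks are stochastic but seed-pinned.

## Cross-tool comparison (manual)

A fixture written by `chronosite simulate` can be exported to MCMCTree
(exact-likelihood mode, HKY, independent rates) and the two programs'
posterior mean ages compared with `compare_dates`
(d = 2(d₁−d₂)/(d₁+d₂)); agreement within |d| < 0.005 is the expected
band. This requires the external MCMCTree binary and is a documented
manual procedure, not part of the automated suite.

## Known limitations

- DNA only (5-letter alphabet); no codon/amino-acid models, no partial
  ambiguity resolution.
- Contemporaneous tips only; serially sampled tips are out of scope.
- One calibration family (soft-uniform); no truncation/renormalization of
  calibration densities against (0, t_R).
- Fixed topology by design; no topology proposals.
- The sampler is single-chain; convergence diagnostics beyond seed-to-seed
  comparison are left to external tooling (e.g. arviz on the sample log).
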