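# Methods

## The model

`argtrait` simulates quantitative traits under the standard additive GWAS
model, evaluated directly on an ancestral recombination graph (ARG) held
as succinct tree-sequence tables (nodes, edges, sites, mutations,
individuals; 0-based coordinates, half-open `[left, right)` edge
intervals).

For each trait:

1. **Causal sites.** A number of causal sites is drawn uniformly without
   replacement from the *eligible* sites — those with at least one
   derived allele segregating among the sample nodes (frequency strictly
   inside (0, 1)). Monomorphic-in-sample alleles are rejected rather than
   silently skipped: they carry no association signal, and the frequency
   scaling below is degenerate at p ∈ {0, 1}. Users may instead supply
   the causal sites explicitly (site ids, or a CSV of positions with
   optional alleles and effect sizes).
2. **Causal alleles.** At each causal site one derived allele is chosen
   uniformly among those segregating (an optional frequency-weighted
   choice exists, off by default).
3. **Effect sizes.** A raw effect size β per site is drawn from the trait
   model and scaled by `(2p(1−p))^(α/2)`, where p is the causal-allele
   frequency among sample nodes. α = 0 (the default) is the identity;
   α < 0 up-weights rare variants, which is the usual direction for
   human complex traits. Frequencies are computed over sample nodes only,
   even when internal (pedigree) nodes belong to individuals, because
   allele frequency is a sample-level quantity in the GWAS model.
4. **Genetic values.** At each causal site, every node of the local tree
   that inherits the causal allele carries a genetic value equal to the
   scaled β; a node under a more recent mutation to a different allele
   (a back-mutation) carries zero. An individual's genetic value G is
   the sum of its nodes' values, accumulated over causal sites.
5. **Environmental noise.** E is drawn i.i.d. per individual and trait
   from Normal(0, V_G(1−h²)/h²), where V_G is the *population* variance
   (denominator n) of the genetic values and h² ∈ (0, 1] the requested
   narrow-sense heritability. The phenotype is G + E, computed once so
   the decomposition is exact. No re-standardisation of the total
   phenotypic variance is performed.

## Allele-state resolution and the carrier traversal

A node's allele at a site is the derived state of the most recent
mutation on its path to the root, else the ancestral state. Mutations
stacked on one node are ordered by their parent-mutation links when they
form a complete chain, otherwise by mutation time (most recent =
smallest time); if neither orders them the input is rejected as
ambiguous. Sample nodes isolated from the local tree at a site take the
ancestral state — a documented choice, exercised in tests.

Carrier nodes are found without decoding genotypes: the traversal starts
from every state-change point whose resulting allele equals the causal
allele (each mutation to it, and the parentless nodes when the causal
allele is ancestral) and descends, pruning at any child that carries its
own mutation — that child's subtree is covered by its own traversal
exactly when its state is causal. The cost per site is proportional to
the causal subtree. Per-individual accumulation is
`scaled_beta × (carrier-node count)` per site, summed in ascending site
order, which makes results bit-reproducible and exactly equal to the
genotype-dosage sum `G = Σ_s β_s g_s`.

## Trait models

Five univariate effect-size distributions are provided — normal, fixed,
exponential, gamma, student-t — plus the multivariate normal for
pleiotropic traits (one joint draw per causal site, shared across the k
traits; scaling by the site's frequency factor is applied to the joint
vector after the draw). Exponential and gamma draws are sign-symmetrized
by default (multiplied by ±1 equiprobably), since effect sizes must admit
negative values. The student-t draw is a standard-t variate scaled to the
requested variance and shifted by the mean; df ≤ 2 is rejected (infinite
variance). Covariance matrices must be symmetric positive semi-definite
(checked by eigenvalue).

## Randomness and reproducibility

A single master seed is expanded with numpy's `SeedSequence` into
substreams in a fixed order — site selection, allele choice, effect
sizes, then environmental noise — so changing a late-stage parameter
(e.g. h²) never perturbs earlier draws, and the one-shot `sim_phenotype`
is bit-identical to calling the three stages manually with the spawned
sub-seeds. The fixed model is deterministic regardless of seed.
Environmental noise is independent across traits: pleiotropy enters only
through the effect-size covariance.

## Parameters that matter

| parameter | meaning | default | why |
|---|---|---|---|
| `num_causal` | causal sites drawn uniformly | 1 | smallest meaningful architecture; users scale it up |
| `alpha` | frequency-dependence exponent | 0 | no frequency dependence unless requested |
| `h2` | narrow-sense heritability (per trait) | 0.3 | a typical complex-trait value; h²=1 gives zero noise, h²=0 is rejected since the noise variance formula divides by h² |
| `random_sign` (exp/gamma) | symmetrize one-sided draws | on | effect sizes must admit both signs |

With V_G = 0 and h² < 1 the noise variance formula gives 0, so the noise
is zero rather than an error. Individuals with no associated nodes are
emitted with G = 0 rather than dropped.

## Synthetic ARGs

The test fixtures are generated in `argtrait.fixtures`:

* `make_fig1()` — the canonical worked example: six diploid sample leaves
  a–f (ids 0–5) in three individuals, internal nodes g–k (ids 6–10) with
  topology `k → (g → (a,b), i → (h → (c,d), j → (e,f)))`, one site with
  ancestral A, a mutation to T above i and a back-mutation to A above e.
  The defining facts (who carries T, frequency 0.5, e reverts) pin the
  fixture only partially; this branching order is one consistent choice,
  frozen so all tests agree.
* `make_random_arg(n_samples, n_sites, n_trees, stacked_mutation_rate,
  seed)` — independent random binary merge topologies laid side by side
  (so `n_trees − 1` recombination breakpoints), exponential-ish node
  times, one mutation per site on a random non-root branch (so every
  site segregates), and optional stacked mutations on proper-descendant
  branches producing back-mutations and multiallelic sites.

These generators reproduce the *structural* features the simulator must
handle — recombination, stacked and back mutations, diploid (or
arbitrary-ploidy) individuals, pedigree-embedded internal nodes — but
not population-genetic realism: no demography, no linkage between the
local trees, and a uniform rather than neutral-coalescent site-frequency
spectrum. Passing tests therefore certify the bookkeeping and the
calibration formulas, not any claim about realistic allele-frequency
architectures. An optional `make_coalescent_arg` wraps msprime for
larger integration checks; nothing requires it.

## Numerical choices

* Population variance (denominator n) for V_G.
* Accumulation over causal sites in ascending site order; per-site
  individual contributions as β × dosage. Results are bit-reproducible
  for a given input and seed.
* Eligibility and frequency computations use exact comparisons on
  resolved allele strings; no floating-point tolerance is involved in
  genetic values apart from ordinary summation.
* Local trees and resolved state maps are memoised per ARG (tables are
  treated as immutable after construction).
* Mutation ordering ambiguity, non-PSD covariances, degenerate
  frequencies and out-of-range heritabilities are hard errors naming the
  offending field.

## Problem sizes used in the checks

The oracle-equivalence suite runs 100 random ARGs of up to ~200 nodes
and 20 sites with recombination and stacked mutations. The heritability
recovery check simulates 10⁴ diploid individuals (2×10⁴ samples, 100
causal sites) and averages the realized Var(G)/Var(P) over 20 noise
seeds; distribution moment checks use 10⁵ draws. These sizes give
4-standard-error (moment checks) or ±0.03 (heritability) resolution
while keeping the whole suite under a minute.

## Known limitations

* Additive effects only: no dominance deviations or epistasis.
* No shared-environment terms, covariates, or liability-threshold binary
  traits; noise is Gaussian by construction.
* No LD-aware or annotation-aware causal-site placement.
* The CLI covers univariate models only; multivariate-normal pleiotropy
  is available through the Python API (vector/matrix parameters do not
  map cleanly onto flags).
* The TSV dialect stores alleles as single strings and does not support
  tskit metadata columns; conversion to/from `.trees` preserves logical
  content but canonicalises edge ordering.
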