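# argtrait

Quantitative-trait and phenotype simulation directly on ancestral
recombination graphs (ARGs).

## Why

GWAS method development needs ground-truth data: simulated genotypes plus
phenotypes generated under a known genetic architecture. Modern
population-genetic simulators and ARG inference methods produce their
output as succinct tree sequences — a tabular encoding of the ensemble of
genealogical trees along the genome — which is compact enough for
biobank-scale cohorts. Exporting genotype matrices from such an ARG just
to feed a phenotype simulator is slow, enormous, and throws away the
ancestral information the ARG exists to keep. `argtrait` simulates the
phenotypes on the ARG itself, without ever decoding a genotype matrix.

## Model

Each trait has one or more **causal sites**. At a causal site with causal
allele frequency *p*, a raw effect size β is drawn from a chosen
distribution (normal, fixed, exponential, gamma, student-t, or a
multivariate normal for pleiotropic traits) and optionally scaled by

    β ← β · (2p(1−p))^(α/2)

where α sets the strength of frequency dependence (α < 0 up-weights rare
variants; α = 0 leaves β untouched). Every node of the local tree that
inherits the causal allele — found by traversing down from the causal
mutation and pruning at back-mutations — carries a genetic value of β.
Under the additive model an individual's genetic value *G* is the sum of
its nodes' values over all causal sites. Environmental noise is drawn
i.i.d. from

    E ~ Normal(0, V_G (1 − h²) / h²)

where *V_G* is the population variance of the genetic values and *h²* is
the user-supplied narrow-sense heritability, and the phenotype is
*G + E*. In expectation the realized heritability Var(G)/Var(G+E) equals
the request.

## Worked example

Three diploid individuals (six sample genomes a–f), one site with
ancestral allele A, a mutation to T on the branch above internal node i,
and a back-mutation to A above leaf e — so samples c, d and f carry the
causal allele T at frequency 0.5:

```python
import argtrait as at

arg = at.make_fig1()                         # or at.load_arg("data.trees")
model = at.trait_model("fixed", value=0.05)
result = at.sim_phenotype(arg, model, h2=0.8, random_seed=1)
print(result.trait.to_string(index=False))
print(result.phenotype.to_string(index=False))
```

```
 site_id  position causal_allele  raw_beta  scaled_beta  allele_freq  trait_id
       0      50.0             T      0.05         0.05          0.5         0

 individual_id  trait_id  genetic_value  environmental_noise  phenotype
             0         0           0.00             0.050739   0.050739
             1         0           0.10             0.022575   0.122575
             2         0           0.05            -0.025633   0.024367
```

Individual 0 (nodes a, b) carries no copy of T, so *G* = 0; individual 1
(c, d) carries two copies, *G* = 2 × 0.05 = 0.10; individual 2 (e, f)
carries one copy — e reverted to A through the back-mutation — so
*G* = 0.05. The phenotype of each individual is its genetic value plus
the simulated noise, whose variance is calibrated so that the heritability
is 0.8 in expectation.

The same run from a shell:

```sh
argtrait --arg fig1.tsv --model fixed:value=0.05 --h2 0.8 --seed 1 --out out/
```

writes `out/trait.csv`, `out/phenotype.csv` and a `run_log.json`
recording the seed, parameters and version.

The modular stages are available individually for power users
(`sim_trait` → `genetic_values` → `sim_env`), so causal sites and effect
sizes can also be supplied from a CSV produced by any other tool.

## Documentation

`docs/methods.md` describes the model, its parameters and defaults, the
synthetic-ARG generators used in testing, and the package's numerical
choices and limitations.
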