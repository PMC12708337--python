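# mitocongruence

Phylogenetic-congruence analysis for partitioned mitochondrial genome
alignments.

The 15 genes of an animal mitogenome (13 protein-coding + 2 rRNA) are
physically linked on one circular chromosome, yet their phylogenetic
signals frequently disagree. This package implements the complete
analysis chain for quantifying that disagreement and relating it to
genome biology, for systematists and molecular evolutionists working
with partitioned mitogenome matrices:

* a **TIM2+G+I likelihood engine** (Felsenstein pruning with
  discrete-gamma rates and invariant sites) exposing per-site
  log-likelihood vectors;
* per-partition **ML tree search** (random start, NNI hill climbing)
  and Fitch **parsimony** machinery;
* the **topology-test battery** — bp-RELL, p-KH, p-wKH, p-SH, p-wSH,
  c-ELW and p-AU, all driven by one RELL bootstrap of per-site
  log-likelihoods — plus the parsimony-based **ILD** permutation test;
* the **reciprocal congruence design**: gene pair (A, B) is called
  *incongruent* when each gene's data reject the other gene's tree,
  *congruent* when neither direction rejects, *ambiguous* otherwise;
* the four experiment designs built on it: **pairwise** 15 x 15
  summary matrices, **antigene** (leave-one-out) matrices,
  **functional-category** comparisons (CO / ND / AT / rRNA), and taxon
  **subsampling**;
* **OR-distance regression**: per-gene incongruence counts regressed
  on the gene's replication distance from its strand's origin of
  replication, per strand;
* a **synthetic mitogenome generator** with vertebrate and insect gene
  maps and controllable planted discordance (none, discordant block,
  or an OR-distance-linked gradient), so the entire analysis runs with
  no downloads.

## Worked example

Simulate a 12-taxon vertebrate-layout dataset in which ND4 and ND5
evolve on a shared rearranged topology, then test two informative
pairs:

```python
from mitocongruence.simulate import SimulationScenario, generate_dataset
from mitocongruence.workflows import pairwise_matrix, congruent_proportion
from mitocongruence.toptests import TestConfig

scenario = SimulationScenario(
    n_taxa=12, layout_template="vertebrate",
    scenario="block_discordant", lam=6.0, move_kind="SPR",
    block_genes=("ND4", "ND5"), length_scale=0.5, seed=42,
)
ds = generate_dataset(scenario)
cfg = TestConfig(b_reps=1000, restarts=1, optimize_rates=False,
                 final_rounds=1)
m = pairwise_matrix(ds.data, cfg, seed=1,
                    genes=["COX1", "CYTB", "ND4", "ND5"])
for a, b in m.cells:
    print(a, b, m.call(a, b, "p_au"))
print("congruent proportion (AU):",
      congruent_proportion(m, "p_au"))
```

prints

```
COX1 CYTB congruent
COX1 ND4 incongruent
COX1 ND5 incongruent
CYTB ND4 incongruent
CYTB ND5 incongruent
ND4 ND5 congruent
congruent proportion (AU): 0.3333333333333333
```

exactly the planted structure: the two block genes agree with each
other but conflict with the two clean genes, which agree with each
other, so 2 of the 6 unordered pairs are congruent.

The same analyses are available from the shell
(`mitocongruence pairwise --n-taxa 12 --scenario block_discordant
--lam 6 ...`; see `mitocongruence --help`), and the numbered scripts
under `analysis/` run the package's replicated simulation studies
(engine verification, test calibration and power, workflow signature
recovery, OR-gradient recovery), writing tables under `results/`.

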