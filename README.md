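# hybridexpress

Inheritance-mode classification and trait association for hybrid-family
RNA-seq counts.

## The problem

When two divergent parents are crossed, each gene in an F1 hybrid can express
at the level of one parent (dominant), midway between them (additive), or
outside the parental range entirely (transgressive).  Mapping these
inheritance modes genome-wide — and linking expression to phenotypes such as
pest-damage severity — is a standard design in plant breeding and evolutionary
transcriptomics: sequence two parents and a set of F1 progeny over a time
course, count reads per gene, and ask for every gene how the hybrid level H
relates to the parental levels P1 and P2.

`hybridexpress` implements that analysis for small-replicate biparental
families:

* **Exact test for NB counts.**  Read counts are modelled as negative
  binomial with variance μ + φμ².  After scaling counts to a common library
  size, the sum of n i.i.d. NB(μ, φ) counts is NB(nμ, φ/n); conditioning on
  the two-group total T = A + B leaves a split distribution A | T that is
  free of μ and can be enumerated exactly.  Two-sided p-values sum the
  probabilities of all splits no more likely than the observed one; φ = 0
  reduces to the Poisson/binomial limit.  A single common φ is estimated by
  maximizing the conditional likelihood of within-group splits across genes.
* **Six inheritance modes.**  At FDR α (default 0.01, Benjamini–Hochberg) the
  three contrasts P1 vs P2, H vs P1, H vs P2 are reduced to significance
  flags and fold-change signs, then classified: conserved (P1 ≈ H ≈ P2),
  P1-dominant (H ≈ P1, H ≠ P2), P2-dominant (H ≈ P2, H ≠ P1), additive
  (P1 < H < P2 or the reverse), overdominant (H above both), underdominant
  (H below both); anything else is ambiguous.  Summaries per time point
  (family-averaged over F1 genotypes if classified per genotype) and per
  chromosome in 12 equal-gene-count positional bins.
* **Gene–trait association.**  Genotype-level trait means are regressed on
  per-genotype mean log2-CPM; each gene gets the Manhattan score
  R² × −log10(p) with the genome-wide Bonferroni threshold −log10(α/n).
  Co-expression modules are summarized by their eigengene (first principal
  component of the z-scored member submatrix) and correlated with traits;
  the comparative-Ct helper 2^−ΔΔCt supports qPCR validation.
* **Synthetic families with ground truth.**  A generator emulating the
  2-parent / 7-F1, 4-time-point, 3-replicate design plants known inheritance
  classes, genome positions over 19 chromosomes, unequal library sizes, and a
  causal co-expression module driving a trait — so every stage is testable
  end to end.

## Worked example

```python
import numpy as np
from hybridexpress import (SimulationConfig, simulate_family, simulate_traits,
                           filter_cpm, InheritanceModel, TraitAssociationModel)

cfg = SimulationConfig(n_genes=300, causal_module_size=20, time_points=(0, 6), seed=42)
counts, samples, annotation, truth = simulate_family(cfg)
counts = filter_cpm(counts)                      # CPM > 1 in >= 50% of samples

results = InheritanceModel(counts, samples, annotation).fit(alpha=0.01)
print(results.summary())

traits = simulate_traits(truth, counts, samples, effect=1.0, noise_sd=0.25, seed=42)
assoc = TraitAssociationModel(counts, samples, traits, annotation).fit()
print(assoc.summary())
```

prints

```
Inheritance-mode classification
  FDR alpha: 0.01   rule: literal   F1 handling: pooled
  genes classified: 300

 time_point  P1_dominant  P2_dominant  additive  overdominant  underdominant  conserved  ambiguous
          0           54           48        11            14             14        158          1
          6           57           47         9            13             15        158          1

Gene-trait association (score = R^2 x -log10 p)
  genes: 300   alpha: 0.05   genome-wide threshold: 3.7782
  damage_severity: 10 genes pass; top gene00003 (score 4.969, R^2 0.954)
```

The simulation planted 55% conserved genes plus a 20-gene causal module whose
genotype-level activity drives the trait: the classifier recovers the planted
class mix at both time points, and the top-scoring genes (all above the
Bonferroni threshold −log10(0.05/300) ≈ 3.78) are members of the causal
module.  `results.calls` holds the per-gene calls,
`results.bin_by_chromosome()` the 12-bin positional summary, and
`assoc.manhattan_table("damage_severity")` a plotting-ready
chromosome/position/score table.

The same workflow is scriptable from a shell:

```sh
hybridexpress simulate --out data --n-genes 300 --seed 42
hybridexpress classify --counts data/counts.tsv --samples data/samples.tsv \
    --bed data/genes.bed --out calls
hybridexpress associate --counts data/counts.tsv --samples data/samples.tsv \
    --traits data/traits.tsv --bed data/genes.bed --out assoc
hybridexpress detest --counts data/counts.tsv --samples data/samples.tsv --out de
```

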