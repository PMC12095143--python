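# dosagenet

Dosage-weighted network pharmacology for multi-herb prescriptions.

Network pharmacology models a traditional-medicine prescription as a
drug–metabolite–target–disease graph and reads its mechanism off the
network's hubs. Standard practice treats every herb equally — yet
prescriptions dose their components very unequally, and the dose ratio
is part of the recipe. `dosagenet` builds **paired** networks for each
prescription — a conventional unweighted one and one whose edges carry
the standardized dosage ratios — predicts key targets and drug targets
from (weighted) degree centrality in both, runs hypergeometric pathway
over-representation on each prediction, and quantifies how much the
dosage information changed the analysis.

It is written for researchers studying herbal formularies and, more
generally, dosage effects in drug combinations.

## The method

For a prescription with gram doses `g = (g₁ … gₙ)` (historical Fen /
Qian / Liang units are converted per dynastic standard: 1 Liang =
10 Qian = 100 Fen; 1 Fen = 0.4 g Song-Yuan, 0.37 g Ming-Qing), the
standardized dosage vector is

```
x = g / min(g)          (so min(x) = 1),     y = (1, …, 1)
```

`x` weights the dosage network's drug-incident edges (metabolite→target
edges inherit the summed dosages of the metabolite's parent drugs); `y`
defines the non-dosage variant. Targets with weighted degree strictly
above the target-layer mean are *key targets*; those also in the
disease gene list are *drug targets* (sets S₁ from the non-dosage and
S₂ from the dosage-weighted network). Four indicators measure the
difference the dosage made:

| indicator | definition | side |
|---|---|---|
| Dedis | ‖x − y‖₂ | input |
| DeSD | sd(x) (sample SD; sd(y) ≡ 0) | input |
| DeDT | 1 − J(S₁, S₂) on drug targets | output |
| DePy | 1 − J(S₁, S₂) on enriched pathway sets | output |

with J the Jaccard similarity; `compound_Dedis`/`compound_DeSD` are the
input indicators at the metabolite level. Zero Dedis forces zero output
change; positive Dedis permits it without forcing it — Dedis, not DeSD,
is the operative signal of whether dosage will alter the prediction.

## Worked example

The Chong He powder prescription — one Fen of Bai Yao Zi, one Fen of
Gan Cao, one Qian of Xiong Huang (Song-Yuan units) — ships as a
self-contained fixture with a small synthetic component map:

```python
from dosagenet import chong_he_fixture, compare_prescription, standardize

bundle = chong_he_fixture()
print(standardize(bundle.records).values)
panel = compare_prescription(
    bundle.records, bundle.maps, bundle.disease_targets,
    bundle.gene_sets, min_genes=bundle.min_genes,
)
print(panel)
```

prints

```
(1.0, 1.0, 10.0)
IndicatorPanel(dedis=9.0, desd=5.196152422706632,
               compound_dedis=12.727922061357855,
               compound_desd=4.3172381043286805,
               dedt=0.75, depy=0.6666666666666667)
```

The doses [0.4 g, 0.4 g, 4 g] standardize to [1, 1, 10], at Euclidean
distance 9 from the all-ones input. Weighting moves the drug-target set
from {T0, T4} to {T0, T2, T3}: the shared core survives and the
ten-fold-dosed Xiong Huang's targets enter, so the two predictions
differ by DeDT = 1 − 1/4 = 0.75, and the enriched-pathway sets by
DePy = 1 − 1/3 ≈ 0.67.

The same pipeline is available from the shell:

```
dosagenet simulate --seed 1 --out bundles/ --n-prescriptions 94
dosagenet batch --bundles-dir bundles/ --out-dir results/
dosagenet standardize prescription.csv
dosagenet compare bundle_dir/ --out-dir out/ --min-genes 1
dosagenet enrich --targets genes.txt --gmt sets.gmt --out enrich.tsv
```

`batch` writes one indicator row per prescription plus a JSON report of
median-split Wilcoxon comparisons (input indicators between low/high
output-change groups; dosage SD and total dose between small/large
prescriptions) and Pearson correlations.

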