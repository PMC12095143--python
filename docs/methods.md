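# Methods

## The model

A multi-herb prescription is represented as a four-layer undirected
graph: botanical drugs → bioactive metabolites → protein targets →
disease. Two variants of this network are built for every prescription
and their predictions compared.

**Dosage standardization.** Each drug's dose is converted to grams and
divided by the smallest gram dose in the prescription, giving a
dimensionless ratio vector `x` with `min(x) = 1`. Historical units are
converted with the dynastic standards (1 Liang = 10 Qian = 100 Fen; one
Fen is 0.4 g under the Song-Yuan standard and 0.37 g under the
Ming-Qing standard). Because only ratios survive, multiplying every dose
by a constant — or re-expressing the prescription in a finer unit —
changes nothing downstream; this scaling invariance is asserted by a
property test. Mixed units within a prescription are allowed, mixed
dynasties are not (the two gram standards differ), and there is no
default dynasty. Count or volume doses ("50 grains") are rejected, not
coerced.

**Edge weights.** The non-dosage variant is defined as the pipeline
evaluated at the all-ones vector `y`. In the dosage-weighted variant,
each drug→metabolite edge carries the drug's component of `x`, and each
metabolite→target edge carries the combined dosage of the metabolite's
parent drugs. The combination rule is summation by default (a metabolite
contributed by two drugs counts both sources), with `max` available as an
alternative. A consequence worth noting: when a metabolite is shared by
several drugs, even the all-ones vector produces metabolite→target
weights above 1 (the parent count). We accept this rather than force
unit weights, because the defining contract of the method is exact
coincidence of the two variants at equal dosages, which this
construction guarantees bit-for-bit. Target→disease edges always have
weight 1.

**Target prediction.** A target is a *key target* when its weighted
degree strictly exceeds the mean weighted degree; the averaging
population is the target layer by default (key targets are selected
among targets), with an all-nodes option for sensitivity analysis. Ties
at the mean are excluded. Key targets intersected with the
disease-associated gene list give the *drug targets*.

**Enrichment.** Drug targets are tested for over-representation in each
gene set of a GMT collection with the exact hypergeometric upper tail
P(X ≥ k). The universe defaults to the union of the collection's sets
(overridable). Pathways with p < 0.05 and at least 10 overlapping genes
are reported; both thresholds are configurable (small hand-built
collections need `min_genes` lowered — the worked-example fixture uses
1). No multiple-testing correction is applied by default; a
Benjamini–Hochberg option exists but changes the default behaviour of
nothing.

## The four indicators

Input side, comparing `x` against `y`:

- **Dedis** = ‖x − y‖₂, the Euclidean distance. Zero iff all doses are
  equal.
- **DeSD** = sd(x), the sample standard deviation (n−1 denominator).
  Since sd(y) ≡ 0, sd(x) is itself the difference in spread.

Their metabolite-level variants (`compound_dedis`, `compound_desd`)
apply the same definitions to the metabolite dosage vectors, in which
each distinct metabolite carries the summed standardized dosages of its
parent drugs (deduplicated, lexicographically ordered for
reproducibility). The reference is the metabolite expansion of `y` —
not a literal all-ones vector — because shared metabolites make that
expansion non-uniform; `compound_desd` is the absolute difference of the
two standard deviations. This keeps the defining invariant: every
indicator is exactly zero for an equal-dosage prescription.

Output side, comparing the two variants' predictions with
1 − Jaccard similarity (both in [0, 1]):

- **DeDT** on the two drug-target sets;
- **DePy** on the two enriched-pathway id sets.

Two identical empty sets count as difference 0 (identical outputs mean
no difference); the 0/0 case is otherwise undefined.

Zero Dedis forces zero DeDT and DePy (the networks coincide), but
positive Dedis only permits output change — re-weighting can leave the
above-average set intact. The test suite asserts both the necessity
direction and the existence of Dedis > 0, DeDT = 0 cases.

## Statistics

Group comparisons use the two-sided Wilcoxon rank-sum test: the exact
permutation null when the combined sample is ≤ 12 with no ties
(threshold configurable), otherwise the normal approximation with
midranks, tie correction and continuity correction. Correlations are
Pearson product-moment with the t-transform p-value (n−2 df). Median
splits label items strictly above the sample median "high"/"more" and
the rest "low"/"less"; the median is the midpoint convention for even n.
The batch report median-splits prescriptions on each output indicator
and compares each input indicator between groups, splits on drug count
to compare dosage SD and total gram dose, and reports the
(Dedis, DeSD) and (drug count, DeSD) correlations.

## Synthetic data

No herb-chemistry database, disease-gene list or pathway annotation is
redistributable, so all inputs are fabricated:

- **Worked example.** The Chong He powder prescription (one Fen of Bai
  Yao Zi, one Fen of Gan Cao, one Qian of Xiong Huang; Song-Yuan
  units; ratio vector [1, 1, 10]) with a hand-built component map of 5
  metabolites (one shared), 7 targets, 5 disease genes and 5 gene sets
  over a 20-gene universe. The map is constructed so that weighting
  promotes the ten-fold-dosed drug's targets: drug targets move from
  {T0, T4} to {T0, T2, T3}, giving DeDT = 0.75 and DePy = 2/3. Some
  sources give the composition as 1 Liang / 1 Qian / 1 Qian instead;
  both readings yield the same [1, 1, 10] ratio vector, and the fixture
  uses the Fen/Fen/Qian record.
- **Ensembles.** A seeded generator samples a shared synthetic
  "database" (40 drugs with 2–6 metabolites each from a pool of 80,
  each metabolite hitting 2–8 of 300 genes) plus a disease list (30% of
  the universe — large relative to a genome-wide fraction, chosen so
  drug-target sets and enrichment overlaps are non-degenerate at this
  pool size) and 20 pathways of 10–40 genes, each drawing half its
  genes from the disease list so over-representation can occur. Default
  ensemble: 94 prescriptions of 2–12 drugs, per-drug dose ratios
  log-uniform on [1, 99] (matching the order of magnitude of dose
  spreads seen in historical formularies), with exactly
  `round(null_fraction·n)` = 19 equal-dosage null prescriptions.
  Identifiers are synthetic (D…/M…/G…) and imply no real biology.
- **Dosage patterns.** Besides the default i.i.d. log-uniform pattern,
  `monarch` doses a single chief drug above a unit base, and
  `monarch_fixed_sd` scales the chief drug's dose excess with √(drug
  count) so the sample SD is the same (up to log-normal noise of scale
  `sd_noise = 0.02` around `sd_level = 3`) for every prescription. The
  latter is a deliberate sensitivity construction: it makes the dosage
  SD uninformative about output change while the Euclidean distance
  still varies, demonstrating that the distance, not the spread, is the
  operative signal. The noise scale is kept small because the noise
  enters the chief-drug dose itself and larger values re-couple the SD
  to the output difference.

What the generator does **not** emulate: real chemistry (no structural
filtering — bioactive-metabolite selection is assumed applied upstream),
realistic degree distributions of protein-interaction data, curated
pathway hierarchies, or any historical dosage-efficacy signal. Passing
tests therefore show the pipeline's internal contracts — exact null
equivalence, scaling invariance, the necessity direction, the
qualitative distance→output coupling — not that dosage-weighted
predictions are biologically superior on real data.

## Numerical choices and degenerate inputs

- Conversions and standardization are done in double precision with no
  rounding; standardized minima are exactly 1 by construction.
- Strict `>` against the mean for key targets: an all-equal-degree
  target layer yields an empty key set, hence empty drug-target sets in
  both variants and DeDT = 0 by the both-empty convention.
- Indicator table serialization keeps full float precision; percent
  display is formatting only.
- Degenerate median splits (one empty group, e.g. an all-null ensemble)
  skip the rank-sum test and record a warning instead of failing.
- Enrichment ties in p are broken by pathway id for deterministic
  output; query genes outside the universe are dropped with a logged
  warning.
- Ensemble generation is fully deterministic given the seed (one
  `numpy` Generator, sorted iteration everywhere, no hash-order
  dependence).

## Problem sizes

The default ensemble (94 prescriptions against a 300-gene universe) runs
the full double pipeline including enrichment in a few seconds; the
brute-force oracles in the test suite (exhaustive hypergeometric
enumeration to N = 12, full rank-sum permutation enumeration to group
size 6, 1,000-replicate null calibration) are sized to stay desk-scale
while still covering every parameter combination they claim.

## Known limitations

- The sum propagation rule for shared metabolites is a declared
  convention, not an established fact about herb chemistry; `max` is
  provided as an alternative and results with heavy metabolite sharing
  should be read with that in mind.
- Degree averaging over the target layer (vs all nodes) is likewise a
  convention; both options are exposed.
- Dataset-level magnitudes reported for any particular historical corpus
  (indicator ranges, specific correlations and p-values) depend on that
  corpus and its upstream databases and are not reproducible from
  synthetic data; only sign-level, qualitative analogues are asserted
  here.
- The disease layer is a single merged node; per-disease resolution is
  out of scope.
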