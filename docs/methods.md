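# Methods

## Triallelic genotype model

The two common pathogenic *HFE* variants are modelled as alternative
alleles of a single locus (wild type, C282Y, H63D), so every individual
occupies exactly one of six genotype classes and the compound heterozygote
has Hardy-Weinberg frequency `2·p_C·p_H`. This deliberately excludes a
cis C282Y–H63D haplotype: the two changes essentially never co-occur on
one chromosome, and the triallelic treatment is what makes predicted
compound-heterozygote frequencies products of allele frequencies.
Predicted genotype frequencies (`p_C²`, `2·p_C·p_H`) are used in place of
observed homozygote counts throughout, because allele-frequency estimates
draw on the ~20-fold more numerous heterozygotes and are correspondingly
more precise.

## Penetrance-weighted combined risk

`risk = pen_hom·p_C² + pen_cmpd·2·p_C·p_H`, with defaults
`pen_hom = 0.56` and `pen_cmpd = 0.06` — cumulative incidence of clinical
iron overload to age 80 in European-heritage males. Simple heterozygotes
and H63D homozygotes carry zero risk in this model. Female penetrance is
lower and has no consensus value, so a female model must be constructed
explicitly; every risk report carries the penetrance label to prevent
silent mixing of models. `solve_p_c282y` inverts the quadratic to recover
the allele frequency implied by a published risk figure, which is how the
demo scenario reconstructs regional frequencies from the printed risk
column.

## Statistical tests

* **HWE check** per variant collapses the third allele into "other" and
  runs the three-genotype Pearson χ² against expectations from the sample
  allele frequency (1 df, upper-tail p). A monomorphic sample is rejected
  as degenerate rather than reported as χ² = 0.
* **Between-region comparisons** use the 2×2 allele-count Pearson χ²
  without continuity correction. One-sided p-values follow the
  direction-matching half-p convention: half the two-sided p when the
  observed difference matches the stated alternative, otherwise one minus
  that half; exactly equal frequencies give p = 0.5.

## Prevalence arithmetic

Raw prevalence is `100·count/denominator`; "1 in N" uses
round-to-nearest. Counts released rounded to increments of 5 are used
as-is — no de-rounding correction — matching how the published prevalences
were computed. No age or sex standardisation is applied; strata are
opaque labels. The deprivation-decile spread is `(max/min − 1)·100`,
rounded to the nearest percent.

Discrepancy ratios are computed at full precision and rounded only for
display; when reproducing a published comparison table, the convention is
to recompute ratios from that table's own printed columns, since
full-precision prevalence shifts some ratios by ±0.01 at the second
decimal. The interpretation of a high ratio as under-diagnosis assumes
penetrance is uniform across regions; environmental modifiers of iron
loading are a recognised caveat that the reports state but do not model.

## "One in N" formatting

N = round(1/f) (round-half-even). Below 1000 the integer is printed as-is;
in the thousands it is shown at two significant figures with a `k` suffix
(16,309 → `16k`, 2,703 → `2.7k`); at a million and above with an `M`
suffix. A zero frequency has no finite reciprocal and prints `inf`.

## Ancestry clustering

**DBSCAN** (2-D Euclidean) counts the point itself towards `min_pts`.
Clusters are connected components of core points under the within-`eps`
relation, numbered by their smallest member id; a border point joins the
cluster of its smallest-id core neighbour. This tie rule makes the
labelling a pure function of the point set, independent of input order,
and is enforced in tests by equality against a brute-force
density-reachability closure oracle on instances of up to 50 points.

**IBD graph**: segments with length strictly between 3 and 30 cM are
summed per pair into edge weights. The lower bound removes unreliable
short-segment calls; the upper bound removes close relatives, whose
sharing reflects pedigree rather than population structure.

**Community detection** is a Leiden-style optimiser written in the
package: queue-based greedy local moving, a refinement phase in which only
singleton sub-communities may merge within their community, and
aggregation, repeated until weighted modularity (resolution default 1.0)
stops improving, followed by a final local-moving pass on the flat
partition so that no single node move can improve the objective. Node
visiting order comes from the seed; candidate communities are scanned in
sorted order with a strict 1e-12 improvement threshold, making results
reproducible. The returned objective is recomputed from the final
membership with an independent modularity routine, and tests cross-check
both the objective (against networkx) and the partition (against the
`leidenalg` reference implementation on planted-partition graphs).
Annotation is majority vote of reference labels per community; exact ties
produce a joint slash-separated name and communities without references
are `"unlabelled"`.

## Synthetic data

The generators emulate the statistical structure of the restricted
individual-level inputs:

* **Genotypes**: per-region six-class multinomial draws at the region's
  allele frequencies. Defaults in tests use the study-scale frequencies
  (C282Y 0.078, H63D 0.151).
* **Diagnoses**: each individual is coded with probability
  `penetrance(class) × ascertainment(region)`; counts optionally rounded
  to the nearest 5 (half-counts round away from zero), so a released
  count is never more than 2.5 from the truth. Ascertainment is a
  modelling convenience for generating under-diagnosis patterns, not an
  estimate from data; age structure is ignored because the comparison
  uses all-ages prevalence.
* **PC clouds**: one isotropic Gaussian per group plus uniform background
  noise.
* **IBD segments**: per-pair Poisson segment counts with planted
  community rates (within 2.0, between 0.05 segments/pair in the standard
  scenario) and lengths uniform on the open interval (3, 30) cM.

What the generators do **not** emulate: linkage disequilibrium, genotype
error and missingness patterns, realistic IBD length distributions
(exponential-like decay), spatially continuous admixture, or age/sex
structure in diagnosis. Passing tests therefore demonstrate correctness
of the estimators and algorithms under their stated assumptions, not
robustness to real-data artefacts.

## Problem sizes and numerics

Simulation-based checks use 1,000 replicate cohorts of n = 1,000 for the
HWE test-size calibration, n = 100,000 for allele-frequency recovery
(3-standard-error bound), n = 200,000 for the ascertainment experiment,
200 random instances of ≤50 points for the DBSCAN oracle comparison, and
five planted communities of 60 for community recovery — sizes at which
the Monte-Carlo error is comfortably inside the asserted bounds while the
whole suite stays fast. The demo pipeline simulates 20,000 individuals
per region. Frequencies are validated to sum to one within 1e-12;
degenerate statistical inputs (zero expected counts, zero variance, zero
prevalence) raise typed errors or return explicit `None`/`inf` sentinels
rather than propagating NaNs.

## Known limitations

* Exact HWE tests, confidence intervals on frequencies and multi-locus LD
  are out of scope.
* Published regional "1 in N" risk figures derive from unrounded
  supplementary frequencies; recomputing them from headline-rounded
  inputs can differ in the last digit, so validation of the risk formula
  uses direct arithmetic identities instead.
* The VCF layer handles exactly the two canonical biallelic sites;
  multi-allelic records, BGEN/PLINK formats and liftover are unsupported.
* Choropleth rendering is out of scope; the pipeline exports plain
  region-value CSV for external GIS tools.
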