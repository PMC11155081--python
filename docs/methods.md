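# Methods

## The consistency model

A SNP in linkage disequilibrium r² with a causal variant carries a
non-centrality that scales with r²: if the causal variant's association
statistic is χ², the linked SNP's expected statistic is r²·χ². On the
−log₁₀(p) scale this translates, to good approximation for moderately strong
signals, into the linear prediction

    ŝ = s_max · r²,

where s_max is the −log₁₀(p) of the group's top SNP. A group of SNPs tagging
one real signal therefore falls near this line; genotyping artifacts have
significance unrelated to their LD and scatter away from it. The mean
absolute error

    MAE = Σₖ |sₖ − ŝₖ| / K

over the K group members (the top SNP included; its residual is identically
zero) quantifies the deviation, and regions containing at least one
LD-corroborated group with MAE below threshold are prioritized.

The approximation deliberately ignores the finite-sample noise of both the
p-values and the r̂² estimates; the MAE threshold (default 3.0 log units)
absorbs that noise. Both scores use base-10 logarithms, the Manhattan-plot
convention.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 0.05 | a SNP is "significant" when p < threshold (strict) |
| `max_gap_bp` | 5,000 | chaining distance between consecutive significant SNPs |
| `min_significant` | 10 | minimum significant SNPs for a region to be kept |
| `r2_threshold` | 0.4 | LD cut for group membership (strict, r² > cut) |
| `mae_threshold` | 3.0 | prioritization cut (strict, MAE < cut) |
| `min_group_size` | 2 | members needed for a group's MAE to qualify a region |
| `flank_bp` | 5,000 | region extension on each side before gene overlap |
| QC | 10% missingness, MAF ≥ 1%, HWE p ≥ 1e−4 | variant/sample filters |

Boundary semantics are strict everywhere: MAF exactly 0.01 and HWE p exactly
1e−4 are retained, p exactly 0.05 is not significant, MAE exactly 3.0 is not
prioritized.

### Why `min_group_size` exists

A group with a single member has MAE identically zero — the top SNP always
sits on its own prediction line — so a singleton carries no LD corroboration
whatsoever. Because every significant SNP that fails the r² cut against every
existing anchor ends up anchoring its own (possibly singleton) group, counting
singletons would prioritize any dense cluster unconditionally and the method
would never discard anything. A group must therefore contain at least one SNP
*besides* its anchor for its MAE to count. Singleton groups are still formed,
reported and listed in the region report; they simply do not qualify a region
on their own.

### Other algorithmic choices

- **Chaining** distance is measured between significant SNPs only;
  non-significant SNPs neither bridge nor break chains, but every SNP inside
  the final boundaries is reported with the region.
- **Group formation** is iterative greedy re-anchoring: the strongest
  unassigned same-direction SNP becomes the next anchor. Ties on −log₁₀(p)
  break by smaller position, then lexicographic SNP id, so results are
  deterministic across platforms.
- **SNPs with OR exactly 1** belong to neither direction class; they are
  reported in the region but never grouped or scored.
- **MAE is computed over significant SNPs only** (config-gated alternative:
  all region SNPs via `score_all_region_snps`). The selection step precedes
  consistency evaluation, and sub-threshold SNPs would otherwise dilute the
  score with members the region was never anchored on.
- **r²** is the squared Pearson correlation of unphased additive dosages over
  pairwise-complete samples (allele-count r², as PLINK 1.9 reports for
  unphased data), not the EM-haplotype r². LD is computed on the combined
  case+control panel by default; a pairs file can substitute. Undefined LD
  (monomorphic site, fewer than two complete pairs, unknown id) is a NaN
  sentinel, distinct from 0: it propagates through ŝ and MAE, and a group
  with sentinel MAE can never qualify — the method fails safe rather than
  fabricate consistency.

## Upstream statistics

- **QC order**: non-autosomal variants → sample missingness → variant
  missingness → MAF → HWE, each tallied in the report.
- **HWE** uses the conditional exact test with the probability-ordering
  two-sided rule (sum of all heterozygote configurations no more probable
  than the observed one, given the allele counts). The chi-square
  approximation misbehaves exactly at the rare-variant margin where the 1%
  MAF cut operates. Evaluated on all samples by default, controls-only on
  request.
- **Association** is a per-variant additive logistic regression
  (logit P(case) ~ dosage + covariates) fitted by Newton/IRLS: at most 25
  iterations, coefficient-change tolerance 1e−8, Wald two-sided p-value.
  Fits that do not converge (the usual symptom of complete separation),
  produce a singular information matrix, or diverge are dropped with a
  logged count rather than reported. Principal components and sex enter as
  ordinary pre-computed covariate columns; the package does not compute PCA.
- **Genomic inflation factor** λ = median(χ²_observed)/median(χ²_null) with
  χ² = quantile transform of p at 1 df; the null median is computed from the
  chi-square distribution at run time, not hard-coded.

## The synthetic-data generator

The generator emulates the data regime the method targets: a small
case-control cohort (default 35 cases / 478 controls; "power runs" scale the
same 35:478 ratio to 2,000 samples, i.e. 136/1,864), common variants in
haplotype blocks, one planted causal variant, and artifact spikes.

- **LD blocks**: within a block, a latent standard-normal AR(1) chain with
  per-step correlation `block_r2_decay` (default 0.95) is thresholded at each
  site's allele-frequency quantile; two haplotypes sum to a dosage. Each
  block draws a base frequency U(0.05, 0.5) with ±0.01 per-site jitter —
  variants on a shared haplotype background have near-equal allele
  frequencies, and strongly unequal thresholds would destroy dosage LD even
  at perfect latent correlation. Blocks are independent, > 50 kb apart, with
  within-block spacing < 5 kb so chained regions can never span blocks.
- **Phenotype**: disease odds exp(α + log(OR)·dosage) at the causal variant
  (default OR 3); cases are drawn without replacement with probability
  proportional to those odds. This retrospective (case-control) sampling
  yields exact class counts while preserving the dosage log-OR up to the
  intercept — the recovery tests confirm the planted log-OR is recovered
  within ±3 SE in ≈98% of runs. With OR = 1 the phenotype is independent of
  every dosage.
- **Isolated spikes** model sporadic genotyping artifacts: independent base
  variants > 50 kb from everything, corrupted by phenotype-correlated
  miscalls whose strength is bisected (≤ 30 iterations) until the marginal
  Wald p lands at a log-uniform target inside `spike_p_range`, by default
  (1e−30, 0.04). Artifact significance is unrelated to LD, so the default
  range spans the whole scale from barely significant to far beyond
  genome-wide significance — the regime in which artifact towers dominate
  small-cohort WGS scans.
- **Clustered stress stack** (`spike_clustered`) models one systematically
  miscalled locus: a single base signal across a 5 kb window (latent decay
  1.0), the *same* samples miscalled at every site (a shared corruption
  ordering), with per-site penetrance calibrated as above. The stack is in
  tight mutual LD and ≥ 10 of its members are significant, so a region always
  forms. Because graded penetrance of a shared artifact re-creates a
  p-vs-r² relationship, the operational "significance decoupled from LD"
  condition is produced by `permute_pvalues_in_window`, which shuffles the
  (OR, p) pairs within the window while keeping positions and genotypes —
  the canonical negative control for the consistency score.

Everything is deterministic under `SimulationConfig.seed`.

### What the generator does not emulate

Recombination-map realism, population structure and admixture, allele
frequency spectra below 5%, genotype missingness patterns, and read-level
error processes are all out of scope. Passing tests on this generator
demonstrate the algorithmic contracts (chaining, grouping, scoring,
calibration) and the method's discrimination between LD-consistent and
LD-decoupled significance — not performance on any particular real cohort.

## Measured behavior and problem sizes

The test suite and `scripts/acceptance.py` run at desk scale, chosen to keep
a full run on one CPU within a couple of minutes: scans of ~240 variants ×
2,000 samples (25–100 replicate seeds), a 5,000-variant null genome, 10⁶
p-values for λ calibration, and an exhaustive HWE sweep over all genotype
tables with ≤ 200 samples. Under these conditions the causal region is
recovered in ≥ 90% of seeds, isolated spikes never survive (a single SNP
cannot meet the 10-significant minimum), and permuted stacks are rejected in
≥ 90% of seeds.

## Known limitations

- **Weak signals always look consistent.** Every residual is bounded by
  s_max, so any group whose top SNP has p > 10⁻³ satisfies MAE < 3
  automatically. Region formation (≥ 10 significant SNPs within 5 kb
  chaining) is then the only effective filter; occasionally a correlated null
  block crosses it by chance and is prioritized as a weak stack. On a
  5,000-variant null genome this happens roughly once per run — comparable,
  per SNP, to the region rate real scans report — and such regions are
  recognizable by their weak top SNPs. The MAE criterion discriminates
  strong stacks, not weak ones.
- **Small groups are chance-consistent.** A 2–3 member group's MAE falls
  below 3 with high probability under the null; after permutation, loosely
  linked clusters can splinter into such groups and escape rejection. The
  `min_group_size` floor removes only the singleton case.
- **A graded systematic artifact mimics a true signal.** If one error process
  hits the same samples across a window with penetrance that decays along the
  window, the induced p-values correlate with LD exactly as a real signal's
  would, and no summary-level consistency score can tell them apart.
- **Regions of weak LD cannot be prioritized**: hypervariable loci where
  pairwise r² rarely exceeds the 0.4 cut produce only small or singleton
  groups, so true signals there are invisible to the method.
- The logistic fitter drops separated variants rather than applying a
  penalized (Firth-type) correction; with very few cases and rare alleles
  this discards some genuinely associated variants.
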