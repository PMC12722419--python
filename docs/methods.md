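# Methods

This note records the model underlying `umevo`, the default parameter
choices and why they were made, what the simulator does and does not
emulate, and the numerical decisions that matter for reproducing its
outputs.

## 1. Generative model of a synthetic cohort

Each patient is drawn independently from the following chain
(`umevo.simulate.simulate_cohort`, one `numpy.random.default_rng(seed)`
stream for the whole cohort, so cohorts are bitwise reproducible):

1. **Gene-expression class.** `class ~ Bernoulli(class1_fraction)` with
   default `class1_fraction = 0.628`.
2. **Founder Gq mutation.** Every tumor receives exactly one clonal,
   heterozygous hotspot mutation with gene probabilities
   GNAQ 0.489, GNA11 0.465, PLCB4 0.022, CYSLTR2 0.012 (a second Gq event
   with probability 0.005, modelling rare co-occurrence).
3. **BSE event.** Conditional on class:
   Class 1 → none 0.38, BAP1 0.035, SF3B1 0.225, EIF1AX 0.36;
   Class 2 → none 0.10, BAP1 0.80, SF3B1 0.07, EIF1AX 0.03
   (second BSE event with probability 0.023). This yields marginal carrier
   fractions near BAP1 ≈ 0.32, SF3B1 ≈ 0.16, EIF1AX ≈ 0.25 at the default
   class mix.
4. **Tumor size.** Thickness/diameter are drawn per class (Class 2 larger),
   with gene-specific shifts; "small" means thickness ≤ 2.5 mm **and**
   diameter ≤ 12 mm, both inclusive. About 10 % of tumors are small, and
   small tumors are Class-1-enriched by construction.
5. **Purity.** Small tumors: mean 0.586; larger: mean 0.819. The source
   figures for those means are standard errors over large cohorts, not
   spreads; backing population SDs out of them (≈0.35/0.25) would pile
   mass at the truncation bounds, so the package uses SD 0.15 (small) and
   0.10 (larger), truncated to [0.10, 1]. This is a package choice.
6. **3p state.** BAP1-mutant tumors: retention 0.15, loss 0.70,
   isodisomy 0.15; BAP1-wild-type tumors are almost always 3p-intact.
7. **CCFs.** BAP1 CCF ~ Beta(6, 2) (near-clonal with a subclonal tail,
   chosen a priori); SF3B1/EIF1AX CCFs trend upward with tumor size.
8. **Discriminant score.** A latent variable
   `z = −1 + 2.6 · deficit · (1 − e^{−t/24}) + N(0, 0.25)` driven by the
   BAP1 dosage deficit and months since BAP1 loss (proportional to
   diameter); the reported `dscore = clamp(|z|, 0, 1)`. The drawn class
   gives the side of the boundary; sign/class mismatches are the
   discordant, possibly-in-transition tumors. Population means: small
   Class 2 ≈ 0.51 vs larger Class 2 ≈ 0.71.
9. **Outcome.** Exponential metastasis-free and overall survival with
   class- and driver-dependent hazards, administratively censored at 96
   months.

### Read models

Expected VAF at sequencing depth D (reads ~ Binomial(D′, E[VAF]) with
lognormal depth noise, SD 0.10):

| locus | `paper_consistent` | `copy_aware` |
|---|---|---|
| heterozygous autosome | p·c/2 | p·c/2 |
| BAP1 with 3p loss | p·c | p·c/(2−p) |
| BAP1 with isodisomy | p·c | p·c |
| male X (EIF1AX) | p·c | p·c |

where p is purity and c the CCF. `paper_consistent` inverts the CCF
estimator exactly (zero structural bias); `copy_aware` mixes the tumor and
normal allele pools explicitly, so the estimator applied to a clonal BAP1
mutation under 3p loss recovers ≈ 1/(2−p) instead of 1 — a real bias of
the field's estimator that the simulator makes measurable.

The 3p SNP panel (74 loci, 1–89 Mb, 20 % dropout to homozygous loci,
panel depth 300×) has expected mirrored BAF 0.5 under retention,
1/(2−p) under loss and **(1+p)/2 under isodisomy** — the isodisomy value
follows from counting allele copies (tumor cell contributes two copies of
one haplotype; a normal cell one of each) and differs from the loss value
at any p strictly between 0 and 1. Depth is scaled by (2−p)/2 under loss
and unchanged otherwise.

## 2. Estimation chain

* **Purity.** TP = min(2·VAF<sub>Gq</sub>, 1) from the highest-VAF
  pathogenic Gq mutation (ties break in the canonical order
  GNAQ > GNA11 > PLCB4 > CYSLTR2). Capping is flagged; absence of a Gq
  mutation is a flagged state, not an error.
* **CCF.** corrected VAF = VAF/TP, left uncapped; values > 1 are flagged
  inconsistent and capped only in the final CCF. Multipliers: SF3B1 ×2;
  EIF1AX ×2 (female) / ×1 (male); BAP1 ×2 under 3p retention, ×1 under
  loss or isodisomy (both treated as fully clonal LOH). BAP1 CCF is left
  undefined when no LOH call of confidence ≥ 2 exists.
* **LOH3p.** Per informative locus: mirrored BAF = max(b, 1−b) and
  lfc = log2(depth/normals). Whole-arm call: loss iff median BAF ≥
  threshold and median lfc < −0.15; isodisomy iff median BAF ≥ threshold
  and |median lfc| ≤ 0.15; retention otherwise. The threshold is the
  purity-aware LOH expectation 1/(2−TP) − 0.08 (fixed 0.60 when purity is
  unknown) — a literal BAF = 1 rule would miss LOH at any realistic
  purity. Confidence 0–3 requires both MAD(BAF) and MAD(lfc) within
  level-specific bounds and enough loci, so adding noise or removing loci
  can never raise it.

## 3. Statistics

* Categorical contrasts: chi-square without continuity correction, unless
  ≥ 25 % of expected cell counts are < 5, then Fisher exact
  (scipy for 2×2; for r×c a seeded Monte-Carlo conditional test using
  Patefield sampling of fixed-margin tables with the chi-square ordering
  statistic, since no installed library provides the exact network
  algorithm).
* Continuous contrasts: two-tailed Mann–Whitney rank-sum.
* Survival: lifelines Kaplan–Meier, log-rank, and Cox (Efron ties); a
  singular or separated Cox design raises `CoxConvergenceError` instead of
  returning unstable estimates, and < 5 events per covariate warns.
* Matching: greedy nearest-neighbour 3:1 propensity matching without
  replacement on tumor thickness and diameter (logistic propensity,
  caliper 0.2 × SD of the logit), with standardised mean differences
  before/after.
* Power: the Monte-Carlo simulation draws exponential event times anchored
  to the stated horizon survivals, censors administratively at the
  horizon, and applies an own vectorised two-group log-rank statistic
  (unit-tested to ≤ 1e-8 relative agreement with lifelines); 10,000
  replicates run in ~2 s.

### The power discrepancy

For the 25-vs-85 design with 5-year survivals 0.90 vs 0.70, the Schoenfeld
events-based closed form
Φ(√(d·p₁·p₂)·|ln HR| − z<sub>0.975</sub>) gives 0.772 (HR 3.385, d ≈ 28
expected events). Exact simulation of the identical design gives ≈ 0.52,
confirmed by two independent implementations (lifelines in Python, and
`survival::survdiff` in R). The closed form's d·p₁·p₂ term assumes events
split across arms in proportion to the allocation, which is valid only for
hazard ratios near 1; at HR ≈ 3.4 roughly 91 % of the events fall in one
arm and the approximation overstates power badly. The package therefore
reports the simulated value as the power estimate and exposes the closed
form separately as a cross-check (`schoenfeld_power`); the acceptance test
asserting their agreement fails by design and is documented as such.

## 4. What the simulator does and does not emulate

Emulated: the ordered Gq → BSE → LOH3p driver sequence and its
mutual-exclusivity structure, class/size/purity/score relationships,
read-level sampling noise at realistic depths, annotation-score spectra
per gene, and censored survival.

Not emulated: real sequencing artefacts (mapping error, strand bias,
FFPE damage), germline variation beyond panel-SNP heterozygosity,
subclonal copy-number beyond whole-arm 3p, treatment effects, and
competing risks. SGE joins are exercised on synthetic tables only; the
published mappability/depletion fractions depend on an external database
and are not reproduced.

## 5. Numerical and testing choices

* All stochastic behaviour flows through explicit `numpy` Generators; no
  global seeding.
* Problem sizes in the test suite (cohorts of 80–2000, 200 panels per LOH
  state, 20 seeds for direction-of-effect, 50 seeds for Cox recovery) were
  chosen to keep the full suite within a few minutes on one CPU while
  leaving statistical margins of ≥ 3 SE on every calibrated assertion.
* Test oracles (hypergeometric enumeration for Fisher, exact permutation
  for small-sample log-rank, allele-pool counting for panel expectations,
  binomial error propagation for CCF accuracy bounds) were computed before
  the corresponding expected values were frozen.

## 6. Known limitations

* CCF mean absolute error for ×2-multiplier allelic models at depth 1000×
  is ~0.035 per model by error propagation (σ per sample ≈ 0.045); pooled
  per gene it is < 0.03. Claims tighter than that are not attainable
  without deeper sequencing.
* The LOH caller treats LOH as whole-arm and clonal; focal or subclonal
  3p events will be miscalled or dropped to low confidence.
* The transition-state classifier is a rule on the discriminant score and
  BAP1-pathway evidence, not a trained model; its threshold (0.2) is a
  reporting convention.
* Direction-of-effect checks on small Class 2 tumors are limited by the
  subgroup size (~10 per 1000 patients); the planted direction reproduces
  in ~88 % of seeds, not more, at that size.
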