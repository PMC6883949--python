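# Methods

This note documents the models, conventions and numerical choices behind
`lncnet`, and what the synthetic cohort does and does not emulate.

## Phenotype-based group assignment

Energy-corrected milk for the pre-slaughter week is
`ECM_w = ((0.37·F% + 0.21·P% + 0.95)/3.1)·MY_7d` (F%, P% fat and protein
percentages, MY_7d the 7-day milk yield in kg). The formula is the standard
energy-correction of milk yield; the divisor 3.1 converts the energy
content multiplier back to kg of energy-corrected milk, so ECM is linear in
yield.

RFI is defined as the ordinary-least-squares residual of energy intake on
an intercept, average daily gain (ADG) and metabolic mid-weight
(MMW = mean body weight of months 17–18 to the power 0.75). The regression
form is the minimal standard RFI model; additional covariates (e.g. year)
can be handled upstream by residualizing intake before the call. Residuals
sum to zero and are orthogonal to the predictors; a singular design
(constant or collinear ADG/MMW) raises instead of silently pseudo-inverting.

Selection rules: bulls are high-efficiency if RFI ≤ mean − 1 SD and
low-efficiency if RFI ≥ mean + 1 SD (boundary ties satisfy the criterion,
reading "at least one SD" inclusively), with positive daily gain not below
mean − 1 SD required; cows are high if ECM_w > 140 kg with carcass fat
below the cow mean + 1 SD, low if 14 ≤ ECM_w ≤ 40 kg with carcass fat above
the cow mean − 1 SD, and all cows require calving interval < 540 days,
age ≤ 1,510 days and no pathology flag. Population moments may be supplied
(a reference herd) or computed from the records at hand.

## Expression filters

FPKM is `fragments · 1e9 / (library size · exonic length in bp)`; the log
transform is `log2(FPKM + 0.001)`. Three filters with deliberately distinct
semantics:

* **Global abundance:** mean FPKM strictly above 0.2 in at least one
  tissue ("> 0.2" is read strictly), with structural-RNA biotypes (rRNA,
  snoRNA, snRNA, Y-RNA, SRP-RNA) excluded outright.
* **DE count filter:** within a tissue, at least 10 fragments in at least
  10 individuals (both bounds inclusive).
* **Above-tissue-average:** a gene passes for a tissue when its mean log2
  abundance exceeds the grand mean over genes of per-gene tissue means
  (strict; shift-invariant). The network-stage variant requires this in at
  least one tissue.

All filters are idempotent.

## Tissue-enriched (TS) genes

A gene is TS in tissue *t* when every other tissue mean is below half the
across-tissue average of its four tissue means and the focal mean exceeds
that average plus one SD (SD across the four tissue means, not across
samples — the criterion compares tissues). The rule is applied to log2
means as they are. An alternative convention that first shifts means to a
non-negative scale was considered and rejected: with a +10 shift the
"half the average" condition degenerates (it then demands the focal tissue
exceed roughly five times the shifted off-tissue level, which no realistic
log2-FPKM profile meets), and it contradicts the direct arithmetic of the
defining example (means (10,1,1,1) → TS in tissue 1). Because the rule is
not shift-invariant, results depend on the overall abundance scale; this
is inherent to the criterion, not an implementation artefact.

## Stand-in differential expression test

The built-in DE test is Welch's t on covariate-residualized log2 FPKM with
Benjamini–Hochberg adjustment per tissue, selecting q < 0.05 (strict). It
is a stand-in for a negative-binomial count model: it shares the contract
(per-gene p/q, covariate adjustment for sex and year) but not the
dispersion modelling, and external DE tables can be supplied instead.
Under the null its type-I error is calibrated (≈ 5% at nominal 5%,
verified over 2,000 null genes in the acceptance suite). Constant genes
get p = 1.

## RIF

For regulator *i* and target *j*, with within-condition target means
`e1_j, e2_j` (condition 1 = high efficiency), within-condition Pearson
correlations `r1_ij, r2_ij`, `PIF_j = ½(e1+e2)(e1−e2)` and
`DW_ij = r1_ij − r2_ij`:

    RIF1_i = (1/n) Σ_j PIF_j · DW_ij²
    RIF2_i = (1/n) Σ_j [(e1_j·r1_ij)² − (e2_j·r2_ij)²]

RIF1 weights squared differential wiring by the targets' phenotypic
impact; RIF2 contrasts squared abundance-weighted predictive ability
between conditions. Only the verbal definition of the two metrics is fixed
by the workflow lineage, so each formula lives in its own function and can
be swapped for published variants. Conventions: condition labels are fixed
by configuration (swapping them flips the sign of both raw metrics and
leaves |z| ranks unchanged); z-standardization is per metric per tissue
(mean 0, SD 1; SD = 0 yields all-zero z); significance is |z| ≥ 1.96
(two-sided 95% normal coverage) on either metric; self-pairs (a regulator
that is also a target) are excluded from the average; constant expression
vectors correlate 0 with a warning.

## PCIT

For every unordered pair (x, y) and conditioning gene z the three
first-order partial correlations define the tolerance
`ε = ⅓(r_xy·z/r_xy + r_xz·y/r_xz + r_yz·x/r_yz)`, and (x, y) is eliminated
if some z gives |r_xy| < |ε·r_xz| and |r_xy| < |ε·r_yz|. A single
explaining trio suffices. Trios with a near-zero raw correlation
(|r| < 1e-12; the ε ratio is undefined) or a unit correlation (the partial
is undefined) never eliminate a pair. With n = 2 every off-diagonal pair is
significant. The implementation vectorizes the O(n³) loop per conditioning
gene; a plain-Python exhaustive-trio reference (`pcit_mask_bruteforce`) is
kept as an independent oracle and the two agree exactly on randomized
instances (asserted for n ≤ 12 in the unit suite and on 50 instances in
the acceptance suite).

One property worth stating explicitly: the tolerance is *relative*, so a
strong indirect edge need not be eliminated. In an exact chain
r_xz = r_yz = 0.9, r_xy = 0.81, the partial r_xy·z ≈ 0 drives its ratio to
≈ 0, ε ≈ 0.49, and 0.81 > 0.49·0.9 — the x–y edge survives. The algorithm
is permissive for strongly correlated trios by construction; group
exclusivity and the |r| > 0.8 strength filter, not PCIT alone, carry the
burden of specificity in the network stage.

Expression vectors for PCIT concatenate all samples (animal × tissue) of a
condition, since the network stage runs across tissues; a per-tissue mode
is available by subsetting columns before the call.

## Networks and hubs

Edges are materialized only between significant-RIF lncRNAs and
prioritized genes, when the pair is PCIT-significant in exactly one
condition and that condition's |r| exceeds 0.8 (strict; configurable). The
high and low edge sets are disjoint by construction and asserted on every
run. Connectivity counts distinct partners; hubs require strictly more
than 100. Node tables cover edge endpoints only. Exports: SIF, GraphML
(with node category flags and edge r/group attributes), edge-list TSV.

## Metabolites

Metabolites with more than five missing animals are dropped; remaining
missing values are imputed with the metabolite's observed minimum
(missingness treated as below-detection); each metabolite is divided by
`sqrt(Σx²/(n−1))` without centering (the common "scale without centering"
convention). Preprocessing is idempotent and Pearson correlations are
invariant to it. Hub–metabolite correlation uses the tissue where the hub
lncRNA is most abundant (argmax of mean FPKM), log2 expression per animal,
p from `t = r·√((n−2)/(1−r²))` with n−2 df, and selection at p ≤ 0.05
(inclusive; the threshold is a parameter).

## Enrichment

Over-representation uses the hypergeometric upper tail `P(X ≥ k)` over a
declared universe (default: prioritized genes plus retained metabolites),
BH across sets. Genes and metabolites share one query list through
namespaced identifiers (`gene:`, `met:`). No numerical comparability with
proprietary pathway tools is claimed.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 48 animals
(24 per sex; 25 high / 23 low, i.e. 12♂+13♀ vs 12♂+11♀), four tissues
(jejunum, liver, muscle, rumen), DE planted in the first three tissues
only, lncRNAs drawn systematically lower-expressed than mRNAs, 640
metabolites with ~8% missing-completely-at-random entries, and planted
regulator lncRNAs whose correlation to their target module is
`wiring_r_high` in the high group and `wiring_r_low` in the low group.

Log2 expression is baseline + tissue offset + covariate effects + group
effect + wiring + N(0, noise_sd) noise; counts are Poisson with mean
FPKM × length_kb × library/1e6 (library sizes uniform in 40–55 M
fragments, echoing the targeted sequencing depth; gene lengths uniform in
500–10,000 bp — both conventions, not data-derived facts). Wiring is
implemented through an animal-level latent factor per module; the target
loading is `β = r·σ/√(1−r²)` so the within-group regulator–target
correlation equals the configured r. All randomness flows from one root
seed through named substreams (layout, expression, counts, metabolites,
missingness, phenotypes, QTL).

Deliberate idealisations, and what they imply about the tests:

* **Planted modules are clean.** Planted regulators and targets carry flat
  tissue profiles, no sex/year effects, and enter the prioritized set via
  QTL intervals placed over the targets rather than via planted DE.
  Without this, covariate and DE-shift variance attenuates the realized
  cross-tissue correlation below the configured wiring (≈ 0.78 instead of
  0.80), i.e. the wiring parameter would not mean what it says. Passing
  recovery tests therefore demonstrate the method's behaviour at a known
  true correlation, not robustness to confounded modules.
* **Matched bull pairs.** Bulls are efficiency-contrast pairs sharing ADG
  and body weights with equal-and-opposite planted RFI, making the planted
  vector exactly orthogonal to the intake regression design; realized
  residuals reproduce the planted separation and group assignment recovers
  the generating labels exactly. Real cohorts have no such matching and
  their RFI rankings are noisier.
* **TS genes are pinned near-silent off-tissue** (absolute log2 FPKM ≈ −2)
  because the half-the-average rule is not shift-invariant and the
  FPKM back-transform introduces a global abundance offset.
* Not emulated: read-level artefacts, alignment/assembly noise, batch
  effects beyond a sex and year column, fractional counting, metabolite
  annotation structure, and any real linkage between QTL positions and
  expression.

Default problem sizes (1,000 loci, 200 lncRNAs, 4 regulators × 30 targets)
are chosen so a full pipeline run takes seconds and the whole test suite a
few minutes on one CPU while leaving every stage non-trivially populated;
they are one to two orders of magnitude below a real transcriptome.

## Edge recall at the strength threshold

With true wiring r = 0.8 equal to the strict |r| > 0.8 edge threshold and
~100 concatenated samples per group, each planted edge's sample correlation
is approximately N(0.8, 0.036²), so individual edges clear the threshold
with probability ≈ ½ and a 120-target regulator reaches an expected
exclusive degree near 55–60 — below the > 100 hub bar, whose attainment at
this operating point would require true wiring ≈ 0.84 or more. This is a
property of thresholding at the true correlation, not an implementation
limit; the hub-recovery property test therefore uses clearly separated
wiring (0.9 vs 0.0), where all planted regulators become group-exclusive
hubs, while the acceptance suite also records the behaviour at 0.8.

## Determinism

Reports are plain-text tables with fixed 6-significant-digit float
formatting and sorted ordering; two runs with the same seed are
byte-identical, which the acceptance suite asserts by hashing both output
trees.
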