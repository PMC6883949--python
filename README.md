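# lncnet

Network-based prioritization of candidate regulatory long non-coding RNAs
(lncRNAs) from multi-tissue RNA-seq of two contrasting physiological
conditions — high versus low metabolic efficiency in cattle. The package is
aimed at quantitative geneticists and systems biologists who want a tested,
reproducible implementation of the RIF + PCIT differential co-expression
workflow, together with a synthetic cohort generator with planted ground
truth so every stage can be validated without access to a real cohort.

## The pipeline

1. **Phenotype groups.** Cows are ranked by energy-corrected milk for the
   week before slaughter, `ECM_w = ((0.37·F% + 0.21·P% + 0.95)/3.1)·MY_7d`,
   bulls by residual feed intake (RFI), the residual of energy intake
   regressed on average daily gain and metabolic mid-weight
   `MMW = (mean body weight, months 17–18)^0.75`. Selection rules (±1 SD of
   RFI; ECM_w > 140 kg vs 14–40 kg with carcass-fat, calving-interval and
   age conditions) split the cohort into high/low efficiency groups.
2. **Expression.** Fragment counts → FPKM → `log2(FPKM + 0.001)`, with a
   0.2-FPKM minimal-abundance filter, a 10-fragments-in-10-individuals
   filter ahead of differential expression, and above-tissue-average
   abundance filters ahead of the correlation stages.
3. **Prioritized gene set.** Union of differentially expressed genes
   (q < 0.05, Benjamini–Hochberg), tissue-enriched genes, genes physically
   overlapping RFI/milk-yield QTL, and positional lncRNA candidates
   (≥ 200 nt, multi-exonic or mono-exonic antisense), minus structural-RNA
   biotypes.
4. **Regulatory impact factors.** For regulator *i* and target *j*, with
   within-condition target means `e1_j, e2_j`, phenotypic impact factor
   `PIF_j = ½(e1_j+e2_j)(e1_j−e2_j)` and differential wiring
   `DW_ij = r1_ij − r2_ij`:

       RIF1_i = (1/n) Σ_j PIF_j · DW_ij²
       RIF2_i = (1/n) Σ_j [(e1_j·r1_ij)² − (e2_j·r2_ij)²]

   Scores are z-standardized per metric within a tissue; |z| ≥ 1.96 calls a
   regulator significant.
5. **PCIT networks.** For every gene pair (x, y) and third gene z, the
   first-order partials of the trio define a tolerance
   `ε = ⅓(r_xy·z/r_xy + r_xz·y/r_xz + r_yz·x/r_yz)`; the pair is dropped if
   some z satisfies |r_xy| < |ε·r_xz| and |r_xy| < |ε·r_yz|. Edges between
   significant-RIF lncRNAs and prioritized genes that are PCIT-significant
   in exactly one condition with |r| > 0.8 form the condition-exclusive
   networks; lncRNAs with > 100 partners are hubs.
6. **Metabolite integration and enrichment.** Plasma metabolites
   (> 5 missing animals dropped, minimum-imputed, scaled without centering)
   are Pearson-correlated with each hub lncRNA in its most abundant tissue
   (p ≤ 0.05 selected); each hub's correlated genes and metabolites are
   tested for over-representation in user-supplied GMT sets
   (hypergeometric upper tail, BH across sets).

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_assign_groups.py
python analysis/03_run_network_pipeline.py
python analysis/04_evaluate_recovery.py
```

The default synthetic cohort has 48 animals (24 bulls, 24 cows; 25 high /
23 low), four tissues, 1,000 loci with 200 lncRNAs, four planted regulator
lncRNAs wired to 30-gene target modules at r = 0.8 in the high group and
r = 0 in the low group, and 640 metabolites with 8% missingness. The run
prints, among others:

```
group assignment: {'high': 25, 'low': 23}
agreement with generating labels: 100.0%
                    metric  numerator  denominator  fraction
     rif_planted_recovered          4            4     1.000
       edges_true_positive         47           47     1.000
    edges_planted_recalled         47          120     0.392
metabolite_links_recovered          5            8     0.625
edge precision vs planted modules: 1.00
```

All four planted regulators are recovered as significant RIF lncRNAs, and
every group-exclusive network edge points at a planted regulator–target
pair (precision 1.00). Recall against the planted modules is limited by
sampling noise around the |r| > 0.8 edge threshold when the true wiring is
exactly 0.8 — see `docs/methods.md` for the analysis. The same pipeline is
available as a CLI: `lncnet simulate`, `lncnet assign-groups`,
`lncnet run-all`.

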