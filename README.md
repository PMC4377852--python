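# immunoscape

Characterization of tumor **immunophenotypes** and the **antigenome**
from bulk expression cohorts, with the supporting statistics: metagene
compendium derivation, single-sample gene-set enrichment (ssGSEA) and
relative immune-cell quantification, cancer-germline and neo-antigen
calling, clonal-heterogeneity scoring, survival-annotated
TIL–immunomodulator networks, and a lasso model of tumor
immunogenicity. A synthetic-cohort generator with planted ground truth
makes every stage testable at desk scale, without any external data.

The package is written for computational immuno-oncology analysts who
have bulk RNA-seq (TPM-like) tumor/normal matrices, somatic mutation
tables with transcript models, HLA class I allele calls,
cancer-cell-fraction (CCF) estimates and clinical follow-up, and want
the full immunogenomic read-out reproducibly scripted.

## The quantities it computes

**Metagene compendium.** From labeled reference profiles of purified
immune cells, cell-type-specific genes are selected by one-way ANOVA
(p < 0.05), a two-fold dominance cutoff of the top cell type's median
over the runner-up (linear scale), a label-permutation test on that
median difference (10,000 permutations), and a Jensen–Shannon
specificity score; per cell type, genes are pruned until the average
pairwise Pearson correlation is r ≥ 0.6 (p < 0.01), keeping sets of at
least 11 genes.

**Relative immune-cell abundance.** For cell type *c* with metagenes
*i = 1…n_c*, weights *w_i* (median log2 intensity in the reference) and
sample TPM *x_i*:

```
I_c = Σ_i  log10(x_i + 1) / w_i
```

**ssGSEA.** Genes are z-scored across patients and ranked per sample;
a weighted Kolmogorov–Smirnov running sum scores each metagene set,
normalized against a gene-set permutation null (NES); a cell type is
enriched at BH q ≤ 0.10.

**Antigenome.** Neo-antigens are 8–11-mer windows over the altered
protein region of expressed missense/nonstop/frameshift/in-frame-indel
mutations (start-codon, splice and exon-border mutations excluded),
kept when the binding predictor reports percentile rank ≤ 2 for a
patient allele and the peptide is absent from the reference proteome.
Cancer-germline antigens are called positive above the normal baseline
median + 3 SD (zero-SD and tumor-downregulated genes excluded).

**Heterogeneity.** Per tumor, the exact area under the empirical CDF of
its CCFs on [0, 1] (0 = fully clonal); tumors are compared by the
two-sample Kolmogorov–Smirnov D and clustered into clonal groups
(Ward).

**Survival & networks.** Optimal marker cutpoints are scanned inside
the inner 80% of the marker distribution by minimal log-rank p,
corrected for the selection (Altman/Miller–Siegmund), or by maximal
Harrell's C; the TIL–immunomodulator network links cell types and genes
with Pearson r ≥ 0.6 (p < 0.05), annotating nodes with hazard ratios.

**Immunogenicity model.** Cytotoxic-cell presence (mean of the CD8, NK
and Tgd metagene summaries) is regressed on ~221 tumor-intrinsic and
-extrinsic features with lasso selection, OLS refit (BH-adjusted
p < 0.005) and 10-fold cross-validation.

## Worked example

```python
from immunoscape import synthetic as syn
from immunoscape.compendium import build_compendium
from immunoscape.phenotyping import relative_abundance

cfg = syn.SyntheticConfig(seed=1)
reference, truth = syn.generate_reference_profiles(cfg)
sets, records = build_compendium(reference, n_perm=10_000, seed=1)
print(len(sets), "cell types,", sum(len(s) for s in sets), "metagenes")

cohort, cohort_truth = syn.generate_tumor_cohort(cfg, reference)
abundance = relative_abundance(cohort, sets)
print(abundance.iloc[:2, :3].round(2))
```

prints

```
10 cell types, 150 metagenes
           CT00  CT01  CT02
sample_id
P000       3.50  2.82  2.70
P001       2.64  2.95  2.61
```

i.e. all ten planted cell types yielded a valid metagene set (15 genes
each), and the first two tumors' relative abundances `I_c` for three
cell types — unitless scores proportional to each cell type's true
mixture fraction (Spearman ρ ≈ 0.98 against the planted fractions over
200 tumors).

The same pipeline is scriptable from the shell:

```sh
immunoscape simulate --outdir study --seed 3
immunoscape compendium --expr study/reference.tsv \
    --labels study/reference_labels.tsv --out compendium.json
immunoscape heterogeneity --ccf study/ccf.tsv --k 4 --out het/
```

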