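# Methods

This note records the models, the parameter choices that matter, the
numerical conventions, and what the synthetic data does and does not
emulate.

## Signature compendium

The reference compendium is a labeled genes × samples matrix of
purified immune-cell profiles (log2 scale by convention for microarray
intensities). The specificity chain is:

1. **ANOVA** across cell types, p < 0.05. The F-test runs on the log2
   scale (log2(x+1) for linear input), where expression noise is
   closest to Gaussian; constant genes get p = 1 and drop out.
2. **Fold dominance**: per-type medians are compared on the *linear*
   scale — "two-fold change" is a linear-scale notion — and the top
   type must exceed the runner-up by ≥ 2 (inclusive at the boundary,
   chosen for determinism; a zero runner-up with positive top counts
   as an infinite ratio and passes).
3. **Permutation test**: the statistic is the difference between the
   top-type median and the runner-up median; all sample labels are
   permuted (default 10,000 times) and the p-value uses the add-one
   estimator (b+1)/(n+1), which can never be zero. One permutation
   index block is drawn per run and shared across genes; p-values
   remain valid per gene and the run is reproducible. The literature
   phrasing of this test ("fix the top median, permute the data") is
   ambiguous; this interpretation is isolated in a single function.
4. **Jensen–Shannon specificity** (descriptive): JSD in bits between
   the normalized per-type median pattern and the one-hot pattern of
   the top type, with 0·log 0 ≡ 0; the score is 1 − sqrt(JSD). The
   transform from divergence to score is our convention; base-2 logs
   bound JSD by 1.
5. **Metagene selection**: greedy backward elimination — repeatedly
   drop the gene with the lowest average Pearson correlation (computed
   on log2(x+1) across all reference samples) until all remaining
   averages are ≥ 0.6 with correlation-test p < 0.01. Sets finishing
   below 11 genes are discarded with a warning. The search procedure
   is a design choice; a global search is combinatorial and the greedy
   variant is stable on well-separated markers.

Metagene weights are the median log2 intensity of each gene in its own
cell type; they must be positive because they divide the abundance sum.
Myeloid-derived suppressor cells have no usable purified reference
profiles, so their metagene list is supplied via configuration rather
than derived.

## Enrichment and quantification

ssGSEA details are config knobs, with these defaults: weight exponent 1
on |z|; gene-set permutation null (a phenotype-permutation null does
not exist for a single sample); NES = ES / mean(|null ES| of the same
sign); p from the same-sign null tail with the add-one estimator;
BH adjustment across the cell types tested within one sample (the
alternative — a global family — is a judgement call; within-sample is
the unit at which the enrichment read-out is interpreted). The running
sum is evaluated only at hit boundaries (O(set size) instead of
O(universe)); near-ties in |deviation| (within 1e-12) resolve to the
earliest scan position, matching a sequential scan's behaviour.

Rankings order by descending z, ties broken by ascending gene ID.
Group rankings use the mean z over the group, which commutes with
averaging the z matrix.

`I_c = Σ log10(x_i + 1) / w_i` uses a +1 pseudocount, so an unexpressed
gene contributes exactly 0 and the score is strictly increasing in
every metagene's expression. I_c is comparable across samples within a
cell type, not across cell types.

Hypermutation: rate = non-silent mutations per covered Mb; the
threshold 8.24 separates hypermutated from non-hypermutated tumors with
a *strict* inequality at the boundary (the published threshold
separates groups; strictness is our documented choice).

Tumor-group-vs-normal summaries rank genes by the difference in mean
z-scores and run the enrichment engine on the ranking and its reverse,
so depletion is scored symmetrically to enrichment. Gene-level fold
changes are log2((mean_T + 1)/(mean_N + 1)) — zero-safe and consistent
with the log10(x+1) convention — with a built-in rank-sum + BH test;
model-based differential-expression engines can replace the built-in
test through an external results table. A self-comparison (identical
groups) short-circuits to an all-neutral report.

Fisher association maps use the sample odds ratio with the
Haldane–Anscombe 0.5 correction whenever any cell is zero, keeping the
log-OR finite; the log-OR matrix is clustered on both axes (Euclidean,
average linkage).

## Antigenome

Transcript models are simplified: whole exons are coding, the CDS
starts with ATG and ends with its only in-frame stop, and a downstream
UTR sequence supports read-through. Genomic intervals are 1-based
inclusive in files; CDS positions are 1-based.

Filtering removes splice-site and start-codon mutations (any
substitution or deletion touching CDS positions 1–3 counts as a
start-codon change), indels spanning an exon junction, and
non-protein-altering classes, each logged with its reason.

Translation conventions: missense and in-frame indels alter the local
stretch found by trimming the common prefix and suffix against the
wild-type protein (a pure C-terminal truncation maps to the new
junction residue); frameshifts translate in the new frame from the
edit until the first stop, running into the downstream UTR when the
CDS ends first; nonstop mutations read through into the UTR until the
next in-frame stop. Missing stops truncate at the sequence end with a
warning. Edits that are silent at the protein level are rejected —
silent mutations can never produce peptides.

Window enumeration emits every 8–11-mer overlapping at least one
altered residue and lying fully within the protein, collapsing
duplicate peptides with multiplicity. An interior single-residue
change therefore yields 8+9+10+11 = 38 windows.

Binding prediction is a pluggable callable (peptide, allele) →
percentile rank; an adapter parses pre-computed netMHCpan-style
tables. The rank filter is inclusive at 2 (covering both strong and
weak binders; the ≤ 0.5 strong-binder sub-label is recorded but not
used for filtering), and the proteome self-filter is an exact
substring match — near-matches are retained as novel.

"Expressed" mutations default to gene-level expression > 1 TPM in the
carrying patient (configurable); allele-level expression is not
modelled. The per-patient neo-antigen frequency is the fraction of
expressed protein-altering mutations yielding ≥ 1 called neo-antigen;
an alternative read-out (called neo-antigens per mutation) is available
behind a flag. Patients with zero eligible mutations are reported as
missing, not zero.

Cancer-germline antigen calling: baseline = normal median + 3 × normal
SD (sample SD, ddof = 1); positivity is strictly above the baseline;
genes with zero normal SD or significant tumor downregulation (per the
supplied DE table or the built-in test) are excluded. K-means
(k-means++, seeded) groups the retained genes' log10(x+1) tumor
profiles.

## Heterogeneity

The per-tumor score is the exact integral of the right-continuous
empirical CDF of the CCFs over [0, 1] — a sum of rectangle areas, no
quadrature. It is 0 for a fully clonal tumor, 1 − c for a point mass
at c, and converges to 0.5 for uniform CCFs. KS-D between tumors is
evaluated exactly at pooled breakpoints. For clustering, "Euclidean +
Ward on a KS-D similarity" is ambiguous; the default treats each
tumor's row of the D matrix as its feature vector (honoring both the
Euclidean metric and Ward linkage), with direct-D + average linkage
available behind a flag. k defaults to 4.

## Survival machinery

Candidate cutpoints are midpoints between consecutive distinct marker
values whose split keeps both groups within the inner 80% of patients
(selection fraction ε = 0.1 per side). The log-rank scan is vectorized
across candidates with exact tie handling. The minimal-p correction is
the asymptotic supremum formula for the standardized log-rank process,

    p_cor = φ(z)·(z − 1/z)·ln[(1−ε)²/ε²] + 4φ(z)/z ,

a tail approximation: below its mode in z the monotone envelope is
used and the result is clipped to [p_min, 1], so corrected p is
monotone in uncorrected p and never smaller. Under the null
(1,000 cohorts of n = 200) the uncorrected minimal p rejects ~45% of
the time at the 5% level while the corrected p rejects ~4–5%.

Harrell's C counts a pair as comparable when the earlier time is an
observed event; score ties count 0.5; time-tied double events are not
comparable. KM curves, log-rank tests and Cox hazard ratios delegate
to lifelines (no bespoke contribution there); the HR convention is
hi-vs-lo group, and disease-free survival is handled by column
selection. Multivariate Cox accepts binary covariates (MSI,
hypermutation, methylation subtype, tumor site) from the clinical
table.

The network links cell types (dichotomized at median abundance) and
immunomodulator genes (dichotomized at the min-p cutpoint, corrected p)
when Pearson r ≥ 0.6 with p < 0.05. Gene nodes that are not
survival-significant are dropped from the final graph; cell-type nodes
are kept regardless (a flag filters both). Survival annotation is only
computed for genes that enter the graph. Graphs serialize to GraphML
and edge-list TSV.

## Immunogenicity model

The response is the mean of the CD8, NK and Tgd summaries per patient.
Features are standardized (zero-variance columns dropped with a
warning; complete-case join across blocks). Lambda is chosen by inner
5-fold cross-validation on MSE over a 60-step path with floor
alpha_max/100 (relevant features enter the path early; the OLS refit
supplies final coefficients, so a deeper path adds cost without
benefit). Nonzero-coefficient features are refit by OLS; BH-adjusted
refit p-values below 0.005 define the final model. This naive
post-selection inference ignores the selection event — a known caveat
accepted by design. Outer 10-fold cross-validation repeats the whole
selection per training fold and reports mean R² and MSE. Fold
assignment is seeded.

## Synthetic data: what it emulates, and what it does not

The generator plants every quantity a downstream test needs and
serializes it as ground truth. Identical configs and seeds give
bit-identical outputs (each stage derives an independent stream from
the seed and a stage tag).

* **Reference profiles**: markers exceed their off level by
  `marker_fold` (default 4) plus a noise margin of 6 SD + 0.5 on the
  log2 scale, so the dominance filter passes by construction; noise is
  Gaussian on the log2 scale (SD 0.2), i.e. log-normal multiplicative —
  the standard abundance noise model. Default scale: 10 cell types ×
  5 replicates, 15 markers/type, 1,850 background genes (2,000 total).
* **Bulk cohorts**: convex Dirichlet mixtures of the per-type mean
  profiles plus a tumor-cell background profile (markers off); tumors
  use a tumor-heavy prior, normals an even heavier one. Planted
  mixture fractions are the ground truth for quantification checks.
* **Mutations**: random multi-exon CDSs (40–80 codons); all seven
  mutation classes at configured proportions (largest-remainder
  rounding, so ±1 count), including the decoys the filters must
  remove. The mock binding predictor hashes (peptide, allele) with a
  seeded 64-bit hash to a uniform rank on (0, 100]; with planted
  binders, planted pairs land in (0, 2] and all others in (2, 100], so
  the rank ≤ 2 rule recovers exactly the planted set — this makes the
  end-to-end identity check exact rather than statistical.
* **CCF tables**: four default clonal architectures as Beta mixtures,
  from near-clonal (Beta(40,2)) to dominantly subclonal, 25 tumors ×
  200 CCFs each — chosen to span the heterogeneity range a cohort
  shows while remaining distinguishable at 200 mutations/tumor.
* **Survival**: exponential event times, hazard multiplied by the
  planted ratio for marker-high patients; independent exponential
  censoring tuned to a target censoring fraction (default 25%);
  censoring rate 1 censors everyone (degenerate-case testing).

What it does **not** emulate: read-level data, copy number,
methylation, batch effects, correlated background genes, cell-type
covariance structure in mixtures, allele-specific expression, or
realistic HLA binding motifs. Passing tests therefore demonstrate the
*statistical machinery* is correct and calibrated under the stated
generative assumptions — not that the biological signal in real
cohorts is as clean.

## Problem sizes

The verification suite and the results script use: compendium recovery
at 2,000 genes / 50 reference samples with 10,000 permutations; ssGSEA
null calibration over 1,000 samples × 10 sets (200-permutation nulls);
cutpoint calibration over 1,000 (suite) / 500 (script) null cohorts of
n = 200; network recovery over 100 (suite) / 30 (script) cohorts of
n = 200 with 5 planted signals among 40 decoys; lasso recovery over 50
(suite) / 20 (script) replicates of n = 400 × 221 features with 20 / 5
permuted-response nulls. These sizes give binomial standard errors
comfortably inside the asserted margins.

## Known limitations

* Post-lasso OLS p-values ignore selection; they are screening
  devices, not honest inference.
* The minimal-p correction is asymptotic; at very small n or extreme
  censoring its calibration degrades.
* The ssGSEA gene-set permutation null ignores inter-gene correlation;
  on strongly co-expressed universes the q-values are optimistic.
* The proteome self-filter is exact-match only; peptides differing by
  one residue from a self peptide are retained as novel.
* Heterogeneity scoring treats CCF point estimates as exact, ignoring
  their posterior uncertainty.
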