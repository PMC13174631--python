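# Methods

This note documents the models, estimators, defaults and design choices in
`heteroscreen`, and what the synthetic-data experiments do and do not show
about real data.

## Composite depletion and the limiting subpopulation

Cells carrying guide *j* against gene *g* in subpopulation *k* grow
deterministically as

    N_jk(T) = N_jk(0) · 2^((r_k + s_{g,k} · e_j) · T)

where *T* counts population doublings, *r_k* is a per-subpopulation
baseline clock multiplier (default 1), *s_{g,k}* is the per-doubling log2
fitness effect (negative = depleting) and *e_j* ∈ [0, 1] the guide
efficiency. Bulk depletion of a mixture with initial fractions *f_k* is

    β_bulk = (1/T) · log2( Σ_k f_k · 2^(s_k·T) ),

computed in log space (`scipy.special.logsumexp`) so extreme exponents
cannot overflow. Two exact properties anchor the implementation and its
tests: min(s) ≤ β ≤ max(s), and the deviation from the resistant pole is
exactly log2(f_limiting)/T once the limiting clone dominates, so β
converges to max(s) like 1/T. With f = (0.99, 0.01) and s = (−3, 0) the
deviation at T = 60 is |log2(0.01)|/60 ≈ 0.111; an absolute tolerance of
0.05 on |β − max(s)| is first met near T ≈ 133, and the tests check the
exact law at T = 60 plus the 0.05 bound at T = 150.

## Screen simulation

Stochasticity enters only twice: multinomial seeding of
`coverage × n_guides` initial cells (uniform over guides, proportional to
fractions over subpopulations), and multinomial sequencing sampling of
`depth` reads per sample at T0 and T1. Growth itself is deterministic,
which isolates the composite-depletion arithmetic from demographic noise;
an optional Dirichlet-multinomial knob (off by default) adds PCR-style
overdispersion. Guide efficiencies default to Beta(9, 1) — most guides
effective — and can be pinned per guide. Defaults: coverage 500×,
depth 10^7, T = 8 doublings; none of these are stated constraints of the
protocol being emulated, they are exposed in the config and were chosen
once as typical values for a well-powered pooled screen.

Library design follows the mini-pool layout: disjoint gene lists per pool,
4 guides per gene, and controls added per pool as
round(c/(1−c) · n_targeting) so that non-targeting/safe-harbor guides make
up exactly the fraction *c* (default 5%) of the final pool. The "fraction
of the final pool" reading was chosen over "fraction of targeting guides";
the two differ by < 0.3% at c = 0.05.

## β estimation

The gene-level estimator is intentionally simple and fully specified
rather than a re-implementation of MAGeCK-MLE:

1. **Normalization** — each sample is scaled so its median control-guide
   count matches the across-sample median of control medians (falls back
   to total-count scaling, with a warning, when no controls are present).
2. **Guide LFC** — log2((c1 + 0.5)/(c0 + 0.5)) per replicate pair,
   averaged at the LFC level, then centered on the organoid's control
   median. The 0.5 pseudocount bounds the LFC of extinct guides; β is
   therefore censored at roughly −log2(c0/0.5)/T for guides whose T1
   counts reach zero.
3. **β** — median guide LFC divided by T: a per-doubling log2 fitness
   effect, robust to a single bad guide out of four (the median moves at
   most to an adjacent order statistic).
4. **Significance** — a control-resampling null: B (default 1000) medians
   of guide-sized control-LFC sets, drawn without replacement within a set
   to mirror a real gene's distinct guides; two-sided
   p = (1 + #{|null| ≥ |β|})/(B + 1), BH-adjusted within organoid. Because
   all genes in an organoid share one finite control set, p-values are
   exchangeable but not independent; calibration experiments therefore use
   libraries with ≥ 250 control guides, where the shared-null variance is
   small.

## Subtype annotation

Per-cell scoring replaces graph clustering: the score of template *t* is
the mean z-scored expression (genes z-scored across cells; zero-variance
genes set to z = 0 so dimensionality is stable) over *t*'s markers, and a
cell is labeled by the argmax, or "intermediate" when the top-vs-second
margin is below 0.1. Marker ranking uses a one-sided rank-sum test per
gene (label vs rest), BH FDR, and reports the top 20 by log2 fold change
(difference of means on the log2 scale) among FDR < 0.05 genes. A subtype
is retained when ≥ 10 of its top-20 markers pass FDR < 0.05 and
log2FC > 0.5 — a quantified reading of "differentially enriched", with
both knobs exposed.

**NTP.** A sample's distance to a template is the cosine distance between
its z-vector restricted to the template genes and the matching all-ones
vector (range [0, 2]); the prediction is the argmin. The permutation null
mirrors the selection step: each of n_perm (default 1000) permutations
draws one random same-size gene set per template and records the minimum
distance. When the template sizes fit inside the gene universe the sets of
a permutation are disjoint blocks of one random gene permutation, matching
the dependence structure of disjoint marker programs; a null built from a
single random set per permutation would make noise p-values
anti-conservative by roughly 1 − (1 − p)^K. With the min-mirrored null,
noise p-values are uniform-to-conservative (super-uniform), a perfect
match sits at the 1/(n_perm + 1) floor, and BH across samples drives the
noise unclassification rate from ~95% (per-sample p > 0.05) toward 100%.
Composition estimates use hard per-sample classification, with
"unclassified" reported as its own fraction.

## Plasticity metrics

ISI = 1/Σp² is the effective number of evenly used features. It is
computed on downsampled pseudobulk proportions — "within each group" is a
group-level quantity — not per cell: per group and replicate, n_cells are
subsampled without replacement, pooled, downsampled without replacement
(multivariate hypergeometric) to a fixed depth, and ISI is taken on the
proportions; mean ± SD over B = 100 replicates is reported. Defaults
control for sample size: n_cells is the smallest group and depth the
smallest achievable pseudobulk total, so every group is measured on the
same footing; doubling depth leaves the expectation unchanged within
replicate noise. GEX uses raw counts and ATAC binary peak indicators, both
swappable. Topic weights are consumed, not fitted (no LDA dependency): the
per-cell module is the argmax weight, and an organoid is "mixed" when ≥ 2
modules each hold ≥ 10% of its cells.

## Leave-one-out framework

Regression direction is expression-on-β per gene across organoids (the
reverse is available by swapping arguments), ordinary least squares,
minimum 4 training organoids, with a degenerate-fit flag when β is
constant in training. Residuals are absolute. The winning subpopulation
minimizes |x_sub − x̂|, with ties broken by larger cell fraction then
lexicographic label; the lowest-expressing subpopulation is the argmin of
mean expression with the mirror tie-break (smaller fraction first).
Proportional improvement is (|res_bulk| − |res_winner|)/|res_bulk| and may
be negative. R²_sub substitutes the winner's observed values for bulk in
both the residual and the variance term; either R² may be negative. The
G-test is the standard likelihood-ratio test, G = 2 Σ O·ln(O/E) over
cells with O > 0, df = (rows−1)(cols−1), chi-square upper tail, zero
margins dropped with a warning and no Williams correction (flag-free; the
continuity-corrected variant was deliberately not added).

## The planted limiting-subpopulation cohort

`simulate_limiting_cohort` is the fixture on which the
winner/lowest-expressor association is demonstrated, and its structure is
the direct consequence of what a bulk-trained linear LOO can detect. The
prediction x̂ is an affine function of β fit to bulk expression, so it
tracks the conditional mean of bulk; with fully independent per-
(gene, organoid, subpopulation) expression the prediction sits equidistant
from both subpopulations and the winner is a coin flip. A recoverable
signal requires three ingredients, each defensible as biology:

1. **Shared regulatory variation with stable offsets.** Expression of
   gene *g* in the dominant clone is x_A = μ_g + N(0, 0.7) across
   organoids, and the minority clone sits at a stable gene-specific offset
   x_B = x_A + δ_g with |δ_g| ~ U(0.8, 1.4). Clones within an organoid
   share organoid-level regulatory state; subtype identity contributes a
   consistent shift.
2. **The lowest expressor is usually the dominant clone** (80% of genes;
   clone A holds 65–85% of cells). A resistant, lowly expressing dominant
   population coexisting with a minority high-expressing specialized clone
   is exactly the configuration in which bulk screening is misleading.
3. **Bulk measurement noise.** Bulk expression is the composition-weighted
   mean plus N(0, 0.5) — an independent, noisier assay than the
   single-cell-derived subpopulation means. This is the noise that
   subpopulation-resolved prediction removes, making R²_sub exceed
   R²_bulk.

Fitness couples to expression as s = −0.22·x, so the lowest-expressing
clone is always the limiting (least-depleting) pole; β estimated from the
simulated screens is then, to good approximation, −0.22·x_min plus a
gene-specific constant. The slope keeps the strongest depletions above the
pseudocount censoring floor at the default depth. With these defaults the
pooled winner/lowest-expressor match rate is ~0.6–0.8 against a 0.5 null
(binomial p well below 0.01 over 400 gene-organoid pairs) and
R²_sub > R²_bulk for the large majority of genes.

What this does **not** show: the fixture plants the association; passing
it demonstrates that the pipeline recovers a planted limiting-population
structure end-to-end (through library design, growth, sequencing noise,
normalization, β estimation and LOO), not that any particular real tumor
has this structure.

## Synthetic atlas

RNA counts are negative binomial with a shared log-normal baseline rate
per gene, markers of a cell's subtype shifted up by 2^effect_size
(default effect size 2), gene-level dispersion 0.3 and expected depth
2000 counts/cell; peaks are Bernoulli at 0.05 base accessibility, 0.6 on
the subtype's program peaks. These values make marker recovery
comfortable at the default sizes (200 cells per subpopulation) and are
all configurable. The generator does not model doublets, cell-cycle
structure, batch effects, UMI collapsing or lentiviral MOI; tests passing
on this atlas show the annotation logic is correct, not that it is robust
to those artifacts.

## Pipeline

The config is a validated dataclass read from YAML (unknown keys and
out-of-range thresholds are rejected). All randomness flows through
per-stage substreams keyed by a hash of the stage name, so toggling one
stage never shifts another's draws; identical config + seed reproduces
byte-identical outputs, verified via content hashes in `manifest.json`.
Demo problem sizes (8 organoids × 200 cells, a 50-gene screen cohort at
500× coverage and 10^6 reads, 1000 permutations) were chosen so a full
run completes in well under a minute on one CPU while leaving every
statistical check comfortably powered.
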