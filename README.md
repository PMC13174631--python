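# heteroscreen

Subpopulation-resolved interpretation of pooled CRISPR dropout screens in
heterogeneous organoid models.

Pooled CRISPR dropout screens report one depletion value per gene, but
patient-derived organoids (PDOs) — for example from castrate-resistant and
neuroendocrine prostate cancer — contain co-existing lineage subpopulations
with different dependencies. `heteroscreen` is a tested pipeline, built on
synthetic data with known ground truth, for everything between a single-cell
multiome atlas and a subpopulation-resolved dependency call:

* **synthetic_data** — generators for lineage programs, multi-subpopulation
  single-cell RNA/ATAC atlases, sgRNA libraries, and pooled-screen count
  tables under exponential subpopulation growth.
* **subtype_annotation** — signature scoring, the top-20 marker-retention
  rule, nearest-template prediction (NTP) with permutation FDR, and bulk
  subtype-composition estimation.
* **plasticity** — inverse Simpson diversity (ISI) of expression or
  chromatin accessibility with sample-size control, and topic-module
  composition.
* **screen_stats** — guide-count normalization, control-centered log2 fold
  changes, gene-level per-doubling depletion (β) with a control-resampling
  null, and dosage-sensitivity correlations.
* **composite_dependency** — the composite-depletion model, the limiting
  subpopulation principle, the leave-one-out expression-from-β framework,
  winning-subpopulation statistics and a G-test of independence.
* **pipeline / cli** — config-driven orchestration with reproducible seeds.

## The model

If subpopulation *k* starts at fraction *f_k* and carries a per-doubling
log2 fitness effect *s_k* (negative = depleting), the bulk depletion
measured over *T* population doublings is

    β_bulk = (1/T) · log2( Σ_k f_k · 2^(s_k · T) )

which always lies between min(s) and max(s) and converges to max(s) as *T*
grows, at rate log2(f_limiting)/T. The subpopulation with the **weakest**
dependency — the *limiting* subpopulation — therefore dominates the
aggregate signal: resistant clones outgrow the rest and mask
vulnerabilities confined to other states.

The leave-one-out (LOO) framework quantifies this on data: per gene, each
organoid is held out, expression is regressed on β across the remaining
organoids, and the held-out organoid's observed expression values — bulk
and per-subpopulation — are compared against the prediction. The
subpopulation with the smallest residual is the *winning subpopulation*;
a G-test (and an exact binomial test on the match rate) asks whether
winners coincide with the lowest-expressing subpopulations.

## Worked example

```python
import heteroscreen as hs
from heteroscreen import synthetic_data as sd, screen_stats as ss
from heteroscreen import composite_dependency as cd

# Composite depletion of a 90/10 mixture where the minority clone is resistant
hs.composite_beta([0.9, 0.1], [-2.0, 0.0], T=8)   # -0.41522
hs.limiting_subpop([0.9, 0.1], [-2.0, 0.0])       # (0.0, [1])

# A planted 8-organoid cohort: the lowest-expressing clone limits depletion
co = sd.simulate_limiting_cohort(seed=1)
lfc = ss.guide_lfc(ss.normalize_counts(co.screens, co.library), co.library)
beta = ss.gene_beta(lfc, co.library, co.doublings)
beta.head(3)
#   gene organoid      beta  n_guides
# DEP000    ORG01 -0.337959         4
# DEP000    ORG02 -0.462059         4
# DEP000    ORG03 -0.927908         4

loo = cd.subpop_residuals(cd.loo_fit_all(beta, co.bulk_expression),
                          co.subpop_expression)
summary = cd.winner_lowexpr_association(loo, co.subpop_expression)
summary.pooled_match_rate, summary.pooled_binom_p
# (0.585, 3.94e-04)

cd.r2_compare(loo).head(3)
#   gene  n_holdouts  r2_bulk  r2_sub
# DEP000           8    0.807   0.930
# DEP001           8    0.368   0.512
# DEP002           8    0.678   0.924
```

The mixture's bulk β (−0.415) sits far from the depleting clone's true
effect (−2): the resistant 10% minority dominates after 8 doublings. In
the cohort, winners match the lowest-expressing subpopulation well above
the 1/2 chance level (match rate 0.585, binomial p ≈ 4e-4), and
subpopulation-resolved R² beats the bulk R² for most genes — the
qualitative signature of the limiting-subpopulation principle.

A full demo run (atlas → annotation → plasticity → screen → LOO) from the
shell:

```bash
heteroscreen run-all --seed 3 --outdir demo_out
# ran 9 stages -> demo_out/manifest.json
```

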