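"""Gene-level depletion estimation from pooled-screen guide counts.

The estimator is deliberately simple and fully specified: counts are
normalized so control-guide medians agree across samples, per-guide log2
fold changes (T1 vs T0) are centered on the control median, and the
gene-level depletion beta is the median per-guide LFC divided by the
number of population doublings — a per-doubling log2 fitness effect,
negative for dependencies. Significance comes from a control-resampling
null rather than a parametric Wald test: null betas are medians of
guide-sized sets resampled from control LFCs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust
from .synthetic_data import LibraryDesign, ScreenCounts

logger = logging.getLogger(__name__)


def normalize_counts(screen_counts: ScreenCounts, library: LibraryDesign) -> ScreenCounts:
    """Scale each sample so control-guide medians match across samples.

    The per-sample scale factor maps its median control count to the
    across-sample median of control medians. Zero counts stay zero. With
    no control guides in the table, falls back to total-count scaling
    with a warning.
    """
    counts = screen_counts.counts.astype(float)
    ctrl = [g for g in library.control_guides if g in counts.index]
    if ctrl:
        if len(ctrl) < 10:
            warnings.warn(f"only {len(ctrl)} control guides present; normalization is noisy")
        ref = counts.loc[ctrl].median(axis=0)
    else:
        warnings.warn("no control guides present; falling back to total-count scaling")
        ref = counts.sum(axis=0)
    target = float(ref.median())
    scaled = counts.mul(target / ref, axis=1)
    return ScreenCounts(counts=scaled, sample_meta=screen_counts.sample_meta.copy())


def guide_lfc(
    normalized: ScreenCounts,
    library: LibraryDesign,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Control-centered per-guide log2 fold change T1 vs T0, per organoid.

    Replicates are paired by replicate id and averaged at the LFC level.
    Each organoid's LFC vector is centered by subtracting the median LFC
    of its control guides. Returns guides x organoids.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = normalized.counts
    meta = normalized.sample_meta
    ctrl_mask = library.guides.set_index("guide_id")["is_control"].reindex(counts.index)
    out = {}
    for org, sub in meta.groupby("organoid", sort=False):
        t0 = sub[sub["timepoint"] == "T0"]
        t1 = sub[sub["timepoint"] == "T1"]
        if t0.empty or t1.empty:
            raise ValueError(f"organoid {org!r} is missing a timepoint")
        reps = sorted(set(t0["replicate"]) & set(t1["replicate"]))
        lfcs = []
        if reps:
            for rep in reps:
                c0 = counts[t0.index[t0["replicate"] == rep][0]]
                c1 = counts[t1.index[t1["replicate"] == rep][0]]
                lfcs.append(np.log2(c1 + pseudocount) - np.log2(c0 + pseudocount))
        else:  # unpaired replicates: average log-counts per timepoint
            l0 = np.log2(counts[t0.index] + pseudocount).mean(axis=1)
            l1 = np.log2(counts[t1.index] + pseudocount).mean(axis=1)
            lfcs.append(l1 - l0)
        lfc = pd.concat(lfcs, axis=1).mean(axis=1)
        ctrl_median = lfc[ctrl_mask.fillna(False).to_numpy(dtype=bool)].median()
        out[org] = lfc - (ctrl_median if np.isfinite(ctrl_median) else 0.0)
    return pd.DataFrame(out)


def gene_beta(
    lfc_table: pd.DataFrame,
    library: LibraryDesign,
    doublings: float,
) -> pd.DataFrame:
    """Per-(gene, organoid) beta: median guide LFC divided by doublings.

    The median across a gene's guides keeps beta robust to individual
    inefficient guides. Genes with no guides in the table are omitted
    with a warning. Returns a long table (gene, organoid, beta, n_guides).
    """
    if doublings <= 0:
        raise ValueError("doublings must be > 0")
    guides = library.guides[~library.guides["is_control"]]
    present = guides[guides["guide_id"].isin(lfc_table.index)]
    absent_genes = set(guides["gene"]) - set(present["gene"])
    if absent_genes:
        warnings.warn(f"{len(absent_genes)} genes have no guides in the LFC table; omitted")
    rows = []
    for gene, grp in present.groupby("gene", sort=False):
        sub = lfc_table.loc[grp["guide_id"]]
        for org in lfc_table.columns:
            rows.append((gene, org, float(sub[org].median()) / doublings, len(grp)))
    return pd.DataFrame(rows, columns=["gene", "organoid", "beta", "n_guides"])


def beta_significance(
    lfc_table: pd.DataFrame,
    library: LibraryDesign,
    doublings: float,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """BetaTable with permutation p-values from a control-resampling null.

    For every guide count n, B null betas are built as medians of
    guide-sized sets resampled from the organoid's control guides
    (without replacement within a set, mirroring a real gene's distinct
    guides), divided by doublings; two-sided ``p = (1 + #{|null| >=
    |beta|}) / (B + 1)``, BH-adjusted across genes within each organoid.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    betas = gene_beta(lfc_table, library, doublings)
    ctrl_ids = [g for g in library.control_guides if g in lfc_table.index]
    if not ctrl_ids:
        raise ValueError("no control guides available for the null")
    if len(ctrl_ids) < 50:
        warnings.warn(f"only {len(ctrl_ids)} control guides; null resolution is limited")
    rng = np.random.default_rng(seed)
    out = []
    for org, sub in betas.groupby("organoid", sort=False):
        ctrl = lfc_table.loc[ctrl_ids, org].to_numpy(dtype=float)
        nulls: dict[int, np.ndarray] = {}
        for n in sub["n_guides"].unique():
            n = int(n)
            if n <= len(ctrl):
                idx = np.argsort(rng.random((B, len(ctrl))), axis=1)[:, :n]
                draws = ctrl[idx]
            else:
                draws = rng.choice(ctrl, size=(B, n), replace=True)
            nulls[n] = np.abs(np.median(draws, axis=1) / doublings)
        p = np.array(
            [
                (1 + (nulls[int(n)] >= abs(b)).sum()) / (B + 1)
                for b, n in zip(sub["beta"], sub["n_guides"])
            ]
        )
        sub = sub.copy()
        sub["p"] = p
        sub["fdr"] = bh_adjust(p)
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def dosage_correlation(
    beta_table: pd.DataFrame,
    expression_by_organoid: pd.DataFrame,
    r_threshold: float = 0.5,
    min_n: int = 4,
) -> pd.DataFrame:
    """Per-gene Pearson correlation between beta and expression across organoids.

    ``expression_by_organoid`` is genes x organoids (expression or any
    activity score). A gene is dosage-sensitive iff |r| >= ``r_threshold``
    over at least ``min_n`` organoids; genes with constant beta or
    constant expression get an undefined flag and are never sensitive.
    """
    if min_n < 4:
        raise ValueError("min_n must be >= 4")
    rows = []
    for gene, sub in beta_table.groupby("gene", sort=False):
        if gene not in expression_by_organoid.index:
            continue
        expr = expression_by_organoid.loc[gene]
        orgs = [o for o in sub["organoid"] if o in expr.index and np.isfinite(expr[o])]
        b = sub.set_index("organoid").loc[orgs, "beta"].to_numpy(dtype=float)
        x = expr.loc[orgs].to_numpy(dtype=float)
        n = len(orgs)
        if n < 2 or np.ptp(b) == 0 or np.ptp(x) == 0:
            rows.append((gene, np.nan, n, True, False))
            continue
        r = float(stats.pearsonr(b, x).statistic)
        rows.append((gene, r, n, False, bool(abs(r) >= r_threshold and n >= min_n)))
    return pd.DataFrame(
        rows, columns=["gene", "r", "n_organoids", "undefined", "dosage_sensitive"]
    )
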