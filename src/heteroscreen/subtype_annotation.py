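"""Lineage-subtype assignment for cells and samples.

Four stages, mirroring how multi-organoid atlases are annotated in
practice: (1) per-cell signature scoring against marker-gene templates,
(2) label assignment with a margin rule that flags intermediate cells,
(3) marker ranking per label with a retention rule requiring that a
subtype's top markers really are differentially enriched against the
rest of the atlas, and (4) nearest-template prediction (NTP) with a
permutation null for classifying external bulk or pseudobulk cohorts,
plus cohort-level subtype-composition estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, zscore_genes
from .synthetic_data import ReferencePrograms

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class SubtypeTemplate:
    """A named set of up-regulated marker genes."""

    name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.markers) == 0:
            raise ValueError(f"template {self.name!r} has no markers")


def templates_from_programs(programs: ReferencePrograms) -> list[SubtypeTemplate]:
    return [
        SubtypeTemplate(name, tuple(programs.markers[name]))
        for name in programs.subtype_names
    ]


def _check_unique_names(templates: Sequence[SubtypeTemplate]) -> None:
    names = [t.name for t in templates]
    if len(set(names)) != len(names):
        raise ValueError("template names must be unique")


# ---------------------------------------------------------------------------
# scoring and assignment
# ---------------------------------------------------------------------------


def score_signatures(
    expr: pd.DataFrame, templates: Sequence[SubtypeTemplate]
) -> pd.DataFrame:
    """Mean z-scored expression of each template's genes, per sample.

    ``expr`` is samples/cells x genes, log-normalized. Genes are z-scored
    across samples (zero-variance genes get z = 0); template genes absent
    from the matrix are dropped with a warning, and a template with no
    measured genes raises.
    """
    _check_unique_names(templates)
    z = zscore_genes(expr)
    scores = {}
    for t in templates:
        present = [g for g in t.markers if g in z.columns]
        if not present:
            raise ValueError(f"template {t.name!r} has no genes in the matrix")
        if len(present) < len(t.markers):
            warnings.warn(
                f"template {t.name!r}: {len(t.markers) - len(present)} genes absent, dropped"
            )
        scores[t.name] = z[present].mean(axis=1)
    return pd.DataFrame(scores)


def assign_subtypes(score_table: pd.DataFrame, margin_threshold: float = 0.1) -> pd.Series:
    """Argmax label per sample; small top-vs-second margins become "intermediate"."""
    if score_table.empty:
        raise ValueError("empty score table")
    arr = score_table.to_numpy(dtype=float)
    order = np.argsort(arr, axis=1)
    top = arr[np.arange(len(arr)), order[:, -1]]
    labels = score_table.columns.to_numpy()[order[:, -1]].astype(object)
    if score_table.shape[1] > 1:
        second = arr[np.arange(len(arr)), order[:, -2]]
        labels[top - second < margin_threshold] = INTERMEDIATE
    return pd.Series(labels, index=score_table.index, name="subtype")


# ---------------------------------------------------------------------------
# marker ranking and retention
# ---------------------------------------------------------------------------


def rank_markers(
    expr: pd.DataFrame,
    labels: pd.Series | Sequence[str],
    n_top: int = 20,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Top marker genes per label by one-sided rank-sum test vs the rest.

    Returns a table with columns (subtype, gene, log2fc, p, fdr, rank);
    per subtype, up to ``n_top`` genes with BH FDR < ``fdr_threshold``,
    ranked by log2 fold change (difference of means on the log2 scale).
    Labels with fewer than 3 members are excluded with a warning.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=expr.index)
    counts = labels.value_counts()
    usable = counts[counts >= 3].index
    dropped = counts[counts < 3].index
    for lab in dropped:
        warnings.warn(f"label {lab!r} has <3 members; excluded from marker ranking")
    if len(usable) < 2:
        raise ValueError("need >=2 labels with >=3 members each")

    mat = expr.to_numpy(dtype=float)
    rows = []
    for lab in usable:
        mask = (labels == lab).to_numpy()
        inside, outside = mat[mask], mat[~mask]
        with np.errstate(all="ignore"):
            res = stats.mannwhitneyu(
                inside, outside, alternative="greater", axis=0, method="asymptotic"
            )
        pvals = np.nan_to_num(res.pvalue, nan=1.0)
        lfc = inside.mean(axis=0) - outside.mean(axis=0)
        fdr = bh_adjust(pvals)
        tab = pd.DataFrame(
            {"subtype": lab, "gene": expr.columns, "log2fc": lfc, "p": pvals, "fdr": fdr}
        )
        tab = tab[tab["fdr"] < fdr_threshold].sort_values("log2fc", ascending=False)
        tab = tab.head(n_top).reset_index(drop=True)
        tab["rank"] = np.arange(1, len(tab) + 1)
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def retention_test(
    marker_table: pd.DataFrame,
    expr: pd.DataFrame | None = None,
    labels: pd.Series | Sequence[str] | None = None,
    min_significant: int = 10,
    lfc_threshold: float = 0.5,
    fdr_threshold: float = 0.05,
) -> tuple[set[str], pd.Series]:
    """Keep subtypes whose top markers are genuinely enriched against the rest.

    A subtype is retained iff at least ``min_significant`` of its top-20
    markers pass FDR < ``fdr_threshold`` and log2FC > ``lfc_threshold``.
    ``expr``/``labels`` are accepted for interface symmetry with
    :func:`rank_markers`; the decision uses the marker table. Returns the
    retained set and per-subtype passing-marker counts.
    """
    passing = marker_table[
        (marker_table["fdr"] < fdr_threshold) & (marker_table["log2fc"] > lfc_threshold)
    ]
    counts = passing.groupby("subtype").size()
    counts = counts.reindex(marker_table["subtype"].unique(), fill_value=0)
    retained = set(counts[counts >= min_significant].index)
    return retained, counts


# ---------------------------------------------------------------------------
# nearest template prediction
# ---------------------------------------------------------------------------


def _cosine_to_ones(v: np.ndarray) -> np.ndarray:
    """Cosine distance between rows of v and the all-ones vector."""
    m = v.shape[-1]
    norm = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = v.sum(axis=-1) / (norm * np.sqrt(m))
    return np.where(norm > 0, 1.0 - cos, 1.0)


def ntp_classify(
    expr: pd.DataFrame,
    templates: Sequence[SubtypeTemplate],
    n_perm: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Nearest-template prediction with a permutation null.

    Per sample, the distance to template ``t`` is the cosine distance
    between the sample's z-scored expression restricted to the template's
    genes and the matching all-ones vector; the prediction is the argmin.
    The null mirrors the selection step: each permutation draws one random
    same-size gene set per template and records the minimum distance, so
    noise-sample p-values are uniform. ``p = (1 + #{null <= d_pred}) /
    (n_perm + 1)``; BH across samples; a sample is unclassified iff its
    FDR exceeds ``fdr_threshold``.

    Returns a table indexed by sample with one ``dist_<template>`` column
    per template plus (predicted, p, fdr, label).
    """
    _check_unique_names(templates)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_genes = expr.shape[1]
    for t in templates:
        if len(t.markers) > n_genes:
            raise ValueError(f"template {t.name!r} larger than measured gene count")
    rng = np.random.default_rng(seed)
    z = zscore_genes(expr).to_numpy(dtype=float)
    cols = {g: i for i, g in enumerate(expr.columns)}

    dists = np.empty((len(expr), len(templates)))
    for j, t in enumerate(templates):
        idx = [cols[g] for g in t.markers if g in cols]
        if not idx:
            raise ValueError(f"template {t.name!r} has no genes in the matrix")
        dists[:, j] = _cosine_to_ones(z[:, idx])
    pred_idx = dists.argmin(axis=1)
    d_pred = dists[np.arange(len(expr)), pred_idx]

    sizes = [len([g for g in t.markers if g in cols]) for t in templates]
    z_sq = z**2

    def _null_dists(sets: np.ndarray, m: int) -> np.ndarray:
        """Distances of every sample to each of the given gene sets."""
        n_sets = sets.shape[0]
        ind = np.zeros((n_genes, n_sets))
        ind[sets.T, np.arange(n_sets)[None, :]] = 1.0
        sums = z @ ind
        norms = np.sqrt(z_sq @ ind)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - sums / (norms * np.sqrt(m))
        return np.where(norms > 0, d, 1.0)

    # The null mirrors the selection step: per permutation, one random gene
    # set per template, with the minimum distance recorded. When the template
    # sizes fit into the gene universe (as the disjoint marker programs do),
    # each permutation's sets are disjoint blocks of one random gene
    # permutation, matching the dependence structure of the real templates;
    # otherwise independent sets are drawn per template.
    null_min = np.full((len(expr), n_perm), np.inf)
    if sum(sizes) <= n_genes:
        perms = np.argsort(rng.random((n_perm, n_genes)), axis=1)
        offset = 0
        for m in sizes:
            d_null = _null_dists(perms[:, offset : offset + m], m)
            null_min = np.minimum(null_min, d_null)
            offset += m
    else:
        for m in sizes:
            sets = np.argsort(rng.random((n_perm, n_genes)), axis=1)[:, :m]
            null_min = np.minimum(null_min, _null_dists(sets, m))

    p = (1 + (null_min <= d_pred[:, None]).sum(axis=1)) / (n_perm + 1)
    fdr = bh_adjust(p)
    predicted = np.array([templates[i].name for i in pred_idx], dtype=object)
    label = predicted.copy()
    label[fdr > fdr_threshold] = UNCLASSIFIED

    out = pd.DataFrame(
        {f"dist_{t.name}": dists[:, j] for j, t in enumerate(templates)},
        index=expr.index,
    )
    out["predicted"] = predicted
    out["p"] = p
    out["fdr"] = fdr
    out["label"] = label
    return out


def estimate_composition(ntp_result: pd.DataFrame) -> pd.Series:
    """Per-label fraction of samples, with "unclassified" reported explicitly."""
    if ntp_result.empty:
        raise ValueError("empty NTP result")
    frac = ntp_result["label"].value_counts(normalize=True)
    if UNCLASSIFIED not in frac.index:
        frac[UNCLASSIFIED] = 0.0
    return frac.rename("fraction")


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------


def write_gmt(templates: Sequence[SubtypeTemplate], path: str | Path) -> None:
    lines = [
        "\t".join([t.name, f"{len(t.markers)} markers", *t.markers]) for t in templates
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> list[SubtypeTemplate]:
    templates = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        templates.append(SubtypeTemplate(fields[0], tuple(fields[2:])))
    _check_unique_names(templates)
    return templates
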