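"""Regulatory-diversity metrics and topic-module composition.

The inverse Simpson index (ISI), 1 / sum(p_i^2), is the effective number
of evenly used features. Applied to pseudobulk gene-expression
proportions (ISI GEX) or pooled binary peak accessibility (ISI ATAC) it
quantifies how broadly a group of cells spreads its regulatory output;
higher values mean more diversity and weaker lineage commitment. Because
ISI is sensitive to the number of cells pooled and the total counts,
:func:`isi_profile` subsamples every group to a common cell number and
downsamples the pseudobulk to a common depth before computing it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def inverse_simpson(p) -> float:
    """ISI = 1 / sum(p_i^2) for a proportion vector p (nonnegative, sums to 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0 or np.all(p == 0):
        raise ValueError("undefined for an all-zero vector")
    if np.any(p < 0):
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, expected 1")
    return float(1.0 / np.sum(p**2))


def isi_profile(
    counts: pd.DataFrame,
    group_labels,
    n_cells: int | None = None,
    depth: int | None = None,
    B: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample-size-controlled ISI per group of cells.

    For each group and each of ``B`` replicates: draw ``n_cells`` cells
    without replacement, pool them into a pseudobulk count vector,
    downsample that vector without replacement to exactly ``depth`` total
    counts, and compute the ISI of the resulting proportions. Defaults:
    ``n_cells`` is the smallest group size; ``depth`` is the smallest
    pseudobulk total any subsample can achieve (sum of the ``n_cells``
    lowest per-cell totals across groups), so downsampling is always
    feasible. Groups smaller than ``n_cells`` are skipped with a warning.

    Returns a table indexed by group with columns (mean_isi, sd_isi,
    n_cells, depth, B).
    """
    labels = pd.Series(np.asarray(group_labels, dtype=object), index=counts.index)
    groups = labels.groupby(labels).groups
    mat = counts.to_numpy()
    totals = mat.sum(axis=1)

    sizes = {g: len(ix) for g, ix in groups.items()}
    if n_cells is None:
        n_cells = min(sizes.values())
    if depth is None:
        depth = min(
            int(np.sort(totals[counts.index.get_indexer(ix)])[:n_cells].sum())
            for g, ix in groups.items()
            if sizes[g] >= n_cells
        )
    if depth <= 0:
        raise ValueError("depth must be positive")

    rng = np.random.default_rng(seed)
    rows = []
    for g in sorted(groups, key=str):
        ix = counts.index.get_indexer(groups[g])
        if len(ix) < n_cells:
            warnings.warn(f"group {g!r} has {len(ix)} < {n_cells} cells; skipped")
            continue
        vals = np.empty(B)
        for b in range(B):
            chosen = rng.choice(ix, size=n_cells, replace=False)
            pseudo = mat[chosen].sum(axis=0).astype(np.int64)
            total = int(pseudo.sum())
            if total < depth:
                raise ValueError(
                    f"group {g!r}: pseudobulk total {total} below requested depth {depth}"
                )
            down = rng.multivariate_hypergeometric(pseudo, depth)
            vals[b] = inverse_simpson(down / depth)
        rows.append((g, vals.mean(), vals.std(ddof=1) if B > 1 else 0.0, n_cells, depth, B))
    return pd.DataFrame(
        rows, columns=["group", "mean_isi", "sd_isi", "n_cells", "depth", "B"]
    ).set_index("group")


@dataclass
class TopicComposition:
    """Per-organoid fraction of cells per topic module with a mixing flag."""

    fractions: pd.DataFrame  # organoids x modules
    mixed: pd.Series
    dominant: pd.Series
    mixing_threshold: float


def topic_composition(
    topic_weights: pd.DataFrame,
    cell_organoid_labels,
    mixing_threshold: float = 0.10,
) -> TopicComposition:
    """Assign each cell to its argmax topic module and summarize per organoid.

    An organoid is flagged mixed iff at least two modules each hold at
    least ``mixing_threshold`` of its cells.
    """
    w = topic_weights.to_numpy(dtype=float)
    if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("topic weight rows must sum to 1 within 1e-6")
    labels = pd.Series(np.asarray(cell_organoid_labels, dtype=object), index=topic_weights.index)
    module = pd.Series(
        topic_weights.columns.to_numpy()[w.argmax(axis=1)], index=topic_weights.index
    )
    frac = (
        pd.crosstab(labels, module, normalize="index")
        .reindex(columns=topic_weights.columns, fill_value=0.0)
    )
    mixed = (frac >= mixing_threshold).sum(axis=1) >= 2
    dominant = frac.idxmax(axis=1)
    return TopicComposition(
        fractions=frac,
        mixed=mixed.rename("mixed"),
        dominant=dominant.rename("dominant"),
        mixing_threshold=mixing_threshold,
    )
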