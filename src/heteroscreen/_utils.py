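"""Small shared helpers: seeding, z-scoring, multiple-testing adjustment."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent substream for a named pipeline stage.

    The substream key is derived from the stage name, so enabling or
    disabling one stage never shifts the draws of another.
    """
    digest = hashlib.sha256(stage.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (gene) across rows (samples/cells).

    Zero-variance genes are set to z = 0 rather than dropped, keeping the
    sample dimensionality stable.
    """
    mu = expr.mean(axis=0)
    sd = expr.std(axis=0, ddof=0)
    z = (expr - mu).div(sd.where(sd > 0, 1.0), axis=1)
    z.loc[:, sd == 0] = 0.0
    return z


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
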