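"""Readers and writers for the standard on-disk formats.

* 10x-style triplet (matrix.mtx in Matrix Market coordinate integer
  format + features.tsv + barcodes.tsv, plus cell_meta.tsv) for atlases;
  peak intervals follow the BED convention, 0-based half-open.
* MAGeCK-style guide-count tables (guide_id, gene, one column per
  sample) with sample names encoding organoid_timepoint_replicate.
* Plain TSV for every tabular stage output.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .synthetic_data import AtlasBundle, LibraryDesign, ScreenCounts


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


# ---------------------------------------------------------------------------
# 10x-style triplet
# ---------------------------------------------------------------------------


def write_matrix_market(bundle: AtlasBundle, outdir: str | Path) -> None:
    """Write the RNA counts of an atlas as a 10x-style triplet directory.

    features.tsv rows are genes followed by peaks (peaks carry their
    BED-convention interval columns); only the gene block enters
    matrix.mtx, peaks are stored in atac.tsv as a dense binary table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(bundle.rna_counts.to_numpy())
    # Matrix Market convention here: genes x cells (features as rows)
    spio.mmwrite(outdir / "matrix.mtx", mat.T.astype(np.int64))
    genes = pd.DataFrame(
        {"feature_id": bundle.rna_counts.columns, "feature_type": "Gene Expression"}
    )
    genes.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(bundle.rna_counts.index).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    bundle.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    atac = bundle.atac_binary.copy()
    atac.to_csv(outdir / "atac.tsv", sep="\t")
    peaks = bundle.peak_meta.copy()
    peaks.index.name = "peak_id"
    peaks.to_csv(outdir / "peaks.tsv", sep="\t")


def read_matrix_market(indir: str | Path) -> AtlasBundle:
    """Read a triplet directory written by :func:`write_matrix_market`.

    Round-trips integer counts losslessly. Raises :class:`FormatError`
    on dimension mismatches between matrix.mtx and the feature/barcode
    files, and on empty matrices.
    """
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").tocsr().T  # back to cells x genes
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise FormatError(f"{indir / 'matrix.mtx'}: empty matrix")
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)
    if len(features) != mat.shape[1]:
        raise FormatError(
            f"features.tsv has {len(features)} rows but matrix.mtx claims "
            f"{mat.shape[1]} features"
        )
    if len(barcodes) != mat.shape[0]:
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix.mtx claims "
            f"{mat.shape[0]} cells"
        )
    cells = barcodes[0].astype(str).tolist()
    genes = features[0].astype(str).tolist()
    rna = pd.DataFrame(np.asarray(mat.todense(), dtype=np.int64), index=cells, columns=genes)
    cell_meta = pd.read_csv(indir / "cell_meta.tsv", sep="\t", index_col=0)
    atac_path = indir / "atac.tsv"
    if atac_path.exists():
        atac = pd.read_csv(atac_path, sep="\t", index_col=0)
        peak_meta = pd.read_csv(indir / "peaks.tsv", sep="\t", index_col=0)
    else:
        atac = pd.DataFrame(index=cells)
        peak_meta = pd.DataFrame(columns=["chrom", "start", "end"])
    return AtlasBundle(rna_counts=rna, atac_binary=atac, cell_meta=cell_meta, peak_meta=peak_meta)


# ---------------------------------------------------------------------------
# MAGeCK-style guide counts and library tables
# ---------------------------------------------------------------------------


def write_library(library: LibraryDesign, path: str | Path) -> None:
    library.guides.to_csv(path, sep="\t", index=False)


def read_library(path: str | Path) -> LibraryDesign:
    guides = pd.read_csv(path, sep="\t")
    guides["is_control"] = guides["is_control"].astype(bool)
    targeted = guides[~guides["is_control"]]
    gpg = int(targeted.groupby("gene").size().iloc[0]) if len(targeted) else 0
    n_ctrl = int(guides["is_control"].sum())
    cf = n_ctrl / len(guides) if len(guides) else 0.0
    from .synthetic_data import LibraryDesign as LD

    return LD(
        guides=guides,
        pools=tuple(dict.fromkeys(guides["pool"])),
        guides_per_gene=gpg,
        control_fraction=cf,
    )


def write_guide_counts(screen: ScreenCounts, library: LibraryDesign, path: str | Path) -> None:
    gene = library.guides.set_index("guide_id")["gene"]
    out = screen.counts.copy()
    out.insert(0, "gene", gene.reindex(out.index).to_numpy())
    out.index.name = "guide_id"
    out.round().astype(np.int64, errors="ignore").to_csv(path, sep="\t")


def read_guide_counts(path: str | Path) -> ScreenCounts:
    """Parse a MAGeCK-style count table.

    Columns: guide_id, gene, then one integer column per sample named
    ``organoid_timepoint_replicate``. Raises :class:`FormatError` (with
    the offending line number where applicable) for duplicate guide ids
    and negative or non-integer counts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "guide_id" or df.columns[1] != "gene":
        raise FormatError(f"{path}: first two columns must be guide_id, gene")
    dup = df["guide_id"].duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicated guide_id {df.loc[dup, 'guide_id'].iloc[0]!r}")
    sample_cols = list(df.columns[2:])
    counts = {}
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
            raise FormatError(f"{path}: non-integer or negative count at line {line}, column {col!r}")
        counts[col] = vals.astype(np.int64).to_numpy()
    mat = pd.DataFrame(counts, index=df["guide_id"].to_numpy())
    mat.index.name = "guide_id"
    meta_rows = []
    for col in sample_cols:
        parts = col.rsplit("_", 2)
        if len(parts) != 3:
            raise FormatError(
                f"{path}: sample column {col!r} does not follow organoid_timepoint_replicate"
            )
        org, tp, rep = parts
        meta_rows.append((col, org, tp, rep, int(mat[col].sum())))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "organoid", "timepoint", "replicate", "depth"]
    ).set_index("sample")
    return ScreenCounts(counts=mat, sample_meta=meta)


def read_bulk_expression(path: str | Path) -> pd.DataFrame:
    """Bulk expression TSV, genes x samples."""
    return pd.read_csv(path, sep="\t", index_col=0)
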