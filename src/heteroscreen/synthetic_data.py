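"""Generators for every input the pipeline consumes, with known ground truth.

The module emulates the study design of a multi-organoid single-cell
multiome atlas coupled to pooled CRISPR dropout screens:

* seven lineage programs (marker-gene sets and accessible-peak sets),
* per-organoid single-cell RNA count and binary peak-accessibility
  matrices composed of one to three latent subpopulations,
* custom sgRNA libraries (pools of targeted genes plus a fixed fraction
  of non-targeting/safe-harbor controls),
* pooled-screen guide-count tables produced by deterministic exponential
  growth of guide-carrying cells with subpopulation-specific per-doubling
  fitness effects, sampled multinomially at sequencing depth.

Stochasticity enters only through initial multinomial seeding of cells
and through sequencing sampling; growth itself is deterministic per
(guide, subpopulation). All outputs are byte-reproducible given a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel used in the `gene` column for non-targeting / safe-harbor guides
CONTROL_GENE = "CTRL"

DEFAULT_SUBTYPES = (
    "AR-high",
    "SCL",
    "SCL/VIM+",
    "SCL/ASCL1-low",
    "NEPC-A",
    "NEPC-A/N",
    "WNT",
)


class InvalidConfigError(ValueError):
    """Raised when a generator is configured inconsistently."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferencePrograms:
    """Lineage programs: per-subtype marker genes and accessible peaks."""

    subtype_names: tuple[str, ...]
    markers: dict[str, list[str]]
    effect_size: float
    peak_programs: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.subtype_names) < 1:
            raise InvalidConfigError("need at least one subtype")
        for name in self.subtype_names:
            genes = self.markers[name]
            if not genes:
                raise InvalidConfigError(f"empty marker list for {name!r}")
            if len(set(genes)) != len(genes):
                raise InvalidConfigError(f"duplicate gene ids within {name!r}")

    @property
    def all_marker_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for name in self.subtype_names:
            for g in self.markers[name]:
                seen.setdefault(g)
        return list(seen)


@dataclass(frozen=True)
class SubpopulationSpec:
    """One latent subpopulation inside an organoid."""

    label: str
    subtype: str
    fraction: float


@dataclass(frozen=True)
class OrganoidSpec:
    """Mixture of subpopulations making up one organoid."""

    organoid: str
    subpopulations: tuple[SubpopulationSpec, ...]

    def __post_init__(self) -> None:
        fr = np.array([s.fraction for s in self.subpopulations], dtype=float)
        if len(fr) == 0:
            raise InvalidConfigError(f"{self.organoid}: no subpopulations")
        if np.any(fr <= 0):
            raise InvalidConfigError(f"{self.organoid}: fractions must be > 0")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise InvalidConfigError(
                f"{self.organoid}: fractions sum to {fr.sum()!r}, expected 1"
            )


@dataclass(frozen=True)
class MixtureSpec:
    """Initial subpopulation fractions of one screened organoid."""

    organoid: str
    labels: tuple[str, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if len(self.labels) != len(fr) or len(fr) == 0:
            raise InvalidConfigError("labels and fractions must align and be nonempty")
        if np.any(fr <= 0):
            raise InvalidConfigError("all fractions must be > 0")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise InvalidConfigError(f"fractions sum to {fr.sum()!r}, expected 1")


@dataclass
class AtlasBundle:
    """Single-cell RNA counts plus binary peak accessibility with truth labels.

    ``rna_counts``: cells x genes nonnegative integers; ``atac_binary``:
    cells x peaks in {0, 1}; ``cell_meta`` carries the organoid id and the
    true subpopulation/subtype label of every cell; ``peak_meta`` holds
    0-based half-open peak intervals.
    """

    rna_counts: pd.DataFrame
    atac_binary: pd.DataFrame
    cell_meta: pd.DataFrame
    peak_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rna_counts.index.has_duplicates or self.rna_counts.columns.has_duplicates:
            raise InvalidConfigError("cell or gene ids are not unique")
        if (self.rna_counts.to_numpy() < 0).any():
            raise InvalidConfigError("negative counts")
        if not self.rna_counts.index.equals(self.cell_meta.index):
            raise InvalidConfigError("cell_meta does not match count matrix rows")

    def log_normalized(self, target_sum: float | None = None) -> pd.DataFrame:
        """Depth-normalize to ``target_sum`` (default: median depth), log2(1+x)."""
        totals = self.rna_counts.sum(axis=1).astype(float)
        if target_sum is None:
            target_sum = float(totals.median())
        scaled = self.rna_counts.div(totals.where(totals > 0, 1.0), axis=0) * target_sum
        return np.log2(1.0 + scaled)

    def to_anndata(self):
        """Return an :class:`anndata.AnnData` view of the RNA counts."""
        import anndata as ad
        from scipy import sparse

        return ad.AnnData(
            X=sparse.csr_matrix(self.rna_counts.to_numpy()),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.rna_counts.columns),
        )


@dataclass
class LibraryDesign:
    """sgRNA library: guide -> (gene | control sentinel, pool)."""

    guides: pd.DataFrame  # columns: guide_id, gene, pool, is_control
    pools: tuple[str, ...]
    guides_per_gene: int
    control_fraction: float

    def __post_init__(self) -> None:
        g = self.guides
        if g["guide_id"].duplicated().any():
            raise InvalidConfigError("duplicate guide ids")
        targeted = g.loc[~g["is_control"]]
        per_gene = targeted.groupby("gene", sort=False)
        if (per_gene["pool"].nunique() > 1).any():
            raise InvalidConfigError("a gene appears in more than one pool")
        if (per_gene.size() != self.guides_per_gene).any():
            raise InvalidConfigError("every targeted gene needs guides_per_gene guides")

    @property
    def targeted_genes(self) -> list[str]:
        return list(dict.fromkeys(self.guides.loc[~self.guides["is_control"], "gene"]))

    @property
    def control_guides(self) -> list[str]:
        return list(self.guides.loc[self.guides["is_control"], "guide_id"])


@dataclass
class FitnessModel:
    """Per-(gene, subpopulation) log2 fitness effects per doubling.

    ``s`` is a genes x subpopulations table; negative values deplete.
    ``baseline_r`` multiplies the shared doubling clock per subpopulation
    (default 1 for every subpopulation). ``guide_efficiency`` maps guide id
    to a value in [0, 1]; guides absent from the map get an efficiency
    drawn from Beta(9, 1) at simulation time (most guides effective).
    """

    s: pd.DataFrame
    baseline_r: pd.Series | None = None
    guide_efficiency: pd.Series | None = None
    doublings: float = 8.0

    def __post_init__(self) -> None:
        if self.doublings <= 0:
            raise InvalidConfigError("doublings must be > 0")
        if self.guide_efficiency is not None:
            eff = self.guide_efficiency.to_numpy(dtype=float)
            if np.any((eff < 0) | (eff > 1)):
                raise InvalidConfigError("guide efficiency must lie in [0, 1]")

    def baseline_for(self, labels: Sequence[str]) -> np.ndarray:
        if self.baseline_r is None:
            return np.ones(len(labels))
        return self.baseline_r.reindex(labels).fillna(1.0).to_numpy(dtype=float)


@dataclass
class ScreenCounts:
    """Guide x sample nonnegative integer counts with sample metadata."""

    counts: pd.DataFrame  # index guide_id, one column per sample
    sample_meta: pd.DataFrame  # index sample, columns organoid, timepoint, replicate, depth

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise InvalidConfigError("negative counts")
        if not self.counts.columns.equals(self.sample_meta.index):
            raise InvalidConfigError("sample metadata does not match count columns")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_reference_programs(
    n_subtypes: int = 7,
    genes_per_program: int = 50,
    overlap_fraction: float = 0.0,
    effect_size: float = 2.0,
    seed: int = 0,
    peaks_per_program: int = 30,
    subtype_names: Sequence[str] | None = None,
) -> ReferencePrograms:
    """Construct lineage programs with bounded pairwise marker overlap.

    Each program receives ``floor(overlap_fraction * genes_per_program)``
    genes from a shared pool plus private genes, so any two programs share
    at most that many markers.
    """
    if n_subtypes < 1:
        raise InvalidConfigError("n_subtypes must be >= 1")
    if not (0 <= overlap_fraction < 1):
        raise InvalidConfigError("overlap_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    if subtype_names is None:
        if n_subtypes == len(DEFAULT_SUBTYPES):
            subtype_names = DEFAULT_SUBTYPES
        else:
            subtype_names = tuple(f"SUBTYPE{i + 1}" for i in range(n_subtypes))
    subtype_names = tuple(subtype_names)

    n_shared = int(np.floor(overlap_fraction * genes_per_program))
    n_private = genes_per_program - n_shared
    shared = [f"SHR{j:04d}" for j in range(n_shared)]
    markers: dict[str, list[str]] = {}
    peak_programs: dict[str, list[str]] = {}
    for i, name in enumerate(subtype_names):
        private = [f"M{i:02d}G{j:03d}" for j in range(n_private)]
        genes = shared + private
        rng.shuffle(genes)
        markers[name] = genes
        peak_programs[name] = [f"peak_{i:02d}_{j:03d}" for j in range(peaks_per_program)]
    return ReferencePrograms(
        subtype_names=subtype_names,
        markers=markers,
        effect_size=float(effect_size),
        peak_programs=peak_programs,
    )


def simulate_atlas(
    programs: ReferencePrograms,
    organoid_specs: Sequence[OrganoidSpec],
    cells_per_organoid: int = 200,
    nb_dispersion: float = 0.3,
    depth_mean: float = 2000.0,
    seed: int = 0,
    n_background_genes: int = 300,
    n_background_peaks: int = 200,
    base_accessibility: float = 0.05,
    program_accessibility: float = 0.6,
) -> AtlasBundle:
    """Draw a multi-organoid single-cell atlas from the lineage programs.

    RNA counts follow a negative-binomial model: every gene has a shared
    log-normal baseline rate, markers of a cell's subtype are shifted up
    by ``2**effect_size``, and rates are scaled so the expected per-cell
    depth is ``depth_mean``. Peak accessibility is Bernoulli at
    ``base_accessibility`` everywhere and ``program_accessibility`` on the
    subtype's program peaks.
    """
    if cells_per_organoid <= 0:
        raise InvalidConfigError("cells_per_organoid must be > 0 (empty output)")
    if not organoid_specs:
        raise InvalidConfigError("no organoids specified (empty output)")
    rng = np.random.default_rng(seed)

    genes = programs.all_marker_genes + [f"BG{j:04d}" for j in range(n_background_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    peaks = [p for name in programs.subtype_names for p in programs.peak_programs[name]]
    peaks += [f"peak_bg_{j:04d}" for j in range(n_background_peaks)]
    peak_index = {p: i for i, p in enumerate(peaks)}

    base_rate = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    fold = 2.0 ** programs.effect_size
    subtype_rate: dict[str, np.ndarray] = {}
    subtype_peak_p: dict[str, np.ndarray] = {}
    for name in programs.subtype_names:
        rate = base_rate.copy()
        idx = [gene_index[g] for g in programs.markers[name]]
        rate[idx] *= fold
        subtype_rate[name] = depth_mean * rate / rate.sum()
        pvec = np.full(len(peaks), base_accessibility)
        pvec[[peak_index[p] for p in programs.peak_programs[name]]] = program_accessibility
        subtype_peak_p[name] = pvec

    r = 1.0 / nb_dispersion
    cell_ids: list[str] = []
    meta_rows: list[tuple[str, str, str]] = []
    rna_blocks: list[np.ndarray] = []
    atac_blocks: list[np.ndarray] = []
    for spec in organoid_specs:
        fractions = np.array([s.fraction for s in spec.subpopulations])
        assignment = rng.choice(len(fractions), size=cells_per_organoid, p=fractions)
        for ci, k in enumerate(assignment):
            sub = spec.subpopulations[k]
            cell_ids.append(f"{spec.organoid}_c{ci:05d}")
            meta_rows.append((spec.organoid, sub.label, sub.subtype))
        for k, sub in enumerate(spec.subpopulations):
            n_k = int((assignment == k).sum())
            if n_k == 0:
                continue
            mu = subtype_rate[sub.subtype]
            counts = rng.negative_binomial(r, r / (r + mu), size=(n_k, len(genes)))
            rna_blocks.append(counts)
            acc = rng.random((n_k, len(peaks))) < subtype_peak_p[sub.subtype]
            atac_blocks.append(acc.astype(np.int8))
    # blocks were drawn per subpopulation; scatter rows back to per-cell order
    rna = np.zeros((len(cell_ids), len(genes)), dtype=np.int64)
    atac = np.zeros((len(cell_ids), len(peaks)), dtype=np.int8)
    row = 0
    block = 0
    for spec in organoid_specs:
        n = cells_per_organoid
        labels = np.array([meta_rows[row + i][1] for i in range(n)])
        for sub in spec.subpopulations:
            mask = labels == sub.label
            if not mask.any():
                continue
            rna[row + np.flatnonzero(mask)] = rna_blocks[block]
            atac[row + np.flatnonzero(mask)] = atac_blocks[block]
            block += 1
        row += n

    cell_meta = pd.DataFrame(
        meta_rows, columns=["organoid", "subpopulation", "subtype"], index=cell_ids
    )
    peak_meta = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(len(peaks)) * 1000,
            "end": np.arange(len(peaks)) * 1000 + 500,
        },
        index=peaks,
    )
    return AtlasBundle(
        rna_counts=pd.DataFrame(rna, index=cell_ids, columns=genes),
        atac_binary=pd.DataFrame(atac, index=cell_ids, columns=peaks),
        cell_meta=cell_meta,
        peak_meta=peak_meta,
    )


def design_library(
    gene_lists_per_pool: Mapping[str, Sequence[str]],
    guides_per_gene: int = 4,
    control_fraction: float = 0.05,
    seed: int = 0,
) -> LibraryDesign:
    """Build an sgRNA library from per-pool gene lists.

    Controls are added per pool so that they make up exactly
    ``control_fraction`` of the final pool:
    ``n_controls = round(control_fraction / (1 - control_fraction) * n_targeting)``.
    """
    if not (0 <= control_fraction < 1):
        raise InvalidConfigError("control_fraction must lie in [0, 1)")
    seen: set[str] = set()
    for pool, genes in gene_lists_per_pool.items():
        dup = seen.intersection(genes)
        if dup:
            raise InvalidConfigError(f"genes in multiple pools: {sorted(dup)[:5]}")
        if len(set(genes)) != len(genes):
            raise InvalidConfigError(f"duplicate genes within pool {pool!r}")
        seen.update(genes)

    rows: list[tuple[str, str, str, bool]] = []
    for pool, genes in gene_lists_per_pool.items():
        for gene in genes:
            for i in range(guides_per_gene):
                rows.append((f"{gene}_sg{i + 1}", gene, pool, False))
        n_targeting = len(genes) * guides_per_gene
        n_controls = int(round(control_fraction / (1 - control_fraction) * n_targeting))
        for i in range(n_controls):
            rows.append((f"{pool}_{CONTROL_GENE}_{i + 1:04d}", CONTROL_GENE, pool, True))
    guides = pd.DataFrame(rows, columns=["guide_id", "gene", "pool", "is_control"])
    return LibraryDesign(
        guides=guides,
        pools=tuple(gene_lists_per_pool),
        guides_per_gene=guides_per_gene,
        control_fraction=control_fraction,
    )


def simulate_screen(
    library: LibraryDesign,
    fitness: FitnessModel,
    mixture: MixtureSpec | Sequence[MixtureSpec],
    T: float | None = None,
    coverage: float = 500.0,
    depth: int = 10_000_000,
    n_replicates: int = 1,
    seed: int = 0,
    overdispersion: float | None = None,
) -> ScreenCounts:
    """Simulate a pooled dropout screen under exponential subpopulation growth.

    Cells carrying guide ``j`` in subpopulation ``k`` grow deterministically as
    ``N_jk(T) = N_jk(0) * 2**((r_k + s_[g(j),k] * e_j) * T)``; sequencing counts
    at T0 and T1 are multinomial draws of size ``depth`` from the respective
    cell-share vectors. Initial cells are seeded multinomially, uniform over
    guides and proportional to the mixture fractions over subpopulations.

    ``overdispersion``, if set, replaces the multinomial read sampling with a
    Dirichlet-multinomial of that concentration scale (PCR noise knob).
    """
    if T is None:
        T = fitness.doublings
    if T <= 0:
        raise InvalidConfigError("T must be > 0")
    if depth <= 0:
        raise InvalidConfigError("depth must be > 0")
    if coverage < 50:
        raise InvalidConfigError("coverage must be >= 50x")
    mixtures = [mixture] if isinstance(mixture, MixtureSpec) else list(mixture)

    rng = np.random.default_rng(seed)
    guides = library.guides
    n_guides = len(guides)
    genes = guides["gene"].to_numpy()
    is_control = guides["is_control"].to_numpy()

    eff = np.empty(n_guides)
    known = (
        fitness.guide_efficiency.reindex(guides["guide_id"])
        if fitness.guide_efficiency is not None
        else pd.Series(np.nan, index=guides["guide_id"])
    )
    missing_eff = known.isna().to_numpy()
    eff[~missing_eff] = known.to_numpy(dtype=float)[~missing_eff]
    eff[missing_eff] = rng.beta(9, 1, size=int(missing_eff.sum()))

    missing = sorted(
        set(genes[~is_control]) - set(fitness.s.index.astype(str))
    )
    if missing:
        logger.warning(
            "%d library genes absent from fitness model; treated as neutral (s=0)",
            len(missing),
        )

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for mix in mixtures:
        labels = list(mix.labels)
        f = np.asarray(mix.fractions, dtype=float)
        s = (
            fitness.s.reindex(index=pd.Index(genes), columns=labels)
            .fillna(0.0)
            .to_numpy()
        )
        s[is_control, :] = 0.0
        r_k = fitness.baseline_for(labels)

        n_cells0 = int(round(coverage * n_guides))
        p0 = np.outer(np.full(n_guides, 1.0 / n_guides), f).ravel()
        n0 = rng.multinomial(n_cells0, p0).reshape(n_guides, len(labels)).astype(float)
        growth = 2.0 ** ((r_k[None, :] + s * eff[:, None]) * T)
        n1 = n0 * growth

        for tp, cells in (("T0", n0), ("T1", n1)):
            share = cells.sum(axis=1)
            share = share / share.sum()
            for rep in range(1, n_replicates + 1):
                if overdispersion is not None:
                    probs = rng.dirichlet(np.maximum(share, 1e-12) * overdispersion)
                else:
                    probs = share
                name = f"{mix.organoid}_{tp}_rep{rep}"
                cols[name] = rng.multinomial(depth, probs)
                meta_rows.append((name, mix.organoid, tp, f"rep{rep}", depth))

    counts = pd.DataFrame(cols, index=guides["guide_id"].to_numpy())
    counts.index.name = "guide_id"
    sample_meta = pd.DataFrame(
        meta_rows, columns=["sample", "organoid", "timepoint", "replicate", "depth"]
    ).set_index("sample")
    return ScreenCounts(counts=counts, sample_meta=sample_meta)


def simulate_bulk_cohort(
    programs: ReferencePrograms,
    subtype_per_sample: Sequence[str | None],
    noise_sd: float = 0.5,
    baseline_mean: float = 5.0,
    seed: int = 0,
    sample_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bulk log2-expression cohort: marker shift for the sample's subtype plus noise.

    ``None`` entries produce pure-noise samples carrying no program signal.
    Returns a samples x genes table over the full program gene universe.
    """
    rng = np.random.default_rng(seed)
    genes = programs.all_marker_genes
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(baseline_mean, 1.0, size=len(genes))
    rows = np.empty((len(subtype_per_sample), len(genes)))
    for i, subtype in enumerate(subtype_per_sample):
        x = baseline + rng.normal(0.0, noise_sd, size=len(genes))
        if subtype is not None:
            idx = [gene_index[g] for g in programs.markers[subtype]]
            x[idx] += programs.effect_size
        rows[i] = x
    if sample_names is None:
        sample_names = [f"S{i + 1:03d}" for i in range(len(subtype_per_sample))]
    return pd.DataFrame(rows, index=list(sample_names), columns=genes)


@dataclass
class LimitingCohort:
    """Planted fixture in which the lowest-expressing subpopulation is resistant.

    Dependency strength scales with expression (``s = -slope * x``), so the
    subpopulation expressing a gene least carries the weakest depletion,
    making it the resistant, growth-limiting pole of the mixture.
    """

    library: LibraryDesign
    screens: ScreenCounts
    bulk_expression: pd.DataFrame  # genes x organoids
    subpop_expression: pd.DataFrame  # gene, organoid, subpopulation, mean_expr, cell_fraction
    mixtures: list[MixtureSpec]
    doublings: float
    truth_s: pd.DataFrame  # gene, organoid, subpopulation, s


def simulate_limiting_cohort(
    n_organoids: int = 8,
    n_genes: int = 50,
    doublings: float = 8.0,
    coverage: float = 500.0,
    depth: int = 1_000_000,
    slope: float = 0.22,
    mu_range: tuple[float, float] = (2.0, 5.0),
    expr_sd: float = 0.7,
    shift_range: tuple[float, float] = (0.8, 1.4),
    p_low_dominant: float = 0.8,
    bulk_noise_sd: float = 0.5,
    seed: int = 0,
) -> LimitingCohort:
    """Simulate a multi-organoid screen cohort with expression-coupled fitness.

    Every organoid holds the same two subpopulation identities: a
    dominant clone (subA, fraction ~ U(0.65, 0.85)) and a minority clone
    (subB). Expression of gene ``g`` in organoid ``o`` shares an
    organoid-level regulatory component, ``x_A = mu_g + N(0, expr_sd)``,
    and the minority clone sits at a stable gene-specific offset,
    ``x_B = x_A + delta_g`` with ``|delta_g| ~ U(*shift_range)``; the
    dominant clone is the lower expressor for a fraction
    ``p_low_dominant`` of genes. Fitness couples to expression as
    ``s = -slope * x``, so the lowest-expressing clone always carries the
    weakest depletion and is the limiting (resistant) pole of the
    mixture. Bulk expression is the composition-weighted mean plus
    independent N(0, ``bulk_noise_sd``) measurement noise — the bulk
    assay is noisier than the single-cell-derived subpopulation means —
    which is what subpopulation-resolved prediction can recover from.
    """
    rng = np.random.default_rng(seed)
    genes = [f"DEP{g:03d}" for g in range(n_genes)]
    organoids = [f"ORG{o + 1:02d}" for o in range(n_organoids)]
    sublabels = ("subA", "subB")
    library = design_library({"pool1": genes}, guides_per_gene=4, control_fraction=0.05)
    efficiency = pd.Series(
        rng.beta(9, 1, size=len(library.guides)), index=library.guides["guide_id"]
    )

    mu = rng.uniform(*mu_range, size=n_genes)
    delta = rng.uniform(*shift_range, size=n_genes)
    delta *= np.where(rng.random(n_genes) < p_low_dominant, 1.0, -1.0)

    mixtures = []
    sub_rows = []
    truth_rows = []
    bulk = pd.DataFrame(index=genes, columns=organoids, dtype=float)
    col_frames = []
    meta_frames = []
    for o, org in enumerate(organoids):
        f_a = rng.uniform(0.65, 0.85)
        fractions = (f_a, 1.0 - f_a)
        mix = MixtureSpec(organoid=org, labels=sublabels, fractions=fractions)
        mixtures.append(mix)
        x_a = np.maximum(mu + rng.normal(0.0, expr_sd, size=n_genes), 0.1)
        x = np.column_stack([x_a, np.maximum(x_a + delta, 0.1)])
        s = -slope * x
        for gi, gene in enumerate(genes):
            for k, lab in enumerate(sublabels):
                sub_rows.append((gene, org, lab, x[gi, k], fractions[k]))
                truth_rows.append((gene, org, lab, s[gi, k]))
        bulk[org] = x @ np.asarray(fractions) + rng.normal(0.0, bulk_noise_sd, size=n_genes)
        fitness = FitnessModel(
            s=pd.DataFrame(s, index=genes, columns=sublabels),
            guide_efficiency=efficiency,
            doublings=doublings,
        )
        sc = simulate_screen(
            library,
            fitness,
            mix,
            T=doublings,
            coverage=coverage,
            depth=depth,
            seed=int(rng.integers(2**31)),
        )
        col_frames.append(sc.counts)
        meta_frames.append(sc.sample_meta)

    screens = ScreenCounts(
        counts=pd.concat(col_frames, axis=1),
        sample_meta=pd.concat(meta_frames, axis=0),
    )
    subpop_expression = pd.DataFrame(
        sub_rows, columns=["gene", "organoid", "subpopulation", "mean_expr", "cell_fraction"]
    )
    truth_s = pd.DataFrame(truth_rows, columns=["gene", "organoid", "subpopulation", "s"])
    return LimitingCohort(
        library=library,
        screens=screens,
        bulk_expression=bulk,
        subpop_expression=subpop_expression,
        mixtures=mixtures,
        doublings=doublings,
        truth_s=truth_s,
    )


def write_truth(path: str | Path, fitness: FitnessModel, mixtures: Sequence[MixtureSpec], seed: int) -> None:
    """Dump simulation ground truth (fitness matrix, fractions, T, seed) as JSON."""
    payload = {
        "seed": seed,
        "doublings": fitness.doublings,
        "fitness": {g: fitness.s.loc[g].to_dict() for g in fitness.s.index},
        "mixtures": {
            m.organoid: dict(zip(m.labels, m.fractions)) for m in mixtures
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
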