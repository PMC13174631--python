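"""End-to-end orchestration of the analysis stages from a single config.

The demo pipeline wires the stages the way the analysis is meant to be
run on real data: simulate (or load) a multi-organoid atlas, annotate
subtypes and check marker retention, quantify plasticity (ISI, topic
composition), estimate gene-level depletion from pooled screen counts,
and run the subpopulation-resolved leave-one-out inference. Every stage
writes plain TSV/JSON outputs into the run directory and registers row
counts and content hashes in manifest.json, so identical config + seed
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composite_dependency as cd
from . import io as hsio
from . import plasticity, screen_stats, subtype_annotation as ann
from . import synthetic_data as sd
from ._utils import stage_rng

logger = logging.getLogger(__name__)

STAGE_ORDER = [
    "simulate_atlas",
    "simulate_screen",
    "annotate",
    "ntp",
    "isi",
    "topics",
    "screen_beta",
    "loo",
    "report",
]

STAGE_DEPS = {
    "simulate_atlas": [],
    "simulate_screen": [],
    "annotate": ["simulate_atlas"],
    "ntp": ["simulate_atlas"],
    "isi": ["simulate_atlas"],
    "topics": ["simulate_atlas"],
    "screen_beta": ["simulate_screen"],
    "loo": ["simulate_screen", "screen_beta"],
    "report": [],
}


class StageOrderError(RuntimeError):
    """An enabled stage depends on a stage that is neither enabled nor done."""


@dataclass
class PipelineConfig:
    """Validated knobs for every stage; see docs/methods.md for units."""

    seed: int = 0
    outdir: str = "hs_out"
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    # atlas
    n_subtypes: int = 7
    genes_per_program: int = 50
    overlap_fraction: float = 0.0
    effect_size: float = 2.0
    n_organoids: int = 8
    cells_per_organoid: int = 200
    max_subpops: int = 3
    nb_dispersion: float = 0.3
    depth_mean: float = 2000.0
    # screen cohort
    screen_organoids: int = 8
    screen_genes: int = 50
    doublings: float = 8.0
    coverage: float = 500.0
    screen_depth: int = 1_000_000
    beta_permutations: int = 1000
    # annotation / NTP
    margin_threshold: float = 0.1
    min_significant: int = 10
    fdr_threshold: float = 0.05
    ntp_permutations: int = 1000
    ntp_samples_per_subtype: int = 5
    ntp_noise_samples: int = 10
    # plasticity
    isi_replicates: int = 50
    mixing_threshold: float = 0.10
    # dosage
    r_threshold: float = 0.5
    min_n_organoids: int = 4

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name, lo, hi in [
            ("margin_threshold", 0.0, np.inf),
            ("fdr_threshold", 0.0, 1.0),
            ("r_threshold", 0.0, 1.0),
            ("mixing_threshold", 0.0, 0.5),
            ("overlap_fraction", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_significant < 0 or self.min_significant > 20:
            raise ValueError("min_significant must lie in [0, 20]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate_atlas(cfg: PipelineConfig, outdir: Path) -> dict:
    rng = stage_rng(cfg.seed, "simulate_atlas")
    programs = sd.build_reference_programs(
        cfg.n_subtypes,
        cfg.genes_per_program,
        cfg.overlap_fraction,
        cfg.effect_size,
        seed=int(rng.integers(2**31)),
    )
    specs = []
    for o in range(cfg.n_organoids):
        k = int(rng.integers(1, cfg.max_subpops + 1))
        subtypes = rng.choice(programs.subtype_names, size=k, replace=False)
        fr = rng.dirichlet(np.full(k, 5.0))
        fr = fr / fr.sum()
        specs.append(
            sd.OrganoidSpec(
                organoid=f"PDO{o + 1:02d}",
                subpopulations=tuple(
                    sd.SubpopulationSpec(label=f"sub{j + 1}", subtype=str(st), fraction=float(f))
                    for j, (st, f) in enumerate(zip(subtypes, fr))
                ),
            )
        )
    atlas = sd.simulate_atlas(
        programs,
        specs,
        cells_per_organoid=cfg.cells_per_organoid,
        nb_dispersion=cfg.nb_dispersion,
        depth_mean=cfg.depth_mean,
        seed=int(rng.integers(2**31)),
    )
    hsio.write_matrix_market(atlas, outdir / "atlas")
    ann.write_gmt(ann.templates_from_programs(programs), outdir / "templates.gmt")
    return {
        "n_cells": int(atlas.rna_counts.shape[0]),
        "n_genes": int(atlas.rna_counts.shape[1]),
        "n_peaks": int(atlas.atac_binary.shape[1]),
        "files": ["atlas/matrix.mtx", "templates.gmt"],
    }


def stage_simulate_screen(cfg: PipelineConfig, outdir: Path) -> dict:
    rng = stage_rng(cfg.seed, "simulate_screen")
    cohort = sd.simulate_limiting_cohort(
        n_organoids=cfg.screen_organoids,
        n_genes=cfg.screen_genes,
        doublings=cfg.doublings,
        coverage=cfg.coverage,
        depth=cfg.screen_depth,
        seed=int(rng.integers(2**31)),
    )
    hsio.write_library(cohort.library, outdir / "library.tsv")
    hsio.write_guide_counts(cohort.screens, cohort.library, outdir / "counts.tsv")
    bulk = cohort.bulk_expression.copy()
    bulk.index.name = "gene"
    _write_tsv(bulk, outdir / "bulk_expression.tsv", index=True)
    _write_tsv(cohort.subpop_expression, outdir / "subpop_expression.tsv")
    _write_tsv(cohort.truth_s, outdir / "truth_s.tsv")
    return {
        "n_guides": int(len(cohort.library.guides)),
        "n_samples": int(cohort.screens.counts.shape[1]),
        "files": ["library.tsv", "counts.tsv", "bulk_expression.tsv", "subpop_expression.tsv"],
    }


def _load_atlas(outdir: Path):
    return hsio.read_matrix_market(outdir / "atlas")


def stage_annotate(cfg: PipelineConfig, outdir: Path) -> dict:
    atlas = _load_atlas(outdir)
    templates = ann.read_gmt(outdir / "templates.gmt")
    logn = atlas.log_normalized()
    scores = ann.score_signatures(logn, templates)
    labels = ann.assign_subtypes(scores, margin_threshold=cfg.margin_threshold)
    assigned = labels[labels != ann.INTERMEDIATE]
    markers = ann.rank_markers(logn.loc[assigned.index], assigned, n_top=20)
    retained, counts = ann.retention_test(markers, min_significant=cfg.min_significant)
    out = pd.DataFrame({"subtype": labels})
    out.index.name = "cell"
    _write_tsv(out, outdir / "annotation.tsv", index=True)
    _write_tsv(markers, outdir / "markers.tsv")
    ret = counts.rename("n_passing").to_frame()
    ret["retained"] = [s in retained for s in ret.index]
    ret.index.name = "subtype"
    _write_tsv(ret, outdir / "retention.tsv", index=True)
    return {
        "n_cells": int(len(labels)),
        "n_intermediate": int((labels == ann.INTERMEDIATE).sum()),
        "n_retained": len(retained),
        "files": ["annotation.tsv", "markers.tsv", "retention.tsv"],
    }


def stage_ntp(cfg: PipelineConfig, outdir: Path) -> dict:
    rng = stage_rng(cfg.seed, "ntp")
    templates = ann.read_gmt(outdir / "templates.gmt")
    programs = sd.ReferencePrograms(
        subtype_names=tuple(t.name for t in templates),
        markers={t.name: list(t.markers) for t in templates},
        effect_size=cfg.effect_size,
        peak_programs={t.name: [] for t in templates},
    )
    subtypes: list[str | None] = [
        t.name for t in templates for _ in range(cfg.ntp_samples_per_subtype)
    ]
    subtypes += [None] * cfg.ntp_noise_samples
    cohort = sd.simulate_bulk_cohort(programs, subtypes, seed=int(rng.integers(2**31)))
    result = ann.ntp_classify(
        cohort,
        templates,
        n_perm=cfg.ntp_permutations,
        fdr_threshold=cfg.fdr_threshold,
        seed=int(rng.integers(2**31)),
    )
    truth = pd.Series([s if s is not None else "noise" for s in subtypes], index=cohort.index)
    result = result.assign(truth=truth)
    result.index.name = "sample"
    _write_tsv(result, outdir / "ntp.tsv", index=True)
    comp = ann.estimate_composition(result).rename_axis("label").to_frame()
    _write_tsv(comp, outdir / "composition.tsv", index=True)
    correct = (result.loc[truth != "noise", "label"] == truth[truth != "noise"]).mean()
    return {
        "n_samples": int(len(result)),
        "accuracy_on_signal": float(correct),
        "files": ["ntp.tsv", "composition.tsv"],
    }


def stage_isi(cfg: PipelineConfig, outdir: Path) -> dict:
    rng = stage_rng(cfg.seed, "isi")
    atlas = _load_atlas(outdir)
    gex = plasticity.isi_profile(
        atlas.rna_counts,
        atlas.cell_meta["organoid"],
        B=cfg.isi_replicates,
        seed=int(rng.integers(2**31)),
    ).assign(modality="GEX")
    atac = plasticity.isi_profile(
        atlas.atac_binary,
        atlas.cell_meta["organoid"],
        B=cfg.isi_replicates,
        seed=int(rng.integers(2**31)),
    ).assign(modality="ATAC")
    isi = pd.concat([gex, atac])
    _write_tsv(isi, outdir / "isi.tsv", index=True)
    return {"n_groups": int(len(isi)), "files": ["isi.tsv"]}


def stage_topics(cfg: PipelineConfig, outdir: Path) -> dict:
    rng = stage_rng(cfg.seed, "topics")
    atlas = _load_atlas(outdir)
    subtypes = sorted(atlas.cell_meta["subtype"].unique())
    modules = {s: i for i, s in enumerate(subtypes)}
    alpha = np.full(len(subtypes), 0.5)
    weights = np.empty((len(atlas.cell_meta), len(subtypes)))
    for i, st in enumerate(atlas.cell_meta["subtype"]):
        a = alpha.copy()
        a[modules[st]] = 8.0
        weights[i] = rng.dirichlet(a)
    tw = pd.DataFrame(
        weights, index=atlas.cell_meta.index, columns=[f"topic{j + 1}" for j in range(len(subtypes))]
    )
    comp = plasticity.topic_composition(
        tw, atlas.cell_meta["organoid"], mixing_threshold=cfg.mixing_threshold
    )
    out = comp.fractions.copy()
    out["mixed"] = comp.mixed
    out["dominant"] = comp.dominant
    out.index.name = "organoid"
    _write_tsv(out, outdir / "topics.tsv", index=True)
    return {
        "n_organoids": int(len(out)),
        "n_mixed": int(comp.mixed.sum()),
        "files": ["topics.tsv"],
    }


def stage_screen_beta(cfg: PipelineConfig, outdir: Path) -> dict:
    rng = stage_rng(cfg.seed, "screen_beta")
    library = hsio.read_library(outdir / "library.tsv")
    screen = hsio.read_guide_counts(outdir / "counts.tsv")
    normalized = screen_stats.normalize_counts(screen, library)
    lfc = screen_stats.guide_lfc(normalized, library)
    beta = screen_stats.beta_significance(
        lfc, library, cfg.doublings, B=cfg.beta_permutations, seed=int(rng.integers(2**31))
    )
    _write_tsv(beta, outdir / "beta.tsv")
    bulk = hsio.read_bulk_expression(outdir / "bulk_expression.tsv")
    dosage = screen_stats.dosage_correlation(
        beta, bulk, r_threshold=cfg.r_threshold, min_n=cfg.min_n_organoids
    )
    _write_tsv(dosage, outdir / "dosage.tsv")
    return {
        "n_gene_organoid": int(len(beta)),
        "n_dosage_sensitive": int(dosage["dosage_sensitive"].sum()),
        "files": ["beta.tsv", "dosage.tsv"],
    }


def stage_loo(cfg: PipelineConfig, outdir: Path) -> dict:
    beta = pd.read_csv(outdir / "beta.tsv", sep="\t")
    bulk = hsio.read_bulk_expression(outdir / "bulk_expression.tsv")
    subpop = pd.read_csv(outdir / "subpop_expression.tsv", sep="\t")
    preds = cd.loo_fit_all(beta, bulk, min_train=4)
    loo = cd.subpop_residuals(preds, subpop)
    r2 = cd.r2_compare(loo)
    summary = cd.winner_lowexpr_association(loo, subpop)
    _write_tsv(loo.summary, outdir / "loo_results.tsv")
    _write_tsv(r2, outdir / "r2_compare.tsv")
    _write_tsv(summary.per_organoid, outdir / "winner_summary.tsv")
    gtab = summary.per_organoid[["organoid", "G", "df", "g_p"]]
    _write_tsv(gtab, outdir / "gtest.tsv")
    return {
        "n_gene_organoid": int(len(loo.summary)),
        "pooled_match_rate": float(summary.pooled_match_rate),
        "pooled_binom_p": float(summary.pooled_binom_p),
        "files": ["loo_results.tsv", "r2_compare.tsv", "winner_summary.tsv", "gtest.tsv"],
    }


def stage_report(cfg: PipelineConfig, outdir: Path) -> dict:
    lines = []
    for f in sorted(outdir.glob("*.tsv")):
        n = sum(1 for _ in f.open()) - 1
        lines.append(f"{f.name}\t{n}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return {"n_outputs": len(lines), "files": ["report.txt"]}


STAGE_FUNCS = {
    "simulate_atlas": stage_simulate_atlas,
    "simulate_screen": stage_simulate_screen,
    "annotate": stage_annotate,
    "ntp": stage_ntp,
    "isi": stage_isi,
    "topics": stage_topics,
    "screen_beta": stage_screen_beta,
    "loo": stage_loo,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write manifest.json.

    Raises :class:`StageOrderError` before running anything if an enabled
    stage's dependency is neither enabled nor already satisfied on disk.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGE_ORDER if s in cfg.stages]
    done_markers = {
        "simulate_atlas": outdir / "atlas" / "matrix.mtx",
        "simulate_screen": outdir / "counts.tsv",
        "screen_beta": outdir / "beta.tsv",
    }
    for s in enabled:
        for dep in STAGE_DEPS[s]:
            if dep not in enabled and not done_markers.get(dep, Path("/nonexistent")).exists():
                raise StageOrderError(f"stage {s!r} requires {dep!r}, which is not enabled")

    cfg_text = json.dumps(asdict(cfg), sort_keys=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }
    for s in enabled:
        t0 = time.monotonic()
        logger.info("stage %s ...", s)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            info = STAGE_FUNCS[s](cfg, outdir)
        for w in caught:
            manifest["warnings"].append(f"{s}: {w.message}")
        info["seconds"] = round(time.monotonic() - t0, 3)
        info["output_hashes"] = {
            f: _hash_file(outdir / f) for f in info.get("files", []) if (outdir / f).exists()
        }
        manifest["stages"][s] = info
        logger.info("stage %s done in %.1fs", s, info["seconds"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
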