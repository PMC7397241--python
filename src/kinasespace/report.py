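"""End-to-end pipeline orchestration and tabular report bundle.

Runs the stages of the analysis — ingestion, descriptor/rule profiling
and guidelines, PCA, PMI, scaffold diversity, ring-system frequencies,
similarity — over one labeled molecule set and writes every result as a
CSV (plus a JSON manifest with seeds, stage list and row counts), so any
number in the bundle is re-derivable from the per-stage tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .chemio import MoleculeRecord, read_molecules, standardize_library, write_records
from .chemspace import PCA_VARIABLES, correlation_circle, fit_pca, project
from .descriptors import (
    derive_guidelines,
    descriptor_frame,
    guidelines_frame,
    violation_distribution,
)
from .ringsys import bicycle_frequency, bicycle_prevalence
from .scaffolds import diversity_stats, scaffold_records
from .shape3d import pmi_table
from .similarity import pairwise_similarity

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ["ingest", "descriptors", "pca", "pmi", "scaffolds", "rings", "similarity"]


@dataclass
class RunConfig:
    input_path: str
    input_format: str = "smi"
    smiles_col: str = "smiles"
    label: str = "OTHER"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    out_dir: str = "kinasespace_out"
    seed: int = 42
    sd_mult: float = 2.0
    n_confs: int = 10
    butina_threshold: float = 0.6
    top_k_rings: int = 10
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        if not Path(cfg.input_path).exists():
            raise FileNotFoundError(cfg.input_path)
        unknown = set(cfg.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        return cfg


def _frequency_csv(table, path: Path) -> None:
    ranked = table.top(len(table.entries))
    pd.DataFrame(ranked, columns=["key", "count", "frequency"]).to_csv(path, index=False)


def run_pipeline(
    config: RunConfig, records: Optional[Sequence[MoleculeRecord]] = None
) -> dict:
    """Run the configured stages and write the report bundle.

    ``records`` may be passed directly (already standardized) to bypass
    file ingestion.  Returns the manifest dictionary; a stage failure
    marks the bundle partial instead of aborting the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "partial": False,
        "config": dataclasses.asdict(config),
    }

    def run_stage(name, fn):
        if name not in config.stages:
            manifest["stages"][name] = {"status": "skipped"}
            return
        t0 = time.perf_counter()
        try:
            info = fn() or {}
            info.update(status="ok", seconds=round(time.perf_counter() - t0, 2))
        except Exception as exc:
            logger.exception("stage %s failed", name)
            info = {"status": "failed", "error": str(exc)}
            manifest["partial"] = True
        manifest["stages"][name] = info

    state: dict = {"records": list(records) if records is not None else None}

    def stage_ingest():
        if state["records"] is None:
            from .chemio import DatasetLabel

            raw, n_skipped = read_molecules(
                config.input_path, config.input_format,
                smiles_col=config.smiles_col,
                default_label=DatasetLabel(config.label),
            )
            state["records"], report = standardize_library(raw, n_skipped)
        else:
            state["records"], report = standardize_library(state["records"])
        write_records(state["records"], out / "molecules.csv")
        return dataclasses.asdict(report)

    def stage_descriptors():
        frame = descriptor_frame(state["records"])
        state["descriptors"] = frame
        frame.to_csv(out / "descriptors.csv", index_label="id")
        from .descriptors import compute_descriptors

        vectors = [compute_descriptors(r) for r in state["records"]]
        violation_distribution(vectors).to_csv(out / "lipinski_violations.csv", index=False)
        guidelines = derive_guidelines(frame, config.sd_mult)
        guidelines_frame(guidelines).to_csv(out / "guidelines.csv", index=False)
        return {"n_molecules": len(frame)}

    def stage_pca():
        frame = state["descriptors"]
        model = fit_pca(frame, PCA_VARIABLES)
        labels = [r.dataset_label.value for r in state["records"]]
        proj = project(model, frame, labels=labels)
        model.loadings.to_csv(out / "pca_loadings.csv", index_label="variable")
        model.contributions.to_csv(out / "pca_contributions.csv", index_label="variable")
        pd.DataFrame(
            {"eigenvalue": model.eigenvalues, "explained_ratio": model.explained_ratio},
            index=model.loadings.columns,
        ).to_csv(out / "pca_variance.csv", index_label="component")
        scores = proj.scores.copy()
        scores["dataset_label"] = labels
        scores.to_csv(out / "pca_scores.csv", index_label="id")
        correlation_circle(model).to_csv(out / "pca_correlation_circle.csv", index_label="variable")
        if config.make_plots:
            _plot_pca(proj, model, out)
        return {"explained_pc1_pct": round(100 * model.explained_ratio[0], 1),
                "explained_pc2_pct": round(100 * model.explained_ratio[1], 1)}

    def stage_pmi():
        table = pmi_table(state["records"], n_confs=config.n_confs, seed=config.seed)
        table.to_csv(out / "pmi.csv", index=False)
        if config.make_plots:
            _plot_pmi(table, out)
        return {"n_points": len(table)}

    def stage_scaffolds():
        scaffs = scaffold_records(state["records"])
        pd.DataFrame(
            [(s.molecule_id, s.bm_smiles, s.gf_smiles, s.is_macrocyclic) for s in scaffs],
            columns=["molecule_id", "bm_smiles", "gf_smiles", "is_macrocyclic"],
        ).to_csv(out / "scaffolds.csv", index=False)
        stats = diversity_stats(state["records"])
        with open(out / "scaffold_stats.json", "w") as fh:
            json.dump(
                {
                    "n_molecules": stats.n_molecules,
                    "n_macrocycles": stats.n_macrocycles,
                    "pct_macrocycles": round(stats.pct_macrocycles, 1),
                    "n_unique_bm": stats.n_unique_bm,
                    "pct_unique_bm": round(stats.pct_unique_bm, 1),
                    "n_unique_gf": stats.n_unique_gf,
                    "pct_unique_gf": round(stats.pct_unique_gf, 1),
                    "similarity_mean": stats.similarity_mean,
                    "similarity_sd": stats.similarity_sd,
                },
                fh,
                indent=2,
            )
        return {"n_unique_bm": stats.n_unique_bm, "n_unique_gf": stats.n_unique_gf}

    def stage_rings():
        for mode in ("unpositioned", "positioned"):
            table = bicycle_frequency(state["records"], mode)
            _frequency_csv(table, out / f"bicycles_{mode}.csv")
        prevalence = bicycle_prevalence(state["records"])
        with open(out / "ring_stats.json", "w") as fh:
            json.dump({"bicycle_prevalence_pct": round(100 * prevalence, 1)}, fh)
        return {"bicycle_prevalence_pct": round(100 * prevalence, 1)}

    def stage_similarity():
        stats = pairwise_similarity(state["records"], "structural_keys_166")
        with open(out / "similarity.json", "w") as fh:
            json.dump(dataclasses.asdict(stats), fh, indent=2)
        return {"mean": round(stats.mean, 3)}

    run_stage("ingest", stage_ingest)
    if state["records"] is None or not state["records"]:
        manifest["partial"] = True
    else:
        run_stage("descriptors", stage_descriptors)
        if "descriptors" in state:
            run_stage("pca", stage_pca)
        run_stage("pmi", stage_pmi)
        run_stage("scaffolds", stage_scaffolds)
        run_stage("rings", stage_rings)
        run_stage("similarity", stage_similarity)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _plot_pca(proj, model, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 5))
    ax1.scatter(proj.scores.iloc[:, 0], proj.scores.iloc[:, 1], s=8, alpha=0.6)
    ax1.set_xlabel("PC1")
    ax1.set_ylabel("PC2")
    circle = correlation_circle(model)
    for var, (x, y) in circle.iterrows():
        ax2.annotate(var, (x, y))
        ax2.arrow(0, 0, x, y, head_width=0.02, length_includes_head=True)
    ax2.add_patch(plt.Circle((0, 0), 1.0, fill=False))
    ax2.set_xlim(-1.1, 1.1)
    ax2.set_ylim(-1.1, 1.1)
    ax2.set_aspect("equal")
    fig.savefig(out / "pca.png", dpi=120)
    plt.close(fig)


def _plot_pmi(table: pd.DataFrame, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    refs = table[table.dataset_label == "REFERENCE"]
    rest = table[table.dataset_label != "REFERENCE"]
    ax.plot([0, 0.5, 1, 0], [1, 0.5, 1, 1], "k-", lw=1)
    ax.scatter(rest.NPR1, rest.NPR2, s=10, alpha=0.6)
    ax.scatter(refs.NPR1, refs.NPR2, marker="^", color="red")
    ax.set_xlabel("NPR1")
    ax.set_ylabel("NPR2")
    fig.savefig(out / "pmi.png", dpi=120)
    plt.close(fig)
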