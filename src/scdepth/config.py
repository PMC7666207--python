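"""Run-level configuration and the reproducible study driver.

``RunConfig`` nests the generator, pipeline and grid parameters under a
single global seed, serialises to human-readable YAML, and every study
run writes its resolved configuration next to its outputs so runs are
diffable and repeatable. ``run_study`` is the deterministic end-to-end
entry point: same config + seed, byte-identical metric TSVs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benchmark, report
from .cluster import run_tsne
from .datagen import GeneratorConfig, SubtypePopulation, generate_dataset
from .pipeline import PipelineConfig, cluster_pipeline
from .subsample import (
    CellGrid,
    DepthGrid,
    compute_depth_metrics,
    fraction_for_target_depth,
    subsample_reads,
)

__all__ = ["RunConfig", "run_study"]

log = logging.getLogger(__name__)
_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    depth_grid: DepthGrid = field(default_factory=DepthGrid)
    cell_grid: CellGrid = field(default_factory=CellGrid)
    cell_arm_depths: tuple = ("full",)
    seed: int = 0
    with_tsne: bool = False

    def resolved(self) -> "RunConfig":
        """Propagate the global seed into every seeded sub-config."""
        return replace(
            self,
            generator=replace(self.generator, seed=self.seed),
            pipeline=replace(self.pipeline, seed=self.seed),
            depth_grid=replace(self.depth_grid, base_seed=self.seed + 1),
            cell_grid=replace(self.cell_grid, base_seed=self.seed + 2),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["subtypes"] = [asdict(s) for s in self.generator.subtypes]
        d["generator"]["marker_expression_band"] = list(self.generator.marker_expression_band)
        d["pipeline"] = self.pipeline.to_dict()
        d["pipeline"]["required_markers"] = list(self.pipeline.required_markers)
        d["cell_arm_depths"] = list(self.cell_arm_depths)
        d["depth_grid"]["targets"] = list(self.depth_grid.targets)
        d["cell_grid"]["targets"] = list(self.cell_grid.targets)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.get("generator", {}))
        if "subtypes" in gen:
            gen["subtypes"] = tuple(SubtypePopulation(**s) for s in gen["subtypes"])
        if "marker_expression_band" in gen:
            gen["marker_expression_band"] = tuple(gen["marker_expression_band"])
        dg = dict(d.get("depth_grid", {}))
        cg = dict(d.get("cell_grid", {}))
        dg["targets"] = tuple(dg.get("targets", ()))
        cg["targets"] = tuple(cg.get("targets", ()))
        return cls(
            generator=GeneratorConfig(**gen),
            pipeline=PipelineConfig.from_dict(d.get("pipeline", {})),
            depth_grid=DepthGrid(**dg),
            cell_grid=CellGrid(**cg),
            cell_arm_depths=tuple(d.get("cell_arm_depths", ("full",))),
            seed=int(d.get("seed", 0)),
            with_tsne=bool(d.get("with_tsne", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_study(cfg: RunConfig, out_dir, depth_metric_replicates: int = 1) -> dict:
    """Simulate, benchmark and summarise one study; write TSVs + figures.

    Outputs under ``out_dir``: the resolved config (``config.yaml``),
    sequencing metrics across the depth grid (``depth_metrics.tsv``), the
    benchmark grid (``benchmark_grid.tsv``), the median-accuracy tiles
    (``accuracy_tiles.tsv``) and, optionally, tSNE coordinates of the
    reference clustering plus the report figures.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = cfg.resolved()
    cfg.to_yaml(out_dir / "config.yaml")
    log.info("running study into %s (seed %d)", out_dir, cfg.seed)

    cm, reads, truth = generate_dataset(cfg.generator)

    # depth-metric curves across the depth grid (plus the full dataset)
    metric_rows = []
    realized = reads.total_reads / cm.n_cells
    for target in list(cfg.depth_grid.targets) + ["full"]:
        n_rep = 1 if target == "full" else depth_metric_replicates
        for rep in range(n_rep):
            if target == "full":
                t_cm, t_reads, t_label = cm, reads, realized
                seed = cfg.seed
            else:
                if target > realized:
                    continue
                seed = cfg.depth_grid.replicate_seed(target, rep)
                f = fraction_for_target_depth(reads, target)
                t_cm, t_reads = subsample_reads(cm, reads, f, seed)
                t_label = float(target)
            m = compute_depth_metrics(t_cm, t_reads)
            metric_rows.append(
                {
                    "condition": cfg.generator.condition,
                    "depth_target": t_label,
                    "replicate": rep,
                    "seed": seed,
                    **m.as_dict(),
                }
            )
    depth_metrics = pd.DataFrame(metric_rows)
    _write_tsv(depth_metrics, out_dir / report.DEPTH_TSV)

    records = benchmark.run_grid(
        cm,
        reads,
        cfg.pipeline,
        depth_grid=cfg.depth_grid,
        cell_grid=cfg.cell_grid,
        cell_arm_depths=cfg.cell_arm_depths,
        condition=cfg.generator.condition,
    )
    grid = benchmark.records_to_frame(records)
    _write_tsv(grid, out_dir / report.GRID_TSV)
    tiles = benchmark.median_accuracy_table(records)
    _write_tsv(tiles, out_dir / "accuracy_tiles.tsv")

    if cfg.with_tsne:
        ref = cluster_pipeline(cm, cfg.pipeline, seed=cfg.seed)
        keep = np.isin(ref.cm_qc.barcodes, ref.labels.barcodes)
        coords = run_tsne(ref.pca.embeddings[keep], seed=cfg.seed)
        tsne = pd.DataFrame(
            {
                "barcode": ref.labels.barcodes,
                "tsne_1": coords[:, 0],
                "tsne_2": coords[:, 1],
                "cluster": ref.labels.labels,
            }
        )
        _write_tsv(tsne, out_dir / report.TSNE_TSV)

    figures = report.make_report(out_dir)
    return {
        "out_dir": out_dir,
        "records": records,
        "grid": grid,
        "depth_metrics": depth_metrics,
        "tiles": tiles,
        "figures": figures,
        "truth": truth,
    }
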