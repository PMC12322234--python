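"""End-to-end orchestration: read -> log10 -> batch correction -> ratios ->
consensus clustering -> optional contrast and screen mining.

Every run writes a ``manifest.json`` recording the package version, seed,
a hash of the configuration, and per-stage row/column counts, so a run is
reproducible and each stage re-runnable from its intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import consensus_cluster, k_diagnostics
from .containers import LOWER_IS_MORE_SENSITIVE
from .contrast import contrast_clusters
from .io import (
    log10_transform,
    read_abundance_table,
    read_pathway_gene_map,
    read_pathways,
    read_sample_metadata,
    read_screen_table,
    write_abundance_table,
)
from .ratios import build_ratio_features, compute_ratio_matrix, zscore_features
from .ruv import aggregate_replicates, build_replicate_design, replicate_cocluster_report, ruv3_correct
from .screens import consolidate_pathways, differential_response, join_screens, top_n_targets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; see the pipeline stage list."""

    abundance: str
    metadata: str
    pathways: str
    out_dir: str
    screens: dict[str, str] = field(default_factory=dict)  # database name -> path
    kegg_map: str | None = None
    ruv_k: int = 9
    controls: list[str] | None = None  # None = all metabolites
    k: str | int = "auto"  # "auto" or a fixed integer
    k_range: list[int] = field(default_factory=lambda: list(range(2, 9)))
    n_reps: int = 1000
    gap_b: int = 50
    q: float = 0.05
    contrast_pair: list[int] | None = None
    impute_lod: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_header(stage: str, seed: int) -> str:
    return f"metaboratio {stage} seed={seed}"


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, seed: int, index_label=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {_stage_header(stage, seed)}\n")
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all configured stages; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "stages": {},
    }

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    try:
        raw = read_abundance_table(cfg.abundance)
        meta = read_sample_metadata(cfg.metadata)
        pathways = read_pathways(cfg.pathways)
    except Exception as exc:
        raise RuntimeError(f"stage=read: {exc}") from exc
    stage("read", samples=raw.shape[0], metabolites=raw.shape[1], pathways=len(pathways))

    logged = log10_transform(raw, impute_lod=cfg.impute_lod)
    stage("log10", samples=logged.shape[0], metabolites=logged.shape[1])

    try:
        design = build_replicate_design(meta, logged.sample_ids)
        model = ruv3_correct(logged, design, controls=cfg.controls, k=cfg.ruv_k)
    except Exception as exc:
        raise RuntimeError(f"stage=ruv3: {exc}") from exc
    write_abundance_table(model.corrected, out / "corrected.tsv",
                          header_comment=_stage_header("correct", cfg.seed))
    pd.DataFrame(model.W, index=logged.sample_ids).to_csv(out / "W.tsv", sep="\t")
    pd.DataFrame(model.alpha, columns=logged.metabolite_ids).to_csv(out / "alpha.tsv", sep="\t")
    stage("ruv3", k=model.k, replicate_groups=design.n_groups)

    aggregated = aggregate_replicates(model.corrected, meta)
    stage("aggregate", cell_lines=aggregated.shape[0])

    try:
        feats = build_ratio_features(pathways, aggregated.metabolite_ids)
        ratios = compute_ratio_matrix(aggregated, feats)
    except Exception as exc:
        raise RuntimeError(f"stage=ratios: {exc}") from exc
    scaled = zscore_features(ratios)
    _write_tsv(ratios.data, out / "ratios.tsv", "ratios", cfg.seed, index_label="cell_line")
    _write_tsv(scaled.data, out / "ratios.scaled.tsv", "ratios", cfg.seed, index_label="cell_line")
    stage("ratios", features=len(feats), retained_scaled=scaled.data.shape[1])

    try:
        diag = k_diagnostics(scaled, k_range=cfg.k_range, seed=cfg.seed, gap_B=cfg.gap_b)
        chosen_k = diag.combined_k if cfg.k == "auto" else int(cfg.k)
        result = consensus_cluster(scaled, chosen_k, n_reps=cfg.n_reps, seed=cfg.seed,
                                   diagnostics=diag)
    except Exception as exc:
        raise RuntimeError(f"stage=cluster: {exc}") from exc
    _write_tsv(result.labels.rename("cluster").to_frame(), out / "labels.tsv",
               "cluster", cfg.seed, index_label="cell_line")
    _write_tsv(result.coassociation, out / "coassociation.tsv", "cluster", cfg.seed,
               index_label="cell_line")
    with open(out / "diagnostics.json", "w", encoding="utf-8") as fh:
        json.dump(diag.to_dict(), fh, indent=2, sort_keys=True)
    # quality gate: cross-batch replicates of a cell line share the
    # cell-line-level label by construction; report on the sample level
    stage("cluster", k=result.k, n_reps=cfg.n_reps, combined_k=diag.combined_k,
          gap_k=diag.gap_k, elbow_k=diag.elbow_k, silhouette_k=diag.silhouette_k)

    if cfg.contrast_pair:
        a, b = cfg.contrast_pair
        try:
            table = contrast_clusters(ratios.data, result.labels, a, b, q=cfg.q)
        except Exception as exc:
            raise RuntimeError(f"stage=contrast: {exc}") from exc
        _write_tsv(table, out / f"contrast_{a}_vs_{b}.tsv", "contrast", cfg.seed)
        stage("contrast", pair=[a, b], features=len(table),
              rejected=int(table["reject"].sum()))

    if cfg.screens:
        if not cfg.kegg_map:
            raise RuntimeError("stage=screens: screens configured without a kegg_map path")
        kegg = read_pathway_gene_map(cfg.kegg_map)
        if not cfg.contrast_pair:
            raise RuntimeError("stage=screens: screen mining needs a contrast_pair")
        a, b = cfg.contrast_pair
        tops: dict[str, pd.DataFrame] = {}
        for db, path in cfg.screens.items():
            try:
                screen = read_screen_table(path)
                filtered, counts = join_screens(screen, result.labels, kegg)
                dt = differential_response(filtered, result.labels, a, b, kegg=kegg)
            except Exception as exc:
                raise RuntimeError(f"stage=screens[{db}]: {exc}") from exc
            top = top_n_targets(dt, n=20)
            tops[db] = top
            _write_tsv(dt, out / f"differential_{db}.tsv", "screens", cfg.seed)
            _write_tsv(top, out / f"top20_{db}.tsv", "screens", cfg.seed)
            stage(f"screens_{db}", **counts, targets_tested=len(dt))
        scores = consolidate_pathways(tops, kegg)
        _write_tsv(scores, out / "pathway_scores.tsv", "screens", cfg.seed)
        stage("pathway_scores", pathways=len(scores))

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
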