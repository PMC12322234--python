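"""Synthetic abundance panels, metadata, and screen tables.

The generator emulates the structure of a targeted cell-line metabolomics
study: ~60 cell lines profiled in triplicate across 6 batches with shared
anchor (control) cell lines, log-normal concentrations, planted cluster
structure expressed as pathway product-to-precursor ratio shifts, a
per-sample global scaling that masks raw-abundance clustering, and
cluster-dependent vulnerabilities in loss-of-function / drug screens.

All effects are additive on the log10 scale (multiplicative on
concentrations).  Precursor metabolites receive no cluster shift, so the
planted "pathway activity" is by construction a product-to-precursor ratio
shift that the ratio transform recovers.  The ground truth is emitted
alongside the data and is never consumed by the pipeline under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    LOWER_IS_MORE_SENSITIVE,
    RAW,
    AbundanceMatrix,
    Pathway,
    PathwaySet,
    ScreenTable,
    validate_pathway_gene_map,
    validate_sample_metadata,
)


def default_pathway_set() -> PathwaySet:
    """Seven central-carbon / amino-acid pathways over a 50-metabolite panel.

    Precursors (denominators) follow the usual convention: glucose for
    glycolysis and the pentose phosphate pathway, pyruvate for the TCA
    cycle, and glutamine, serine, proline, methionine for their pathways.
    Shared intermediates (pyruvate, alpha-ketoglutarate) appear in more
    than one pathway, as they do in real panels.
    """
    return PathwaySet(
        [
            Pathway(
                "glycolysis",
                "glucose",
                ("G6P", "F6P", "FBP", "DHAP", "GAP", "3PG", "2PG", "PEP", "pyruvate", "lactate"),
            ),
            Pathway("pentose_phosphate", "glucose", ("6PG", "R5P", "X5P", "S7P", "E4P")),
            Pathway(
                "tca_cycle",
                "pyruvate",
                ("citrate", "aconitate", "AKG", "succinate", "fumarate", "malate",
                 "OAA", "acetyl-CoA", "NADH", "NADPH"),
            ),
            Pathway("glutamine", "glutamine", ("glutamate", "AKG", "aspartate", "asparagine", "GSH")),
            Pathway("serine", "serine", ("glycine", "3PHP", "phosphoserine", "sarcosine")),
            Pathway("proline", "proline", ("P5C", "ornithine", "arginine", "hydroxyproline")),
            Pathway(
                "methionine",
                "methionine",
                ("SAM", "SAH", "homocysteine", "cystathionine", "cysteine"),
            ),
        ]
    )


#: Panel metabolites outside any pathway (measured but never ratioed).
EXTRA_METABOLITES = ("ATP", "ADP", "AMP")


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study-scale conditions.

    Standard deviations are on the log10 scale: ``baseline_log_sd``
    spreads metabolite baselines, ``batch_effect_sd`` is a per-(batch,
    metabolite) shift, ``sample_scaling_sd`` a per-sample shift added to
    all metabolites (cell-amount/extraction artifact), and
    ``technical_noise_sd`` independent measurement noise.
    """

    n_clusters: int = 5
    cell_lines_per_cluster: int = 12
    n_batches: int = 6
    replicates_per_cell_line: int = 3
    n_anchor_cell_lines: int = 3
    pathway_set: PathwaySet = field(default_factory=default_pathway_set)
    delta_magnitude: float = 0.5
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 0.4
    batch_effect_sd: float = 0.3
    sample_scaling_sd: float = 0.3
    technical_noise_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        for name in ("baseline_log_sd", "batch_effect_sd", "sample_scaling_sd", "technical_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_batches < 1 or self.replicates_per_cell_line < 1:
            raise ValueError("n_batches and replicates_per_cell_line must be >= 1")
        if self.n_anchor_cell_lines > self.n_cell_lines:
            raise ValueError("more anchors than cell lines")
        if self.n_anchor_cell_lines < 0:
            raise ValueError("n_anchor_cell_lines must be >= 0")

    @property
    def n_cell_lines(self) -> int:
        return self.n_clusters * self.cell_lines_per_cluster


@dataclass
class SyntheticTruth:
    """Ground truth emitted with a synthetic panel (never fed to the pipeline)."""

    cluster_labels: pd.Series  # cell_line -> cluster id (1..K)
    delta: pd.DataFrame  # clusters x pathways, log10 shift applied to members
    batch_effects: pd.DataFrame  # batches x metabolites
    sample_scaling: pd.Series  # sample_id -> per-sample log10 shift
    baseline: pd.Series  # metabolite -> baseline log10 mean
    vulnerable_pathways: dict[int, list[str]]  # cluster -> pathway names

    def to_dict(self) -> dict:
        return {
            "cluster_labels": self.cluster_labels.to_dict(),
            "delta": {str(c): row.to_dict() for c, row in self.delta.iterrows()},
            "batch_effects": {str(b): row.to_dict() for b, row in self.batch_effects.iterrows()},
            "sample_scaling": self.sample_scaling.to_dict(),
            "baseline": self.baseline.to_dict(),
            "vulnerable_pathways": {str(c): v for c, v in self.vulnerable_pathways.items()},
        }


def _delta_table(cfg: SyntheticConfig) -> pd.DataFrame:
    """Deterministic cluster x pathway shift pattern.

    Cluster g (1-based) up-shifts pathway (g-1) mod P and down-shifts
    pathway g mod P by ``delta_magnitude``; adjacent clusters therefore
    disagree in sign on a shared pathway, which keeps all cluster profiles
    distinct.
    """
    names = cfg.pathway_set.names
    P = len(names)
    delta = pd.DataFrame(0.0, index=range(1, cfg.n_clusters + 1), columns=names)
    for g in range(1, cfg.n_clusters + 1):
        delta.iloc[g - 1, (g - 1) % P] += cfg.delta_magnitude
        delta.iloc[g - 1, g % P] -= cfg.delta_magnitude
    return delta


def generate_panel(
    cfg: SyntheticConfig,
) -> tuple[AbundanceMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a raw-scale abundance panel with metadata and ground truth.

    The log10 abundance of metabolite j in sample i of cell line c is

        x_ij = mu0_j + delta(cluster(c), pathway(j)) + batch(b_i, j) + s_i + eps_ij

    where delta applies to pathway members only (summed if j is a member of
    several pathways), s_i is the per-sample global scaling, and eps is
    technical noise.  The emitted matrix holds 10**x.  Anchor cell lines
    appear in every batch; all samples of a cell line share one
    replicate_group.
    """
    rng = np.random.default_rng(cfg.seed)
    pathways = cfg.pathway_set
    metabolites = pathways.all_metabolites() + [
        m for m in EXTRA_METABOLITES if m not in pathways.all_metabolites()
    ]
    n_met = len(metabolites)
    met_idx = {m: j for j, m in enumerate(metabolites)}

    cell_lines = [f"CL{i + 1:02d}" for i in range(cfg.n_cell_lines)]
    clusters = pd.Series(
        [(i % cfg.n_clusters) + 1 for i in range(cfg.n_cell_lines)], index=cell_lines
    )
    anchors = set(cell_lines[: cfg.n_anchor_cell_lines])

    delta = _delta_table(cfg)
    # per-metabolite cluster shift: sum of delta over pathways listing it as member
    met_shift = np.zeros((cfg.n_clusters, n_met))
    for p in pathways:
        for m in p.members:
            met_shift[:, met_idx[m]] += delta[p.name].to_numpy()

    mu0 = cfg.baseline_log_mean + cfg.baseline_log_sd * rng.standard_normal(n_met)
    batch_eff = cfg.batch_effect_sd * rng.standard_normal((cfg.n_batches, n_met))

    rows, meta_rows = [], []
    non_anchor_batch = {}
    i = 0
    for cl in cell_lines:
        if cl not in anchors:
            non_anchor_batch[cl] = (i % cfg.n_batches) + 1
            i += 1
    for cl in cell_lines:
        batches = range(1, cfg.n_batches + 1) if cl in anchors else [non_anchor_batch[cl]]
        for b in batches:
            for r in range(1, cfg.replicates_per_cell_line + 1):
                sid = f"{cl}_b{b}_r{r}"
                rows.append((sid, cl, b))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "cell_line": cl,
                        "batch": b,
                        "replicate_group": cl,
                        "tissue_type": "normal" if int(cl[2:]) % 8 == 0 else "tumor",
                        "cancer_type": f"type{(int(cl[2:]) % 6) + 1}",
                        "media": "DMEM",
                    }
                )

    n_samples = len(rows)
    s_i = cfg.sample_scaling_sd * rng.standard_normal(n_samples)
    eps = cfg.technical_noise_sd * rng.standard_normal((n_samples, n_met))

    X = np.empty((n_samples, n_met))
    for idx, (sid, cl, b) in enumerate(rows):
        g = clusters[cl]
        X[idx] = mu0 + met_shift[g - 1] + batch_eff[b - 1] + s_i[idx] + eps[idx]

    sample_ids = [r[0] for r in rows]
    abundance = AbundanceMatrix(
        pd.DataFrame(10.0 ** X, index=sample_ids, columns=metabolites), scale=RAW
    )
    meta = validate_sample_metadata(pd.DataFrame(meta_rows))

    vulnerable = {
        g: [pathways.names[(g - 1) % len(pathways)]] for g in range(1, cfg.n_clusters + 1)
    }
    truth = SyntheticTruth(
        cluster_labels=clusters,
        delta=delta,
        batch_effects=pd.DataFrame(
            batch_eff, index=range(1, cfg.n_batches + 1), columns=metabolites
        ),
        sample_scaling=pd.Series(s_i, index=sample_ids),
        baseline=pd.Series(mu0, index=metabolites),
        vulnerable_pathways=vulnerable,
    )
    return abundance, meta, truth


FITNESS_DATABASES = ("DEMETER", "ProjectScore")
AUC_DATABASES = ("PRISM", "GDSC2")


def generate_screens(
    truth: SyntheticTruth,
    n_targets_per_pathway: int = 20,
    effect: float = -1.0,
    noise_sd: float = 0.1,
    databases: Sequence[str] = FITNESS_DATABASES + AUC_DATABASES,
    seed: int = 0,
) -> tuple[dict[str, ScreenTable], pd.DataFrame]:
    """Simulate screen tables with cluster-dependent vulnerabilities.

    score(cell, target) = baseline + effect * 1[cluster(cell) vulnerable to
    pathway(target)] + N(0, noise_sd).  All simulated databases read lower =
    more sensitive (fitness scores and AUCs alike), so a vulnerability is
    planted with ``effect`` < 0.  Returns one ScreenTable per database plus
    the target -> pathway map.
    """
    if not databases:
        raise ValueError("databases list must not be empty")
    if not any(truth.vulnerable_pathways.values()):
        raise ValueError("truth declares no vulnerable pathway for any cluster")
    rng = np.random.default_rng(seed)
    pathway_names = list(truth.delta.columns)
    targets = [
        (f"{p}_T{t + 1:02d}", p) for p in pathway_names for t in range(n_targets_per_pathway)
    ]
    kegg = validate_pathway_gene_map(
        pd.DataFrame(targets, columns=["target", "kegg_pathway"])
    )
    cell_lines = list(truth.cluster_labels.index)
    screens: dict[str, ScreenTable] = {}
    for db in databases:
        baseline = 1.0 if db in AUC_DATABASES else 0.0
        recs = []
        for cl in cell_lines:
            g = int(truth.cluster_labels[cl])
            vuln = set(truth.vulnerable_pathways.get(g, []))
            for target, p in targets:
                score = baseline + (effect if p in vuln else 0.0) + noise_sd * rng.standard_normal()
                recs.append({"cell_line": cl, "target": target, "score": score, "database": db})
        screens[db] = ScreenTable(pd.DataFrame(recs), score_direction=LOWER_IS_MORE_SENSITIVE)
    return screens, kegg
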