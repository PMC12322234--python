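"""Differential mining of loss-of-function and drug-sensitivity screens.

Screen tables (cell line x target fitness scores or AUCs) are filtered to
labeled cell lines and to targets with a pathway annotation, z-scored per
target across the screen's filtered cell-line set, and contrasted between
two clusters.  Per-database top lists are then consolidated into a
pathway-level vulnerability score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import LOWER_IS_MORE_SENSITIVE, ScreenTable


def join_screens(
    screen: ScreenTable, labels: pd.Series, kegg: pd.DataFrame
) -> tuple[ScreenTable, dict[str, int]]:
    """Restrict a screen to labeled cell lines and pathway-annotated targets.

    Returns the filtered table plus retained/dropped counts.  An empty
    cell-line intersection is an error.
    """
    if labels.empty:
        raise ValueError("labels must not be empty")
    recs = screen.records
    keep_cells = recs["cell_line"].isin(set(labels.index))
    if not keep_cells.any():
        raise ValueError("no screen cell lines overlap the labeled panel")
    keep_targets = recs["target"].isin(set(kegg["target"]))
    kept = recs[keep_cells & keep_targets].reset_index(drop=True)
    counts = {
        "records_in": len(recs),
        "records_kept": len(kept),
        "cell_lines_kept": kept["cell_line"].nunique(),
        "targets_dropped_no_pathway": int((keep_cells & ~keep_targets).sum()),
        "records_dropped_unlabeled": int((~keep_cells).sum()),
    }
    return ScreenTable(kept, score_direction=screen.score_direction), counts


def differential_response(
    filtered: ScreenTable,
    labels: pd.Series,
    cluster_a,
    cluster_b,
    kegg: pd.DataFrame | None = None,
    zscore: bool = True,
) -> pd.DataFrame:
    """Per-target differential response between two clusters.

    Scores are z-scored per target across all retained cell lines (n-1
    denominator); differential = mean z over A - mean z over B.  With
    ``zscore=False`` raw scores are compared instead (the usual choice for
    fitness scores, which are already on a common scale).  Targets
    measured in fewer than 2 cell lines of either cluster, or with zero
    variance, are excluded (with a warning for the former).  The table is
    ranked most-A-vulnerable first: ascending differential when the score
    reads lower-is-more-sensitive, descending otherwise; ties break on
    target id.
    """
    recs = filtered.records.copy()
    recs["cluster"] = recs["cell_line"].map(labels)
    in_a = recs["cluster"] == cluster_a
    in_b = recs["cluster"] == cluster_b
    if recs.loc[in_a, "cell_line"].nunique() < 2 or recs.loc[in_b, "cell_line"].nunique() < 2:
        raise ValueError("each contrasted cluster needs >=2 labeled cell lines in the screen")
    pathway_of: dict[str, str] = {}
    if kegg is not None:
        pathway_of = (
            kegg.groupby("target")["kegg_pathway"].apply(lambda s: ";".join(sorted(set(s)))).to_dict()
        )
    rows, skipped = [], []
    for (target, db), grp in recs.groupby(["target", "database"], sort=False):
        scores = grp["score"].to_numpy(dtype=float)
        sd = scores.std(ddof=1) if len(scores) > 1 else 0.0
        na = int((grp["cluster"] == cluster_a).sum())
        nb = int((grp["cluster"] == cluster_b).sum())
        if na < 2 or nb < 2:
            skipped.append(target)
            continue
        if sd == 0:
            continue
        z = (scores - scores.mean()) / sd if zscore else scores
        za = z[(grp["cluster"] == cluster_a).to_numpy()].mean()
        zb = z[(grp["cluster"] == cluster_b).to_numpy()].mean()
        rows.append(
            {
                "target": target,
                "database": db,
                "n_a": na,
                "n_b": nb,
                "mean_z_a": float(za),
                "mean_z_b": float(zb),
                "differential": float(za - zb),
                "kegg_pathways": pathway_of.get(target, ""),
            }
        )
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} target(s) measured in <2 cell lines per cluster",
            stacklevel=2,
        )
    table = pd.DataFrame(
        rows,
        columns=["target", "database", "n_a", "n_b", "mean_z_a", "mean_z_b",
                 "differential", "kegg_pathways"],
    )
    ascending = filtered.score_direction == LOWER_IS_MORE_SENSITIVE
    table = table.sort_values(
        ["differential", "target"], ascending=[ascending, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def top_n_targets(dt: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """First ``n`` targets by rank (the whole table if shorter)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if dt.empty:
        raise ValueError("differential table is empty")
    return dt.nsmallest(min(n, len(dt)), "rank").sort_values("rank").reset_index(drop=True)


def consolidate_pathways(
    top_lists: dict[str, pd.DataFrame], kegg: pd.DataFrame
) -> pd.DataFrame:
    """Pathway-level consolidation of per-database top lists.

    For each pathway and database, count the pathway's targets inside that
    database's top list (a target in several pathways counts once per
    pathway), normalize by the list length, and sum across databases.
    Ranked descending; ties break alphabetically.
    """
    if not top_lists:
        raise ValueError("need at least one database top list")
    membership = kegg.groupby("kegg_pathway")["target"].apply(set)
    rows = []
    for pathway, targets in membership.items():
        counts = {}
        score = 0.0
        for db, top in top_lists.items():
            in_top = len(set(top["target"]) & targets)
            counts[f"count_{db}"] = in_top
            score += in_top / len(top) if len(top) else 0.0
        rows.append({"kegg_pathway": pathway, **counts, "score": score})
    table = pd.DataFrame(rows).sort_values(
        ["score", "kegg_pathway"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table
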