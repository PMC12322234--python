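"""Replicate-anchored removal of unwanted variation (RUV-III).

Technical replicates of the same cell line measured in different runs
carry no biological contrast, so any systematic structure in the subspace
orthogonal to replicate means is unwanted (batch/run) variation.  The
algorithm:

1. residualize the log-abundance matrix on replicate-group means,
   ``Y0 = (I - M (M'M)^-1 M') Y``;
2. take the top-k left singular vectors ``U_k`` of ``Y0`` and set the
   loadings ``alpha = U_k' Y``;
3. restrict the loadings to control features, ``alpha_c``, and score the
   unwanted factors ``W = Y_c alpha_c' (alpha_c alpha_c')^-1``;
4. return ``corrected = Y - W alpha``.

``k = 0`` is the identity map.  By default every metabolite serves as a
control feature; a negative-control subset can be supplied instead.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import (
    LOG10,
    AbundanceMatrix,
    ReplicateDesign,
    Ruv3Model,
)

logger = logging.getLogger(__name__)

#: condition-number ceiling for inverting alpha_c alpha_c'
_COND_LIMIT = 1e12


def build_replicate_design(meta: pd.DataFrame, samples: list[str]) -> ReplicateDesign:
    """Build the binary samples x replicate-groups membership matrix.

    Rows follow ``samples``; groups are ordered by first appearance.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    meta = meta.set_index("sample_id", drop=False) if meta.index.name != "sample_id" else meta
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:10]}")
    groups_of = meta.loc[samples, "replicate_group"]
    if groups_of.isna().any():
        bad = groups_of.index[groups_of.isna()].tolist()
        raise ValueError(f"samples without replicate_group: {bad[:10]}")
    group_ids: list[str] = []
    seen: dict[str, int] = {}
    for g in groups_of:
        if g not in seen:
            seen[g] = len(group_ids)
            group_ids.append(g)
    M = np.zeros((len(samples), len(group_ids)))
    for i, g in enumerate(groups_of):
        M[i, seen[g]] = 1.0
    return ReplicateDesign(M=M, group_ids=group_ids, sample_ids=list(samples))


def ruv3_correct(
    Y: AbundanceMatrix,
    design: ReplicateDesign,
    controls: list[str] | None = None,
    k: int = 9,
) -> Ruv3Model:
    """Fit RUV-III and return the corrected log10 matrix with W and alpha.

    ``controls`` defaults to all metabolites.  ``k`` must satisfy
    ``0 <= k <= n_samples - n_groups`` and ``k <= len(controls)``.
    """
    if Y.scale != LOG10:
        raise ValueError("RUV-III expects a log10-scale matrix")
    if Y.data.isna().to_numpy().any():
        raise ValueError("RUV-III requires a complete matrix (no missing values)")
    if list(Y.sample_ids) != list(design.sample_ids):
        raise ValueError("sample order of Y and replicate design disagree")
    mets = Y.metabolite_ids
    if controls is None:
        controls = list(mets)
    unknown = [c for c in controls if c not in set(mets)]
    if unknown:
        raise ValueError(f"unknown control features: {unknown[:10]}")

    n, _ = Y.shape
    max_k = n - design.n_groups
    if not (0 <= k <= max_k):
        raise ValueError(f"k must be in [0, {max_k}] (samples - replicate groups), got {k}")
    if k > len(controls):
        raise ValueError(f"k={k} exceeds number of control features ({len(controls)})")

    Yv = Y.values
    if k == 0:
        corrected = AbundanceMatrix(Y.data.copy(), scale=LOG10)
        return Ruv3Model(k=0, control_features=list(controls), W=np.zeros((n, 0)),
                         alpha=np.zeros((0, len(mets))), corrected=corrected)

    M = design.M
    # residualize on replicate-group means (M has orthogonal columns)
    group_means = (M.T @ Yv) / M.sum(axis=0)[:, None]
    Y0 = Yv - M @ group_means
    U, _, _ = np.linalg.svd(Y0, full_matrices=False)
    Uk = U[:, :k]
    alpha = Uk.T @ Yv
    ctrl_idx = [mets.index(c) for c in controls]
    alpha_c = alpha[:, ctrl_idx]
    G = alpha_c @ alpha_c.T
    if np.linalg.cond(G) > _COND_LIMIT:
        raise ValueError(
            "control loadings are numerically singular "
            f"(condition number {np.linalg.cond(G):.2e}); try a smaller k"
        )
    W = Yv[:, ctrl_idx] @ alpha_c.T @ np.linalg.inv(G)
    corrected = AbundanceMatrix(
        pd.DataFrame(Yv - W @ alpha, index=Y.sample_ids, columns=mets), scale=LOG10
    )
    return Ruv3Model(k=k, control_features=list(controls), W=W, alpha=alpha, corrected=corrected)


def aggregate_replicates(
    Y: AbundanceMatrix, meta: pd.DataFrame, by: str = "cell_line"
) -> AbundanceMatrix:
    """Average corrected replicate samples per cell line.

    Downstream clustering operates on cell lines; aggregation happens here,
    immediately after correction, by the mean of corrected replicates.
    Output rows follow first appearance of each cell line.
    """
    meta = meta.set_index("sample_id", drop=False) if meta.index.name != "sample_id" else meta
    groups = meta.loc[Y.sample_ids, by]
    agg = Y.data.groupby(groups, sort=False).mean()
    agg.index.name = by
    return AbundanceMatrix(agg, scale=Y.scale)


def replicate_cocluster_report(
    labels: pd.Series, meta: pd.DataFrame
) -> pd.DataFrame:
    """Quality gate: do cross-batch replicate sets land in one cluster?

    ``labels`` maps sample_id -> cluster.  Returns one row per replicate
    group spanning >1 batch with its modal-cluster agreement fraction, and
    warns if any group is split across clusters.
    """
    meta = meta.set_index("sample_id", drop=False) if meta.index.name != "sample_id" else meta
    rows = []
    for g, grp in meta.loc[labels.index].groupby("replicate_group", sort=False):
        if grp["batch"].nunique() < 2:
            continue
        lab = labels.loc[grp.index]
        frac = (lab == lab.mode().iloc[0]).mean()
        rows.append({"replicate_group": g, "n_samples": len(grp),
                     "n_batches": grp["batch"].nunique(), "modal_fraction": float(frac)})
    report = pd.DataFrame(rows, columns=["replicate_group", "n_samples", "n_batches", "modal_fraction"])
    split = report[report["modal_fraction"] < 1.0]
    if len(split):
        warnings.warn(
            f"{len(split)} cross-batch replicate group(s) split across clusters "
            f"after correction: {split['replicate_group'].tolist()}",
            stacklevel=2,
        )
    return report
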