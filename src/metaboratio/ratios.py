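"""Pathway-centric ratio features.

Each feature is the log10 abundance of a downstream pathway metabolite
(numerator) minus that of the pathway's designated precursor
(denominator).  Because the ratio is a difference of log values, any
per-sample global shift — cell amount, extraction efficiency — cancels
exactly, which is what makes ratios a better clustering substrate than
raw abundances.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .containers import LOG10, AbundanceMatrix, PathwaySet, RatioFeature, RatioMatrix

logger = logging.getLogger(__name__)


def build_ratio_features(
    pathways: PathwaySet, available: list[str]
) -> list[RatioFeature]:
    """One feature per (pathway, member present in the matrix).

    Feature order is pathway order, then member order.  Members missing
    from ``available`` are skipped with a warning; a missing precursor is a
    hard error naming the pathway.  A metabolite listed in two pathways
    yields two features with different pathway tags.
    """
    avail = set(available)
    feats: list[RatioFeature] = []
    for p in pathways:
        if p.precursor not in avail:
            raise ValueError(
                f"precursor {p.precursor!r} of pathway {p.name!r} absent from the matrix"
            )
        for m in p.members:
            if m not in avail:
                warnings.warn(
                    f"pathway {p.name!r}: member {m!r} not quantified, skipping",
                    stacklevel=2,
                )
                continue
            feats.append(RatioFeature(numerator=m, denominator=p.precursor, pathway=p.name))
    return feats


def compute_ratio_matrix(Y: AbundanceMatrix, feats: list[RatioFeature]) -> RatioMatrix:
    """value(i, f) = log10 numerator - log10 denominator, per cell line."""
    if Y.scale != LOG10:
        raise ValueError("ratio computation expects a log10-scale matrix")
    mets = set(Y.metabolite_ids)
    for f in feats:
        for m in (f.numerator, f.denominator):
            if m not in mets:
                raise ValueError(f"feature {f.feature_id}: metabolite {m!r} absent from matrix")
    referenced = {m for f in feats for m in (f.numerator, f.denominator)}
    if Y.data[sorted(referenced)].isna().to_numpy().any():
        raise ValueError("missing values among metabolites referenced by ratio features")
    cols = {
        f.feature_id: Y.data[f.numerator].to_numpy() - Y.data[f.denominator].to_numpy()
        for f in feats
    }
    data = pd.DataFrame(cols, index=Y.sample_ids)
    return RatioMatrix(data=data, features=list(feats), scaled=False)


def zscore_features(m: RatioMatrix, tol: float = 1e-12) -> RatioMatrix:
    """Center each feature to mean 0, sd 1 (n-1 denominator).

    Zero-variance features are dropped with a warning.  Idempotent: an
    already-scaled matrix comes back unchanged.
    """
    if m.data.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    sd = m.data.std(ddof=1)
    keep = sd > tol
    dropped = list(m.data.columns[~keep])
    if dropped:
        warnings.warn(f"dropping zero-variance ratio features: {dropped}", stacklevel=2)
    data = m.data.loc[:, keep]
    scaled = (data - data.mean()) / data.std(ddof=1)
    feats = [f for f in m.features if f.feature_id not in set(dropped)]
    return RatioMatrix(data=scaled, features=feats, scaled=True)
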