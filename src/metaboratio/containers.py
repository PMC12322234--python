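"""Domain containers shared across the pipeline.

The in-memory currency of the package is a small set of typed wrappers
around :class:`pandas.DataFrame`.  Wrapping (rather than subclassing)
keeps validation explicit: every container checks its own invariants at
construction time, so downstream stages can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOG10 = "log10"

#: Screen databases whose scores read "lower = more sensitive"
#: (loss-of-function fitness scores and drug-response AUCs alike).
LOWER_IS_MORE_SENSITIVE = "lower_is_more_sensitive"
HIGHER_IS_MORE_SENSITIVE = "higher_is_more_sensitive"


def _check_unique(ids: Iterable[str], axis: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {axis} ids: {sorted(dups.index.tolist())}")


@dataclass
class AbundanceMatrix:
    """Samples x metabolites abundance matrix with a declared scale.

    ``scale`` is ``"raw"`` for concentration-like values (positive,
    non-positive/NaN cells are treated as missing) or ``"log10"`` after
    log transformation.
    """

    data: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG10):
            raise ValueError(f"scale must be 'raw' or 'log10', got {self.scale!r}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "metabolite")
        values = self.data.to_numpy(dtype=float)
        if self.scale == LOG10 and np.isinf(values).any():
            raise ValueError("log10 matrix contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Cells regarded as missing: NaN anywhere; additionally <=0 on raw scale."""
        if self.scale == RAW:
            return self.data.isna() | (self.data <= 0)
        return self.data.isna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


class Pathway(NamedTuple):
    """One pathway: a precursor (ratio denominator) plus member metabolites."""

    name: str
    precursor: str
    members: tuple[str, ...]


@dataclass
class PathwaySet:
    """Named pathways, each with one precursor and its member metabolites.

    A metabolite may belong to several pathways (each occurrence yields its
    own ratio feature) but not twice within the same pathway, and never as
    both precursor and member of the same pathway.
    """

    pathways: list[Pathway]

    def __post_init__(self) -> None:
        self.pathways = [
            p if isinstance(p, Pathway) else Pathway(p[0], p[1], tuple(p[2]))
            for p in self.pathways
        ]
        _check_unique((p.name for p in self.pathways), "pathway")
        for p in self.pathways:
            if not p.name:
                raise ValueError("empty pathway name")
            if p.precursor in p.members:
                raise ValueError(
                    f"pathway {p.name!r}: precursor {p.precursor!r} listed among members"
                )
            _check_unique(p.members, f"member (pathway {p.name!r})")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pathways]

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def all_metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pathways:
            seen.setdefault(p.precursor)
            for m in p.members:
                seen.setdefault(m)
        return list(seen)


REQUIRED_METADATA_COLUMNS = ("sample_id", "cell_line", "batch", "replicate_group")


def validate_sample_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table and return it indexed by sample_id."""
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns and c != meta.index.name]
    if meta.index.name == "sample_id":
        meta = meta.reset_index()
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata missing required columns: {missing}")
    _check_unique(meta["sample_id"], "sample")
    if meta["replicate_group"].isna().any():
        bad = meta.loc[meta["replicate_group"].isna(), "sample_id"].tolist()
        raise ValueError(f"samples without replicate_group: {bad}")
    return meta.set_index("sample_id", drop=False)


@dataclass
class ScreenTable:
    """Long-format screen records: (cell_line, target, score, database).

    ``score_direction`` declares how the score reads; fitness scores and
    dose-response AUCs both default to lower-is-more-sensitive.
    """

    records: pd.DataFrame
    score_direction: str = LOWER_IS_MORE_SENSITIVE

    REQUIRED = ("cell_line", "target", "score", "database")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"screen table missing columns: {missing}")
        if self.score_direction not in (LOWER_IS_MORE_SENSITIVE, HIGHER_IS_MORE_SENSITIVE):
            raise ValueError(f"bad score_direction {self.score_direction!r}")
        if not np.isfinite(self.records["score"].to_numpy(dtype=float)).all():
            raise ValueError("screen scores must be finite")
        key = self.records[["cell_line", "target", "database"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].to_records(index=False).tolist()
            raise ValueError(f"duplicate (cell_line, target, database) records: {dups[:5]}")

    def __len__(self) -> int:
        return len(self.records)


def validate_pathway_gene_map(kegg: pd.DataFrame) -> pd.DataFrame:
    """Validate a target -> pathway map (columns ``target``, ``kegg_pathway``)."""
    for c in ("target", "kegg_pathway"):
        if c not in kegg.columns:
            raise ValueError(f"pathway-gene map missing column {c!r}")
    if (kegg["kegg_pathway"].astype(str).str.len() == 0).any() or kegg["kegg_pathway"].isna().any():
        raise ValueError("pathway-gene map contains empty pathway names")
    return kegg.drop_duplicates()


class RatioFeature(NamedTuple):
    """A pathway-centric ratio feature: log10(numerator) - log10(precursor)."""

    numerator: str
    denominator: str
    pathway: str

    @property
    def feature_id(self) -> str:
        return f"{self.numerator}/{self.denominator}@{self.pathway}"


@dataclass
class RatioMatrix:
    """Cell lines x ratio features; values are log10-ratios."""

    data: pd.DataFrame
    features: list[RatioFeature]
    scaled: bool = False

    def __post_init__(self) -> None:
        if len(self.features) != self.data.shape[1]:
            raise ValueError("feature list does not match matrix width")
        expected = [f.feature_id for f in self.features]
        if list(self.data.columns) != expected:
            raise ValueError("matrix columns do not match feature ids")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class KDiagnostics:
    """Per-k model-selection diagnostics and the per-heuristic choices."""

    k_range: list[int]
    wss: dict[int, float]
    gap: dict[int, float]
    gap_se: dict[int, float]
    silhouette: dict[int, float]
    gap_k: int
    elbow_k: int
    silhouette_k: int
    combined_k: int

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "wss": {str(k): v for k, v in self.wss.items()},
            "gap": {str(k): v for k, v in self.gap.items()},
            "gap_se": {str(k): v for k, v in self.gap_se.items()},
            "silhouette": {str(k): v for k, v in self.silhouette.items()},
            "gap_k": self.gap_k,
            "elbow_k": self.elbow_k,
            "silhouette_k": self.silhouette_k,
            "combined_k": self.combined_k,
        }


@dataclass
class ClusterResult:
    """Consensus clustering output.

    ``labels`` maps sample id -> cluster id in 1..k; ``coassociation`` holds
    the pairwise fraction of repetitions in which two samples co-clustered.
    """

    labels: pd.Series
    k: int
    coassociation: pd.DataFrame
    n_reps: int
    seed: int
    diagnostics: KDiagnostics | None = None

    def __post_init__(self) -> None:
        C = self.coassociation.to_numpy(dtype=float)
        if C.shape[0] != C.shape[1]:
            raise ValueError("co-association matrix must be square")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("co-association matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("co-association diagonal must be 1")
        present = set(self.labels.unique())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(present)}")


@dataclass
class ReplicateDesign:
    """Binary samples x replicate-groups membership matrix M."""

    M: np.ndarray
    group_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        M = np.asarray(self.M)
        if M.ndim != 2 or M.shape != (len(self.sample_ids), len(self.group_ids)):
            raise ValueError("membership matrix shape does not match ids")
        if not np.isin(M, (0, 1)).all():
            raise ValueError("membership matrix must be binary")
        if not (M.sum(axis=1) == 1).all():
            raise ValueError("each sample must belong to exactly one replicate group")
        if not (M.sum(axis=0) >= 1).all():
            raise ValueError("each replicate group needs at least one sample")
        self.M = M.astype(float)

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)


@dataclass
class Ruv3Model:
    """Fitted replicate-anchored unwanted-variation model.

    ``W`` (samples x k) scores the latent unwanted factors, ``alpha``
    (k x metabolites) their loadings; ``corrected = Y - W @ alpha``.
    """

    k: int
    control_features: list[str]
    W: np.ndarray
    alpha: np.ndarray
    corrected: AbundanceMatrix
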