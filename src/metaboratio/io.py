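"""Delimited-text readers/writers, log transformation, and QC metrics.

All tables are plain delimited text with one header row; tab is the
default separator and comma is auto-detected.  Decimal points only (no
locale commas).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    LOG10,
    RAW,
    AbundanceMatrix,
    Pathway,
    PathwaySet,
    ScreenTable,
    validate_pathway_gene_map,
    validate_sample_metadata,
)

logger = logging.getLogger(__name__)

SAMPLES_IN_ROWS = "samples_in_rows"
METABOLITES_IN_ROWS = "metabolites_in_rows"


def _detect_sep(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "\t" if "\t" in line else ","
    raise ValueError(f"{path}: empty file")


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_detect_sep(path), comment="#")


def read_abundance_table(
    path: str | Path, orientation: str = SAMPLES_IN_ROWS
) -> AbundanceMatrix:
    """Read a raw-scale abundance matrix from a delimited text file.

    The file has one header row and one id column; ``orientation`` says
    whether rows are samples (default) or metabolites.  Empty/NA cells are
    kept as missing; any other non-numeric cell is an error naming its
    position.
    """
    if orientation not in (SAMPLES_IN_ROWS, METABOLITES_IN_ROWS):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _detect_sep(path)
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = [c.strip() for c in line.rstrip("\n").split(sep)][1:]
                break
    counts = pd.Index(header).value_counts()
    dups = counts[counts > 1]
    if len(dups):  # pandas would silently mangle duplicate header names
        raise ValueError(f"{path}: duplicate column ids: {sorted(dups.index.tolist())}")
    raw = pd.read_csv(path, sep=sep, comment="#", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    for axis, ids in (("row", raw.index), ("column", raw.columns)):
        counts = ids.value_counts()
        dups = counts[counts > 1]
        if len(dups):
            raise ValueError(f"{path}: duplicate {axis} ids: {sorted(dups.index.tolist())}")
    parsed = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = parsed.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r}"
        )
    if orientation == METABOLITES_IN_ROWS:
        parsed = parsed.T
    parsed = parsed.astype(float)
    parsed.index.name = None
    parsed.columns.name = None
    return AbundanceMatrix(parsed, scale=RAW)


def write_abundance_table(m: AbundanceMatrix, path: str | Path, header_comment: str | None = None) -> None:
    """Write an abundance matrix as TSV (samples in rows), full float precision."""
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        m.data.to_csv(fh, sep="\t", index_label="sample_id")


def log10_transform(m: AbundanceMatrix, impute_lod: bool = False) -> AbundanceMatrix:
    """Log10-transform a raw-scale matrix.

    With ``impute_lod``, each missing or non-positive cell is replaced by
    half the minimum positive value of that metabolite before the log
    (the usual limit-of-detection convention); otherwise such cells are a
    hard error listing the offending positions.
    """
    if m.scale != RAW:
        raise ValueError("log10_transform expects a raw-scale matrix")
    data = m.data.astype(float).copy()
    missing = data.isna() | (data <= 0)
    if missing.to_numpy().any():
        if not impute_lod:
            cells = [
                (str(data.index[r]), str(data.columns[c]))
                for r, c in np.argwhere(missing.to_numpy())
            ]
            raise ValueError(
                f"non-positive/missing values without impute_lod: {cells[:10]}"
                + ("..." if len(cells) > 10 else "")
            )
        for col in data.columns[missing.any(axis=0)]:
            positive = data[col][data[col] > 0]
            if positive.empty:
                raise ValueError(f"metabolite {col!r} has no positive values to impute from")
            data.loc[missing[col], col] = positive.min() / 2.0
    return AbundanceMatrix(np.log10(data), scale=LOG10)


def compute_rsd(m: AbundanceMatrix, group: list[str], metabolite: str) -> float:
    """Percent relative standard deviation of ``metabolite`` over ``group``.

    Returns 100 * sd / mean with the n-1 denominator, on raw concentrations.
    """
    if m.scale != RAW:
        raise ValueError("compute_rsd expects raw-scale concentrations")
    if len(group) < 2:
        raise ValueError("RSD needs at least 2 samples")
    vals = m.data.loc[list(group), metabolite].to_numpy(dtype=float)
    mean = vals.mean()
    if not mean > 0:
        raise ValueError(f"group mean must be positive, got {mean}")
    return float(100.0 * vals.std(ddof=1) / mean)


@dataclass
class SharedCorrelation:
    """Per-metabolite Pearson r between two datasets over shared samples."""

    r: pd.Series
    n_shared_samples: int
    n_shared_metabolites: int


def correlate_shared_metabolites(a: AbundanceMatrix, b: AbundanceMatrix) -> SharedCorrelation:
    """Per-metabolite Pearson correlation between two log10 datasets.

    Samples and metabolites are intersected first; r is computed across the
    shared samples only.  A zero-variance metabolite in either matrix gets
    r = NaN (undefined), never 0, so counts of negative correlations stay
    honest.
    """
    for name, m in (("a", a), ("b", b)):
        if m.scale != LOG10:
            raise ValueError(f"matrix {name} must be log10-scaled")
    samples = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if len(samples) < 3:
        raise ValueError(f"need >=3 shared samples, got {len(samples)}")
    mets = [x for x in a.metabolite_ids if x in set(b.metabolite_ids)]
    if not mets:
        raise ValueError("no shared metabolites")
    A = a.data.loc[samples, mets].to_numpy(dtype=float)
    B = b.data.loc[samples, mets].to_numpy(dtype=float)
    r = np.full(len(mets), np.nan)
    for j in range(len(mets)):
        if A[:, j].std() == 0 or B[:, j].std() == 0:
            continue
        r[j] = stats.pearsonr(A[:, j], B[:, j]).statistic
    return SharedCorrelation(pd.Series(r, index=mets, name="pearson_r"), len(samples), len(mets))


# ---------------------------------------------------------------------------
# metadata / pathway / screen / pathway-gene-map tables


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    return validate_sample_metadata(_read_table(path))


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_pathways(path: str | Path) -> PathwaySet:
    """Read a pathway table with columns ``pathway, precursor, member`` (one member per row)."""
    t = _read_table(path)
    for c in ("pathway", "precursor", "member"):
        if c not in t.columns:
            raise ValueError(f"{path}: pathway file missing column {c!r}")
    pathways = []
    for name, grp in t.groupby("pathway", sort=False):
        precursors = grp["precursor"].unique()
        if len(precursors) != 1:
            raise ValueError(f"pathway {name!r} lists several precursors: {list(precursors)}")
        pathways.append(Pathway(str(name), str(precursors[0]), tuple(grp["member"].astype(str))))
    return PathwaySet(pathways)


def write_pathways(pathways: PathwaySet, path: str | Path) -> None:
    rows = [
        {"pathway": p.name, "precursor": p.precursor, "member": m}
        for p in pathways
        for m in p.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_screen_table(path: str | Path, score_direction: str | None = None) -> ScreenTable:
    t = _read_table(path)
    if "score" in t.columns:
        t["score"] = pd.to_numeric(t["score"])
    kwargs = {} if score_direction is None else {"score_direction": score_direction}
    return ScreenTable(t, **kwargs)


def write_screen_table(screen: ScreenTable, path: str | Path) -> None:
    screen.records.to_csv(path, sep="\t", index=False)


def read_pathway_gene_map(path: str | Path) -> pd.DataFrame:
    return validate_pathway_gene_map(_read_table(path))


def write_pathway_gene_map(kegg: pd.DataFrame, path: str | Path) -> None:
    kegg.to_csv(path, sep="\t", index=False)
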