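"""Readers and writers: expression tables, GMT gene sets, result tables, SIF.

Expression tables are tab-separated with a header row; the first column
holds spot identifiers, the second the gene symbol, and the remaining
columns one replicate each.  A *design* map assigns replicate columns to
conditions, so column order never matters.  Rows containing any missing
or non-positive value in either condition are dropped and counted,
mirroring the upstream removal of corrupted / low-signal spots.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    AnalysisConfig,
    ConfigurationError,
    EmptyDatasetError,
    ExpressionDataset,
    GeneSet,
)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
    "write_sif",
    "read_sif",
    "warn_missing_genes",
    "load_config",
]

SPOT_COL = "SPOT"
GENE_COL = "GENE"


def read_expression_table(
    path: str | Path, design: dict[str, list[str]]
) -> ExpressionDataset:
    """Read a spot-level expression TSV into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path
        Tab-separated file with columns ``SPOT``, ``GENE`` and one column
        per replicate sample.
    design
        Map condition label -> list of replicate column names, e.g.
        ``{"N": ["N1", "N2", "N3", "N4"], "L": ["L1", ...]}``.  Exactly
        two conditions, reference first.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ConfigurationError("expression table needs spot and gene columns")
    conditions = tuple(design)
    if len(conditions) != 2:
        raise ConfigurationError("design must declare exactly two conditions")
    for cond, cols in design.items():
        if len(cols) < 2:
            raise ConfigurationError(f"condition {cond!r} needs >= 2 replicates")
        absent = [c for c in cols if c not in df.columns]
        if absent:
            raise ConfigurationError(
                f"condition {cond!r}: columns {absent} not in table"
            )
    spot_col, gene_col = df.columns[:2]
    all_cols = [c for cols in design.values() for c in cols]
    vals = df[all_cols].apply(pd.to_numeric, errors="coerce")
    keep = (vals.notna() & (vals > 0)).all(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    df = df.loc[keep]
    if df.empty:
        raise EmptyDatasetError(f"no usable rows in {path}")
    return ExpressionDataset(
        spot_ids=df[spot_col].tolist(),
        gene_of_spot=dict(zip(df[spot_col], df[gene_col])),
        conditions=conditions,  # type: ignore[arg-type]
        values={
            cond: df[cols].to_numpy(dtype=float) for cond, cols in design.items()
        },
        n_dropped=n_dropped,
    )


def write_expression_table(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write a dataset back to the standard TSV layout (lossless)."""
    cols: dict[str, list | np.ndarray] = {
        SPOT_COL: dataset.spot_ids,
        GENE_COL: [dataset.gene_of_spot[s] for s in dataset.spot_ids],
    }
    for cond in dataset.conditions:
        arr = dataset.values[cond]
        for j in range(arr.shape[1]):
            cols[f"{cond}{j + 1}"] = arr[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def default_design(dataset: ExpressionDataset) -> dict[str, list[str]]:
    """The design map matching :func:`write_expression_table` column names."""
    return {
        cond: [f"{cond}{j + 1}" for j in range(dataset.n_replicates(cond))]
        for cond in dataset.conditions
    }


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: per line ``name<TAB>description<TAB>gene...``.

    Duplicate symbols within a line are deduplicated; sets may freely
    share genes across lines (pathways are not mutually exclusive).
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, kegg_id = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ConfigurationError(f"{path}:{lineno}: gene set has no genes")
            sets.append(GeneSet(name=name, kegg_id=kegg_id, genes=genes))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.kegg_id, *sorted(gs.genes)]) + "\n")


def warn_missing_genes(gene_set: GeneSet, available: set[str]) -> list[str]:
    """Warn about (and return) set members absent from the dataset."""
    missing = sorted(gene_set.genes - available)
    if missing:
        warnings.warn(
            f"gene set {gene_set.name!r}: {len(missing)}/{len(gene_set)} "
            f"genes not quantified: {', '.join(missing[:10])}"
            + ("..." if len(missing) > 10 else ""),
            stacklevel=2,
        )
    return missing


# -- generic result tables --------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with full float precision."""
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# -- SIF network export -----------------------------------------------


def write_sif(edges: pd.DataFrame, path: str | Path) -> None:
    """Write a network edge list in SIF format (gene_i<TAB>class<TAB>gene_j)."""
    edges[["gene_i", "cls", "gene_j"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_sif(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["gene_i", "cls", "gene_j"]
    )


# -- YAML config -------------------------------------------------------


def load_config(path: str | Path) -> AnalysisConfig:
    """Load statistical settings from a YAML mapping; unknown keys error."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in AnalysisConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)
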