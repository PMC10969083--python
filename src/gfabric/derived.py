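"""Derived per-gene characteristics: REC, COORD, and GCH.

* **REC** (relative expression control) — the transcriptome-median REV
  divided by the gene's own REV, so tightly controlled genes (small
  variability) score high; the median gene scores exactly 1.
* **COORD** (coordination degree, %) — over a gene's N-1 partners,
  ``100 * (n_syn + n_ant - n_ind) / (N - 1)``: significant synergisms
  and antagonisms both witness coordination, significant independences
  count against it, and unclassified partners dilute the denominator.
* **GCH** (gene commanding height) — control strength amplified by
  coordination power, ``REC * exp(k * <COR^2>)`` with the mean taken
  over all squared partner correlations (default exponent k = 4).
  The top-GCH gene is the Gene Master Regulator of the phenotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import GeneSet

__all__ = [
    "compute_rec",
    "coordination_degree",
    "compute_coord_gene",
    "compute_gch",
    "derived_stats_table",
    "pathway_average",
    "n_distinct_pairs",
]


def compute_rec(rev_gene: float, rev_median_transcriptome: float) -> float:
    """Relative expression control: median REV over the gene's REV."""
    if rev_median_transcriptome <= 0:
        raise ValueError("transcriptome median REV must be positive")
    if rev_gene <= 0:
        import warnings

        warnings.warn("zero REV: expression control is unbounded, capping", stacklevel=2)
        return float("inf")
    return rev_median_transcriptome / rev_gene


def coordination_degree(
    n_syn: int, n_ant: int, n_ind: int, denominator: int
) -> float:
    """Core COORD arithmetic, ``100 * (S + A - I) / denominator`` (%).

    Used for single genes (denominator = N - 1 partners), within a
    pathway (ordered-pair count G*(G-1)) and between pathways
    (|A|*|B| - |A & B|).
    """
    if denominator <= 0:
        raise ValueError("coordination degree needs a positive denominator")
    return 100.0 * (n_syn + n_ant - n_ind) / denominator


def compute_coord_gene(gene: str, condition: str, pairs: pd.DataFrame) -> float:
    """Coordination degree (%) of *gene* from a pair-classification table.

    *pairs* must contain every partner of the gene exactly once (columns
    gene_i, gene_j, condition, cls as produced by
    :func:`gfabric.primary.classify_pairs`).
    """
    sub = pairs[
        (pairs["condition"] == condition)
        & ((pairs["gene_i"] == gene) | (pairs["gene_j"] == gene))
    ]
    if sub.empty:
        raise ValueError(f"no partners for gene {gene!r} in condition {condition!r}")
    counts = sub["cls"].value_counts()
    return coordination_degree(
        int(counts.get("synergistic", 0)),
        int(counts.get("antagonistic", 0)),
        int(counts.get("independent", 0)),
        len(sub),
    )


def compute_gch(rec: float, mean_squared_cor: float, exponent: float = 4.0) -> float:
    """Gene commanding height: ``rec * exp(exponent * mean_squared_cor)``."""
    if not 0.0 <= mean_squared_cor <= 1.0:
        raise ValueError("mean squared correlation must lie in [0, 1]")
    return float(rec * np.exp(exponent * mean_squared_cor))


def derived_stats_table(
    gene_stats: pd.DataFrame,
    pairs: pd.DataFrame,
    gch_exponent: float = 4.0,
) -> pd.DataFrame:
    """Per-gene, per-condition REC / COORD / GCH and partner counts.

    Parameters
    ----------
    gene_stats
        Output of :func:`gfabric.primary.gene_stats_table`.
    pairs
        Pair classifications covering all distinct pairs of the genes in
        *gene_stats* (both conditions).
    """
    rows = []
    for cond, stats_c in gene_stats.groupby("condition", sort=False):
        rev_median = float(stats_c["rev"].median())
        pairs_c = pairs[pairs["condition"] == cond]
        # partner bookkeeping per gene in one pass
        per_gene: dict[str, dict[str, float]] = {
            g: {"syn": 0, "ant": 0, "ind": 0, "n": 0, "sumsq": 0.0}
            for g in stats_c["gene"]
        }
        for gi, gj, cor, cls in pairs_c[
            ["gene_i", "gene_j", "cor", "cls"]
        ].itertuples(index=False):
            for g in (gi, gj):
                d = per_gene.get(g)
                if d is None:
                    continue
                d["n"] += 1
                if not np.isnan(cor):
                    d["sumsq"] += cor * cor
                if cls == "synergistic":
                    d["syn"] += 1
                elif cls == "antagonistic":
                    d["ant"] += 1
                elif cls == "independent":
                    d["ind"] += 1
        for gene, rev in stats_c[["gene", "rev"]].itertuples(index=False):
            d = per_gene[gene]
            rec = compute_rec(rev, rev_median)
            coord = (
                coordination_degree(d["syn"], d["ant"], d["ind"], d["n"])
                if d["n"]
                else float("nan")
            )
            msq = d["sumsq"] / d["n"] if d["n"] else 0.0
            rows.append(
                (
                    gene,
                    cond,
                    rec,
                    coord,
                    compute_gch(rec, msq, gch_exponent),
                    d["syn"],
                    d["ant"],
                    d["ind"],
                    d["n"],
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "condition",
            "rec",
            "coord",
            "gch",
            "n_syn",
            "n_ant",
            "n_ind",
            "n_partners",
        ],
    )


def pathway_average(
    stats: pd.DataFrame, gene_set: GeneSet, field: str, condition: str | None = None
) -> tuple[float, int, int]:
    """Arithmetic mean of *field* over the set's quantified members.

    Returns ``(mean, n_quantified, n_assigned)``; coverage is reported
    the way pathway tables print it ("130/156").
    """
    sub = stats
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    sub = sub[sub["gene"].isin(gene_set.genes)]
    if sub.empty:
        raise ValueError(f"no quantified members of gene set {gene_set.name!r}")
    return float(sub[field].mean()), int(sub["gene"].nunique()), len(gene_set)


def n_distinct_pairs(n_genes: int) -> int:
    """Number of distinct correlations among *n_genes*: n*(n-1)/2."""
    return n_genes * (n_genes - 1) // 2
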