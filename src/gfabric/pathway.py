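"""Gene-set-level summaries and coordination-network remodeling.

Pathway regulation is summarized by the fractions of significantly
down-/up-regulated quantified members (D%, U%) and the weighted pathway
regulation ``WPR = sqrt(mean(WIR^2))``, a root-mean-square that lets
every member contribute regardless of its call.

Coordination within a set of G genes counts synergistic / antagonistic /
independent classes over the G(G-1)/2 distinct member pairs but divides
by the ordered-pair total G(G-1) — the convention under which the
published percentages reproduce exactly; it halves naive distinct-pair
fractions.  Between two sets A and B the denominator is
``|A|*|B| - |A & B|`` (shared genes contribute no self-pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GeneSet
from .derived import coordination_degree

__all__ = [
    "CouplingRecord",
    "compute_wpr",
    "intra_pathway_coord",
    "inter_pathway_coord",
    "remodeling_ratio",
    "pathway_summary_table",
    "coupling_table",
    "export_fabric_network",
]


@dataclass(frozen=True)
class CouplingRecord:
    """Significant-pair counts and coordination degree for one pair universe."""

    set_a: str
    set_b: str  # == set_a for intra-pathway records
    condition: str
    n_syn: int
    n_ant: int
    n_ind: int
    n_pairs: int  # denominator of the coordination degree

    @property
    def coord(self) -> float:
        return coordination_degree(self.n_syn, self.n_ant, self.n_ind, self.n_pairs)


def compute_wpr(wirs) -> float:
    """Weighted pathway regulation: RMS of the member WIRs."""
    wirs = np.asarray(list(wirs), dtype=float)
    if wirs.size == 0:
        raise ValueError("WPR of an empty gene set is undefined")
    return float(np.sqrt(np.mean(wirs**2)))


def _count_classes(sub: pd.DataFrame) -> tuple[int, int, int]:
    counts = sub["cls"].value_counts()
    return (
        int(counts.get("synergistic", 0)),
        int(counts.get("antagonistic", 0)),
        int(counts.get("independent", 0)),
    )


def intra_pathway_coord(
    pairs: pd.DataFrame, gene_set: GeneSet, condition: str, quantified: set[str]
) -> CouplingRecord:
    """Coordination degree within a gene set (ordered-pair denominator)."""
    members = set(gene_set.quantified(quantified))
    g = len(members)
    if g < 2:
        raise ValueError(f"gene set {gene_set.name!r}: < 2 quantified members")
    sub = pairs[
        (pairs["condition"] == condition)
        & pairs["gene_i"].isin(members)
        & pairs["gene_j"].isin(members)
    ]
    n_syn, n_ant, n_ind = _count_classes(sub)
    return CouplingRecord(
        gene_set.name, gene_set.name, condition, n_syn, n_ant, n_ind, g * (g - 1)
    )


def inter_pathway_coord(
    pairs: pd.DataFrame,
    set_a: GeneSet,
    set_b: GeneSet,
    condition: str,
    quantified: set[str],
) -> CouplingRecord:
    """Coordination degree between two gene sets.

    All (a, b) pairs with a in A, b in B and a != b count once;
    denominator ``|A|*|B| - |A & B|``.
    """
    mem_a = set(set_a.quantified(quantified))
    mem_b = set(set_b.quantified(quantified))
    if not mem_a or not mem_b:
        raise ValueError("both gene sets need quantified members")
    sub = pairs[pairs["condition"] == condition]
    cross = sub[
        (sub["gene_i"].isin(mem_a) & sub["gene_j"].isin(mem_b))
        | (sub["gene_i"].isin(mem_b) & sub["gene_j"].isin(mem_a))
    ]
    # pairs internal to the overlap would be double-counted conceptually;
    # each unordered pair appears once in `pairs`, so no dedup is needed.
    n_syn, n_ant, n_ind = _count_classes(cross)
    n_pairs = len(mem_a) * len(mem_b) - len(mem_a & mem_b)
    return CouplingRecord(
        set_a.name, set_b.name, condition, n_syn, n_ant, n_ind, n_pairs
    )


def remodeling_ratio(coord_n: float, coord_l: float) -> float:
    """Signed fold-change of a coordination degree between conditions.

    Magnitude is the larger coordination over the smaller; the sign is
    negative when coupling decreased in the experimental condition.
    """
    if coord_n == 0 or coord_l == 0:
        raise ZeroDivisionError("remodeling ratio undefined for zero coordination")
    if abs(coord_l) >= abs(coord_n):
        return abs(coord_l / coord_n)
    return -abs(coord_n / coord_l)


def pathway_summary_table(
    regulation: pd.DataFrame,
    derived_stats: pd.DataFrame,
    gene_sets: list[GeneSet],
    conditions: tuple[str, str],
) -> pd.DataFrame:
    """Per gene-set D%, U%, WPR and pathway-level control change.

    ``delta_rec_pct`` is ``100 * (mean REC_L / mean REC_N - 1)`` over
    quantified members (negative = reduced control).
    """
    cond_n, cond_l = conditions
    quantified = set(regulation["gene"])
    rows = []
    for gs in gene_sets:
        members = gs.quantified(quantified)
        if not members:
            raise ValueError(f"no quantified members of gene set {gs.name!r}")
        sub = regulation[regulation["gene"].isin(members)]
        n_q = len(members)
        d_pct = 100.0 * (sub["call"] == "down").sum() / n_q
        u_pct = 100.0 * (sub["call"] == "up").sum() / n_q
        wpr = compute_wpr(sub["wir"])
        dsub = derived_stats[derived_stats["gene"].isin(members)]
        rec_n = dsub.loc[dsub["condition"] == cond_n, "rec"].mean()
        rec_l = dsub.loc[dsub["condition"] == cond_l, "rec"].mean()
        delta_rec = 100.0 * (rec_l / rec_n - 1.0) if rec_n > 0 else float("nan")
        rows.append((gs.name, gs.kegg_id, n_q, len(gs), d_pct, u_pct, wpr, delta_rec))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_set",
            "kegg_id",
            "quantified",
            "assigned",
            "d_pct",
            "u_pct",
            "wpr",
            "delta_rec_pct",
        ],
    )


def coupling_table(
    pairs: pd.DataFrame,
    gene_sets: list[GeneSet],
    conditions: tuple[str, str],
    quantified: set[str],
) -> pd.DataFrame:
    """All intra- and inter-set coupling records, with remodeling ratios."""
    records: list[CouplingRecord] = []
    for cond in conditions:
        for i, gs_a in enumerate(gene_sets):
            records.append(intra_pathway_coord(pairs, gs_a, cond, quantified))
            for gs_b in gene_sets[i + 1 :]:
                records.append(
                    inter_pathway_coord(pairs, gs_a, gs_b, cond, quantified)
                )
    df = pd.DataFrame(
        [
            (r.set_a, r.set_b, r.condition, r.n_syn, r.n_ant, r.n_ind, r.n_pairs, r.coord)
            for r in records
        ],
        columns=[
            "set_a",
            "set_b",
            "condition",
            "n_syn",
            "n_ant",
            "n_ind",
            "n_pairs",
            "coord",
        ],
    )
    cond_n, cond_l = conditions
    wide = df.pivot(index=["set_a", "set_b"], columns="condition", values="coord")
    ratios = {}
    for key, row in wide.iterrows():
        cn, cl = row.get(cond_n), row.get(cond_l)
        try:
            ratios[key] = remodeling_ratio(float(cn), float(cl))
        except (ZeroDivisionError, TypeError):
            ratios[key] = float("nan")
    df["remodeling"] = [ratios[(a, b)] for a, b in zip(df["set_a"], df["set_b"])]
    return df


_CLS_EDGE = {"synergistic": "syn", "antagonistic": "ant", "independent": "ind"}


def export_fabric_network(
    pairs: pd.DataFrame,
    condition: str,
    regulation: pd.DataFrame | None = None,
    gene_sets: list[GeneSet] | None = None,
    include_independent: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build SIF-ready edge and node-annotation tables for one condition.

    Edges keep significant synergistic/antagonistic pairs (and, when
    requested, significant independences); nodes carry the regulation
    call (up/down/none), mirroring red/green/yellow node coloring.
    """
    keep = {"synergistic", "antagonistic"}
    if include_independent:
        keep.add("independent")
    sub = pairs[(pairs["condition"] == condition) & pairs["cls"].isin(keep)]
    if gene_sets is not None:
        allowed = set().union(*(gs.genes for gs in gene_sets))
        sub = sub[sub["gene_i"].isin(allowed) & sub["gene_j"].isin(allowed)]
    edges = pd.DataFrame(
        {
            "gene_i": sub["gene_i"].to_numpy(),
            "cls": sub["cls"].map(_CLS_EDGE).to_numpy(),
            "gene_j": sub["gene_j"].to_numpy(),
        }
    )
    nodes_list = sorted(set(edges["gene_i"]) | set(edges["gene_j"]))
    calls = (
        regulation.set_index("gene")["call"]
        if regulation is not None
        else pd.Series(dtype=object)
    )
    nodes = pd.DataFrame(
        {
            "gene": nodes_list,
            "call": [calls.get(g, "none") for g in nodes_list],
        }
    )
    return edges, nodes
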