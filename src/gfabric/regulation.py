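"""Per-gene regulation between conditions: x, Welch p, CUT, WIR, deltas.

A gene is called significantly regulated when its signed expression
ratio ``x`` (negative for down-regulation, |x| >= 1 by construction)
clears a *per-gene* absolute fold-change threshold

    ``CUT = 1 + sqrt(2) * sqrt(REV_N^2 + REV_L^2) / 100``

and the heteroscedastic (Welch) t-test of the two mean expressions has
p < alpha.  Tying the threshold to the gene's own variability removes
the false hits and missed genes of any uniform 1.5x rule: a noisy gene
needs a larger fold-change, a tightly controlled one a smaller.

The weighted individual regulation

    ``WIR = AVE_N * (|x| - 1) * sign(x) * (1 - p)``

scores every gene's contribution to the transcriptomic change
regardless of its call, weighting the net fold-change by the reference
expression level and the confidence of the difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalysisConfig, ExpressionDataset
from .primary import compute_ave, compute_rev

__all__ = [
    "expression_ratio",
    "welch_p",
    "compute_cut",
    "regulation_call",
    "compute_wir",
    "compute_delta_rec",
    "compute_delta_coord",
    "regulation_table",
    "categorize_vs_uniform",
]


def expression_ratio(ave_n: float, ave_l: float) -> float:
    """Signed expression ratio: ratio of AVEs, negative for down-regulation."""
    if ave_n <= 0 or ave_l <= 0:
        raise ValueError("AVEs must be positive")
    return ave_l / ave_n if ave_l >= ave_n else -ave_n / ave_l


def welch_p(values_n: np.ndarray, values_l: np.ndarray) -> float:
    """Two-tailed Welch t-test p-value for equal means.

    Operates on per-replicate (spot-averaged) gene values; returns 1.0
    in the degenerate zero-variance, equal-means case.
    """
    values_n = np.asarray(values_n, dtype=float)
    values_l = np.asarray(values_l, dtype=float)
    if values_n.size < 2 or values_l.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    if values_n.var() == 0.0 and values_l.var() == 0.0:
        return 1.0 if values_n.mean() == values_l.mean() else 0.0
    return float(stats.ttest_ind(values_n, values_l, equal_var=False).pvalue)


def compute_cut(rev_n: float, rev_l: float) -> float:
    """Per-gene absolute fold-change cut-off from the two REVs (%)."""
    if rev_n < 0 or rev_l < 0:
        raise ValueError("REVs must be non-negative")
    return 1.0 + np.sqrt(2.0) * np.hypot(rev_n, rev_l) / 100.0


def regulation_call(x: float, p: float, cut: float, alpha: float = 0.05) -> str:
    """Composite criterion: {'up', 'down', 'none'}."""
    if p < alpha:
        if x >= cut:
            return "up"
        if x <= -cut:
            return "down"
    return "none"


def compute_wir(ave_n: float, x: float, p: float) -> float:
    """Weighted individual regulation (signed, reference-AVE units)."""
    return float(ave_n * (abs(x) - 1.0) * np.sign(x) * (1.0 - p))


def compute_delta_rec(rec_n: float, rec_l: float) -> float:
    """Regulation of expression control, ``(REC_L - REC_N) * 100`` (%)."""
    return 100.0 * (rec_l - rec_n)


def compute_delta_coord(coord_n: float, coord_l: float) -> float:
    """Change in coordination degree (percentage points; < 0 = decoupling)."""
    return coord_l - coord_n


def regulation_table(
    dataset: ExpressionDataset,
    config: AnalysisConfig | None = None,
    gene_stats: pd.DataFrame | None = None,
    derived_stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full per-gene regulation table between the two conditions.

    Columns: gene, ave_n, ave_l, x, p, cut, call, wir, and — when
    *derived_stats* (from :func:`gfabric.derived.derived_stats_table`)
    is given — delta_rec and delta_coord.
    """
    config = config or AnalysisConfig()
    cond_n, cond_l = dataset.conditions
    rows = []
    for gene in dataset.genes:
        ave_n = compute_ave(dataset, gene, cond_n)
        ave_l = compute_ave(dataset, gene, cond_l)
        if gene_stats is not None:
            gs = gene_stats[gene_stats["gene"] == gene].set_index("condition")["rev"]
            rev_n, rev_l = float(gs[cond_n]), float(gs[cond_l])
        else:
            rev_n = compute_rev(dataset, gene, cond_n, config.cv_correction)
            rev_l = compute_rev(dataset, gene, cond_l, config.cv_correction)
        x = expression_ratio(ave_n, ave_l)
        p = welch_p(
            dataset.replicate_profile(gene, cond_n),
            dataset.replicate_profile(gene, cond_l),
        )
        cut = compute_cut(rev_n, rev_l)
        rows.append(
            (
                gene,
                ave_n,
                ave_l,
                x,
                p,
                cut,
                regulation_call(x, p, cut, config.alpha),
                compute_wir(ave_n, x, p),
            )
        )
    table = pd.DataFrame(
        rows, columns=["gene", "ave_n", "ave_l", "x", "p", "cut", "call", "wir"]
    )
    if derived_stats is not None:
        piv = derived_stats.pivot(index="gene", columns="condition")
        table["delta_rec"] = [
            compute_delta_rec(
                piv.loc[g, ("rec", cond_n)], piv.loc[g, ("rec", cond_l)]
            )
            for g in table["gene"]
        ]
        table["delta_coord"] = [
            compute_delta_coord(
                piv.loc[g, ("coord", cond_n)], piv.loc[g, ("coord", cond_l)]
            )
            for g in table["gene"]
        ]
    return table


def categorize_vs_uniform(
    table: pd.DataFrame, uniform_cut: float = 1.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Compare per-gene calls against a uniform fold-change rule.

    Adds a ``category`` column: ``falsely_up`` / ``falsely_down`` genes
    pass the uniform rule but not the per-gene CUT; ``missed_up`` /
    ``missed_down`` pass the per-gene CUT but not the uniform rule;
    ``agree`` otherwise.
    """
    out = table.copy()

    def cat(row) -> str:
        sig = row["p"] < alpha
        ours = row["call"]
        uniform = "none"
        if sig and row["x"] >= uniform_cut:
            uniform = "up"
        elif sig and row["x"] <= -uniform_cut:
            uniform = "down"
        if ours == uniform:
            return "agree"
        if uniform != "none" and ours == "none":
            return f"falsely_{uniform}"
        if ours != "none" and uniform == "none":
            return f"missed_{ours}"
        return "agree"

    out["category"] = out.apply(cat, axis=1)
    return out
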