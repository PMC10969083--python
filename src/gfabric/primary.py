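"""Primary per-gene characteristics: AVE, REV, and pairwise COR.

The framework characterizes every quantified gene, per condition, by
three mutually independent measures:

* **AVE** — average expression level over all replicates of all spots
  redundantly probing the gene (linear, median-normalized units);
* **REV** — relative expression variation, a corrected coefficient of
  variation (%) built from the pooled within-spot replicate variance.
  The chi-square mid-interval correction removes the small-sample bias
  of the sample CV: with ``nu = s*(n-1)`` pooled degrees of freedom,

  ``REV = 100 * (s_pooled / AVE) * c``, where
  ``c = 0.5 * (sqrt(nu/chi2_{0.975,nu}) + sqrt(nu/chi2_{0.025,nu}))``;

* **COR** — Pearson correlation of the two genes' expression values,
  pairing spot k of one gene with spot k of the other (k up to the
  smaller spot count) within each replicate.

A pair is *synergistically* (resp. *antagonistically*) expressed when
its correlation reaches the two-tailed significance cut-off for the
number of paired values, and *independently* expressed when |COR| falls
below a small threshold (0.05 by convention); everything in between is
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import AnalysisConfig, ExpressionDataset

__all__ = [
    "PairClassification",
    "compute_ave",
    "compute_rev",
    "cv_correction_factor",
    "correlation_cutoff",
    "compute_cor",
    "classify_pair",
    "classify_pairs",
    "gene_stats_table",
    "PAIR_CLASSES",
]

PAIR_CLASSES = ("synergistic", "antagonistic", "independent", "unclassified")


@dataclass(frozen=True)
class PairClassification:
    """One gene pair's correlation and class in one condition."""

    gene_i: str
    gene_j: str
    condition: str
    cor: float  # NaN when undefined (zero variance)
    n_points: int
    cls: str


def compute_ave(dataset: ExpressionDataset, gene: str, condition: str) -> float:
    """Average expression level over all spots and replicates of *gene*."""
    return float(dataset.gene_values(gene, condition).mean())


@lru_cache(maxsize=4096)
def cv_correction_factor(nu: int) -> float:
    """Chi-square mid-interval correction for a CV with *nu* degrees of freedom.

    Averages the two 95% confidence bounds of the standard deviation,
    ``0.5*(sqrt(nu/chi2_upper) + sqrt(nu/chi2_lower))``; always > 1, and
    -> 1 as nu grows.
    """
    if nu < 1:
        raise ValueError("need at least one degree of freedom")
    lo = stats.chi2.ppf(0.025, nu)
    hi = stats.chi2.ppf(0.975, nu)
    return float(0.5 * (np.sqrt(nu / hi) + np.sqrt(nu / lo)))


def compute_rev(
    dataset: ExpressionDataset,
    gene: str,
    condition: str,
    cv_correction: bool = True,
) -> float:
    """Relative expression variation (%) of *gene* in *condition*.

    Pools the within-spot replicate variances over the gene's s spots
    (so spot-level intensity offsets do not inflate the estimate) and
    normalizes by AVE.  Constant replicates give exactly 0.
    """
    vals = dataset.gene_values(gene, condition)
    s, n = vals.shape
    if n < 2:
        raise ValueError("REV needs >= 2 replicates")
    pooled_var = float(vals.var(axis=1, ddof=1).mean())
    ave = float(vals.mean())
    cv = np.sqrt(pooled_var) / ave
    c = cv_correction_factor(s * (n - 1)) if cv_correction else 1.0
    return float(100.0 * cv * c)


@lru_cache(maxsize=4096)
def _cutoff_from_points(n_points: int, alpha: float) -> float:
    df = n_points - 2
    if df <= 0:
        raise ValueError(f"insufficient data: {n_points} paired values")
    t_c = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_c / np.sqrt(t_c * t_c + df))


def correlation_cutoff(
    s_i: int, s_j: int, n: int, alpha: float = 0.05
) -> float:
    """Critical |r| for a significant pair correlation at level *alpha*.

    Uses ``n_points = n * min(s_i, s_j)`` paired values: the two-tailed
    Pearson critical value ``t_c / sqrt(t_c^2 + df)`` with
    ``df = n_points - 2``.  For the study design (n = 4): 0.950 for
    single-spot pairs, 0.71 for two spots, 0.58 for three.
    """
    if min(s_i, s_j) < 1 or n < 2:
        raise ValueError("need s >= 1 spots and n >= 2 replicates")
    return _cutoff_from_points(n * min(s_i, s_j), alpha)


def compute_cor(
    dataset: ExpressionDataset, gene_i: str, gene_j: str, condition: str
) -> tuple[float, int]:
    """Pearson correlation of two genes' expression and the points used.

    Spot k of gene i is paired with spot k of gene j (file order) for
    k up to the smaller spot count, concatenated across replicates.
    Returns ``(nan, n_points)`` when either vector has zero variance.
    """
    vi = dataset.gene_values(gene_i, condition)
    vj = dataset.gene_values(gene_j, condition)
    s_min = min(vi.shape[0], vj.shape[0])
    x = vi[:s_min].ravel()
    y = vj[:s_min].ravel()
    n_points = x.size
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan"), n_points
    return float(np.corrcoef(x, y)[0, 1]), n_points


def classify_pair(
    cor: float,
    n_points: int,
    alpha: float = 0.05,
    independence_threshold: float = 0.05,
    cutoff: float | None = None,
) -> str:
    """Classify a pair correlation into one of :data:`PAIR_CLASSES`.

    ``cutoff`` may be supplied to bypass the t-distribution computation
    (e.g. the published single-spot convention 0.951).
    """
    if np.isnan(cor):
        return "unclassified"
    r_c = _cutoff_from_points(n_points, alpha) if cutoff is None else cutoff
    if cor >= r_c:
        return "synergistic"
    if cor <= -r_c:
        return "antagonistic"
    if abs(cor) < independence_threshold:
        return "independent"
    return "unclassified"


def _pair_cutoff(n_points: int, n: int, config: AnalysisConfig) -> float | None:
    if (
        config.single_spot_cutoff_override is not None
        and n_points == n  # single-spot pair
    ):
        return config.single_spot_cutoff_override
    return None


def classify_pairs(
    dataset: ExpressionDataset,
    condition: str,
    config: AnalysisConfig | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Correlate and classify gene pairs in one condition.

    By default all distinct pairs of quantified genes are processed
    (O(N^2): restrict via *pairs* for large transcriptomes).  Returns a
    DataFrame with columns gene_i, gene_j, condition, cor, n_points, cls.
    """
    config = config or AnalysisConfig()
    genes = dataset.genes
    if pairs is None:
        pairs = list(combinations(genes, 2))
    n = dataset.n_replicates(condition)

    # cache per-gene flattened spot blocks
    flat: dict[str, np.ndarray] = {
        g: dataset.gene_values(g, condition) for g in set(g for p in pairs for g in p)
    }
    rows = []
    for gi, gj in pairs:
        vi, vj = flat[gi], flat[gj]
        s_min = min(vi.shape[0], vj.shape[0])
        x = vi[:s_min].ravel()
        y = vj[:s_min].ravel()
        n_points = x.size
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            cor, cls = float("nan"), "unclassified"
        else:
            cor = float(np.corrcoef(x, y)[0, 1])
            cls = classify_pair(
                cor,
                n_points,
                config.alpha,
                config.independence_threshold,
                cutoff=_pair_cutoff(n_points, n, config),
            )
        rows.append((gi, gj, condition, cor, n_points, cls))
    return pd.DataFrame(
        rows, columns=["gene_i", "gene_j", "condition", "cor", "n_points", "cls"]
    )


def gene_stats_table(
    dataset: ExpressionDataset, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-gene, per-condition AVE / REV / spot count table."""
    config = config or AnalysisConfig()
    rows = []
    for cond in dataset.conditions:
        n = dataset.n_replicates(cond)
        for gene in dataset.genes:
            rows.append(
                (
                    gene,
                    cond,
                    compute_ave(dataset, gene, cond),
                    compute_rev(dataset, gene, cond, config.cv_correction),
                    len(dataset.spots_of_gene(gene)),
                    n,
                )
            )
    return pd.DataFrame(
        rows, columns=["gene", "condition", "ave", "rev", "n_spots", "n_replicates"]
    )
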