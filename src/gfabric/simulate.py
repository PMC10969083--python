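"""Synthetic two-condition spot-level expression data with known truth.

The generator emulates the statistical structure of a four-replicate,
two-condition microarray study: log-normal baseline expression levels,
per-gene coefficients of variation spanning roughly 1-100%, 1-3
redundant probing spots per gene, block-structured inter-gene
correlation (synergistic or antagonistic members within a block,
independent across blocks), and a designated subset of genes with
imposed fold-changes between conditions.

Per replicate r and condition c each correlation block draws one latent
factor f ~ N(0,1) and gene i takes

    value = AVE_ic * (1 + CV_i * (l_i * f + sqrt(1 - l_i^2) * eps)),

with loading ``l_i = sign_i * sqrt(rho)`` for block members and 0
otherwise, eps ~ N(0,1) i.i.d.  Spots of a gene share the replicate
value plus small spot noise (sd = 20% of the replicate-level sd), and
all values are clipped to a tiny positive floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset
from .primary import cv_correction_factor
from .regulation import compute_cut

__all__ = ["Block", "FabricSpec", "GroundTruth", "generate", "truth_table"]

SPOT_NOISE_FRACTION = 0.2  # spot-level sd as a fraction of replicate-level sd
CLIP_FLOOR_FRACTION = 1e-6  # positive floor, relative to the median baseline AVE


@dataclass(frozen=True)
class Block:
    """A correlated gene block: member indices, |rho| < 1, and signs.

    ``signs`` (one +1/-1 per member, default all +1) set the sign of the
    factor loading: two members with equal signs are synergistic, with
    opposite signs antagonistic.
    """

    genes: tuple[int, ...]
    rho: float
    signs: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("block rho must lie in [0, 1)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene indices in block")
        if self.signs is not None and len(self.signs) != len(self.genes):
            raise ValueError("signs must match the number of block members")
        if self.signs is not None and any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")

    def sign_of(self, idx_in_block: int) -> int:
        return 1 if self.signs is None else self.signs[idx_in_block]


@dataclass
class FabricSpec:
    """Generator parameters; the defaults mirror the emulated study design."""

    n_genes: int
    n_replicates: int = 4
    spots_per_gene: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    blocks: tuple[Block, ...] = ()
    ave_lognormal: tuple[float, float] = (0.0, 2.0)  # (mu, sigma) of ln AVE
    cv_range: tuple[float, float] = (0.01, 1.0)  # log-uniform true CVs
    regulated: dict[int, float] = field(default_factory=dict)  # index -> fold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 2:
            raise ValueError("need >= 1 gene and >= 2 replicates")
        if abs(sum(self.spots_per_gene) - 1.0) > 1e-9:
            raise ValueError("spots_per_gene probabilities must sum to 1")
        if not 0.0 < self.cv_range[0] <= self.cv_range[1]:
            raise ValueError("cv_range must be positive and ordered")
        if any(f <= 0 for f in self.regulated.values()):
            raise ValueError("fold-changes must be positive")
        seen: set[int] = set()
        for blk in self.blocks:
            if max(blk.genes, default=-1) >= self.n_genes or min(
                blk.genes, default=0
            ) < 0:
                raise ValueError("block gene index out of range")
            if seen & set(blk.genes):
                raise ValueError("blocks must be disjoint")
            seen |= set(blk.genes)
        if any(i < 0 or i >= self.n_genes for i in self.regulated):
            raise ValueError("regulated gene index out of range")


@dataclass
class GroundTruth:
    """True generator parameters, for recall/precision scoring downstream."""

    genes: pd.DataFrame  # gene, ave_n, ave_l, cv, fold, n_spots, block, loading_sign
    blocks: tuple[Block, ...]

    def expected_pair_class(self, i: int, j: int) -> str:
        """Expected classification of genes *i*, *j* (by generator index)."""
        bi = self.genes.loc[i, "block"]
        bj = self.genes.loc[j, "block"]
        if bi >= 0 and bi == bj and self.blocks[bi].rho > 0:
            same = (
                self.genes.loc[i, "loading_sign"] == self.genes.loc[j, "loading_sign"]
            )
            return "synergistic" if same else "antagonistic"
        return "independent_or_unclassified"


def generate(spec: FabricSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset from *spec*; bit-identical for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_genes, spec.n_replicates

    cv = np.exp(
        rng.uniform(np.log(spec.cv_range[0]), np.log(spec.cv_range[1]), size=m)
    )
    mu, sigma = spec.ave_lognormal
    ave_n = rng.lognormal(mu, sigma, size=m)
    fold = np.ones(m)
    for idx, f in spec.regulated.items():
        fold[idx] = f
    ave = {"N": ave_n, "L": ave_n * fold}

    n_spots = rng.choice([1, 2, 3], size=m, p=spec.spots_per_gene)

    loading = np.zeros(m)
    block_of = np.full(m, -1)
    sign = np.ones(m, dtype=int)
    for b, blk in enumerate(spec.blocks):
        for k, g in enumerate(blk.genes):
            block_of[g] = b
            sign[g] = blk.sign_of(k)
            loading[g] = blk.sign_of(k) * np.sqrt(blk.rho)

    floor = CLIP_FLOOR_FRACTION * float(np.median(ave_n))
    spot_rows = np.repeat(np.arange(m), n_spots)
    values: dict[str, np.ndarray] = {}
    for cond in ("N", "L"):
        f_blk = rng.standard_normal((max(len(spec.blocks), 1), n))
        eps = rng.standard_normal((m, n))
        latent = loading[:, None] * f_blk[np.maximum(block_of, 0)] + np.sqrt(
            1.0 - loading**2
        )[:, None] * eps
        rep_vals = ave[cond][:, None] * (1.0 + cv[:, None] * latent)
        spot_noise = (
            (ave[cond] * SPOT_NOISE_FRACTION * cv)[spot_rows, None]
            * rng.standard_normal((spot_rows.size, n))
        )
        values[cond] = np.maximum(rep_vals[spot_rows] + spot_noise, floor)

    gene_names = [f"G{i:05d}" for i in range(m)]
    spot_ids = [
        f"S{i:05d}.{k}" for i in range(m) for k in range(int(n_spots[i]))
    ]
    gene_of_spot = {
        sid: gene_names[g] for sid, g in zip(spot_ids, spot_rows)
    }
    dataset = ExpressionDataset(
        spot_ids=spot_ids,
        gene_of_spot=gene_of_spot,
        conditions=("N", "L"),
        values=values,
    )
    truth = GroundTruth(
        genes=pd.DataFrame(
            {
                "gene": gene_names,
                "ave_n": ave_n,
                "ave_l": ave["L"],
                "cv": cv,
                "fold": fold,
                "n_spots": n_spots.astype(int),
                "block": block_of,
                "loading_sign": sign,
            }
        ),
        blocks=spec.blocks,
    )
    return dataset, truth


def truth_table(
    truth: GroundTruth, n_replicates: int = 4, cv_correction: bool = True
) -> pd.DataFrame:
    """Expected per-gene regulation from the true CVs and fold-changes.

    The analytic REV is ``100 * CV * c(nu)`` with ``nu = s * (n - 1)``
    (spot noise slightly inflates the realized REV; the approximation is
    conservative for call recall).  Expected call: up/down when the true
    signed ratio clears the analytic CUT, else none.
    """
    rows = []
    for _, g in truth.genes.iterrows():
        rev = 100.0 * g["cv"] * (
            cv_correction_factor(int(g["n_spots"]) * (n_replicates - 1))
            if cv_correction
            else 1.0
        )
        cut = compute_cut(rev, rev)
        f = g["fold"]
        x_true = f if f >= 1.0 else -1.0 / f
        if x_true >= cut:
            call = "up"
        elif x_true <= -cut:
            call = "down"
        else:
            call = "none"
        rows.append((g["gene"], rev, cut, x_true, call))
    return pd.DataFrame(
        rows, columns=["gene", "rev_analytic", "cut_analytic", "x_true", "expected_call"]
    )
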