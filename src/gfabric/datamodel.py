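"""Shared data model for two-condition spot-level expression data.

The central container is :class:`ExpressionDataset`: microarray spots
(one gene may be probed redundantly by 1..s spots) measured on several
biological replicates under a reference condition (normal diet, ``"N"``)
and an experimental condition (low-salt diet, ``"L"``).  All values are
linear, median-normalized intensities and must be finite and positive;
spots failing that filter are dropped at read/construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExpressionDataset",
    "GeneSet",
    "AnalysisConfig",
    "GfabricError",
    "ConfigurationError",
    "EmptyDatasetError",
    "UnknownGeneError",
]


class GfabricError(Exception):
    """Base class for package errors."""


class ConfigurationError(GfabricError):
    """Invalid configuration or file layout (e.g. missing condition columns)."""


class EmptyDatasetError(GfabricError):
    """No usable rows survived filtering."""


class UnknownGeneError(KeyError, GfabricError):
    """A gene symbol is not present in the dataset."""


@dataclass
class ExpressionDataset:
    """Spot-level replicate expression values for two conditions.

    Parameters
    ----------
    spot_ids
        Opaque spot identifiers, in file order.
    gene_of_spot
        Map spot id -> gene symbol (exactly one gene per spot).
    conditions
        Pair ``(reference, experimental)``; the study uses ``("N", "L")``.
    values
        Map condition -> float array of shape ``(n_spots, n_replicates)``.
        Replicate counts may differ between conditions.
    n_dropped
        Number of spots removed by the positivity/finite filter.
    """

    spot_ids: list[str]
    gene_of_spot: dict[str, str]
    conditions: tuple[str, str]
    values: dict[str, np.ndarray]
    n_dropped: int = 0

    _spots_by_gene: dict[str, list[int]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ConfigurationError("exactly two conditions are required")
        for cond in self.conditions:
            if cond not in self.values:
                raise ConfigurationError(f"missing values for condition {cond!r}")
            arr = np.asarray(self.values[cond], dtype=float)
            if arr.ndim != 2 or arr.shape[0] != len(self.spot_ids):
                raise ConfigurationError(
                    f"values[{cond!r}] must be (n_spots, n_replicates)"
                )
            if arr.shape[1] < 2:
                raise ConfigurationError("need >= 2 replicates per condition")
            self.values[cond] = arr
        missing = [s for s in self.spot_ids if s not in self.gene_of_spot]
        if missing:
            raise ConfigurationError(f"spots without gene annotation: {missing[:5]}")
        # index spots per gene, preserving file order
        index: dict[str, list[int]] = {}
        for i, spot in enumerate(self.spot_ids):
            index.setdefault(self.gene_of_spot[spot], []).append(i)
        self._spots_by_gene = index

    # -- basic queries -------------------------------------------------

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def genes(self) -> list[str]:
        """Gene symbols in order of first appearance."""
        return list(self._spots_by_gene)

    @property
    def n_genes(self) -> int:
        return len(self._spots_by_gene)

    def n_replicates(self, condition: str) -> int:
        return self.values[condition].shape[1]

    def spots_of_gene(self, gene: str) -> list[int]:
        """Row indices of the spots probing *gene*, in file order."""
        try:
            return self._spots_by_gene[gene]
        except KeyError:
            raise UnknownGeneError(gene) from None

    def gene_values(self, gene: str, condition: str) -> np.ndarray:
        """All replicate values of *gene*, shape ``(s, n_replicates)``."""
        return self.values[condition][self.spots_of_gene(gene)]

    def replicate_profile(self, gene: str, condition: str) -> np.ndarray:
        """Per-replicate spot-averaged expression, shape ``(n_replicates,)``.

        Biological replicas are the sampling unit, so tests comparing the
        two conditions operate on these spot-averaged values.
        """
        return self.gene_values(gene, condition).mean(axis=0)

    def validate(self) -> None:
        """Assert the dataset invariants (positive finite values)."""
        for cond in self.conditions:
            arr = self.values[cond]
            if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
                raise EmptyDatasetError(
                    f"non-finite or non-positive values in condition {cond!r}"
                )


@dataclass(frozen=True)
class GeneSet:
    """A named gene set, typically one KEGG-style functional pathway."""

    name: str
    kegg_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)

    def quantified(self, available: set[str] | list[str]) -> list[str]:
        """Members present in *available*, sorted for reproducibility."""
        avail = set(available)
        return sorted(g for g in self.genes if g in avail)


@dataclass
class AnalysisConfig:
    """Statistical knobs shared by the whole pipeline.

    alpha
        Per-test significance level for pair correlations and the
        heteroscedastic t-test of regulation (no multiplicity correction,
        by design of the framework).
    independence_threshold
        ``|COR|`` below which a pair is called independently expressed.
    cv_correction
        Apply the chi-square mid-interval correction to the coefficient
        of variation when computing REV.
    single_spot_cutoff_override
        Optional literal critical ``|r|`` to use for single-spot pairs in
        place of the computed t-distribution value (the published
        convention prints 0.951 where the closed form gives 0.950).
    gch_exponent
        Amplification exponent in the gene commanding height.
    seed
        Seed for any randomized routine.
    """

    alpha: float = 0.05
    independence_threshold: float = 0.05
    cv_correction: bool = True
    single_spot_cutoff_override: float | None = None
    gch_exponent: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0.0 <= self.independence_threshold < 1.0:
            raise ConfigurationError("independence_threshold must be in [0, 1)")
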