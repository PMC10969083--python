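"""End-to-end orchestration: dataset -> all result tables and networks.

A run computes, in order: per-gene AVE/REV, pair correlations and their
classes, per-gene regulation (x, Welch p, CUT, call, WIR, delta-REC,
delta-COORD), derived statistics (REC/COORD/GCH), pathway summaries,
intra-/inter-pathway coupling with remodeling ratios, and SIF networks
per condition.  A JSON manifest records the configuration hash, input
digests, package version and seed; identical manifests imply
bit-identical outputs for the deterministic pipeline.

Pairwise correlation over the full transcriptome is quadratic in the
gene count, so by default pairs are restricted to the configured gene
sets plus named anchor genes (which pair against every quantified
gene); full-pair mode is opt-in.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .datamodel import AnalysisConfig, ExpressionDataset, GeneSet, GfabricError
from .derived import derived_stats_table
from .io import write_sif, write_table
from .pathway import coupling_table, export_fabric_network, pathway_summary_table
from .primary import classify_pairs, gene_stats_table
from .regulation import categorize_vs_uniform, regulation_table

__all__ = ["RunManifest", "select_pairs", "run_gfp"]


@dataclass
class RunManifest:
    config_hash: str
    input_digests: dict[str, str]
    version: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def select_pairs(
    genes: list[str],
    gene_sets: list[GeneSet] | None,
    anchors: list[str] | None = None,
    all_pairs: bool = False,
) -> list[tuple[str, str]]:
    """Distinct gene pairs to correlate.

    Within/between the gene sets' quantified members, plus each anchor
    gene against every quantified gene; ``all_pairs=True`` returns the
    full N(N-1)/2 universe.
    """
    if all_pairs or (not gene_sets and not anchors):
        return list(combinations(genes, 2))
    gene_pos = {g: i for i, g in enumerate(genes)}
    scope: set[str] = set()
    if gene_sets:
        for gs in gene_sets:
            scope |= gs.genes & gene_pos.keys()
    pairs: set[tuple[str, str]] = set()
    ordered = sorted(scope, key=gene_pos.__getitem__)
    pairs.update(combinations(ordered, 2))
    for a in anchors or []:
        if a not in gene_pos:
            raise GfabricError(f"anchor gene {a!r} not quantified")
        for g in genes:
            if g != a:
                pairs.add((a, g) if gene_pos[a] < gene_pos[g] else (g, a))
    return sorted(pairs, key=lambda p: (gene_pos[p[0]], gene_pos[p[1]]))


def run_gfp(
    dataset: ExpressionDataset,
    gene_sets: list[GeneSet],
    outdir: str | Path,
    config: AnalysisConfig | None = None,
    anchors: list[str] | None = None,
    all_pairs: bool = False,
    input_paths: dict[str, str | Path] | None = None,
) -> RunManifest:
    """Run the full analysis and write every result table under *outdir*."""
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.validate()

    stage = "gene statistics"
    try:
        gene_stats = gene_stats_table(dataset, config)

        stage = "pair classification"
        pair_list = select_pairs(dataset.genes, gene_sets, anchors, all_pairs)
        pairs = pd.concat(
            [classify_pairs(dataset, c, config, pair_list) for c in dataset.conditions],
            ignore_index=True,
        )

        stage = "derived statistics"
        scoped = sorted(set(p for pr in pair_list for p in pr))
        derived = derived_stats_table(
            gene_stats[gene_stats["gene"].isin(scoped)], pairs, config.gch_exponent
        )

        stage = "regulation"
        regulation = regulation_table(dataset, config, gene_stats)
        drd = derived.pivot(index="gene", columns="condition")
        cond_n, cond_l = dataset.conditions
        reg_idx = regulation.set_index("gene")
        for col, a, b in (
            ("delta_rec", ("rec", cond_l), ("rec", cond_n)),
            ("delta_coord", ("coord", cond_l), ("coord", cond_n)),
        ):
            delta = (drd[a] - drd[b]) * (100.0 if col == "delta_rec" else 1.0)
            regulation[col] = reg_idx.index.map(delta).values
        regulation = categorize_vs_uniform(regulation, alpha=config.alpha)

        stage = "pathway summaries"
        summary = pathway_summary_table(
            regulation, derived, gene_sets, dataset.conditions
        )
        coupling = coupling_table(
            pairs, gene_sets, dataset.conditions, set(dataset.genes)
        )

        stage = "network export"
        outputs: dict[str, Path] = {
            "gene_stats": outdir / "gene_stats.tsv",
            "pairs": outdir / "pairs.tsv",
            "derived_stats": outdir / "derived_stats.tsv",
            "regulation": outdir / "regulation.tsv",
            "pathway_summary": outdir / "pathway_summary.tsv",
            "coupling": outdir / "coupling.tsv",
        }
        write_table(gene_stats, outputs["gene_stats"])
        write_table(pairs, outputs["pairs"])
        write_table(derived, outputs["derived_stats"])
        write_table(regulation, outputs["regulation"])
        write_table(summary, outputs["pathway_summary"])
        write_table(coupling, outputs["coupling"])
        for cond in dataset.conditions:
            edges, nodes = export_fabric_network(pairs, cond, regulation, gene_sets)
            outputs[f"network_{cond}"] = outdir / f"network_{cond}.sif"
            outputs[f"nodes_{cond}"] = outdir / f"nodes_{cond}.tsv"
            write_sif(edges, outputs[f"network_{cond}"])
            write_table(nodes, outputs[f"nodes_{cond}"])
    except GfabricError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise GfabricError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        input_digests={
            name: _digest(p) for name, p in (input_paths or {}).items()
        },
        version=__version__,
        seed=config.seed,
        outputs={k: str(v) for k, v in outputs.items()},
    )
    manifest.write(outdir / "manifest.json")
    return manifest
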