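"""Synthetic cohorts with planted prognosis-discriminative subpathways.

The generator emulates the data model the pipeline consumes: per-pathway
connected gene-gene graphs (random spanning tree plus extra edges), a
log2-scale expression matrix (standard normal per gene), a binary good/poor
prognosis label, and right-censored survival times. Each planted module is a
connected gene set whose genes are mean-shifted by ``effect`` (in per-gene
sd units) in the poor class; survival is exponential with log-hazard
proportional to the planted-module activity, with independent uniform
censoring. Defaults — 50 samples per class, 5-gene modules with a 3-sd
shift, ~30% censoring — are the conditions under which the pipeline's
recovery behaviour is characterised.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_io import ClinicalTable, ExpressionMatrix, GOOD, POOR
from .pathway_io import PathwayGraph, write_pathway_edgelists

logger = logging.getLogger(__name__)

__all__ = ["PlantedModule", "SimulationConfig", "SimulatedCohort",
           "simulate_cohort", "write_cohort"]


@dataclass(frozen=True)
class PlantedModule:
    """A planted class-discriminative connected module.

    ``effect`` is the between-class mean shift in per-gene sd units.
    """

    pathway: int = 0
    module_size: int = 5
    effect: float = 3.0

    def __post_init__(self) -> None:
        if self.module_size < 1:
            raise ValueError("module_size must be positive")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator settings.

    n_per_class
        Samples in each of the good and poor classes (default 50).
    planted
        Planted modules; default one 5-gene module with a 3-sd shift in
        pathway 0.
    beta_true
        Log-hazard per unit of planted-module activity (default 1.0).
    baseline_median_months
        Median survival of a baseline (activity-0) patient; sets the
        exponential baseline hazard (default 80 months).
    censoring_rate
        Approximate fraction of subjects censored, via independent uniform
        censoring times (default 0.3).
    structure_seed
        Seed for the cohort's *structure* (pathway graphs and planted-module
        placement). Defaults to ``seed``. Give two cohorts the same
        ``structure_seed`` but different ``seed`` to emulate an external
        validation cohort: same pathways and true modules, fresh patients.
    """

    n_pathways: int = 5
    genes_per_pathway: int = 30
    extra_edge_fraction: float = 0.3
    n_per_class: int = 50
    planted: tuple[PlantedModule, ...] = (PlantedModule(),)
    beta_true: float = 1.0
    baseline_median_months: float = 80.0
    censoring_rate: float = 0.3
    seed: int = 0
    structure_seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_pathways, self.genes_per_pathway, self.n_per_class) < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.extra_edge_fraction < 0:
            raise ValueError("extra_edge_fraction must be >= 0")
        for m in self.planted:
            if m.module_size > self.genes_per_pathway:
                raise ValueError(
                    f"module_size {m.module_size} exceeds genes_per_pathway "
                    f"{self.genes_per_pathway}"
                )
            if not (0 <= m.pathway < self.n_pathways):
                raise ValueError(f"planted module pathway {m.pathway} out of range")


@dataclass
class SimulatedCohort:
    graphs: list[PathwayGraph]
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: dict


def _random_connected_graph(
    pid: str, genes: list[str], extra_edge_fraction: float,
    rng: np.random.Generator,
) -> PathwayGraph:
    """Random spanning tree (uniform attachment) plus extra random edges."""
    n = len(genes)
    edges: set[tuple[str, str]] = set()
    for k in range(1, n):
        j = int(rng.integers(k))
        a, b = genes[j], genes[k]
        edges.add((a, b) if a < b else (b, a))
    n_extra = math.floor(extra_edge_fraction * n)
    attempts = 0
    while len(edges) < (n - 1) + n_extra and attempts < 50 * n_extra + 50:
        i, j = rng.integers(n, size=2)
        attempts += 1
        if i == j:
            continue
        a, b = genes[int(i)], genes[int(j)]
        edges.add((a, b) if a < b else (b, a))
    return PathwayGraph(pid, frozenset(genes), frozenset(edges))


def _grow_module(
    graph: PathwayGraph, size: int, rng: np.random.Generator
) -> list[str]:
    adj = graph.adjacency()
    genes = sorted(graph.genes)
    seed_gene = genes[int(rng.integers(len(genes)))]
    members = [seed_gene]
    frontier = sorted(adj[seed_gene])
    while len(members) < size:
        if not frontier:
            raise ValueError("pathway too small/disconnected for module")
        pick = frontier[int(rng.integers(len(frontier)))]
        members.append(pick)
        frontier = sorted(
            (set(frontier) | adj[pick]) - set(members)
        )
    return members


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate pathway graphs, expression, clinical data, and ground truth.

    Deterministic given ``config.seed``: the same configuration always
    produces byte-identical outputs.
    """
    structure_seed = (config.structure_seed if config.structure_seed
                      is not None else config.seed)
    rng_struct = np.random.default_rng(structure_seed)
    rng = np.random.default_rng(config.seed)
    graphs: list[PathwayGraph] = []
    gene_lists: list[list[str]] = []
    for p in range(config.n_pathways):
        pid = f"P{p:02d}"
        genes = [f"{pid}G{i:03d}" for i in range(config.genes_per_pathway)]
        graphs.append(
            _random_connected_graph(pid, genes, config.extra_edge_fraction,
                                    rng_struct)
        )
        gene_lists.append(genes)
    planted_genes = [
        _grow_module(graphs[mod.pathway], mod.module_size, rng_struct)
        for mod in config.planted
    ]

    all_genes = [g for genes in gene_lists for g in genes]
    n_good = n_poor = config.n_per_class
    samples = [f"S{j:03d}" for j in range(n_good + n_poor)]
    labels = np.array([GOOD] * n_good + [POOR] * n_poor)

    X = rng.normal(size=(len(all_genes), len(samples)))
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    poor_cols = labels == POOR

    planted_records = []
    module_activity = np.zeros(len(samples))
    for mod, members in zip(config.planted, planted_genes):
        rows = [gene_pos[g] for g in members]
        X[np.ix_(rows, np.flatnonzero(poor_cols))] += mod.effect
        module_activity += X[rows].mean(axis=0)
        planted_records.append(
            {
                "pathway_id": graphs[mod.pathway].pathway_id,
                "genes": members,
                "effect": mod.effect,
            }
        )

    lam0 = math.log(2) / config.baseline_median_months
    log_hazard = config.beta_true * module_activity
    hazard = lam0 * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        b = 1.0 / (lam0 * config.censoring_rate)
        t_cens = rng.uniform(0.0, b, size=len(samples))
    else:
        t_cens = np.full(len(samples), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)  # clinical tables require strictly positive

    expression = ExpressionMatrix(
        pd.DataFrame(X, index=all_genes, columns=samples), log2=True
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "time_months": np.round(time, 4),
                "event": event,
                "label": labels,
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    truth = {
        "planted": planted_records,
        "beta_true": config.beta_true,
        "baseline_median_months": config.baseline_median_months,
        "censoring_rate": config.censoring_rate,
        "seed": config.seed,
        "structure_seed": structure_seed,
    }
    return SimulatedCohort(graphs, expression, clinical, truth)


def write_cohort(
    cohort: SimulatedCohort, outdir: str | Path,
    header_lines: tuple[str, ...] = (),
) -> dict[str, Path]:
    """Write the cohort in the exact formats the I/O modules read."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pathways": outdir / "pathways.tsv",
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    write_pathway_edgelists(cohort.graphs, paths["pathways"],
                            header_lines=header_lines)
    with paths["expression"].open("w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        cohort.expression.data.round(6).to_csv(fh, sep="\t", index_label="gene")
    with paths["clinical"].open("w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        cohort.clinical.data.to_csv(fh, sep="\t", index_label="sample")
    paths["truth"].write_text(
        json.dumps(cohort.truth, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return paths
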