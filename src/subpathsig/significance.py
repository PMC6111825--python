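"""Permutation significance of discovered subpathways, with BH-FDR.

Three complementary nulls are tested for every candidate subpathway, each
with p = M/N where M counts permuted scores whose |t| strictly exceeds the
real |t|:

1. gene-label permutation — the assignment of expression rows to graph nodes
   is globally shuffled across all pathway networks (expression profiles and
   prognosis labels untouched); tests the link to pathway structure.
2. class-label permutation — the prognosis vector is shuffled; tests the
   link to prognosis status.
3. within-pathway permutation — random connected gene sets of the same size,
   grown from the same seed gene, are scored; tests whether the subpathway
   stands out inside its own pathway.

p-values are BH-adjusted per test across all candidates jointly, and a
subpathway is retained only when all three FDRs fall strictly below their
thresholds (defaults 1e-4, 1e-3, 1e-3 — tighter for test 1, which uses ten
times as many permutations).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .activity_search import SearchConfig, Subpathway, _combine, welch_t_rows, poor_mask
from .expression_io import ClinicalTable, ZMatrix
from .pathway_io import PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SignificanceRecord",
    "permtest_gene_labels",
    "permtest_class_labels",
    "permtest_within_pathway",
    "random_connected_set",
    "bh_fdr",
    "evaluate_significance",
    "filter_significant",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (1e-4, 1e-3, 1e-3)


@dataclass
class SignificanceRecord:
    """The three permutation p-values and their BH-FDR adjustments."""

    subpathway_id: str
    p1: float
    p2: float
    p3: float | None
    n_perm1: int
    n_perm2: int
    n_perm3: int
    fdr1: float = np.nan
    fdr2: float = np.nan
    fdr3: float = np.nan

    @property
    def p3_defined(self) -> bool:
        return self.p3 is not None


def _pvalue(m: int, n: int, pseudocount: bool) -> float:
    if pseudocount:
        return (m + 1) / (n + 1)
    return m / n


def _real_abs_scores(
    z: ZMatrix, subpathways: Sequence[Subpathway], mask: np.ndarray,
    divisor: str,
) -> np.ndarray:
    acts = np.stack([
        _combine(z.data.loc[list(sp.genes)].to_numpy().sum(axis=0),
                 sp.size, divisor)
        for sp in subpathways
    ])
    return np.abs(welch_t_rows(acts, mask))


def permtest_gene_labels(
    graphs: Sequence[PathwayGraph],
    z: ZMatrix,
    labels: pd.Series | ClinicalTable,
    subpathways: Sequence[Subpathway],
    n_perm: int = 10_000,
    seed: int | None = None,
    divisor: str = "n",
    scope: str = "global",
    pseudocount: bool = False,
) -> np.ndarray:
    """Gene-label permutation p-values (test 1), one per subpathway.

    ``scope="global"`` shuffles the expression-row assignment once over the
    union of expression-mapped genes of all pathways; ``"per_pathway"``
    shuffles independently within each pathway's gene set.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if scope not in ("global", "per_pathway"):
        raise ValueError(f"unknown scope {scope!r}")
    subpathways = list(subpathways)
    mask = poor_mask(labels, z.data.columns)
    expr_genes = set(z.data.index)
    pool_by_pathway = {
        g.pathway_id: sorted(g.genes & expr_genes) for g in graphs
    }
    if scope == "global":
        pool = sorted(set().union(*pool_by_pathway.values())) if graphs else []
        pools = {pid: pool for pid in pool_by_pathway}
    else:
        pools = pool_by_pathway
    pos_in_pool = {
        pid: {g: i for i, g in enumerate(p)} for pid, p in pools.items()
    }
    Z_by_pool: dict[str, np.ndarray] = {}
    for pid, p in pools.items():
        if scope == "global" and Z_by_pool:
            Z_by_pool[pid] = next(iter(Z_by_pool.values()))
        else:
            Z_by_pool[pid] = z.data.loc[p].to_numpy()
    member_idx = []
    for sp in subpathways:
        pos = pos_in_pool[sp.pathway_id]
        try:
            member_idx.append(np.array([pos[g] for g in sp.genes]))
        except KeyError as exc:
            raise KeyError(
                f"subpathway {sp.subpathway_id} gene {exc} not in its "
                "pathway's expression-mapped gene pool"
            ) from exc

    real = _real_abs_scores(z, subpathways, mask, divisor)
    rng = np.random.default_rng(seed)
    n_samples = len(z.samples)
    exceed = np.zeros(len(subpathways), dtype=int)
    for _ in range(n_perm):
        perms = {
            pid: rng.permutation(len(p)) for pid, p in pools.items()
        } if scope == "per_pathway" else None
        if scope == "global":
            gperm = rng.permutation(len(next(iter(pools.values()))))
        acts = np.empty((len(subpathways), n_samples))
        for k, sp in enumerate(subpathways):
            perm = gperm if scope == "global" else perms[sp.pathway_id]
            rows = Z_by_pool[sp.pathway_id][perm[member_idx[k]]]
            acts[k] = _combine(rows.sum(axis=0), sp.size, divisor)
        t = np.abs(welch_t_rows(acts, mask))
        exceed += t > real
    return np.array([
        _pvalue(int(m), n_perm, pseudocount) for m in exceed
    ])


def permtest_class_labels(
    z: ZMatrix,
    labels: pd.Series | ClinicalTable,
    subpathways: Sequence[Subpathway],
    n_perm: int = 1000,
    seed: int | None = None,
    divisor: str = "n",
    pseudocount: bool = False,
) -> np.ndarray:
    """Class-label permutation p-values (test 2), one per subpathway."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    subpathways = list(subpathways)
    mask = poor_mask(labels, z.data.columns)
    acts = np.stack([
        _combine(z.data.loc[list(sp.genes)].to_numpy().sum(axis=0),
                 sp.size, divisor)
        for sp in subpathways
    ])
    real = np.abs(welch_t_rows(acts, mask))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(subpathways), dtype=int)
    for _ in range(n_perm):
        pm = rng.permutation(mask)
        t = np.abs(welch_t_rows(acts, pm))
        exceed += t > real
    return np.array([
        _pvalue(int(m), n_perm, pseudocount) for m in exceed
    ])


def random_connected_set(
    adj: dict[str, Iterable[str]], seed_gene: str, size: int,
    rng: np.random.Generator,
) -> list[str]:
    """Grow a random connected gene set of ``size`` from ``seed_gene``.

    Uniform random frontier expansion: at each step one gene is drawn
    uniformly from the neighbors of the current set.
    """
    members = [seed_gene]
    member_set = {seed_gene}
    frontier = sorted(set(adj[seed_gene]) - member_set)
    while len(members) < size:
        if not frontier:
            raise ValueError(
                f"fewer than {size} genes reachable from seed {seed_gene!r}"
            )
        pick = frontier[rng.integers(len(frontier))]
        members.append(pick)
        member_set.add(pick)
        frontier = sorted(
            (set(frontier) | set(adj[pick])) - member_set
        )
    return members


def _reachable_count(adj: dict[str, set[str]], seed_gene: str) -> int:
    seen = {seed_gene}
    stack = [seed_gene]
    while stack:
        for n in adj[stack.pop()]:
            if n not in seen:
                seen.add(n)
                stack.append(n)
    return len(seen)


def permtest_within_pathway(
    graph: PathwayGraph,
    z: ZMatrix,
    labels: pd.Series | ClinicalTable,
    subpathway: Subpathway,
    n_perm: int = 1000,
    seed: int | None = None,
    divisor: str = "n",
    pseudocount: bool = False,
) -> float | None:
    """Within-pathway permutation p-value (test 3) for one subpathway.

    Each trial scores a uniformly grown random connected set of the same
    size, anchored at the same seed gene, inside the expression-mapped part
    of the parent pathway. Returns None (undefined) when fewer than ``size``
    genes are reachable from the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    expr_genes = set(z.data.index)
    avail = sorted(graph.genes & expr_genes)
    idx = {g: i for i, g in enumerate(avail)}
    adj_full = graph.adjacency()
    adj = {g: sorted(n for n in adj_full[g] if n in idx) for g in avail}
    if subpathway.seed_gene not in idx:
        return None
    if _reachable_count({g: set(a) for g, a in adj.items()},
                        subpathway.seed_gene) < subpathway.size:
        warnings.warn(
            f"{subpathway.subpathway_id}: fewer than {subpathway.size} genes "
            f"reachable from seed {subpathway.seed_gene!r}; p3 undefined"
        )
        return None
    Z = z.data.loc[avail].to_numpy()
    mask = poor_mask(labels, z.data.columns)
    real = abs(float(welch_t_rows(
        _combine(
            Z[[idx[g] for g in subpathway.genes]].sum(axis=0),
            subpathway.size, divisor,
        )[None, :],
        mask,
    )[0]))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        genes = random_connected_set(adj, subpathway.seed_gene,
                                     subpathway.size, rng)
        act = _combine(Z[[idx[g] for g in genes]].sum(axis=0),
                       subpathway.size, divisor)
        t = abs(float(welch_t_rows(act[None, :], mask)[0]))
        if t > real:
            exceed += 1
    return _pvalue(exceed, n_perm, pseudocount)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def evaluate_significance(
    graphs: Sequence[PathwayGraph],
    z: ZMatrix,
    labels: pd.Series | ClinicalTable,
    subpathways: Sequence[Subpathway],
    n_perm: tuple[int, int, int] = (10_000, 1000, 1000),
    seed: int | None = None,
    config: SearchConfig = SearchConfig(),
    pseudocount: bool = False,
) -> list[SignificanceRecord]:
    """Run all three permutation tests and BH-adjust each across subpathways."""
    subpathways = list(subpathways)
    if not subpathways:
        return []
    graph_by_id = {g.pathway_id: g for g in graphs}
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    p1 = permtest_gene_labels(
        graphs, z, labels, subpathways, n_perm=n_perm[0], seed=s1,
        divisor=config.divisor, pseudocount=pseudocount,
    )
    p2 = permtest_class_labels(
        z, labels, subpathways, n_perm=n_perm[1], seed=s2,
        divisor=config.divisor, pseudocount=pseudocount,
    )
    rng3 = np.random.SeedSequence(s3).spawn(len(subpathways))
    p3 = [
        permtest_within_pathway(
            graph_by_id[sp.pathway_id], z, labels, sp, n_perm=n_perm[2],
            seed=int(c.generate_state(1)[0] % (2**31)),
            divisor=config.divisor, pseudocount=pseudocount,
        )
        for sp, c in zip(subpathways, rng3)
    ]
    records = [
        SignificanceRecord(
            subpathway_id=sp.subpathway_id,
            p1=float(a), p2=float(b), p3=c,
            n_perm1=n_perm[0], n_perm2=n_perm[1], n_perm3=n_perm[2],
        )
        for sp, a, b, c in zip(subpathways, p1, p2, p3)
    ]
    fdr1 = bh_fdr([r.p1 for r in records])
    fdr2 = bh_fdr([r.p2 for r in records])
    defined = [r for r in records if r.p3_defined]
    fdr3 = bh_fdr([r.p3 for r in defined]) if defined else np.array([])
    for r, f1, f2 in zip(records, fdr1, fdr2):
        r.fdr1 = float(f1)
        r.fdr2 = float(f2)
    for r, f3 in zip(defined, fdr3):
        r.fdr3 = float(f3)
    return records


def filter_significant(
    records: Sequence[SignificanceRecord],
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> list[str]:
    """Ids whose three FDRs are *all strictly below* the three thresholds.

    Records with undefined p3 are excluded with a warning.
    """
    out = []
    for r in records:
        if not r.p3_defined:
            warnings.warn(
                f"{r.subpathway_id}: p3 undefined, excluded from filtering"
            )
            continue
        if (r.fdr1 < thresholds[0] and r.fdr2 < thresholds[1]
                and r.fdr3 < thresholds[2]):
            out.append(r.subpathway_id)
    return out
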