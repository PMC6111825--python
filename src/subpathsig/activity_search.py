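"""Subpathway activities and the seeded greedy discriminative search.

A subpathway is a connected gene set inside one pathway graph. Its activity
in sample *j* is the combined z-score of its member genes,

    a_kj = (sum_i z_ij) / n          (divisor configurable: n or sqrt(n))

and its discriminative score S is the Welch two-sample t statistic of the
activity vector between poor- and good-prognosis samples. The greedy search
starts one candidate from every seed gene and repeatedly adds the neighbor
gene that maximizes |S|, accepting an addition only when the new score
exceeds (1 + r) x the current score; with the default improvement rate
r = 0.05 the search stops once no neighbor improves the score by more than
5%, which guards against overfitting the expression data. Grown sets outside
the size window (default 4..49 genes) are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import POOR, ClinicalTable, ZMatrix
from .pathway_io import PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "Subpathway",
    "ActivityMatrix",
    "subpathway_activity",
    "discriminative_score",
    "welch_t_rows",
    "greedy_search",
    "build_activity_matrix",
]


@dataclass(frozen=True)
class SearchConfig:
    """Greedy-search tuning knobs.

    improvement_rate
        Multiplicative threshold r: an addition is accepted only if the new
        score exceeds ``(1 + r) * current``. Default 0.05.
    min_size, max_size
        Inclusive size window for emitted subpathways ("more than three and
        less than 50 genes" read literally: 4..49).
    score_mode
        ``absolute_t`` ranks candidates by |t| (two-sided, the default);
        ``signed_t`` ranks by the raw poor-minus-good t.
    divisor
        Eq-1 combining divisor: ``n`` (plain mean) or ``sqrt_n``.
    """

    improvement_rate: float = 0.05
    min_size: int = 4
    max_size: int = 49
    score_mode: str = "absolute_t"
    divisor: str = "n"

    def __post_init__(self) -> None:
        if self.improvement_rate < 0:
            raise ValueError("improvement_rate must be >= 0")
        if not (1 <= self.min_size <= self.max_size):
            raise ValueError("need 1 <= min_size <= max_size")
        if self.score_mode not in ("absolute_t", "signed_t"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")
        if self.divisor not in ("n", "sqrt_n"):
            raise ValueError(f"unknown divisor {self.divisor!r}")


@dataclass(frozen=True)
class Subpathway:
    """A connected gene set with its signed discriminative score.

    ``genes`` preserves greedy insertion order (seed first). ``score`` is the
    signed Welch t (poor minus good); the search ranked on its absolute value
    unless configured otherwise.
    """

    subpathway_id: str
    pathway_id: str
    seed_gene: str
    genes: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        if self.seed_gene not in self.genes:
            raise ValueError("seed gene must be a member")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in subpathway")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


@dataclass
class ActivityMatrix:
    """Subpathways x samples activity values (a_kj)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("non-finite activity value")

    @property
    def subpathway_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def _combine(total: np.ndarray, n: int, divisor: str) -> np.ndarray:
    if divisor == "sqrt_n":
        return total / math.sqrt(n)
    return total / n


def subpathway_activity(
    z: ZMatrix, genes, divisor: str = "n"
) -> pd.Series:
    """Combined z-score activity of a gene set in every sample (Eq-1 style)."""
    genes = list(genes)
    if not genes:
        raise ValueError("gene set is empty")
    missing = [g for g in genes if g not in z.data.index]
    if missing:
        raise KeyError(f"gene(s) absent from z-matrix: {missing}")
    total = z.data.loc[genes].to_numpy().sum(axis=0)
    return pd.Series(
        _combine(total, len(genes), divisor), index=z.data.columns
    )


def poor_mask(labels: pd.Series | ClinicalTable, samples) -> np.ndarray:
    """Boolean mask (aligned to ``samples``) of poor-prognosis samples."""
    if isinstance(labels, ClinicalTable):
        labels = labels.labels
    aligned = labels.reindex(list(samples))
    if aligned.isna().any():
        missing = list(aligned.index[aligned.isna()][:5])
        raise ValueError(f"missing prognosis label for sample(s) {missing}")
    return (aligned == POOR).to_numpy()


def welch_t_rows(values: np.ndarray, poor: np.ndarray) -> np.ndarray:
    """Welch t statistic (poor minus good) for each row of ``values``.

    Degenerate rows (zero variance in both groups, equal means) score 0;
    unequal means with zero pooled variance score +/-inf.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    poor = np.asarray(poor, dtype=bool)
    n1 = int(poor.sum())
    n2 = int((~poor).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each class needs >= 2 samples (poor={n1}, good={n2})"
        )
    x = values[:, poor]
    y = values[:, ~poor]
    d = x.mean(axis=1) - y.mean(axis=1)
    se2 = x.var(axis=1, ddof=1) / n1 + y.var(axis=1, ddof=1) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d / np.sqrt(se2)
    zero_se = se2 == 0
    t[zero_se & (d == 0)] = 0.0
    t[zero_se & (d > 0)] = np.inf
    t[zero_se & (d < 0)] = -np.inf
    return t


def discriminative_score(
    activity: pd.Series | np.ndarray, labels: pd.Series | ClinicalTable
) -> float:
    """Signed Welch t of an activity vector between poor and good samples."""
    if isinstance(activity, pd.Series):
        mask = poor_mask(labels, activity.index)
        values = activity.to_numpy()
    else:
        if isinstance(labels, ClinicalTable):
            labels = labels.labels
        mask = (np.asarray(labels) == POOR)
        values = np.asarray(activity)
    return float(welch_t_rows(values[None, :], mask)[0])


def _rank_score(t: np.ndarray, mode: str) -> np.ndarray:
    return np.abs(t) if mode == "absolute_t" else t


def greedy_search(
    graph: PathwayGraph,
    z: ZMatrix,
    labels: pd.Series | ClinicalTable,
    config: SearchConfig = SearchConfig(),
) -> list[Subpathway]:
    """Seeded greedy search for locally score-maximal subpathways.

    Every expression-mapped gene of the pathway seeds one candidate. At each
    step the neighbor gene (of any current member) whose addition maximizes
    the ranking score is considered and adopted only if the new score exceeds
    ``(1 + r) x current``; ties between neighbors break to the
    lexicographically smallest symbol. Grown sets are size-filtered and
    de-duplicated across seeds (first seed in sorted order wins). Genes
    without expression are invisible to the search.
    """
    avail = sorted(graph.genes & set(z.data.index))
    if not avail:
        logger.warning(
            "pathway %s shares no genes with the expression matrix",
            graph.pathway_id,
        )
        return []
    idx = {g: i for i, g in enumerate(avail)}
    Z = z.data.loc[avail].to_numpy()
    mask = poor_mask(labels, z.data.columns)
    adj_full = graph.adjacency()
    adj = {
        g: sorted(n for n in adj_full[g] if n in idx) for g in avail
    }

    results: list[Subpathway] = []
    seen: set[frozenset[str]] = set()
    for seed in avail:
        members = [seed]
        member_set = {seed}
        total = Z[idx[seed]].copy()
        act = _combine(total, 1, config.divisor)
        score = float(
            _rank_score(welch_t_rows(act[None, :], mask), config.score_mode)[0]
        )
        while True:
            cands = sorted(
                {n for m in members for n in adj[m]} - member_set
            )
            if not cands:
                break
            cand_rows = Z[[idx[c] for c in cands]]
            acts = _combine(cand_rows + total, len(members) + 1, config.divisor)
            t = welch_t_rows(acts, mask)
            ranked = _rank_score(t, config.score_mode)
            best = int(np.argmax(ranked))  # first max: lexicographic tie-break
            if not ranked[best] > (1.0 + config.improvement_rate) * score:
                break
            gene = cands[best]
            members.append(gene)
            member_set.add(gene)
            total += Z[idx[gene]]
            score = float(ranked[best])
        if not (config.min_size <= len(members) <= config.max_size):
            continue
        fs = frozenset(members)
        if fs in seen:
            continue
        seen.add(fs)
        signed = discriminative_score(
            pd.Series(
                _combine(Z[[idx[m] for m in members]].sum(axis=0),
                         len(members), config.divisor),
                index=z.data.columns,
            ),
            labels,
        )
        results.append(
            Subpathway(
                subpathway_id=f"{graph.pathway_id}_{len(results) + 1}",
                pathway_id=graph.pathway_id,
                seed_gene=seed,
                genes=tuple(members),
                score=signed,
            )
        )
    return results


def build_activity_matrix(
    z: ZMatrix, subpathways, divisor: str = "n"
) -> ActivityMatrix:
    """Stack per-subpathway activity vectors into a subpathways x samples matrix."""
    subpathways = list(subpathways)
    rows = [
        subpathway_activity(z, sp.genes, divisor=divisor).to_numpy()
        for sp in subpathways
    ]
    data = pd.DataFrame(
        np.asarray(rows).reshape(len(rows), -1) if rows
        else np.empty((0, len(z.samples))),
        index=[sp.subpathway_id for sp in subpathways],
        columns=z.data.columns,
    )
    if data.index.has_duplicates:
        dup = data.index[data.index.duplicated()][0]
        raise ValueError(f"duplicate subpathway id {dup!r}")
    return ActivityMatrix(data)
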