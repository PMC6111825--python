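"""Cox-weighted subpathway risk-score signatures.

Each selected subpathway k receives a coefficient beta_k from a univariate
Cox proportional-hazards fit of survival on its activity; a candidate
signature over a subset S of subpathways scores every patient as

    risk = sum_{k in S} beta_k * a_k .

All 2^k - 1 non-empty subsets of the selected subpathways are enumerated;
for each, patients are split at the median risk score (high iff strictly
above) and the subsets are ranked by the two-group log-rank p-value. The
winning subset is frozen — member gene sets, betas, and the training-median
cutoff — and applied verbatim to external cohorts, whose activities are
recomputed on their own z-scores.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .activity_search import ActivityMatrix, Subpathway, _combine
from .expression_io import ClinicalTable, ZMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "SignatureMember",
    "Signature",
    "RiskScoreTable",
    "cox_beta",
    "enumerate_combinations",
    "risk_scores",
    "median_split",
    "select_best_signature",
    "apply_signature",
]

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class CoxResult:
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class SignatureMember:
    subpathway_id: str
    pathway_id: str
    genes: tuple[str, ...]
    beta: float


@dataclass(frozen=True)
class Signature:
    """A frozen risk-score signature: members, betas, and cutoff."""

    members: tuple[SignatureMember, ...]
    cutoff: float
    eq1_divisor: str = "n"
    created_from: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) < 1:
            raise ValueError("signature needs at least one member")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        for m in self.members:
            if not np.isfinite(m.beta):
                raise ValueError(f"non-finite beta for {m.subpathway_id}")

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.subpathway_id for m in self.members)

    @property
    def betas(self) -> dict[str, float]:
        return {m.subpathway_id: m.beta for m in self.members}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "members": [
                {
                    "id": m.subpathway_id,
                    "pathway": m.pathway_id,
                    "genes": list(m.genes),
                    "beta": m.beta,
                }
                for m in self.members
            ],
            "cutoff": self.cutoff,
            "eq1_divisor": self.eq1_divisor,
            "created_from": dict(self.created_from),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Signature":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        payload = json.loads(text)
        return cls(
            members=tuple(
                SignatureMember(m["id"], m["pathway"], tuple(m["genes"]),
                                float(m["beta"]))
                for m in payload["members"]
            ),
            cutoff=float(payload["cutoff"]),
            eq1_divisor=payload.get("eq1_divisor", "n"),
            created_from=payload.get("created_from", {}),
        )


@dataclass
class RiskScoreTable:
    """Per-sample risk score and high/low group assignment."""

    data: pd.DataFrame  # index sample, columns: score, group

    def __post_init__(self) -> None:
        for col in ("score", "group"):
            if col not in self.data.columns:
                raise ValueError(f"risk table lacks column {col!r}")

    @property
    def scores(self) -> pd.Series:
        return self.data["score"]

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.data.index[self.data["group"] == group])


def cox_beta(activity: pd.Series, survival: ClinicalTable) -> CoxResult:
    """Univariate Cox PH fit of overall survival on one activity vector."""
    aligned = activity.reindex(survival.samples)
    if aligned.isna().any():
        raise ValueError("activity missing for some clinical samples")
    if survival.event.sum() < 1:
        raise ValueError("no events observed; Cox model undefined")
    if aligned.nunique() <= 1:
        raise ValueError("constant covariate; Cox model undefined")
    df = pd.DataFrame(
        {
            "T": survival.time.to_numpy(dtype=float),
            "E": survival.event.to_numpy(dtype=int),
            "x": aligned.to_numpy(dtype=float),
        }
    )
    cph = CoxPHFitter()
    cph.fit(df, duration_col="T", event_col="E")
    row = cph.summary.loc["x"]
    return CoxResult(
        beta=float(row["coef"]),
        hr=float(row["exp(coef)"]),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
    )


def enumerate_combinations(ids: Sequence[str]) -> list[tuple[str, ...]]:
    """All 2^k - 1 non-empty subsets, ordered by size then lexicographically."""
    ids = list(ids)
    k = len(ids)
    if k == 0:
        raise ValueError("no ids to combine")
    if k > 20:
        raise ValueError(f"refusing to enumerate 2^{k} - 1 subsets")
    if len(set(ids)) != k:
        raise ValueError("duplicate ids")
    out: list[tuple[str, ...]] = []
    for size in range(1, k + 1):
        out.extend(sorted(combinations(sorted(ids), size)))
    return out


def risk_scores(
    betas: Mapping[str, float] | Signature, activity: ActivityMatrix
) -> pd.Series:
    """Linear risk score per sample: sum_k beta_k * a_kj."""
    if isinstance(betas, Signature):
        betas = betas.betas
    missing = [k for k in betas if k not in activity.data.index]
    if missing:
        raise KeyError(f"member(s) absent from activity matrix: {missing}")
    ids = list(betas)
    b = np.array([betas[k] for k in ids])
    scores = b @ activity.data.loc[ids].to_numpy()
    return pd.Series(scores, index=activity.data.columns, name="score")


def median_split(
    scores: pd.Series, cutoff: float | None = None
) -> RiskScoreTable:
    """Assign high iff score strictly exceeds the cutoff (default: median).

    A frozen training cutoff is reused verbatim on external cohorts.
    """
    if len(scores) == 0:
        raise ValueError("no scores to split")
    if cutoff is None:
        if len(scores) < 2:
            raise ValueError("need >= 2 samples to compute a median cutoff")
        cutoff = float(np.median(scores.to_numpy()))
    groups = np.where(scores.to_numpy() > cutoff, HIGH, LOW)
    return RiskScoreTable(
        pd.DataFrame({"score": scores, "group": groups}, index=scores.index)
    )


def _logrank_p(table: RiskScoreTable, survival: ClinicalTable) -> float | None:
    from .survival_eval import logrank

    try:
        _, p = logrank(table, survival)
    except ValueError:
        return None
    return p


def select_best_signature(
    candidate_ids: Sequence[str],
    subpathways: Mapping[str, Subpathway] | Sequence[Subpathway],
    activity: ActivityMatrix,
    survival: ClinicalTable,
) -> tuple[Signature, pd.DataFrame]:
    """Exhaustively rank all non-empty member subsets by log-rank p.

    Betas are fit once per candidate (univariate, on the supplied training
    cohort); each subset's patients are median-split on its own scores and
    the subset with the smallest log-rank p wins (ties: smaller size, then
    lexicographic member order). Returns the frozen signature (cutoff = the
    winner's training median) and a per-size report of the best subset of
    each size.
    """
    if not isinstance(subpathways, Mapping):
        subpathways = {sp.subpathway_id: sp for sp in subpathways}
    candidate_ids = list(candidate_ids)
    betas: dict[str, float] = {}
    for cid in candidate_ids:
        betas[cid] = cox_beta(activity.data.loc[cid], survival).beta

    best: tuple[float, int, tuple[str, ...]] | None = None
    best_per_size: dict[int, tuple[float, tuple[str, ...]]] = {}
    for subset in enumerate_combinations(candidate_ids):
        sub_betas = {k: betas[k] for k in subset}
        scores = risk_scores(sub_betas, activity)
        table = median_split(scores)
        if not table.samples_in(HIGH) or not table.samples_in(LOW):
            warnings.warn(f"subset {subset}: degenerate split, skipped")
            continue
        p = _logrank_p(table, survival)
        if p is None:
            warnings.warn(f"subset {subset}: log-rank undefined, skipped")
            continue
        key = (p, len(subset), subset)
        if best is None or key < best:
            best = key
        size = len(subset)
        if size not in best_per_size or p < best_per_size[size][0]:
            best_per_size[size] = (p, subset)

    if best is None:
        raise ValueError("no subset produced a valid two-group split")
    _, _, winner = best
    win_scores = risk_scores({k: betas[k] for k in winner}, activity)
    cutoff = float(np.median(win_scores.to_numpy()))
    members = tuple(
        SignatureMember(
            subpathway_id=cid,
            pathway_id=subpathways[cid].pathway_id,
            genes=tuple(subpathways[cid].genes),
            beta=betas[cid],
        )
        for cid in winner
    )
    report = pd.DataFrame(
        {
            "size": sorted(best_per_size),
            "members": [";".join(best_per_size[s][1])
                        for s in sorted(best_per_size)],
            "logrank_p": [best_per_size[s][0] for s in sorted(best_per_size)],
        }
    )
    sig = Signature(
        members=members,
        cutoff=cutoff,
        created_from={
            "n_samples": len(activity.samples),
            "n_candidates": len(candidate_ids),
        },
    )
    return sig, report


def apply_signature(sig: Signature, z_external: ZMatrix) -> RiskScoreTable:
    """Score an external cohort with a frozen signature.

    Activities are recomputed from the external cohort's own z-scores;
    betas and the cutoff are reused verbatim. Member genes missing from the
    external matrix are skipped with a warning (the activity averages over
    the present genes); a member with no mapped genes is an error.
    """
    rows = []
    for m in sig.members:
        present = [g for g in m.genes if g in z_external.data.index]
        if not present:
            raise ValueError(
                f"signature member {m.subpathway_id}: no genes present "
                "in the external matrix"
            )
        if len(present) < len(m.genes):
            warnings.warn(
                f"{m.subpathway_id}: {len(m.genes) - len(present)} of "
                f"{len(m.genes)} genes missing; activity uses the "
                f"{len(present)} present genes"
            )
        total = z_external.data.loc[present].to_numpy().sum(axis=0)
        rows.append(_combine(total, len(present), sig.eq1_divisor))
    act = ActivityMatrix(
        pd.DataFrame(
            np.asarray(rows),
            index=[m.subpathway_id for m in sig.members],
            columns=z_external.data.columns,
        )
    )
    scores = risk_scores(sig.betas, act)
    return median_split(scores, cutoff=sig.cutoff)
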