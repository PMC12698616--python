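"""Leave-one-protein-out evaluation, metrics, and screening benchmarks.

Provides the evaluation protocol used throughout the package:

* :func:`lopo_splits` — one train/test split per protein target, with an
  optional leakage purge that removes training pairs sharing a compound
  with the held-out target's actives (on by default).
* :func:`roc_auc` / :func:`pr_auc` — midrank-tied ROC-AUC (equivalently
  the Mann-Whitney U probability) and interpolation-free PR-AUC.
* :func:`enrichment_factor` — fraction of actives recovered in the top
  slice of a ranking relative to their prevalence (EF at top 2% by
  default).
* :func:`next_active_rank` — the virtual-screening experiment: given a
  known active as the query, the rank of the best-scoring other active
  in a large decoy-dominated library.
* :func:`paired_ttest` — two-sided paired t-test between per-protein
  metric vectors of two scorers.

All ranking-based metrics run over pluggable scorers; TC and
cosine-over-embedding baselines are provided so the learned index and
the reference similarities share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .chem import cosine, tanimoto_matrix
from .pairs import CompoundPair, FingerprintSet

__all__ = [
    "LopoSplit",
    "MetricReport",
    "RankResult",
    "PairedTestResult",
    "lopo_splits",
    "roc_auc",
    "pr_auc",
    "enrichment_factor",
    "next_active_rank",
    "mean_next_active_rank",
    "paired_ttest",
    "tc_baseline_scorer",
    "cosine_baseline_scorer",
]

Scorer = Callable[[str, str], float]


@dataclass
class LopoSplit:
    held_out_target: str
    train_pairs: List[CompoundPair]
    test_pairs: List[CompoundPair]


@dataclass
class MetricReport:
    """Per-protein metrics and their group summary for one scorer."""

    scorer: str
    per_protein: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def summary(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        if not self.per_protein:
            return out
        metrics = next(iter(self.per_protein.values())).keys()
        for m in metrics:
            vals = np.array([row[m] for row in self.per_protein.values()])
            out[f"mean_{m}"] = float(vals.mean())
            out[f"sd_{m}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return out


@dataclass(frozen=True)
class RankResult:
    query_id: str
    next_active_rank: int
    library_size: int

    def __post_init__(self) -> None:
        if not (1 <= self.next_active_rank <= self.library_size):
            raise ValueError("rank must lie in [1, library_size]")


@dataclass(frozen=True)
class PairedTestResult:
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def lopo_splits(
    group_pairs: Sequence[CompoundPair],
    actives_by_target: Optional[Mapping[str, Sequence[str]]] = None,
    purge: bool = True,
) -> List[LopoSplit]:
    """One split per source target: its pairs are the test set, the rest train.

    With ``purge`` on, training pairs containing any compound active on
    the held-out target are removed, so no test-set active leaks into
    training. ``actives_by_target`` supplies the active membership; when
    omitted, it is reconstructed from the S pairs of each target.
    """
    targets = sorted({p.source_target for p in group_pairs})
    if len(targets) < 2:
        raise ValueError("LOPO needs at least two distinct source targets")
    if actives_by_target is None:
        actives_by_target = {}
        for p in group_pairs:
            if p.label == "S":
                actives_by_target.setdefault(p.source_target, set()).update(p.key)
    splits = []
    for t in targets:
        test = [p for p in group_pairs if p.source_target == t]
        train = [p for p in group_pairs if p.source_target != t]
        if purge:
            held = set(actives_by_target.get(t, ()))
            train = [p for p in train if p.id_a not in held and p.id_b not in held]
        splits.append(LopoSplit(held_out_target=t, train_pairs=train, test_pairs=test))
    return splits


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC-AUC with midrank tie handling (Mann-Whitney U probability)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("ROC-AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Precision-recall AUC by step summation (average precision)."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("PR-AUC requires both classes")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def enrichment_factor(
    scores: Sequence[float],
    labels: Sequence[int],
    top_frac: float = 0.02,
) -> float:
    """Enrichment factor at the top ``top_frac`` of the ranking.

    EF = (actives in top ceil(top_frac*N) / slice size) / (actives / N).
    Ties at the cutoff are resolved by descending score with stable input
    order, so the metric is deterministic and invariant under strictly
    monotone score transforms.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not (0.0 < top_frac < 1.0):
        raise ValueError("top_frac must be in (0, 1)")
    n = len(scores)
    n_act = int(labels.sum())
    if n == 0 or n_act == 0 or n_act == n:
        raise ValueError("enrichment factor requires both classes")
    n_top = int(np.ceil(top_frac * n))
    order = np.argsort(-scores, kind="stable")
    hits = int(labels[order[:n_top]].sum())
    return (hits / n_top) / (n_act / n)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def next_active_rank(
    query: str,
    library: Sequence[str],
    actives: Set[str],
    scorer: Scorer,
) -> RankResult:
    """Rank of the best-scoring other active when screening with ``query``.

    The library (which must exclude the query) is sorted by descending
    ``scorer(query, member)``; tied scores receive the mean of their tied
    positions, rounded half-up. The reported rank is the best (smallest)
    rank among the library's actives.
    """
    if query not in actives:
        raise ValueError("query must be an active compound")
    if query in library:
        raise ValueError("library must exclude the query")
    others = [m for m in library if m in actives]
    if not others:
        raise ValueError("no other active in the library")
    scores = np.array([scorer(query, m) for m in library], dtype=float)
    # midrank positions on descending scores
    ranks = stats.rankdata(-scores, method="average")
    active_mask = np.array([m in actives for m in library])
    best = float(np.min(ranks[active_mask]))
    return RankResult(
        query_id=query,
        next_active_rank=_round_half_up(best),
        library_size=len(library),
    )


def mean_next_active_rank(
    queries: Sequence[str],
    library_without: Callable[[str], Sequence[str]],
    actives: Set[str],
    scorer: Scorer,
) -> float:
    """Average next-active rank over a set of query actives."""
    ranks = [
        next_active_rank(q, library_without(q), actives, scorer).next_active_rank
        for q in queries
    ]
    return float(np.mean(ranks))


def paired_ttest(metric_a: Sequence[float], metric_b: Sequence[float]) -> PairedTestResult:
    """Two-sided paired Student t-test on per-protein metric differences."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("paired test needs equal-length vectors of length >= 3")
    diffs = a - b
    if np.allclose(diffs.std(ddof=1), 0.0):
        if np.allclose(diffs, 0.0):
            return PairedTestResult(0.0, 1.0, int(a.size), degenerate=True)
        return PairedTestResult(np.inf * np.sign(diffs.mean()), 0.0, int(a.size),
                                degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTestResult(float(res.statistic), float(res.pvalue), int(a.size))


def tc_baseline_scorer(fps: FingerprintSet) -> Scorer:
    """Tanimoto similarity over a fingerprint set, as a pluggable scorer."""

    def score(query: str, member: str) -> float:
        a = fps.rows([query])
        b = fps.rows([member])
        return float(tanimoto_matrix(a, b)[0, 0])

    return score


def cosine_baseline_scorer(embeddings: Mapping[str, np.ndarray]) -> Scorer:
    """Cosine similarity over externally supplied embedding vectors."""

    def score(query: str, member: str) -> float:
        for cid in (query, member):
            if cid not in embeddings:
                raise KeyError(f"no embedding for compound {cid!r}")
        return cosine(embeddings[query], embeddings[member])

    return score
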