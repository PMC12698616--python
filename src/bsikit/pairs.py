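"""S/N pair dataset construction.

Builds the training material for the bioactivity similarity classifier:

1. Discretize bioactivity records into active / inactive / ambiguous
   (pChEMBL > 6.5 active, < 4.5 or an explicit "inactive" comment
   inactive, the band in between excluded from both classes).
2. Select property-matched decoys for each active (six DUD-E windows plus
   a Tanimoto ceiling of 0.3 against the paired active).
3. Reduce per-target active sets with a diversity cascade:
   Bemis-Murcko scaffold representatives -> Butina clustering at TC 0.4
   -> K-means down to at most 100 actives.
4. Enumerate S pairs (active x active, all-vs-all) and N pairs
   (active x inactives-and-decoys), keep only pairs with TC < 0.4,
   deduplicate, and drop pairs with conflicting labels across targets.
5. Encode each pair by elementwise summation of the two 256-bit Morgan
   fingerprints, and assemble class-ratio-controlled datasets
   (25:75 or 4:96 S:N).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans

from .chem import CompoundRecord, Fingerprint, tanimoto_matrix

logger = logging.getLogger("bsikit.pairs")

__all__ = [
    "ActivityRecord",
    "ActivityLabel",
    "TargetLigandSet",
    "CompoundPair",
    "PairEncoding",
    "PairDataset",
    "DistributionMatchReport",
    "FingerprintSet",
    "DECOY_WINDOWS",
    "label_activity",
    "label_activity_table",
    "select_decoys",
    "scaffold_representatives",
    "butina_cluster",
    "kmeans_cap",
    "diversity_cascade",
    "build_pairs",
    "dedup_pairs",
    "encode_pair",
    "assemble_dataset",
    "distribution_match",
]

ACTIVE_ABOVE = 6.5
INACTIVE_BELOW = 4.5
INACTIVE_COMMENTS = ("inactive", "not active")

# property windows: |d mw| <= 25 Da, |d logP| <= 1, |d rot| <= 2,
# |d HBA| <= 1, |d HBD| <= 1, identical net charge
DECOY_WINDOWS = np.array([25.0, 1.0, 2.0, 1.0, 1.0, 0.0])


@dataclass(frozen=True)
class ActivityRecord:
    """One compound-target bioactivity measurement."""

    compound_id: str
    target_id: str
    group_id: str
    pchembl: Optional[float] = None
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pchembl is None and not self.comment:
            raise ValueError("record needs a pChEMBL value or a comment")
        if not self.group_id:
            raise ValueError("group_id must be non-empty")


ActivityLabel = str  # "active" | "inactive" | "ambiguous"


@dataclass
class TargetLigandSet:
    target_id: str
    group_id: str
    actives: List[str]
    inactives_experimental: List[str] = field(default_factory=list)
    decoys: List[str] = field(default_factory=list)

    @property
    def negatives(self) -> List[str]:
        return list(self.inactives_experimental) + list(self.decoys)

    def validate(self) -> None:
        overlap = set(self.actives) & set(self.negatives)
        if overlap:
            raise ValueError(
                f"target {self.target_id}: compounds on both sides: {sorted(overlap)[:5]}"
            )


@dataclass(frozen=True)
class CompoundPair:
    """Unordered compound pair with its label, TC, and source target."""

    id_a: str
    id_b: str
    label: str  # "S" or "N"
    tc: float
    source_target: str

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("pair members must differ")
        if self.id_a > self.id_b:
            a, b = self.id_b, self.id_a
            object.__setattr__(self, "id_a", a)
            object.__setattr__(self, "id_b", b)
        if self.label not in ("S", "N"):
            raise ValueError("label must be 'S' or 'N'")

    @property
    def key(self) -> Tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass(frozen=True)
class PairEncoding:
    """Summed-fingerprint feature vector; entries in {0, 1, 2}."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=np.int8))


@dataclass
class DistributionMatchReport:
    ks_D: float
    ks_p: float
    jsd: float


class FingerprintSet:
    """Indexed matrix of equal-parameter fingerprints keyed by compound id."""

    def __init__(self, ids: Sequence[str], matrix: np.ndarray,
                 kind: str = "morgan", radius: int = 2):
        matrix = np.asarray(matrix, dtype=np.uint8)
        if len(ids) != matrix.shape[0]:
            raise ValueError("ids and matrix rows differ")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate compound ids in fingerprint set")
        self.ids = list(ids)
        self.matrix = matrix
        self.kind = kind
        self.radius = radius
        self.index = {cid: i for i, cid in enumerate(self.ids)}

    @property
    def n_bits(self) -> int:
        return self.matrix.shape[1]

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        try:
            idx = [self.index[c] for c in ids]
        except KeyError as e:
            raise KeyError(f"no fingerprint for compound {e.args[0]!r}") from None
        return self.matrix[idx]

    def fingerprint(self, cid: str) -> Fingerprint:
        return Fingerprint(bits=self.rows([cid])[0], n_bits=self.n_bits,
                           radius=self.radius, kind=self.kind)

    @classmethod
    def from_fingerprints(cls, fps: Mapping[str, Fingerprint]) -> "FingerprintSet":
        ids = sorted(fps)
        first = fps[ids[0]]
        for cid in ids:
            if not fps[cid].same_params(first):
                raise ValueError("mixed fingerprint parameters")
        matrix = np.stack([fps[c].bits for c in ids])
        return cls(ids, matrix, kind=first.kind, radius=first.radius)


# ---------------------------------------------------------------------------
# activity labeling


def label_activity(
    records: Sequence[ActivityRecord],
    active_above: float = ACTIVE_ABOVE,
    inactive_below: float = INACTIVE_BELOW,
    inactive_comments: Sequence[str] = INACTIVE_COMMENTS,
) -> ActivityLabel:
    """Discretize all measurements of one compound-target combination.

    Numeric pChEMBL values are aggregated by their median before
    thresholding; an explicit inactive comment forces the inactive label
    unless the aggregated pChEMBL contradicts it (i.e. crosses the active
    threshold).
    """
    if not records:
        raise ValueError("no activity records given")
    keys = {(r.compound_id, r.target_id) for r in records}
    if len(keys) != 1:
        raise ValueError("records must share one (compound, target) combination")
    values = [r.pchembl for r in records if r.pchembl is not None]
    comments = {
        (r.comment or "").strip().lower() for r in records if r.comment
    }
    flagged_inactive = any(c in comments for c in inactive_comments)
    if values:
        agg = float(np.median(values))
        if agg > active_above:
            return "active"
        if agg < inactive_below or flagged_inactive:
            return "inactive"
        return "ambiguous"
    if flagged_inactive:
        return "inactive"
    return "ambiguous"


def label_activity_table(records: Iterable[ActivityRecord]) -> Dict[Tuple[str, str], ActivityLabel]:
    """Label every (compound, target) combination in a stream of records."""
    grouped: Dict[Tuple[str, str], List[ActivityRecord]] = {}
    for r in records:
        grouped.setdefault((r.compound_id, r.target_id), []).append(r)
    return {k: label_activity(v) for k, v in grouped.items()}


# ---------------------------------------------------------------------------
# decoy selection


def select_decoys(
    active_id: str,
    active_props: np.ndarray,
    active_fp: np.ndarray,
    pool_ids: Sequence[str],
    pool_props: np.ndarray,
    pool_fps: np.ndarray,
    n: int,
    tc_max: float = 0.3,
    seed: int = 0,
) -> List[str]:
    """Sample ``n`` property-matched decoys for one active compound.

    Eligibility requires all six property windows (``DECOY_WINDOWS``,
    with exact net-charge match) and Tanimoto below ``tc_max`` against
    this active only. Sampling is uniform without replacement under the
    seed; a shortfall returns every eligible candidate with a warning.
    """
    if len(pool_ids) == 0:
        logger.warning("decoy pool empty for active %s", active_id)
        return []
    pool_props = np.asarray(pool_props, dtype=float)
    active_props = np.asarray(active_props, dtype=float)
    delta = np.abs(pool_props - active_props[None, :])
    ok = np.all(delta[:, :5] <= DECOY_WINDOWS[:5], axis=1)
    ok &= delta[:, 5] == 0
    ok &= np.asarray(pool_ids) != active_id
    if ok.any():
        tcs = tanimoto_matrix(active_fp[None, :], pool_fps[ok])[0]
        eligible = np.flatnonzero(ok)[tcs < tc_max]
    else:
        eligible = np.array([], dtype=int)
    if len(eligible) <= n:
        if len(eligible) < n:
            logger.warning(
                "decoy shortfall for active %s: %d eligible of %d requested",
                active_id, len(eligible), n,
            )
        chosen = eligible
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(eligible, size=n, replace=False)
    return sorted(pool_ids[i] for i in chosen)


# ---------------------------------------------------------------------------
# diversity cascade


def scaffold_representatives(compounds: Sequence[CompoundRecord]) -> List[str]:
    """One representative per distinct Bemis-Murcko scaffold.

    Acyclic molecules have an empty scaffold and are each kept as their
    own singleton cluster. The representative of a cluster is the
    lexicographically smallest compound id.
    """
    from rdkit.Chem.Scaffolds import MurckoScaffold

    clusters: Dict[str, List[str]] = {}
    for rec in compounds:
        mol = rec.require_mol()
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
        if scaffold == "":
            # acyclic: private singleton cluster
            clusters[f"__acyclic__{rec.compound_id}"] = [rec.compound_id]
        else:
            clusters.setdefault(scaffold, []).append(rec.compound_id)
    return sorted(min(members) for members in clusters.values())


def butina_cluster(
    ids: Sequence[str],
    fps: np.ndarray,
    tc_threshold: float = 0.4,
) -> Tuple[Dict[str, int], List[str]]:
    """Sphere-exclusion (leader) clustering at a Tanimoto threshold.

    Two compounds are neighbours when TC >= ``tc_threshold``. Leaders are
    processed in order of descending neighbour count with compound-id
    tiebreak; each leader claims its still-unassigned neighbours.
    Returns the cluster assignment (id -> cluster index) and the leaders.
    """
    if len(ids) == 0:
        raise ValueError("at least one fingerprint required")
    fps = np.asarray(fps, dtype=np.uint8)
    tc = tanimoto_matrix(fps, fps)
    neighbor = tc >= tc_threshold
    np.fill_diagonal(neighbor, False)
    counts = neighbor.sum(axis=1)
    order = sorted(range(len(ids)), key=lambda i: (-counts[i], ids[i]))
    assignment: Dict[str, int] = {}
    leaders: List[str] = []
    assigned = np.zeros(len(ids), dtype=bool)
    for i in order:
        if assigned[i]:
            continue
        cluster = len(leaders)
        leaders.append(ids[i])
        members = np.flatnonzero(neighbor[i] & ~assigned)
        assigned[i] = True
        assignment[ids[i]] = cluster
        for j in members:
            assigned[j] = True
            assignment[ids[j]] = cluster
    return assignment, leaders


def kmeans_cap(
    ids: Sequence[str],
    fps: np.ndarray,
    cap: int = 100,
    seed: int = 0,
) -> List[str]:
    """Reduce a set to at most ``cap`` members by K-means on the bit vectors.

    Below the cap, everything is returned. Otherwise the bit vectors are
    clustered into ``cap`` groups and the member nearest each centroid is
    kept (compound-id tiebreak), giving a diverse subset of fixed size.
    """
    if len(ids) == 0:
        raise ValueError("fps non-empty required")
    if len(ids) <= cap:
        return sorted(ids)
    X = np.asarray(fps, dtype=np.float64)
    km = KMeans(n_clusters=cap, random_state=seed, n_init=4)
    labels = km.fit_predict(X)
    picked: List[str] = []
    for c in range(cap):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            continue
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        best = min(zip(d, (ids[m] for m in members)))
        picked.append(best[1])
    return sorted(picked)


def diversity_cascade(
    ids: Sequence[str],
    fps: FingerprintSet,
    records: Optional[Mapping[str, CompoundRecord]] = None,
    butina_tc: float = 0.4,
    cap: int = 100,
    seed: int = 0,
) -> List[str]:
    """Scaffold -> Butina -> K-means reduction of a per-target active set.

    The scaffold stage requires parsed structures and is skipped when
    ``records`` is None (fingerprint-only inputs).
    """
    selected = sorted(ids)
    if records is not None:
        selected = scaffold_representatives([records[c] for c in selected])
    _, leaders = butina_cluster(selected, fps.rows(selected), tc_threshold=butina_tc)
    selected = sorted(leaders)
    selected = kmeans_cap(selected, fps.rows(selected), cap=cap, seed=seed)
    if len(selected) > len(ids):
        raise AssertionError("cascade must be a contraction")
    return selected


# ---------------------------------------------------------------------------
# pair construction


def build_pairs(
    ligand_set: TargetLigandSet,
    fps: FingerprintSet,
    tc_max: float = 0.4,
) -> List[CompoundPair]:
    """All-vs-all S pairs and active-vs-negative N pairs under the TC filter.

    Candidate S pairs are every unordered combination of the target's
    actives; candidate N pairs are every active crossed with every
    experimental inactive and decoy. Pairs at or above ``tc_max``
    Tanimoto are discarded, keeping only structurally dissimilar pairs.
    """
    ligand_set.validate()
    actives = sorted(ligand_set.actives)
    negatives = sorted(ligand_set.negatives)
    if len(actives) == 0:
        raise ValueError(f"target {ligand_set.target_id} has no actives")
    if len(actives) < 2:
        logger.warning("target %s: fewer than 2 actives, no S pairs",
                       ligand_set.target_id)
    pairs: List[CompoundPair] = []
    A = fps.rows(actives)
    tc_aa = tanimoto_matrix(A, A)
    for i in range(len(actives)):
        for j in range(i + 1, len(actives)):
            t = float(tc_aa[i, j])
            if t < tc_max:
                pairs.append(CompoundPair(actives[i], actives[j], "S", t,
                                          ligand_set.target_id))
    if negatives:
        N = fps.rows(negatives)
        tc_an = tanimoto_matrix(A, N)
        for i in range(len(actives)):
            for j in range(len(negatives)):
                t = float(tc_an[i, j])
                if t < tc_max:
                    pairs.append(CompoundPair(actives[i], negatives[j], "N", t,
                                              ligand_set.target_id))
    return pairs


def dedup_pairs(pairs: Sequence[CompoundPair]) -> Tuple[List[CompoundPair], int, int]:
    """Deduplicate unordered pairs and drop label conflicts.

    A pair observed as S via one target and N via another carries an
    ambiguous training signal and is removed entirely. Returns the
    surviving pairs plus the numbers of duplicates and conflicting pairs
    removed.
    """
    by_key: Dict[Tuple[str, str], List[CompoundPair]] = {}
    for p in sorted(pairs, key=lambda p: (p.id_a, p.id_b, p.label, p.source_target)):
        by_key.setdefault(p.key, []).append(p)
    kept: List[CompoundPair] = []
    n_conflict = 0
    n_dup = 0
    for key, members in sorted(by_key.items()):
        labels = {m.label for m in members}
        if len(labels) > 1:
            n_conflict += 1
            continue
        n_dup += len(members) - 1
        kept.append(members[0])
    if n_conflict:
        logger.warning("dropped %d pairs with conflicting S/N labels", n_conflict)
    return kept, n_dup, n_conflict


def encode_pair(fp_a: Fingerprint, fp_b: Fingerprint) -> PairEncoding:
    """Elementwise sum of two fingerprints; symmetric in its operands."""
    if not fp_a.same_params(fp_b):
        raise ValueError("fingerprint parameter mismatch in pair encoding")
    return PairEncoding(vector=fp_a.bits.astype(np.int8) + fp_b.bits.astype(np.int8))


class PairDataset:
    """Labelled pair collection with its encoding matrix built on demand."""

    def __init__(self, pairs: Sequence[CompoundPair]):
        self.pairs = list(pairs)
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate unordered pair in dataset")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([1 if p.label == "S" else 0 for p in self.pairs], dtype=np.int64)

    @property
    def s_fraction(self) -> float:
        if not self.pairs:
            return float("nan")
        return float(self.labels.mean())

    def encode(self, fps: FingerprintSet) -> np.ndarray:
        ia = [fps.index[p.id_a] for p in self.pairs]
        ib = [fps.index[p.id_b] for p in self.pairs]
        return (fps.matrix[ia].astype(np.int8) + fps.matrix[ib].astype(np.int8))

    def counts(self) -> Counter:
        return Counter(p.label for p in self.pairs)


REGIME_S_FRACTION = {"slight": 0.25, "heavy": 0.04}


def assemble_dataset(
    pairs: Sequence[CompoundPair],
    regime: str,
    seed: int = 0,
) -> PairDataset:
    """Impose a class ratio (slight 25:75 or heavy 4:96 S:N) by subsampling.

    All of the scarcer side (relative to the requested ratio) is kept and
    the other side is subsampled under the seed; the decoy augmentation
    that makes the heavy regime reachable (ten decoys per active) happens
    upstream in pair construction.
    """
    if regime not in REGIME_S_FRACTION:
        raise ValueError(f"unknown regime {regime!r}")
    f = REGIME_S_FRACTION[regime]
    s_pairs = [p for p in pairs if p.label == "S"]
    n_pairs = [p for p in pairs if p.label == "N"]
    if not s_pairs:
        raise ValueError("no S pairs available; cannot assemble dataset")
    if not n_pairs:
        raise ValueError("no N pairs available; cannot assemble dataset")
    ratio = (1.0 - f) / f  # N per S
    rng = np.random.default_rng(seed)
    k_s = min(len(s_pairs), int(len(n_pairs) / ratio))
    if k_s == 0:
        raise ValueError(
            f"cannot reach {regime} regime: need {int(np.ceil(ratio))} N per S, "
            f"have {len(n_pairs)} N for {len(s_pairs)} S"
        )
    k_n = int(round(k_s * ratio))
    k_n = min(k_n, len(n_pairs))
    chosen_s = s_pairs if k_s == len(s_pairs) else [
        s_pairs[i] for i in sorted(rng.choice(len(s_pairs), size=k_s, replace=False))
    ]
    chosen_n = n_pairs if k_n == len(n_pairs) else [
        n_pairs[i] for i in sorted(rng.choice(len(n_pairs), size=k_n, replace=False))
    ]
    return PairDataset(chosen_s + chosen_n)


# ---------------------------------------------------------------------------
# decoy-quality diagnostics


def distribution_match(
    tc_samples_a: Sequence[float],
    tc_samples_b: Sequence[float],
    bins: int = 50,
) -> DistributionMatchReport:
    """Two-sample KS test plus Jensen-Shannon divergence on [0, 1].

    Used to verify that the TC distribution of decoy-based N pairs
    replicates that of N pairs built from experimentally verified
    inactives. The JSD is computed base-2 between normalized histograms
    on ``bins`` equal-width bins of [0, 1].
    """
    a = np.asarray(tc_samples_a, dtype=float)
    b = np.asarray(tc_samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both TC samples must be non-empty")
    ks = ks_2samp(a, b, method="asymp")
    edges = np.linspace(0.0, 1.0, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    pa = pa / pa.sum()
    pb = pb / pb.sum()
    jsd = float(jensenshannon(pa, pb, base=2) ** 2)
    if np.isnan(jsd):
        jsd = 0.0
    return DistributionMatchReport(ks_D=float(ks.statistic), ks_p=float(ks.pvalue), jsd=jsd)
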