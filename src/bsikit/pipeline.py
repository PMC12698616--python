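"""Workflow stages: dataset build, training, LOPO, transfer, screening.

These functions bind the modules into the complete protocol:
synthesize / load a compound universe -> discretize activities ->
diversity-reduce actives -> select decoys -> build S/N pairs ->
impose the class ratio -> train -> evaluate (LOPO metrics, enrichment
factor, next-active ranking, transfer learning). The CLI in
:mod:`bsikit.cli` is a thin wrapper over this module.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from . import evaluate as ev
from .chem import tanimoto_matrix
from .io import RunManifest
from .model import (BsiModel, LARGE_CONFIG, ModelConfig, build_model, finetune,
                    predict_bsi, train)
from .pairs import (CompoundPair, FingerprintSet, PairDataset, TargetLigandSet,
                    assemble_dataset, build_pairs, dedup_pairs,
                    diversity_cascade, label_activity_table, select_decoys)
from .synthetic import PROPERTY_COLUMNS, SyntheticUniverse

logger = logging.getLogger("bsikit.pipeline")

__all__ = [
    "GroupData",
    "build_ligand_sets",
    "build_group_datasets",
    "train_group_model",
    "lopo_evaluate",
    "bsi_scorer",
    "transfer_arms",
    "vs_rank_experiment",
    "write_pairs_file",
    "read_pairs_file",
]


@dataclass
class GroupData:
    """Assembled pair dataset and provenance for one protein group."""

    group_id: str
    dataset: PairDataset
    raw_pairs: List[CompoundPair]
    ligand_sets: Dict[str, TargetLigandSet]
    manifest: RunManifest = field(default_factory=RunManifest)

    @property
    def actives_by_target(self) -> Dict[str, List[str]]:
        return {t: ls.actives for t, ls in self.ligand_sets.items()}


def _activity_records(universe: SyntheticUniverse):
    from .pairs import ActivityRecord

    records = []
    for row in universe.activities.itertuples(index=False):
        pchembl = None if row.pchembl != row.pchembl else float(row.pchembl)  # NaN check
        comment = row.comment or None
        records.append(ActivityRecord(row.compound_id, row.target_id,
                                      row.group_id, pchembl, comment))
    return records


def build_ligand_sets(
    universe: SyntheticUniverse,
    seed: int = 0,
    decoys_per_active: int = 10,
    tc_decoy_max: float = 0.3,
    cap: int = 100,
    butina_tc: float = 0.4,
    manifest: Optional[RunManifest] = None,
) -> Dict[str, TargetLigandSet]:
    """Label activities, diversity-reduce actives, and select decoys per target."""
    manifest = manifest if manifest is not None else RunManifest()
    labels = label_activity_table(_activity_records(universe))
    by_target: Dict[str, Dict[str, List[str]]] = {}
    for (cid, tid), lab in labels.items():
        by_target.setdefault(tid, {"active": [], "inactive": [], "ambiguous": []})
        by_target[tid][lab].append(cid)

    props = universe.properties.set_index("compound_id")
    records = None
    if universe.config.mode == "smiles":
        from .chem import canonicalize
        records = {
            row.compound_id: canonicalize(row.smiles, row.compound_id)
            for row in universe.compounds.itertuples(index=False)
        }

    rng = np.random.default_rng(seed)
    sets: Dict[str, TargetLigandSet] = {}
    n_actives_in = n_actives_out = n_decoys = 0
    for tid in sorted(by_target):
        actives = sorted(by_target[tid]["active"])
        if not actives:
            continue
        n_actives_in += len(actives)
        actives = diversity_cascade(
            actives, universe.fingerprints_tc,
            records={c: records[c] for c in actives} if records else None,
            butina_tc=butina_tc, cap=cap, seed=seed,
        )
        n_actives_out += len(actives)
        pool_ids = np.array(universe.pool_by_target.get(tid, []))
        pool_props = props.loc[pool_ids, PROPERTY_COLUMNS].to_numpy(dtype=float) \
            if len(pool_ids) else np.empty((0, 6))
        pool_fps = universe.fingerprints_tc.rows(pool_ids) if len(pool_ids) \
            else np.empty((0, universe.fingerprints_tc.n_bits), dtype=np.uint8)
        decoys: Set[str] = set()
        for cid in actives:
            chosen = select_decoys(
                cid,
                props.loc[cid, PROPERTY_COLUMNS].to_numpy(dtype=float),
                universe.fingerprints_tc.rows([cid])[0],
                pool_ids, pool_props, pool_fps,
                n=decoys_per_active, tc_max=tc_decoy_max,
                seed=int(rng.integers(2 ** 31)),
            )
            decoys.update(chosen)
        # decoy candidates that are themselves active on this target are
        # excluded by construction (actives never appear in the pool shard)
        inactives = sorted(set(by_target[tid]["inactive"]) - set(actives))
        n_decoys += len(decoys)
        sets[tid] = TargetLigandSet(
            target_id=tid,
            group_id=universe.group_of_target[tid],
            actives=list(actives),
            inactives_experimental=inactives,
            decoys=sorted(decoys),
        )
    manifest.count("actives_before_cascade", n_actives_in)
    manifest.count("actives_after_cascade", n_actives_out)
    manifest.count("decoys_selected", n_decoys)
    return sets


def build_group_datasets(
    universe: SyntheticUniverse,
    regime: str = "slight",
    seed: int = 0,
    tc_pair_max: float = 0.4,
    decoys_per_active: int = 10,
    tc_decoy_max: float = 0.3,
    cap: int = 100,
    butina_tc: float = 0.4,
) -> Dict[str, GroupData]:
    """Run the full dataset-construction stage for every protein group."""
    manifest = RunManifest()
    sets = build_ligand_sets(
        universe, seed=seed, decoys_per_active=decoys_per_active,
        tc_decoy_max=tc_decoy_max, cap=cap, butina_tc=butina_tc,
        manifest=manifest,
    )
    by_group: Dict[str, List[TargetLigandSet]] = {}
    for ls in sets.values():
        by_group.setdefault(ls.group_id, []).append(ls)

    out: Dict[str, GroupData] = {}
    for gid in sorted(by_group):
        raw: List[CompoundPair] = []
        candidates = 0
        for ls in sorted(by_group[gid], key=lambda s: s.target_id):
            nA, nNeg = len(ls.actives), len(ls.negatives)
            candidates += nA * (nA - 1) // 2 + nA * nNeg
            raw.extend(build_pairs(ls, universe.fingerprints_tc, tc_max=tc_pair_max))
        tc_filtered = candidates - len(raw)
        pairs, n_dup, n_conflict = dedup_pairs(raw)
        gman = RunManifest(counts=dict(manifest.counts),
                           warnings=list(manifest.warnings))
        gman.count("pairs_candidates", candidates)
        gman.count("pairs_tc_filtered", tc_filtered)
        gman.count("pairs_duplicate", n_dup)
        gman.count("pairs_conflict_dropped", n_conflict)
        gman.count("pairs_in", len(raw))
        gman.count("pairs_out", len(pairs))
        dataset = assemble_dataset(pairs, regime=regime, seed=seed)
        gman.count("pairs_assembled", len(dataset))
        gman.counts["s_fraction_permille"] = int(round(dataset.s_fraction * 1000))
        out[gid] = GroupData(group_id=gid, dataset=dataset, raw_pairs=pairs,
                             ligand_sets={ls.target_id: ls for ls in by_group[gid]},
                             manifest=gman)
    return out


def train_group_model(
    groups: Sequence[GroupData],
    fps: FingerprintSet,
    config: ModelConfig,
    seed: Optional[int] = None,
) -> BsiModel:
    """Train one model on the merged pair data of the given groups."""
    pairs: List[CompoundPair] = []
    for g in groups:
        pairs.extend(g.dataset.pairs)
    ds = PairDataset(pairs)
    X = ds.encode(fps)
    y = ds.labels
    model = build_model(config)
    return train(model, X, y, seed=seed)


def bsi_scorer(model: BsiModel, fps: FingerprintSet) -> ev.Scorer:
    """Pairwise scorer applying the trained index to summed encodings."""

    def score(query: str, member: str) -> float:
        enc = (fps.rows([query])[0].astype(np.int8)
               + fps.rows([member])[0].astype(np.int8))
        return float(predict_bsi(model, enc))

    return score


def lopo_evaluate(
    group: GroupData,
    fps: FingerprintSet,
    config: ModelConfig,
    seed: int = 0,
    top_frac: float = 0.02,
    purge: bool = True,
    embeddings: Optional[Mapping[str, np.ndarray]] = None,
) -> Dict[str, ev.MetricReport]:
    """Leave-one-protein-out metrics for the learned index and baselines.

    For every held-out protein, a model is trained from scratch on the
    remaining proteins' pairs and scored on the held-out pairs; the TC
    baseline (and optionally a cosine-over-embeddings baseline) is
    evaluated on the identical test pairs.
    """
    splits = ev.lopo_splits(group.dataset.pairs,
                            actives_by_target=group.actives_by_target,
                            purge=purge)
    reports = {"bsi": ev.MetricReport(scorer="bsi"),
               "tc": ev.MetricReport(scorer="tc")}
    if embeddings is not None:
        reports["cosine"] = ev.MetricReport(scorer="cosine")
        cos = ev.cosine_baseline_scorer(embeddings)
    for split in splits:
        train_ds = PairDataset(split.train_pairs)
        test_ds = PairDataset(split.test_pairs)
        y_test = test_ds.labels
        if np.unique(y_test).size < 2 or np.unique(train_ds.labels).size < 2:
            logger.warning("target %s skipped: single-class split",
                           split.held_out_target)
            continue
        model = train(build_model(config), train_ds.encode(fps), train_ds.labels,
                      seed=seed)
        scores = predict_bsi(model, test_ds.encode(fps))
        row = {
            "roc_auc": ev.roc_auc(scores, y_test),
            "pr_auc": ev.pr_auc(scores, y_test),
            "ef": ev.enrichment_factor(scores, y_test, top_frac=top_frac),
        }
        reports["bsi"].per_protein[split.held_out_target] = row
        tc_scores = np.array([p.tc for p in test_ds.pairs])
        reports["tc"].per_protein[split.held_out_target] = {
            "roc_auc": ev.roc_auc(tc_scores, y_test),
            "pr_auc": ev.pr_auc(tc_scores, y_test),
            "ef": ev.enrichment_factor(tc_scores, y_test, top_frac=top_frac),
        }
        if embeddings is not None:
            cs = np.array([cos(p.id_a, p.id_b) for p in test_ds.pairs])
            reports["cosine"].per_protein[split.held_out_target] = {
                "roc_auc": ev.roc_auc(cs, y_test),
                "pr_auc": ev.pr_auc(cs, y_test),
                "ef": ev.enrichment_factor(cs, y_test, top_frac=top_frac),
            }
    return reports


# ---------------------------------------------------------------------------
# transfer learning


def _transfer_split(
    group: GroupData,
    fps: FingerprintSet,
    n_train_actives: int,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split one small group's data by compounds for the transfer protocol.

    ``n_train_actives`` actives (drawn evenly across the group's targets)
    and an equal number of decoys form the fine-tuning set; the held-out
    compounds form the evaluation set. No compound is shared between the
    two sides.
    """
    rng = np.random.default_rng(seed)
    chosen: Set[str] = set()
    targets = sorted(group.ligand_sets)
    per_target = int(np.ceil(n_train_actives / len(targets)))
    for tid in targets:
        actives = group.ligand_sets[tid].actives
        k = min(per_target, len(actives))
        chosen.update(rng.choice(actives, size=k, replace=False))
    chosen = set(sorted(chosen)[:n_train_actives]) if len(chosen) > n_train_actives else chosen
    train_decoys: Set[str] = set()
    all_decoys = sorted({d for ls in group.ligand_sets.values() for d in ls.decoys})
    k = min(len(chosen), len(all_decoys))
    train_decoys.update(rng.choice(all_decoys, size=k, replace=False))
    train_ids = chosen | train_decoys

    def encode(pairs):
        ds = PairDataset(pairs)
        return ds.encode(fps), ds.labels

    train_pairs = [p for p in group.raw_pairs
                   if p.id_a in train_ids and p.id_b in train_ids]
    eval_pairs = [p for p in group.raw_pairs
                  if p.id_a not in train_ids and p.id_b not in train_ids]
    Xtr, ytr = encode(train_pairs)
    Xev, yev = encode(eval_pairs)
    return Xtr, ytr, Xev, yev


def transfer_arms(
    pretrained: BsiModel,
    group: GroupData,
    fps: FingerprintSet,
    n_train_actives: int = 20,
    seed: int = 0,
    epochs: int = 5,
    learning_rate: float = 1e-4,
) -> Tuple[float, float]:
    """ROC-AUC of the fine-tuned model versus a scratch-trained control.

    Both arms use the same architecture, data, epochs (5) and learning
    rate (1e-4); only the initialization differs: the pretrained
    cross-family weights versus a fresh seed.
    """
    Xtr, ytr, Xev, yev = _transfer_split(group, fps, n_train_actives, seed)
    if np.unique(ytr).size < 2 or np.unique(yev).size < 2:
        raise ValueError("transfer split lacks both classes")
    tuned = finetune(pretrained, Xtr, ytr, epochs=epochs,
                     learning_rate=learning_rate, seed=seed)
    scratch_cfg = ModelConfig(
        hidden_sizes=pretrained.config.hidden_sizes,
        dropout=pretrained.config.dropout, epochs=epochs,
        learning_rate=learning_rate, batch_size=pretrained.config.batch_size,
        seed=seed + 1, input_dim=pretrained.config.input_dim,
    )
    scratch = train(build_model(scratch_cfg), Xtr, ytr, epochs=epochs,
                    learning_rate=learning_rate, seed=seed)
    auc_tuned = ev.roc_auc(predict_bsi(tuned, Xev), yev)
    auc_scratch = ev.roc_auc(predict_bsi(scratch, Xev), yev)
    return auc_tuned, auc_scratch


# ---------------------------------------------------------------------------
# virtual-screening experiment


def vs_rank_experiment(
    library_fps: FingerprintSet,
    active_ids: Sequence[str],
    decoy_ids: Sequence[str],
    scorer: ev.Scorer,
) -> Tuple[float, List[ev.RankResult]]:
    """Mean next-active rank over every active used as the query.

    Each active queries the library of all remaining compounds; the rank
    of its best-scoring fellow active is recorded and the ranks are
    averaged.
    """
    actives = set(active_ids)
    all_ids = list(active_ids) + list(decoy_ids)
    results = []
    for q in active_ids:
        library = [c for c in all_ids if c != q]
        results.append(ev.next_active_rank(q, library, actives, scorer))
    mean_rank = float(np.mean([r.next_active_rank for r in results]))
    return mean_rank, results


# ---------------------------------------------------------------------------
# pairs file round trip


def write_pairs_file(pairs: Sequence[CompoundPair], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id_a", "id_b", "label", "tc", "source_target"])
        for p in pairs:
            w.writerow([p.id_a, p.id_b, p.label, f"{p.tc:.6f}", p.source_target])


def read_pairs_file(path: str) -> List[CompoundPair]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(CompoundPair(row["id_a"], row["id_b"], row["label"],
                                    float(row["tc"]), row["source_target"]))
    return out
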