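"""ChEMBL-like synthetic universes for end-to-end testing and benchmarks.

Real bioactivity extracts cannot be bundled, so this module generates
universes with the statistical features the pipeline depends on: groups
of protein targets whose actives share a latent bioactivity signature
while remaining structurally dissimilar (pairwise TC < 0.4), experimental
inactives, and a candidate pool from which property-matched decoys can
be drawn.

Two tiers:

* **fingerprint mode** (default, no chemistry): compounds are 256-bit
  vectors drawn from a three-layer Bernoulli model —

  - *chemotype bits*: a group-wide set of positions at elevated rate for
    every compound in the group's chemical space (actives, inactives and
    decoys). This is the shared "chemistry" that dominates Tanimoto
    similarity without carrying any activity label.
  - *signature bits*: per-target positions expressed at rate ``signal``
    by that target's actives and at a reduced rate by its decoys and
    inactives. Targets of one group draw a configurable fraction
    (``overlap``) of their signature from a shared group pool, which is
    what lets leave-one-protein-out generalization succeed.
  - *background*: everything else, at ``background_rate``.

  The decoy chemotype rate is solved in closed form so that the expected
  Tanimoto of N pairs equals that of S pairs: the Tanimoto baseline is
  then close to chance while the positional signal remains learnable.
  When ``signal == background_rate`` the solution collapses to decoys
  being statistically identical to actives (the no-leakage control).
  Per-compound property vectors are sampled directly (non-chemical) with
  decoy-pool members sampled inside the six matching windows of an
  active, so decoy selection is always feasible.

* **smiles mode**: compounds are assembled from a bundled fragment
  grammar (scaffold x substituent), parsed with RDKit, with all
  fingerprints and properties computed by :mod:`bsikit.chem`. This tier
  exercises the scaffold / Butina / physicochemical stages on real
  structures.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import canonicalize, morgan_fp, physchem
from .pairs import FingerprintSet

logger = logging.getLogger("bsikit.synthetic")

__all__ = [
    "UniverseConfig",
    "SyntheticUniverse",
    "generate_universe",
    "bayes_oracle_score",
    "generate_vs_library",
    "export_tables",
    "load_universe",
    "decoy_chemotype_rate",
]

PROPERTY_COLUMNS = ["mw", "logp", "rot_bonds", "hba", "hbd", "net_charge"]


@dataclass(frozen=True)
class UniverseConfig:
    n_groups: int = 1
    targets_per_group: int = 8
    actives_per_target: int = 60
    inactives_per_target: int = 10
    pool_per_active: int = 20
    n_bits: int = 256
    signature_bits: int = 24
    signal: float = 0.70
    background_rate: float = 0.08
    chemotype_bits: int = 96
    chemotype_rate: float = 0.28
    chemotype_pool_bits: int = 128
    signature_pool_bits: int = 64
    overlap: float = 0.5
    decoy_signature_factor: float = 0.6
    mode: str = "fingerprint"  # or "smiles"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fingerprint", "smiles"):
            raise ValueError(f"unknown mode {self.mode!r}")
        counts = (self.n_groups, self.targets_per_group, self.actives_per_target,
                  self.inactives_per_target, self.pool_per_active)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.signal < self.background_rate:
            raise ValueError("signal must be >= background_rate")
        if self.signature_bits + self.chemotype_bits >= self.n_bits:
            raise ValueError("signature + chemotype bits must leave background room")
        if self.chemotype_pool_bits + self.signature_pool_bits >= self.n_bits:
            raise ValueError("bit pools must leave background room")
        if self.chemotype_bits > self.chemotype_pool_bits:
            raise ValueError("chemotype_bits exceeds chemotype_pool_bits")
        if 2 * self.signature_bits > self.signature_pool_bits:
            raise ValueError("signature_pool_bits must be at least 2x signature_bits")
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("overlap must lie in [0, 1]")


@dataclass
class SyntheticUniverse:
    config: UniverseConfig
    compounds: pd.DataFrame        # compound_id, smiles
    activities: pd.DataFrame       # compound_id, target_id, group_id, pchembl, comment
    properties: pd.DataFrame       # compound_id + six matching properties
    fingerprints: FingerprintSet   # encoding-width fingerprints (256-bit)
    fingerprints_tc: FingerprintSet  # fingerprints used for TC filters
    pool_by_target: Dict[str, List[str]]
    # ground truth, used only by oracles and diagnostics:
    signatures: Dict[str, np.ndarray] = field(default_factory=dict)
    chemotypes: Dict[str, np.ndarray] = field(default_factory=dict)
    group_of_target: Dict[str, str] = field(default_factory=dict)
    matched_active: Dict[str, str] = field(default_factory=dict)

    @property
    def targets(self) -> List[str]:
        return sorted(self.group_of_target)

    def actives_of(self, target_id: str) -> List[str]:
        sub = self.activities
        mask = (sub["target_id"] == target_id) & (sub["pchembl"] > 6.5)
        return sorted(sub.loc[mask, "compound_id"])


def decoy_chemotype_rate(config: UniverseConfig) -> Tuple[float, float]:
    """Closed-form decoy rates matching N-pair Tanimoto to S-pair Tanimoto.

    Returns ``(chemotype_rate_decoy, signature_rate_decoy)``. The
    signature rate interpolates between background and signal with
    ``decoy_signature_factor``; the chemotype rate solves the linear
    equation E[TC(active, decoy)] = E[TC(active, active')] under the
    generative model (clipped to [background_rate, 1]).
    """
    n, k, C = config.n_bits, config.signature_bits, config.chemotype_bits
    beta, s, ca = config.background_rate, config.signal, config.chemotype_rate
    q = beta + config.decoy_signature_factor * (s - beta)
    R = n - C - k
    pop_a = C * ca + k * s + R * beta
    i_s = C * ca ** 2 + k * s ** 2 + R * beta ** 2
    tau = i_s / (2 * pop_a - i_s)
    T = tau / (1 + tau)
    denom = C * (ca - T)
    if denom <= 0:
        return 1.0, q
    cd = (T * (pop_a + k * q + R * beta) - k * s * q - R * beta ** 2) / denom
    return float(np.clip(cd, beta, 1.0)), float(q)


def _sample_bits(rng: np.random.Generator, rates: np.ndarray) -> np.ndarray:
    bits = (rng.random(rates.shape[0]) < rates).astype(np.uint8)
    if bits.sum() == 0:
        bits[int(np.argmax(rates))] = 1
    return bits


def _sample_active_properties(rng: np.random.Generator) -> np.ndarray:
    return np.array([
        rng.uniform(250.0, 500.0),
        rng.uniform(0.0, 5.0),
        rng.integers(0, 11),
        rng.integers(0, 11),
        rng.integers(0, 6),
        rng.choice([-1, 0, 1], p=[0.15, 0.7, 0.15]),
    ], dtype=float)


def _sample_matched_properties(rng: np.random.Generator, anchor: np.ndarray) -> np.ndarray:
    """Sample a property vector inside all six windows of ``anchor``."""
    return np.array([
        rng.uniform(anchor[0] - 25.0, anchor[0] + 25.0),
        rng.uniform(anchor[1] - 1.0, anchor[1] + 1.0),
        max(0, int(anchor[2]) + int(rng.integers(-2, 3))),
        max(0, int(anchor[3]) + int(rng.integers(-1, 2))),
        max(0, int(anchor[4]) + int(rng.integers(-1, 2))),
        anchor[5],
    ], dtype=float)


def generate_universe(config: UniverseConfig) -> SyntheticUniverse:
    """Deterministically generate a universe from its config and seed."""
    if config.mode == "smiles":
        return _generate_smiles_universe(config)
    return _generate_fingerprint_universe(config)


def _generate_fingerprint_universe(config: UniverseConfig) -> SyntheticUniverse:
    rng = np.random.default_rng(config.seed)
    n = config.n_bits
    cd, q = decoy_chemotype_rate(config)

    compounds: List[Tuple[str, str]] = []
    activity_rows: List[dict] = []
    prop_rows: List[dict] = []
    fp_rows: Dict[str, np.ndarray] = {}
    signatures: Dict[str, np.ndarray] = {}
    chemotypes: Dict[str, np.ndarray] = {}
    group_of_target: Dict[str, str] = {}
    pool_by_target: Dict[str, List[str]] = {}
    matched_active: Dict[str, str] = {}

    def add_compound(cid: str, rates: np.ndarray, props: np.ndarray) -> None:
        compounds.append((cid, ""))
        fp_rows[cid] = _sample_bits(rng, rates)
        prop_rows.append({"compound_id": cid,
                          **dict(zip(PROPERTY_COLUMNS, props))})

    # Universe-level bit pools: every group draws its chemotype bits from a
    # shared chemotype pool and its signature bits from a shared signature
    # pool.  Bit positions therefore keep a consistent meaning across protein
    # groups (as substructure bits do in real fingerprints), which is what
    # makes a model pretrained on some groups transferable to a new group.
    all_bits = rng.permutation(n)
    chemo_pool = np.sort(all_bits[: config.chemotype_pool_bits])
    sig_pool = np.sort(all_bits[config.chemotype_pool_bits:
                                config.chemotype_pool_bits + config.signature_pool_bits])

    for g in range(config.n_groups):
        group_id = f"GRP{g:02d}"
        chemo = rng.choice(chemo_pool, size=config.chemotype_bits, replace=False)
        chemotypes[group_id] = np.sort(chemo)
        k_shared = int(round(config.overlap * config.signature_bits))
        group_pool = rng.choice(sig_pool, size=config.signature_bits, replace=False)
        remaining = np.setdiff1d(sig_pool, group_pool)
        for t in range(config.targets_per_group):
            target_id = f"{group_id}_T{t:02d}"
            group_of_target[target_id] = group_id
            shared = rng.choice(group_pool, size=k_shared, replace=False)
            private = rng.choice(remaining, size=config.signature_bits - k_shared,
                                 replace=False)
            sig = np.sort(np.concatenate([shared, private]))
            signatures[target_id] = sig

            active_rates = np.full(n, config.background_rate)
            active_rates[chemo] = config.chemotype_rate
            active_rates[sig] = config.signal
            decoy_rates = np.full(n, config.background_rate)
            decoy_rates[chemo] = cd
            decoy_rates[sig] = q

            active_props = []
            for i in range(config.actives_per_target):
                cid = f"{target_id}_A{i:03d}"
                props = _sample_active_properties(rng)
                active_props.append((cid, props))
                add_compound(cid, active_rates, props)
                activity_rows.append({
                    "compound_id": cid, "target_id": target_id,
                    "group_id": group_id,
                    "pchembl": round(float(rng.uniform(6.6, 9.5)), 2),
                    "comment": "",
                })
            for i in range(config.inactives_per_target):
                cid = f"{target_id}_I{i:03d}"
                anchor_id, anchor = active_props[int(rng.integers(len(active_props)))]
                add_compound(cid, decoy_rates, _sample_matched_properties(rng, anchor))
                matched_active[cid] = anchor_id
                if i % 2 == 0:
                    activity_rows.append({
                        "compound_id": cid, "target_id": target_id,
                        "group_id": group_id,
                        "pchembl": round(float(rng.uniform(3.0, 4.4)), 2),
                        "comment": "",
                    })
                else:
                    activity_rows.append({
                        "compound_id": cid, "target_id": target_id,
                        "group_id": group_id, "pchembl": np.nan,
                        "comment": "inactive",
                    })
            shard: List[str] = []
            for ai, (anchor_id, anchor) in enumerate(active_props):
                for j in range(config.pool_per_active):
                    cid = f"{target_id}_D{ai:03d}_{j:03d}"
                    add_compound(cid, decoy_rates,
                                 _sample_matched_properties(rng, anchor))
                    matched_active[cid] = anchor_id
                    shard.append(cid)
            pool_by_target[target_id] = shard

    ids = [cid for cid, _ in compounds]
    fps = FingerprintSet(ids, np.stack([fp_rows[c] for c in ids]),
                         kind="morgan", radius=2)
    return SyntheticUniverse(
        config=config,
        compounds=pd.DataFrame(compounds, columns=["compound_id", "smiles"]),
        activities=pd.DataFrame(activity_rows),
        properties=pd.DataFrame(prop_rows),
        fingerprints=fps,
        fingerprints_tc=fps,
        pool_by_target=pool_by_target,
        signatures=signatures,
        chemotypes=chemotypes,
        group_of_target=group_of_target,
        matched_active=matched_active,
    )


# ---------------------------------------------------------------------------
# smiles mode


def _load_grammar() -> Tuple[List[str], List[str]]:
    text = (importlib.resources.files("bsikit") / "data" / "fragment_grammar.txt").read_text()
    scaffolds, subs = [], []
    section = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line == "[scaffolds]":
            section = scaffolds
        elif line == "[substituents]":
            section = subs
        elif section is not None:
            section.append(line)
    return scaffolds, subs


def _generate_smiles_universe(config: UniverseConfig) -> SyntheticUniverse:
    rng = np.random.default_rng(config.seed)
    scaffolds, subs = _load_grammar()
    combos: List[str] = []
    for sc in scaffolds:
        for su in subs:
            combos.append(sc.replace("{R}", su))
    records = []
    for i, smi in enumerate(combos):
        rec = canonicalize(smi, compound_id=f"SYN{i:05d}")
        if rec.parse_ok:
            records.append(rec)
        else:
            logger.warning("grammar produced unparsable SMILES: %s", smi)
    # deduplicate by canonical form, deterministic order
    seen: Dict[str, object] = {}
    for rec in records:
        seen.setdefault(rec.smiles, rec)
    records = sorted(seen.values(), key=lambda r: r.compound_id)

    need = config.n_groups * config.targets_per_group * (
        config.actives_per_target + config.inactives_per_target
    )
    if need > len(records):
        raise ValueError(
            f"smiles-mode universe needs {need} compounds, grammar yields {len(records)}"
        )
    order = rng.permutation(len(records))
    cursor = 0

    compounds, activity_rows, prop_rows = [], [], []
    fp256: Dict[str, np.ndarray] = {}
    fp_tc: Dict[str, np.ndarray] = {}
    group_of_target: Dict[str, str] = {}
    pool_by_target: Dict[str, List[str]] = {}

    def register(rec) -> str:
        nonlocal cursor
        compounds.append((rec.compound_id, rec.smiles))
        fp256[rec.compound_id] = morgan_fp(rec, radius=2, n_bits=256).bits
        fp_tc[rec.compound_id] = morgan_fp(rec, radius=2, n_bits=2048).bits
        pv = physchem(rec)
        prop_rows.append({"compound_id": rec.compound_id,
                          **dict(zip(PROPERTY_COLUMNS, pv.as_array()))})
        return rec.compound_id

    for g in range(config.n_groups):
        group_id = f"GRP{g:02d}"
        for t in range(config.targets_per_group):
            target_id = f"{group_id}_T{t:02d}"
            group_of_target[target_id] = group_id
            for _ in range(config.actives_per_target):
                rec = records[order[cursor]]; cursor += 1
                cid = register(rec)
                activity_rows.append({
                    "compound_id": cid, "target_id": target_id,
                    "group_id": group_id,
                    "pchembl": round(float(rng.uniform(6.6, 9.5)), 2),
                    "comment": "",
                })
            for i in range(config.inactives_per_target):
                rec = records[order[cursor]]; cursor += 1
                cid = register(rec)
                activity_rows.append({
                    "compound_id": cid, "target_id": target_id,
                    "group_id": group_id,
                    "pchembl": round(float(rng.uniform(3.0, 4.4)), 2) if i % 2 == 0 else np.nan,
                    "comment": "" if i % 2 == 0 else "inactive",
                })
    # remaining compounds form one global decoy candidate pool
    pool_ids = []
    for idx in order[cursor:]:
        pool_ids.append(register(records[idx]))
    for target_id in group_of_target:
        pool_by_target[target_id] = pool_ids

    ids = [cid for cid, _ in compounds]
    return SyntheticUniverse(
        config=config,
        compounds=pd.DataFrame(compounds, columns=["compound_id", "smiles"]),
        activities=pd.DataFrame(activity_rows),
        properties=pd.DataFrame(prop_rows),
        fingerprints=FingerprintSet(ids, np.stack([fp256[c] for c in ids]),
                                    kind="morgan", radius=2),
        fingerprints_tc=FingerprintSet(ids, np.stack([fp_tc[c] for c in ids]),
                                       kind="morgan", radius=2),
        pool_by_target=pool_by_target,
        group_of_target=group_of_target,
    )


# ---------------------------------------------------------------------------
# oracles


def _rate_vectors(universe: SyntheticUniverse, target_id: str) -> Tuple[np.ndarray, np.ndarray]:
    cfg = universe.config
    if cfg.mode != "fingerprint":
        raise ValueError("the Bayes oracle is defined for fingerprint mode only")
    cd, q = decoy_chemotype_rate(cfg)
    chemo = universe.chemotypes[universe.group_of_target[target_id]]
    sig = universe.signatures[target_id]
    pa = np.full(cfg.n_bits, cfg.background_rate)
    pa[chemo] = cfg.chemotype_rate
    pa[sig] = cfg.signal
    pd_ = np.full(cfg.n_bits, cfg.background_rate)
    pd_[chemo] = cd
    pd_[sig] = q
    return pa, pd_


def bayes_oracle_score(universe: SyntheticUniverse, id_a: str, id_b: str,
                       target_id: str) -> float:
    """Log-likelihood ratio of S versus N under the known generative model.

    The optimal score for distinguishing "both members drawn from the
    target's active distribution" from "one active, one decoy/inactive"
    (averaged over which member is the active); it upper-bounds the AUC
    any learned model can reach in expectation.
    """
    pa, pdk = _rate_vectors(universe, target_id)
    x = universe.fingerprints.rows([id_a])[0].astype(float)
    y = universe.fingerprints.rows([id_b])[0].astype(float)

    def bern(p: np.ndarray, v: np.ndarray) -> np.ndarray:
        return np.where(v > 0, p, 1.0 - p)

    ps = bern(pa, x) * bern(pa, y)
    pn = 0.5 * (bern(pa, x) * bern(pdk, y) + bern(pdk, x) * bern(pa, y))
    eps = 1e-12
    return float(np.sum(np.log(ps + eps) - np.log(pn + eps)))


def generate_vs_library(
    universe: SyntheticUniverse,
    target_id: str,
    n_actives: int = 10,
    n_decoys: int = 1500,
    seed: int = 0,
    tc_max: float = 0.3,
) -> Tuple[FingerprintSet, List[str], List[str]]:
    """Fresh screening library for one target: actives plus bulk decoys.

    Compounds are drawn from the target's generative distributions (so
    they are new, unseen molecules); every decoy must stay below
    ``tc_max`` Tanimoto against every library active, mirroring the
    screening validation setup (10 actives + 1,500 decoys by default).
    """
    rng = np.random.default_rng(seed)
    pa, pdk = _rate_vectors(universe, target_id)
    active_ids, rows = [], []
    for i in range(n_actives):
        cid = f"VS_{target_id}_A{i:03d}"
        active_ids.append(cid)
        rows.append(_sample_bits(rng, pa))
    A = np.stack(rows)
    decoy_ids, decoy_rows = [], []
    attempts = 0
    while len(decoy_ids) < n_decoys:
        attempts += 1
        if attempts > 50 * n_decoys:
            raise RuntimeError("cannot satisfy the decoy TC ceiling")
        bits = _sample_bits(rng, pdk)
        from .chem import tanimoto_matrix
        if tanimoto_matrix(bits[None, :], A).max() < tc_max:
            decoy_ids.append(f"VS_{target_id}_D{len(decoy_ids):04d}")
            decoy_rows.append(bits)
    fps = FingerprintSet(active_ids + decoy_ids, np.stack(rows + decoy_rows),
                         kind="morgan", radius=2)
    return fps, active_ids, decoy_ids


# ---------------------------------------------------------------------------
# table export / import


def export_tables(universe: SyntheticUniverse, out_dir: str) -> Dict[str, str]:
    """Write the universe as delimited-text tables plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": str(out / "compounds.csv"),
        "activities": str(out / "activities.csv"),
        "properties": str(out / "properties.csv"),
        "fingerprints": str(out / "fingerprints.tsv"),
        "meta": str(out / "universe.json"),
    }
    universe.compounds.to_csv(paths["compounds"], index=False)
    universe.activities.to_csv(paths["activities"], index=False)
    universe.properties.to_csv(paths["properties"], index=False)
    with open(paths["fingerprints"], "w") as fh:
        fh.write("compound_id\tbits\n")
        for cid in universe.fingerprints.ids:
            bits = "".join(map(str, universe.fingerprints.rows([cid])[0]))
            fh.write(f"{cid}\t{bits}\n")
    meta = {
        "config": asdict(universe.config),
        "pool_by_target": universe.pool_by_target,
        "group_of_target": universe.group_of_target,
        "signatures": {t: s.tolist() for t, s in universe.signatures.items()},
        "chemotypes": {g: c.tolist() for g, c in universe.chemotypes.items()},
        "matched_active": universe.matched_active,
    }
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=1)
    return paths


def load_universe(in_dir: str) -> SyntheticUniverse:
    """Re-import a universe written by :func:`export_tables` losslessly."""
    src = Path(in_dir)
    with open(src / "universe.json") as fh:
        meta = json.load(fh)
    config = UniverseConfig(**meta["config"])
    compounds = pd.read_csv(src / "compounds.csv", keep_default_na=False)
    activities = pd.read_csv(src / "activities.csv", keep_default_na=False,
                             na_values={"pchembl": [""]})
    properties = pd.read_csv(src / "properties.csv")
    ids, rows = [], []
    with open(src / "fingerprints.tsv") as fh:
        next(fh)
        for line in fh:
            cid, bits = line.rstrip("\n").split("\t")
            ids.append(cid)
            rows.append(np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0"))
    fps = FingerprintSet(ids, np.stack(rows), kind="morgan", radius=2)
    return SyntheticUniverse(
        config=config,
        compounds=compounds,
        activities=activities,
        properties=properties,
        fingerprints=fps,
        fingerprints_tc=fps,
        pool_by_target=meta["pool_by_target"],
        signatures={t: np.array(v) for t, v in meta["signatures"].items()},
        chemotypes={g: np.array(v) for g, v in meta["chemotypes"].items()},
        group_of_target=meta["group_of_target"],
        matched_active=meta["matched_active"],
    )
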