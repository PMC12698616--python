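"""Table readers/writers, run configuration, and the hyperparameter grid.

Input tables are delimited text (comma or tab, auto-detected from the
header line) with a header row:

* compound table: ``compound_id,smiles``
* activity table: ``compound_id,target_id,group_id,pchembl,comment``
  (``pchembl`` and ``comment`` may be empty, not both)
* embedding table: tab-delimited ``compound_id`` followed by numeric
  columns; all rows must share one dimension.

Row-level problems (unparsable SMILES, bad numbers) are collected with
their line numbers and logged; structural problems (missing required
column, duplicate compound id) raise immediately.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .chem import CompoundRecord, canonicalize
from .model import ModelConfig
from .pairs import ActivityRecord

logger = logging.getLogger("bsikit.io")

__all__ = [
    "RunConfig",
    "RunManifest",
    "read_compounds",
    "read_activities",
    "read_embeddings",
    "write_compounds",
    "write_activities",
    "write_embeddings",
    "enumerate_grid",
]


def _sniff_delimiter(header: str) -> str:
    if "\t" in header:
        return "\t"
    return ","


def _open_table(path: str, required: Sequence[str]) -> Tuple[List[dict], str]:
    p = Path(path)
    with open(p, newline="") as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        cols = reader.fieldnames or []
        for col in required:
            if col not in cols:
                raise ValueError(f"{path}: missing required column {col!r}")
        rows = list(reader)
    return rows, delim


def read_compounds(path: str, strict: bool = False) -> List[CompoundRecord]:
    """Read and canonicalize a compound table.

    Unparsable SMILES are dropped with a logged warning (the record
    count difference appears in the run manifest); with ``strict`` they
    abort the run instead.
    """
    rows, _ = _open_table(path, ["compound_id", "smiles"])
    records: List[CompoundRecord] = []
    seen: Dict[str, int] = {}
    bad: List[int] = []
    for lineno, row in enumerate(rows, start=2):
        cid = row["compound_id"].strip()
        if cid in seen:
            raise ValueError(
                f"{path}:{lineno}: duplicate compound_id {cid!r} (first at line {seen[cid]})"
            )
        seen[cid] = lineno
        rec = canonicalize(row["smiles"].strip() or "-", compound_id=cid) \
            if row["smiles"].strip() else CompoundRecord(cid, "", False)
        if not rec.parse_ok:
            bad.append(lineno)
            if strict:
                raise ValueError(f"{path}:{lineno}: unparsable SMILES for {cid!r}")
            continue
        records.append(rec)
    if bad:
        logger.warning("%s: dropped %d unparsable SMILES (lines %s%s)",
                       path, len(bad), bad[:10], "..." if len(bad) > 10 else "")
    return records


def read_activities(path: str) -> List[ActivityRecord]:
    rows, _ = _open_table(
        path, ["compound_id", "target_id", "group_id", "pchembl", "comment"]
    )
    records: List[ActivityRecord] = []
    errors: List[str] = []
    for lineno, row in enumerate(rows, start=2):
        raw = row["pchembl"].strip() if row["pchembl"] else ""
        pchembl: Optional[float] = None
        if raw:
            try:
                pchembl = float(raw)
            except ValueError:
                errors.append(f"line {lineno}: bad pchembl {raw!r}")
                continue
        try:
            records.append(ActivityRecord(
                compound_id=row["compound_id"].strip(),
                target_id=row["target_id"].strip(),
                group_id=row["group_id"].strip(),
                pchembl=pchembl,
                comment=(row["comment"] or "").strip() or None,
            ))
        except ValueError as e:
            errors.append(f"line {lineno}: {e}")
    if errors:
        logger.warning("%s: %d bad activity rows: %s", path, len(errors), errors[:5])
    return records


def read_embeddings(path: str) -> Dict[str, np.ndarray]:
    """Tab-delimited embedding table; all rows must share one dimension."""
    rows, delim = _open_table(path, ["compound_id"])
    out: Dict[str, np.ndarray] = {}
    dim: Optional[int] = None
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delim)
        value_cols = [c for c in header if c != "compound_id"]
    for lineno, row in enumerate(rows, start=2):
        cid = row["compound_id"].strip()
        if cid in out:
            raise ValueError(f"{path}:{lineno}: duplicate compound_id {cid!r}")
        vec = np.array([float(row[c]) for c in value_cols], dtype=float)
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(f"{path}:{lineno}: embedding dimension mismatch")
        out[cid] = vec
    return out


def write_compounds(records: Sequence[CompoundRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "smiles"])
        for rec in records:
            w.writerow([rec.compound_id, rec.smiles])


def write_activities(records: Sequence[ActivityRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "group_id", "pchembl", "comment"])
        for r in records:
            w.writerow([r.compound_id, r.target_id, r.group_id,
                        "" if r.pchembl is None else r.pchembl, r.comment or ""])


def write_embeddings(embeddings: Dict[str, np.ndarray], path: str) -> None:
    ids = sorted(embeddings)
    dim = embeddings[ids[0]].size
    with open(path, "w") as fh:
        fh.write("compound_id\t" + "\t".join(f"e{i}" for i in range(dim)) + "\n")
        for cid in ids:
            fh.write(cid + "\t" + "\t".join(f"{v:.8g}" for v in embeddings[cid]) + "\n")


# ---------------------------------------------------------------------------
# run configuration and manifest


@dataclass
class RunConfig:
    """Effective configuration of a workflow run; echoed into outputs."""

    compounds_path: Optional[str] = None
    activities_path: Optional[str] = None
    embeddings_path: Optional[str] = None
    out_dir: str = "bsikit_out"
    fp_radius: int = 2
    fp_bits_encoding: int = 256
    fp_bits_tc: int = 2048
    regime: str = "slight"
    tc_pair_max: float = 0.4
    tc_decoy_max: float = 0.3
    decoys_per_active: int = 10
    active_cap: int = 100
    butina_tc: float = 0.4
    top_frac: float = 0.02
    purge: bool = True
    seed: int = 0
    model: dict = field(default_factory=lambda: ModelConfig().to_dict())

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def model_config(self, **overrides) -> ModelConfig:
        d = dict(self.model)
        d.update(overrides)
        return ModelConfig.from_dict(d)


@dataclass
class RunManifest:
    """Record counts at each filtering stage plus collected warnings."""

    input_hashes: Dict[str, str] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    version: str = "0.1.0"

    def add_input(self, name: str, path: str) -> None:
        h = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.input_hashes[name] = h

    def count(self, stage: str, value: int) -> None:
        self.counts[stage] = int(value)

    def warn(self, message: str) -> None:
        logger.warning(message)
        self.warnings.append(message)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


def enumerate_grid(
    architectures: Sequence[Sequence[int]],
    dropouts: Sequence[float],
    epoch_settings: Sequence[int],
    base: Optional[ModelConfig] = None,
) -> List[ModelConfig]:
    """Cartesian product of the three tuning axes in deterministic order.

    Duplicate settings within one axis are removed with a warning. The
    standard tuning grid — three architectures ([256], [256,128],
    [256,128,64]), three dropouts (0.1, 0.25, 0.5) and three epoch counts
    (5, 10, 15) — yields 27 configurations.
    """
    def dedup(seq, name):
        seen, out = set(), []
        for item in seq:
            key = tuple(item) if isinstance(item, (list, tuple)) else item
            if key in seen:
                logger.warning("duplicate %s setting %r removed from grid", name, item)
                continue
            seen.add(key)
            out.append(item)
        return out

    base = base or ModelConfig()
    archs = dedup(architectures, "architecture")
    drops = dedup(dropouts, "dropout")
    epochs = dedup(epoch_settings, "epochs")
    configs = []
    for arch, dr, ep in product(archs, drops, epochs):
        configs.append(ModelConfig(
            hidden_sizes=tuple(arch), dropout=float(dr), epochs=int(ep),
            learning_rate=base.learning_rate, batch_size=base.batch_size,
            seed=base.seed, input_dim=base.input_dim,
        ))
    return configs
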