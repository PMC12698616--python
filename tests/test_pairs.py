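import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsikit.chem import canonicalize, morgan_fp
from bsikit.pairs import (ActivityRecord, CompoundPair, FingerprintSet,
                          PairDataset, TargetLigandSet, assemble_dataset,
                          build_pairs, butina_cluster, dedup_pairs,
                          distribution_match, diversity_cascade, encode_pair,
                          kmeans_cap, label_activity, label_activity_table,
                          scaffold_representatives, select_decoys)
from conftest import tanimoto_set_oracle


def rec(cid, tid="T1", gid="G1", pchembl=None, comment=None):
    return ActivityRecord(cid, tid, gid, pchembl, comment)


class TestLabeling:
    def test_thresholds(self):
        assert label_activity([rec("a", pchembl=6.6)]) == "active"
        assert label_activity([rec("a", pchembl=6.5)]) == "ambiguous"
        assert label_activity([rec("a", pchembl=4.5)]) == "ambiguous"
        assert label_activity([rec("a", pchembl=4.4)]) == "inactive"

    def test_median_aggregation(self):
        records = [rec("a", pchembl=v) for v in (7.0, 7.2, 4.0)]
        assert label_activity(records) == "active"  # median 7.0

    def test_inactive_comment(self):
        assert label_activity([rec("a", comment="inactive")]) == "inactive"
        assert label_activity([rec("a", comment="Not Active")]) == "inactive"

    def test_comment_overridden_by_active_median(self):
        records = [rec("a", pchembl=8.0), rec("a", comment="inactive")]
        assert label_activity(records) == "active"

    def test_record_requires_evidence(self):
        with pytest.raises(ValueError):
            ActivityRecord("a", "t", "g", None, None)

    def test_table_keys(self):
        table = label_activity_table([rec("a", "T1", pchembl=7.0),
                                      rec("a", "T2", pchembl=3.0)])
        assert table[("a", "T1")] == "active"
        assert table[("a", "T2")] == "inactive"


def brute_decoy_filter(active_props, active_fp, pool_props, pool_fps,
                       tc_max=0.3):
    """Independent re-implementation of the six windows + TC ceiling."""
    windows = [25.0, 1.0, 2.0, 1.0, 1.0]
    ok = []
    for i in range(pool_props.shape[0]):
        d = pool_props[i]
        if any(abs(d[j] - active_props[j]) > windows[j] for j in range(5)):
            continue
        if d[5] != active_props[5]:
            continue
        if pool_fps[i].sum() + active_fp.sum() > 0 and \
                tanimoto_set_oracle(active_fp, pool_fps[i]) >= tc_max:
            continue
        ok.append(i)
    return ok


class TestDecoys:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_selected_subset_of_brute_filter(self, seed):
        rng = np.random.default_rng(seed)
        n_pool = 60
        active_props = np.array([350.0, 2.5, 4, 3, 1, 0.0])
        pool_props = active_props + np.column_stack([
            rng.uniform(-40, 40, n_pool), rng.uniform(-2, 2, n_pool),
            rng.integers(-4, 5, n_pool), rng.integers(-2, 3, n_pool),
            rng.integers(-2, 3, n_pool), rng.choice([-1, 0, 1], n_pool)])
        active_fp = (rng.random(64) < 0.2).astype(np.uint8)
        active_fp[0] = 1
        pool_fps = (rng.random((n_pool, 64)) < 0.2).astype(np.uint8)
        pool_fps[:, 1] = 1
        pool_ids = [f"d{i}" for i in range(n_pool)]

        eligible = brute_decoy_filter(active_props, active_fp, pool_props, pool_fps)
        chosen = select_decoys("a0", active_props, active_fp, pool_ids,
                               pool_props, pool_fps, n=10, seed=seed)
        chosen_idx = [int(c[1:]) for c in chosen]
        assert set(chosen_idx) <= set(eligible)
        assert len(chosen) == min(10, len(eligible))
        assert chosen == sorted(chosen, key=lambda c: int(c[1:])) or chosen == sorted(chosen)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        props = np.array([300.0, 2.0, 3, 2, 1, 0.0])
        pool_props = np.tile(props, (30, 1))
        fp = np.zeros(32, dtype=np.uint8); fp[0] = 1
        pool_fps = np.zeros((30, 32), dtype=np.uint8); pool_fps[:, 1] = 1
        ids = [f"d{i:02d}" for i in range(30)]
        a = select_decoys("a", props, fp, ids, pool_props, pool_fps, 5, seed=7)
        b = select_decoys("a", props, fp, ids, pool_props, pool_fps, 5, seed=7)
        c = select_decoys("a", props, fp, ids, pool_props, pool_fps, 5, seed=8)
        assert a == b
        assert len(a) == 5 and a != c  # overwhelmingly likely for 30 choose 5


def brute_butina(ids, fps, thr=0.4):
    """Leader-algorithm oracle: descending neighbor count, id tiebreak."""
    n = len(ids)
    neigh = {i: {j for j in range(n) if j != i and
                 tanimoto_set_oracle(fps[i], fps[j]) >= thr}
             for i in range(n)}
    order = sorted(range(n), key=lambda i: (-len(neigh[i]), ids[i]))
    assigned = {}
    reps = []
    for i in order:
        if i in assigned:
            continue
        reps.append(ids[i])
        assigned[i] = ids[i]
        for j in neigh[i]:
            if j not in assigned:
                assigned[j] = ids[i]
    return {ids[i]: c for i, c in assigned.items()}, sorted(reps)


class TestClustering:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_butina_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        fps = (rng.random((n, 24)) < 0.35).astype(np.uint8)
        fps[:, 0] = 1
        ids = [f"c{i:02d}" for i in range(n)]
        assignment, reps = butina_cluster(ids, fps, tc_threshold=0.4)
        oracle_assign, oracle_reps = brute_butina(ids, fps)
        got_reps = sorted({assignment[i] if isinstance(assignment[i], str)
                           else reps[assignment[i]] for i in ids})
        assert sorted(reps) == oracle_reps
        # membership: each compound is within threshold of its leader or is a leader
        for cid in ids:
            leader = assignment[cid] if isinstance(assignment[cid], str) \
                else reps[assignment[cid]]
            i, j = ids.index(cid), ids.index(leader)
            if i != j:
                assert tanimoto_set_oracle(fps[i], fps[j]) >= 0.4

    def test_kmeans_cap_noop_when_small(self):
        rng = np.random.default_rng(1)
        fps = (rng.random((5, 16)) < 0.4).astype(np.uint8)
        ids = list("abcde")
        assert sorted(kmeans_cap(ids, fps, cap=10)) == ids

    def test_kmeans_cap_returns_members(self):
        rng = np.random.default_rng(2)
        fps = (rng.random((30, 16)) < 0.4).astype(np.uint8)
        ids = [f"m{i}" for i in range(30)]
        out = kmeans_cap(ids, fps, cap=8, seed=0)
        assert len(out) == 8
        assert set(out) <= set(ids)

    def test_scaffold_representatives(self):
        records = [canonicalize(s, f"c{i}") for i, s in enumerate(
            ["c1ccccc1CC", "c1ccccc1CCC", "C1CCCCC1O", "CCO"])]
        reps = scaffold_representatives(records)
        # two benzene-scaffold compounds collapse to the min-id one;
        # cyclohexane scaffold and the acyclic compound survive
        assert "c0" in reps and "c1" not in reps
        assert "c2" in reps and "c3" in reps

    def test_cascade_cap(self):
        rng = np.random.default_rng(3)
        n = 40
        fps = (rng.random((n, 64)) < 0.15).astype(np.uint8)
        fps[:, 0] = 1
        ids = [f"x{i:02d}" for i in range(n)]
        fs = FingerprintSet(ids, fps)
        out = diversity_cascade(ids, fs, cap=12, seed=0)
        assert len(out) <= 12
        assert set(out) <= set(ids)


class TestPairs:
    def _fps(self, seed=0, n=12, bits=64, rate=0.15):
        rng = np.random.default_rng(seed)
        M = (rng.random((n, bits)) < rate).astype(np.uint8)
        M[:, 0] = 1
        ids = [f"a{i}" for i in range(n // 2)] + [f"n{i}" for i in range(n - n // 2)]
        return FingerprintSet(ids, M)

    def test_build_pairs_counts_and_filter(self):
        fs = self._fps()
        actives = [i for i in fs.ids if i.startswith("a")]
        negs = [i for i in fs.ids if i.startswith("n")]
        ls = TargetLigandSet("T1", "G1", actives, decoys=negs)
        pairs = build_pairs(ls, fs, tc_max=0.4)
        for p in pairs:
            assert p.tc < 0.4
            assert p.label in ("S", "N")
        s_keys = {p.key for p in pairs if p.label == "S"}
        assert all(k[0].startswith("a") and k[1].startswith("a") for k in s_keys)

    def test_pair_canonical_order(self):
        p = CompoundPair("zz", "aa", "S", 0.1, "T")
        assert (p.id_a, p.id_b) == ("aa", "zz")

    def test_dedup_drops_duplicates_and_conflicts(self):
        mk = lambda a, b, lab, t: CompoundPair(a, b, lab, 0.1, t)
        pairs = [mk("a", "b", "S", "T1"), mk("b", "a", "S", "T2"),
                 mk("c", "d", "S", "T1"), mk("c", "d", "N", "T2"),
                 mk("e", "f", "N", "T1")]
        kept, n_dup, n_conflict = dedup_pairs(pairs)
        keys = {p.key for p in kept}
        assert ("a", "b") in keys and ("e", "f") in keys
        assert ("c", "d") not in keys
        assert n_dup == 1 and n_conflict == 1

    def test_encode_pair_values(self):
        a = morgan_fp(canonicalize("CCO"), n_bits=256)
        b = morgan_fp(canonicalize("CCN"), n_bits=256)
        enc = encode_pair(a, b)
        assert enc.vector.shape == (256,)
        assert set(np.unique(enc.vector)) <= {0, 1, 2}
        np.testing.assert_array_equal(
            enc.vector, a.bits.astype(int) + b.bits.astype(int))

    def test_encoding_symmetric(self):
        a = morgan_fp(canonicalize("c1ccccc1O"), n_bits=256)
        b = morgan_fp(canonicalize("CCCC"), n_bits=256)
        np.testing.assert_array_equal(encode_pair(a, b).vector,
                                      encode_pair(b, a).vector)


class TestAssemble:
    def _pairs(self, n_s, n_n):
        out = []
        for i in range(n_s):
            out.append(CompoundPair(f"s{i}", f"s{i}x", "S", 0.1, "T"))
        for i in range(n_n):
            out.append(CompoundPair(f"n{i}", f"n{i}x", "N", 0.1, "T"))
        return out

    def test_slight_regime_reference_example(self):
        ds = assemble_dataset(self._pairs(100, 1000), "slight", seed=0)
        labels = ds.labels
        assert (labels == 1).sum() == 100
        assert (labels == 0).sum() == 300
        assert ds.s_fraction == pytest.approx(0.25)

    def test_heavy_ratio(self):
        ds = assemble_dataset(self._pairs(10, 500), "heavy", seed=0)
        assert ds.s_fraction == pytest.approx(0.04)
        assert (ds.labels == 1).sum() == 10
        assert (ds.labels == 0).sum() == 240

    def test_excess_s_subsampled(self):
        ds = assemble_dataset(self._pairs(100, 60), "slight", seed=0)
        assert ds.s_fraction == pytest.approx(0.25)
        assert (ds.labels == 0).sum() == 60
        assert (ds.labels == 1).sum() == 20

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            assemble_dataset(self._pairs(0, 10), "slight")
        with pytest.raises(ValueError):
            assemble_dataset(self._pairs(10, 0), "slight")

    def test_unknown_regime_raises(self):
        with pytest.raises(ValueError):
            assemble_dataset(self._pairs(5, 20), "medium")

    def test_deterministic(self):
        a = assemble_dataset(self._pairs(50, 500), "slight", seed=3)
        b = assemble_dataset(self._pairs(50, 500), "slight", seed=3)
        assert [p.key for p in a.pairs] == [p.key for p in b.pairs]


class TestDistributionMatch:
    def test_identical_samples(self):
        x = np.linspace(0.01, 0.39, 200)
        rep = distribution_match(x, x)
        assert rep.ks_D == 0.0
        assert rep.jsd == pytest.approx(0.0, abs=1e-12)

    def test_ks_matches_ecdf_oracle(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 0.4, 150)
        b = rng.uniform(0.05, 0.4, 120)
        rep = distribution_match(a, b)
        # brute-force ECDF sup-difference
        grid = np.sort(np.concatenate([a, b]))
        d = max(abs((a <= g).mean() - (b <= g).mean()) for g in grid)
        assert rep.ks_D == pytest.approx(d, abs=1e-12)
        assert 0.0 <= rep.jsd <= 1.0
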