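import numpy as np
import pytest

from bsikit.chem import canonicalize, tanimoto_matrix
from bsikit.synthetic import (UniverseConfig, bayes_oracle_score,
                              decoy_chemotype_rate, export_tables,
                              generate_universe, generate_vs_library,
                              load_universe)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            UniverseConfig(mode="pictures")
        with pytest.raises(ValueError):
            UniverseConfig(actives_per_target=0)
        with pytest.raises(ValueError):
            UniverseConfig(signal=0.01, background_rate=0.08)
        with pytest.raises(ValueError):
            UniverseConfig(signature_bits=200, chemotype_bits=96)
        with pytest.raises(ValueError):
            UniverseConfig(chemotype_bits=200, chemotype_pool_bits=128)
        with pytest.raises(ValueError):
            UniverseConfig(overlap=1.5)

    def test_zero_signal_rates_collapse(self):
        cfg = UniverseConfig(signal=0.08, background_rate=0.08)
        cd, q = decoy_chemotype_rate(cfg)
        assert q == pytest.approx(cfg.background_rate)
        assert cd == pytest.approx(cfg.chemotype_rate, abs=1e-9)


class TestFingerprintUniverse:
    def test_counts_and_ids(self, small_universe):
        u = small_universe
        cfg = u.config
        n_targets = cfg.n_groups * cfg.targets_per_group
        per_target = (cfg.actives_per_target + cfg.inactives_per_target
                      + cfg.actives_per_target * cfg.pool_per_active)
        assert len(u.compounds) == n_targets * per_target
        assert len(u.targets) == n_targets
        assert all(len(u.actives_of(t)) == cfg.actives_per_target
                   for t in u.targets)

    def test_deterministic(self):
        cfg = UniverseConfig(targets_per_group=2, actives_per_target=8,
                             pool_per_active=5, seed=11)
        a = generate_universe(cfg)
        b = generate_universe(cfg)
        np.testing.assert_array_equal(a.fingerprints.matrix, b.fingerprints.matrix)
        assert a.compounds.equals(b.compounds)

    def test_seed_changes_output(self):
        base = dict(targets_per_group=2, actives_per_target=8, pool_per_active=5)
        a = generate_universe(UniverseConfig(seed=1, **base))
        b = generate_universe(UniverseConfig(seed=2, **base))
        assert not np.array_equal(a.fingerprints.matrix, b.fingerprints.matrix)

    def test_activity_values_in_bands(self, small_universe):
        acts = small_universe.activities
        active_rows = acts[acts.comment == ""]
        assert ((active_rows.pchembl > 6.5) | (active_rows.pchembl < 4.5)).all()

    def test_signature_and_chemotype_pools(self, small_universe):
        u = small_universe
        for gid, chemo in u.chemotypes.items():
            assert len(chemo) == u.config.chemotype_bits
        for tid, sig in u.signatures.items():
            assert len(sig) == u.config.signature_bits
            gid = u.group_of_target[tid]
            assert len(np.intersect1d(sig, u.chemotypes[gid])) == 0

    def test_s_pair_tc_invariant(self, small_universe):
        """Actives of one target: >= 95% of pairwise TCs below 0.4."""
        u = small_universe
        vals = []
        for t in u.targets:
            A = u.fingerprints.rows(u.actives_of(t))
            M = tanimoto_matrix(A, A)
            vals.extend(M[np.triu_indices(len(A), 1)])
        vals = np.array(vals)
        assert (vals < 0.4).mean() >= 0.95

    def test_active_decoy_tc_distributions_match(self, small_universe):
        """E[TC] of active-decoy pairs tracks active-active pairs."""
        u = small_universe
        s_vals, n_vals = [], []
        for t in u.targets:
            act = u.actives_of(t)
            A = u.fingerprints.rows(act)
            P = u.fingerprints.rows(u.pool_by_target[t][:300])
            s_vals.extend(tanimoto_matrix(A, A)[np.triu_indices(len(act), 1)])
            n_vals.extend(tanimoto_matrix(A, P).ravel())
        assert abs(np.mean(s_vals) - np.mean(n_vals)) < 0.03


class TestSmilesUniverse:
    def test_valid_unique_smiles(self, smiles_universe):
        u = smiles_universe
        smis = list(u.compounds.smiles)
        assert len(set(smis)) == len(smis)
        assert all(canonicalize(s).parse_ok for s in smis[:50])

    def test_fingerprint_widths(self, smiles_universe):
        assert smiles_universe.fingerprints.matrix.shape[1] == 256
        assert smiles_universe.fingerprints_tc.matrix.shape[1] == 2048


class TestOracle:
    def test_separates_s_from_n(self, small_universe):
        u = small_universe
        t = u.targets[0]
        act = u.actives_of(t)
        pool = u.pool_by_target[t]
        s_scores = [bayes_oracle_score(u, act[i], act[i + 1], t)
                    for i in range(0, 10, 2)]
        n_scores = [bayes_oracle_score(u, act[i], pool[i], t)
                    for i in range(5)]
        assert min(s_scores) > max(n_scores)

    def test_llr_matches_brute_force(self, small_universe):
        """Exact per-bit Bernoulli computation, re-derived independently."""
        u = small_universe
        cfg = u.config
        t = u.targets[0]
        cd, q = decoy_chemotype_rate(cfg)
        pa = np.full(cfg.n_bits, cfg.background_rate)
        pa[u.chemotypes[u.group_of_target[t]]] = cfg.chemotype_rate
        pa[u.signatures[t]] = cfg.signal
        pdk = np.full(cfg.n_bits, cfg.background_rate)
        pdk[u.chemotypes[u.group_of_target[t]]] = cd
        pdk[u.signatures[t]] = q
        a, b = u.actives_of(t)[:2]
        x = u.fingerprints.rows([a])[0]
        y = u.fingerprints.rows([b])[0]
        ls = ln = 0.0
        for i in range(cfg.n_bits):
            px = pa[i] if x[i] else 1 - pa[i]
            py = pa[i] if y[i] else 1 - pa[i]
            dx = pdk[i] if x[i] else 1 - pdk[i]
            dy = pdk[i] if y[i] else 1 - pdk[i]
            ls += np.log(px * py + 1e-12)
            ln += np.log(0.5 * (px * dy + dx * py) + 1e-12)
        assert bayes_oracle_score(u, a, b, t) == pytest.approx(ls - ln, abs=1e-8)

    def test_smiles_mode_unsupported(self, smiles_universe):
        u = smiles_universe
        t = u.targets[0]
        act = u.actives_of(t)
        with pytest.raises(ValueError):
            bayes_oracle_score(u, act[0], act[1], t)


class TestVsLibrary:
    def test_composition_and_tc_ceiling(self, small_universe):
        u = small_universe
        t = u.targets[0]
        lib, actives, decoys = generate_vs_library(u, t, n_actives=5,
                                                   n_decoys=100, seed=3)
        assert len(actives) == 5 and len(decoys) == 100
        assert len(lib.ids) == 105
        A = lib.rows(actives)
        D = lib.rows(decoys)
        assert tanimoto_matrix(D, A).max() < 0.3

    def test_deterministic(self, small_universe):
        u = small_universe
        t = u.targets[0]
        a = generate_vs_library(u, t, n_actives=3, n_decoys=20, seed=5)
        b = generate_vs_library(u, t, n_actives=3, n_decoys=20, seed=5)
        np.testing.assert_array_equal(a[0].matrix, b[0].matrix)


class TestRoundTrip:
    def test_fingerprint_mode_lossless(self, small_universe, tmp_path):
        u = small_universe
        export_tables(u, str(tmp_path))
        v = load_universe(str(tmp_path))
        assert v.config == u.config
        assert v.fingerprints.ids == u.fingerprints.ids
        np.testing.assert_array_equal(v.fingerprints.matrix, u.fingerprints.matrix)
        assert v.pool_by_target == u.pool_by_target
        assert v.matched_active == u.matched_active
        for t in u.signatures:
            np.testing.assert_array_equal(v.signatures[t], u.signatures[t])
        assert v.activities.equals(u.activities)
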