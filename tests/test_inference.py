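import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from biofilmnet.config import AnalysisConfig
from biofilmnet.inference import (mantel, mantel_matrix,
                                  pairwise_module_permanova, partial_mantel,
                                  permanova)
from tests.oracles import (oracle_mantel_exact, oracle_permanova,
                           oracle_permanova_exact_p)
from tests.test_preprocess import table_from


def rand_dm(n, rng, ids=None):
    d = squareform(pdist(rng.standard_normal((n, 3))))
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


class TestMantel:
    def test_self_comparison(self, rng):
        d = rand_dm(8, rng)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_r_matches_skbio(self, rng):
        from skbio.stats.distance import mantel as sk_mantel
        dx, dy = rand_dm(9, rng), rand_dm(9, rng)
        r_sk, _, _ = sk_mantel(dx, dy, method="spearman", permutations=0)
        res = mantel(dx, dy, n_perm=9, seed=0)
        assert res.r == pytest.approx(float(r_sk))

    def test_sampled_p_matches_exact_enumeration(self, rng):
        dx, dy = rand_dm(4, rng), rand_dm(4, rng)
        r_obs, p_exact = oracle_mantel_exact(dx.data, dy.data)
        res = mantel(dx, dy, n_perm=4999, seed=3)
        assert res.r == pytest.approx(r_obs)
        se = np.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(res.p - p_exact) < 4 * se + 2 / 5000

    def test_null_r_centered_at_zero(self, rng):
        rs = [mantel(rand_dm(10, rng), rand_dm(10, rng),
                     n_perm=49, seed=i).r for i in range(40)]
        assert abs(np.mean(rs)) < 0.12

    def test_p_floor(self, rng):
        d = rand_dm(8, rng)
        res = mantel(d, d, n_perm=999, seed=0)
        assert res.p >= 1 / 1000

    def test_alignment_by_shared_ids(self, rng):
        dx = rand_dm(8, rng)
        perm = list(rng.permutation(8))
        ids_sub = [dx.ids[i] for i in perm[:6]]
        dy_full = rand_dm(8, rng)
        res_sub = mantel(dx.filter(ids_sub), dy_full, n_perm=99, seed=1)
        assert res_sub.n_obs == 6

    def test_zero_variance_error(self):
        flat = DistanceMatrix(1 - np.eye(5), ids=list("abcde"))
        with pytest.raises(ValueError, match="zero variance"):
            mantel(flat, flat, n_perm=9, seed=0)


class TestPartialMantel:
    def test_reduces_to_mantel_when_dz_uncorrelated(self, rng):
        # with r_xz = r_yz = 0 the partial formula collapses to plain r;
        # verify the formula limit numerically on the observed statistic
        dx, dy, dz = rand_dm(7, rng), rand_dm(7, rng), rand_dm(7, rng)
        from scipy.stats import rankdata, spearmanr

        def tri(m):
            return m[np.triu_indices(7, 1)]

        r_xy = spearmanr(tri(dx.data), tri(dy.data))[0]
        r_xz = spearmanr(tri(dx.data), tri(dz.data))[0]
        r_yz = spearmanr(tri(dy.data), tri(dz.data))[0]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        res = partial_mantel(dx, dy, dz, n_perm=9, seed=0)
        assert res.r == pytest.approx(expected)

    def test_self_comparison_gives_one(self, rng):
        dx = rand_dm(7, rng)
        dz = rand_dm(7, rng)
        res = partial_mantel(dx, dx, dz, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_hand_set_triple(self):
        # 5 x 5 matrices built from 1-D coordinates; partial correlation
        # evaluated directly from the three triangle Spearman correlations
        def dm_from(coords):
            c = np.asarray(coords, dtype=float)[:, None]
            return DistanceMatrix(squareform(pdist(c)),
                                  ids=list("abcde"))

        dx = dm_from([0, 1, 2, 3, 4])
        dy = dm_from([0, 1.1, 1.9, 3.2, 3.9])
        dz = dm_from([0, 0.5, 2.5, 2.6, 5.0])
        from scipy.stats import spearmanr

        def tri(m):
            return m.data[np.triu_indices(5, 1)]

        r_xy = spearmanr(tri(dx), tri(dy))[0]
        r_xz = spearmanr(tri(dx), tri(dz))[0]
        r_yz = spearmanr(tri(dy), tri(dz))[0]
        expected = (r_xy - r_xz * r_yz) / np.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2))
        res = partial_mantel(dx, dy, dz, n_perm=99, seed=0)
        assert res.r == pytest.approx(expected)


class TestMantelMatrix:
    def test_identical_matrices_significant(self, rng):
        d = rand_dm(9, rng)
        d2 = DistanceMatrix(d.data.copy(), ids=list(d.ids))
        out = mantel_matrix({"x": d, "y": d2}, n_perm=199, seed=0)
        assert len(out) == 1
        assert out.r.iloc[0] == pytest.approx(1.0)
        assert bool(out.significant.iloc[0])

    def test_pair_count(self, rng):
        mats = {f"m{i}": rand_dm(8, rng) for i in range(4)}
        out = mantel_matrix(mats, n_perm=9, seed=0)
        assert len(out) == 6

    def test_mask_does_not_change_r(self, rng):
        mats = {f"m{i}": rand_dm(8, rng) for i in range(3)}
        a = mantel_matrix(mats, n_perm=99, seed=5, alpha=0.05)
        b = mantel_matrix(mats, n_perm=99, seed=5, alpha=0.5)
        np.testing.assert_allclose(a.r, b.r)
        np.testing.assert_allclose(a.p, b.p)


class TestPermanova:
    def test_perfect_separation(self):
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        dm = DistanceMatrix(d, ids=list("abcdef"))
        res = permanova(dm, ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_f_r2_match_direct_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 12))
            dm = rand_dm(n, rng)
            labels = np.array(["a", "b", "c"])[rng.integers(0, 3, n)]
            if min(np.bincount(pd.factorize(labels)[0])) < 2:
                continue
            res = permanova(dm, labels, n_perm=9, seed=0)
            f, r2 = oracle_permanova(dm.data, labels)
            assert res.f == pytest.approx(f, abs=1e-10)
            assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_f_matches_skbio(self, rng):
        from skbio.stats.distance import permanova as sk_permanova
        dm = rand_dm(10, rng)
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(dm, labels, n_perm=9, seed=0)
        sk = sk_permanova(dm, grouping=labels, permutations=0)
        assert res.f == pytest.approx(float(sk["test statistic"]), abs=1e-10)

    def test_sampled_p_matches_exact_enumeration(self, rng):
        dm = rand_dm(6, rng)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        p_exact = oracle_permanova_exact_p(dm.data, labels)
        res = permanova(dm, labels, n_perm=4999, seed=11)
        se = np.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(res.p - p_exact) < 4 * se + 2 / 5000

    def test_null_p_spread(self, rng):
        ps = [permanova(rand_dm(9, rng), ["a"] * 4 + ["b"] * 5,
                        n_perm=99, seed=i).p for i in range(40)]
        assert 0.25 < np.mean(ps) < 0.75

    def test_singleton_group_error(self, rng):
        with pytest.raises(ValueError, match="singleton"):
            permanova(rand_dm(5, rng), ["a"] * 4 + ["b"], n_perm=9, seed=0)


class TestPairwiseModulePermanova:
    def planted_table(self, rng):
        # two modules with disjoint sample support -> near-perfect separation
        arr = np.zeros((40, 10))
        arr[:20, :5] = rng.uniform(5, 10, (20, 5))
        arr[20:, 5:] = rng.uniform(5, 10, (20, 5))
        t = table_from(arr)
        from biofilmnet.modules import ModulePartition
        assignment = {f"o{i}": (0 if i < 20 else 1) for i in range(40)}
        return t, ModulePartition(assignment=assignment, q=0.6)

    def test_planted_disjoint_modules(self, rng):
        t, part = self.planted_table(rng)
        cfg = AnalysisConfig(n_permutations=199, rng_seed=4)
        out = pairwise_module_permanova(t, part, cfg)
        assert len(out) == 1
        assert out.R2.iloc[0] > 0.5
        assert out.p.iloc[0] == pytest.approx(1 / 200)

    def test_pair_count_with_three_major_modules(self, rng):
        arr = rng.uniform(1, 10, (60, 8))
        t = table_from(arr)
        from biofilmnet.modules import ModulePartition
        assignment = {f"o{i}": i // 20 for i in range(60)}
        part = ModulePartition(assignment=assignment, q=0.5)
        cfg = AnalysisConfig(n_permutations=49, rng_seed=1)
        out = pairwise_module_permanova(t, part, cfg)
        assert len(out) == 3

    def test_random_split_is_null(self, rng):
        arr = rng.uniform(1, 10, (40, 8))
        t = table_from(arr)
        from biofilmnet.modules import ModulePartition
        ps = []
        for seed in range(15):
            r2 = np.random.default_rng(seed)
            halves = r2.permutation(40)
            assignment = {f"o{i}": (0 if k < 20 else 1)
                          for k, i in enumerate(halves)}
            part = ModulePartition(assignment=assignment, q=0.2)
            cfg = AnalysisConfig(n_permutations=99, rng_seed=seed)
            ps.append(pairwise_module_permanova(t, part, cfg).p.iloc[0])
        assert 0.2 < np.mean(ps) < 0.8


def test_mantel_power_monotone_in_effect_size(rng):
    """With dy = (a scaled copy of dx's latent structure) + noise, the
    rejection rate should not decrease as the association strengthens."""
    def power(effect, n_rep=30):
        hits = 0
        for rep in range(n_rep):
            z = rng.standard_normal(11)
            noise = rng.standard_normal(11)
            dx = DistanceMatrix(np.abs(z[:, None] - z[None, :]),
                                ids=[f"s{i}" for i in range(11)])
            y = effect * z + noise
            dy = DistanceMatrix(np.abs(y[:, None] - y[None, :]),
                                ids=[f"s{i}" for i in range(11)])
            hits += mantel(dx, dy, n_perm=99, seed=rep).p < 0.05
        return hits / n_rep

    p0, p1, p2 = power(0.0), power(1.0), power(4.0)
    assert p2 >= p1 - 0.1 >= p0 - 0.2
    assert p2 > 0.8
    assert p0 < 0.3
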