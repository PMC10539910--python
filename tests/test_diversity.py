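import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from soilbiome.diversity import (
    alpha_diversity,
    anosim,
    bray_curtis,
    chao1,
    distance_decay,
    env_distance,
    group_compare_lsd,
    mantel,
    nmds,
    rarefy,
    shannon,
)
from soilbiome.io_formats import ChemistryTable, OtuTable, ValidationError


class TestAlpha:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([10, 0, 0], 0.0),
            ([5, 3, 2], 1.0296530140645737),  # -sum p ln p directly
        ],
    )
    def test_shannon(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)

    def test_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(1, 50, size=8)
            assert shannon(c) <= np.log(8) + 1e-12

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3, 4, 5], 3.0),  # no singletons -> S_obs
            # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
            ([1, 1, 1, 1, 2, 2, 3, 3, 3, 3], 12.0),
        ],
    )
    def test_chao1(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected, abs=1e-12)

    def test_chao1_at_least_observed(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = rng.integers(0, 5, size=30)
            if c.sum() == 0:
                continue
            assert chao1(c) >= (c > 0).sum() - 1e-12

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])
        with pytest.raises(ValidationError):
            chao1([0, 0])

    def test_alpha_frame(self, small_table):
        df = alpha_diversity(small_table)
        assert list(df.columns) == ["shannon", "chao1"]
        assert len(df) == small_table.n_samples


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = OtuTable(["a", "b", "c"], ["o1", "o2"],
                     np.array([[5, 5], [5, 5], [0, 10]]))
        dm = bray_curtis(t)
        assert dm["a", "b"] == pytest.approx(0.0)
        t2 = OtuTable(["a", "b"], ["o1", "o2"], np.array([[7, 0], [0, 3]]))
        assert bray_curtis(t2)["a", "b"] == pytest.approx(1.0)

    def test_direct_formula(self):
        # on relative abundances: a=(0.5,0.5), b=(1,0) -> 1 - 2*0.5/2 = 0.5
        t = OtuTable(["a", "b"], ["o1", "o2"], np.array([[1, 1], [1, 0]]))
        assert bray_curtis(t)["a", "b"] == pytest.approx(0.5, abs=1e-12)
        # equal sample sums: relative-abundance and raw-count forms coincide
        t2 = OtuTable(["a", "b"], ["o1", "o2"], np.array([[3, 1], [1, 3]]))
        assert bray_curtis(t2)["a", "b"] == pytest.approx(0.5, abs=1e-12)

    def test_distance_matrix_invariants(self, small_table):
        dm = bray_curtis(small_table)
        d = dm.data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()


class TestNmds:
    def test_equilateral_embeds_perfectly(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ids=list("abc"))
        res = nmds(dm, k=2, n_restarts=8, seed=0)
        assert res.stress < 0.01
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)

    def test_recovers_planar_configuration(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 2))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(15)])
        res = nmds(dm, k=2, n_restarts=16, seed=1)
        assert res.stress < 0.05

    def test_k_too_large(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=list("ab"))
        with pytest.raises(ValidationError):
            nmds(dm, k=2)


class TestAnosim:
    def _clustered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.05, size=(5, 3))
        b = rng.normal(10, 0.05, size=(5, 3))
        pts = np.vstack([a, b])
        ids = [str(i) for i in range(10)]
        return DistanceMatrix(squareform(pdist(pts)), ids=ids), ["g1"] * 5 + ["g2"] * 5

    def test_perfect_separation(self):
        dm, labels = self._clustered()
        r, p = anosim(dm, labels, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_rank_invariance_to_monotone_transform(self):
        dm, labels = self._clustered()
        r1, _ = anosim(dm, labels, n_perm=49, seed=0)
        dm2 = DistanceMatrix(dm.data**2, ids=dm.ids)
        r2, _ = anosim(dm2, labels, n_perm=49, seed=0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_singleton_group_rejected(self):
        dm, _ = self._clustered()
        with pytest.raises(ValidationError):
            anosim(dm, ["a"] + ["b"] * 9)


class TestMantel:
    def test_linear_relation(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.normal(size=(8, 2))))
        ids = [str(i) for i in range(8)]
        r, _ = mantel(DistanceMatrix(d, ids=ids), DistanceMatrix(2 * d, ids=ids),
                      n_perm=49, seed=0)
        assert r == pytest.approx(1.0)

    def test_mismatched_ids_rejected(self):
        d = np.array([[0, 1], [1, 0]], float)
        with pytest.raises(ValidationError):
            mantel(DistanceMatrix(d, ids=["a", "b"]),
                   DistanceMatrix(d, ids=["a", "c"]))


class TestEnvDistance:
    def test_identical_rows_zero(self, chem_frame):
        chem_frame.iloc[1] = chem_frame.iloc[0]
        dm = env_distance(ChemistryTable(chem_frame))
        assert dm[chem_frame.index[0], chem_frame.index[1]] == pytest.approx(0.0)

    def test_two_sample_closed_form(self):
        # one variable, values 0 and 1: z-scores (sample SD) are -+1/sqrt(2),
        # so the distance is 2/sqrt(2) = sqrt(2)
        df = pd.DataFrame(
            {"SOM": [0.0, 1.0], "pH": [6.5, 6.5], "TN": [1.0, 1.0],
             "AN": [80.0, 80.0], "AP": [40.0, 40.0], "AK": [260.0, 260.0]},
            index=["a", "b"],
        )
        dm = env_distance(ChemistryTable(df), variables=["SOM"])
        assert dm["a", "b"] == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_shift_invariance(self, chem_frame):
        d1 = env_distance(ChemistryTable(chem_frame))
        shifted = chem_frame.copy()
        shifted["SOM"] = shifted["SOM"] + 100
        d2 = env_distance(ChemistryTable(shifted))
        assert np.allclose(d1.data, d2.data, atol=1e-10)


class TestDistanceDecay:
    def test_constant_dissimilarity_zero_slope(self):
        n = 6
        ids = [f"s{i}" for i in range(n)]
        dc = DistanceMatrix(0.5 * (1 - np.eye(n)), ids=ids)
        rng = np.random.default_rng(0)
        de = DistanceMatrix(squareform(pdist(rng.normal(size=(n, 2)))), ids=ids)
        groups = pd.Series(["g"] * n, index=ids)
        out = distance_decay(dc, de, groups, n_perm=49, seed=0)
        assert out.loc["g", "slope"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["g", "n_pairs"] == n * (n - 1) // 2

    def test_small_group_rejected(self):
        ids = ["a", "b", "c"]
        d = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=ids)
        groups = pd.Series(["g1", "g1", "g2"], index=ids)
        with pytest.raises(ValidationError):
            distance_decay(d, d, groups)


class TestLsd:
    def test_identical_groups_share_letter(self):
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.normal(0, 1, 30))
        groups = pd.Series(["a", "b", "c"] * 10)
        out = group_compare_lsd(vals, groups)
        assert len(set(out["letters"])) == 1

    def test_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(5)
        vals = pd.Series(np.concatenate([rng.normal(0, 1, 10),
                                         rng.normal(30, 1, 10)]))
        groups = pd.Series(["lo"] * 10 + ["hi"] * 10)
        out = group_compare_lsd(vals, groups)
        assert set(out.loc["lo", "letters"]).isdisjoint(out.loc["hi", "letters"])

    def test_letters_match_pairwise_t_oracle(self):
        # groups share a letter exactly when the pooled-variance t-test does
        # not reject at alpha
        rng = np.random.default_rng(6)
        for _ in range(20):
            k = rng.integers(2, 5)
            sizes = rng.integers(4, 9, size=k)
            shifts = rng.normal(0, 2, size=k)
            vals, grp = [], []
            for g in range(k):
                vals.extend(rng.normal(shifts[g], 1, sizes[g]))
                grp.extend([f"g{g}"] * sizes[g])
            vals, grp = pd.Series(vals), pd.Series(grp)
            out = group_compare_lsd(vals, grp, alpha=0.05)
            samples = {g: vals[grp == g].to_numpy() for g in out.index}
            mse = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
            df_err = sum(len(v) for v in samples.values()) - len(samples)
            mse /= df_err
            for a, b in itertools.combinations(out.index, 2):
                va, vb = samples[a], samples[b]
                se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
                t = (va.mean() - vb.mean()) / se
                p = 2 * stats.t.sf(abs(t), df_err)
                share = bool(set(out.loc[a, "letters"]) & set(out.loc[b, "letters"]))
                assert share == (p >= 0.05)


class TestRarefy:
    def test_depth_and_determinism(self, small_table):
        depth = int(small_table.counts.sum(axis=1).min())
        r1 = rarefy(small_table, depth, seed=9)
        r2 = rarefy(small_table, depth, seed=9)
        assert (r1.counts.sum(axis=1) == depth).all()
        np.testing.assert_array_equal(r1.counts, r2.counts)
        assert (r1.counts <= small_table.counts).all()
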