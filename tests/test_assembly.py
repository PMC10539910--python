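import io
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from skbio import TreeNode

from soilbiome.assembly import (
    beta_mntd,
    beta_nti,
    classify_assembly,
    classify_pair,
    fit_occurrence_frequencies,
    ncm_fit,
    ncm_predict,
    raup_crick_bray,
)
from soilbiome.io_formats import OtuTable, ValidationError
from soilbiome.synthetic_data import ScenarioConfig, simulate_scenario


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")


class TestNcmPredict:
    def test_abundant_taxon_always_detected(self):
        assert ncm_predict(0.2, 1000.0, 1e-4) == pytest.approx(1.0, abs=1e-9)

    def test_vanishing_abundance_never_detected(self):
        assert ncm_predict(1e-9, 1000.0, 1e-3) == pytest.approx(0.0, abs=1e-6)

    def test_matches_quadrature_of_beta_density(self):
        p, nm, d = 0.001, 1000.0, 0.0001
        a, b = nm * p, nm * (1 - p)
        val, _ = integrate.quad(lambda x: stats.beta.pdf(x, a, b), d, 1.0)
        assert ncm_predict(p, nm, d) == pytest.approx(val, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            ncm_predict(0.0, 100.0, 1e-4)
        with pytest.raises(ValidationError):
            ncm_predict(0.1, -1.0, 1e-4)


class TestNcmFit:
    def test_inverse_crime_recovery(self):
        # noise-free frequencies generated by the model itself must return
        # the generating Nm to within 1%
        rng = np.random.default_rng(0)
        p = np.sort(rng.lognormal(-7, 1.5, size=300))
        p = np.clip(p, 1e-8, 0.2)
        d = 1e-4
        for nm_true in (500.0, 5000.0, 50_000.0):
            freq = ncm_predict(p, nm_true, d)
            nm_hat = fit_occurrence_frequencies(p, freq, d)
            assert abs(nm_hat - nm_true) / nm_true < 0.01

    def test_fit_outputs_well_formed(self):
        sc = simulate_scenario(
            ScenarioConfig(n_samples=20, n_otus=80, N=2000, m=0.3,
                           regime="neutral", seed=3)
        )
        fit = ncm_fit(sc.table)
        per = fit.per_otu
        assert ((per["freq_obs"] >= 0) & (per["freq_obs"] <= 1)).all()
        assert ((per["freq_pred"] >= 0) & (per["freq_pred"] <= 1)).all()
        assert (per["lower"] <= per["upper"] + 1e-12).all()
        assert per["partition"].isin(["above", "within", "below"]).all()
        assert fit.r_squared <= 1
        assert fit.m == pytest.approx(fit.Nm / fit.N)
        assert fit.d == pytest.approx(1 / fit.N)

    def test_too_few_samples(self, small_table):
        with pytest.raises(ValidationError):
            ncm_fit(small_table.select_samples(small_table.sample_ids[:5]))


class TestBetaMntd:
    def test_identical_communities_zero(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = OtuTable(["s1", "s2"], ["A", "B", "C"],
                     np.array([[3, 2, 1], [3, 2, 1]]))
        dm = beta_mntd(t, tree)
        assert dm["s1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_single_otu_communities(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = OtuTable(["s1", "s2"], ["A", "C"], np.array([[5, 0], [0, 7]]))
        dm = beta_mntd(t, tree)
        assert dm["s1", "s2"] == pytest.approx(4.0, abs=1e-12)  # patristic d(A,C)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(1)
        from soilbiome.synthetic_data import simulate_tree

        tree, _ = simulate_tree(8, seed=5)
        otus = sorted(t.name for t in tree.tips())
        counts = rng.integers(0, 6, size=(6, 8))
        counts[:, 0] += 1  # no empty samples
        t = OtuTable([f"s{i}" for i in range(6)], otus, counts)
        dm = beta_mntd(t, tree, abundance_weighted=weighted)
        pat = tree.tip_tip_distances(endpoints=otus)
        rel = counts / counts.sum(axis=1, keepdims=True)
        for i, j in itertools.combinations(range(6), 2):
            total = 0.0
            for a, b in ((i, j), (j, i)):
                pres_b = [otus[k] for k in range(8) if counts[b, k] > 0]
                acc = 0.0
                wsum = 0.0
                for k in range(8):
                    if counts[a, k] == 0:
                        continue
                    dmin = min(pat[otus[k], x] for x in pres_b)
                    w = rel[a, k] if weighted else 1.0
                    acc += w * dmin
                    wsum += w
                total += acc / wsum
            expected = total / 2
            assert dm[f"s{i}", f"s{j}"] == pytest.approx(expected, abs=1e-12)


class TestBetaNti:
    def test_branch_length_scale_invariance(self):
        from soilbiome.synthetic_data import simulate_tree

        tree, _ = simulate_tree(12, seed=6)
        otus = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 8, size=(6, 12))
        counts[:, 0] += 1
        t = OtuTable([f"s{i}" for i in range(6)], otus, counts)
        z1 = beta_nti(t, tree, n_null=49, seed=9)
        scaled = tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length = (node.length or 0) * 7.5
        z2 = beta_nti(t, scaled, n_null=49, seed=9)
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-9)

    def test_no_phylogenetic_signal_gives_standard_null(self):
        # communities assembled independently of the phylogeny: betaNTI
        # should behave like a z-score (mean near 0, spread near 1)
        from soilbiome.synthetic_data import simulate_tree

        tree, _ = simulate_tree(60, seed=7)
        otus = sorted(t.name for t in tree.tips())
        rng = np.random.default_rng(0)
        pres = rng.random((12, 60)) < 0.4  # sparse: dense tables degenerate
        counts = pres * (rng.poisson(5, size=(12, 60)) + 1)
        counts[:, 0] += 1
        t = OtuTable([f"s{i}" for i in range(12)], otus, counts.astype(int))
        z = beta_nti(t, tree, n_null=199, seed=10)
        vals = np.array([z[a, b] for a, b in itertools.combinations(t.sample_ids, 2)])
        assert abs(np.nanmean(vals)) < 0.6
        assert 0.6 < np.nanstd(vals) < 1.6


class TestRaupCrick:
    def test_bounds(self, small_table):
        rc = raup_crick_bray(small_table, n_null=99, seed=0)
        off = rc.data[~np.eye(rc.shape[0], dtype=bool)]
        assert (off >= -1 - 1e-12).all() and (off <= 1 + 1e-12).all()

    def test_identical_samples_more_similar_than_null(self):
        rng = np.random.default_rng(4)
        pool = rng.dirichlet(np.ones(60) * 0.5)
        base = rng.multinomial(800, pool)
        counts = np.vstack([base, base] + [rng.multinomial(800, pool) for _ in range(6)])
        t = OtuTable([f"s{i}" for i in range(8)],
                     [f"O{j}" for j in range(60)], counts)
        rc = raup_crick_bray(t, n_null=199, seed=1)
        assert rc["s0", "s1"] < -0.9

    def test_null_generated_pairs_centre_near_zero(self):
        # samples built by the null procedure itself give RC straddling 0;
        # a mild positive offset remains because the null re-estimates the
        # occupancy and abundance weights from the analysed table, so pool
        # several independent tables
        pooled = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            abund = rng.dirichlet(np.ones(40))
            counts = []
            for _ in range(12):
                chosen = rng.choice(40, size=25, replace=False)
                alloc = rng.multinomial(500 - 25,
                                        abund[chosen] / abund[chosen].sum())
                row = np.zeros(40, dtype=int)
                row[chosen] = 1 + alloc
                counts.append(row)
            t = OtuTable([f"s{i}" for i in range(12)],
                         [f"O{j}" for j in range(40)], np.array(counts))
            rc = raup_crick_bray(t, n_null=199, seed=seed + 100)
            pooled.extend(
                rc[a, b] for a, b in itertools.combinations(t.sample_ids, 2)
            )
        pooled = np.array(pooled)
        assert abs(pooled.mean()) < 0.4
        assert (pooled > 0).any() and (pooled < 0).any()


class TestClassification:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (3.0, 0.0, "heterogeneous_selection"),
            (-3.0, 0.0, "homogeneous_selection"),
            (1.0, 0.99, "dispersal_limitation"),
            (1.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            (2.0, 0.0, "undominated"),  # threshold is strict
        ],
    )
    def test_decision_tree(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(8)]
        n = len(ids)
        z = rng.normal(0, 2, size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        r = rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        from skbio import DistanceMatrix

        groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=ids)
        res = classify_assembly(
            DistanceMatrix(z, ids=ids, validate=False),
            DistanceMatrix(r, ids=ids, validate=False),
            groups,
        )
        sums = res.fractions.sum(axis=1)
        assert np.allclose(sums, 1.0)
        # only within-group pairs are classified
        assert len(res.pairs) == 2 * (4 * 3 // 2)
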