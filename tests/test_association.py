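import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from phycoactivity import (
    DistanceMatrix,
    ValidationError,
    mantel,
    mrpp,
    paired_wilcoxon,
    spearman_panel,
)


def _random_distance(rng, n=8):
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(tuple(f"s{i}" for i in range(n)), squareform(pdist(pts)))


class TestMantel:
    def test_identity_gives_r1_and_min_p(self):
        d = _random_distance(np.random.default_rng(0))
        res = mantel(d, d, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_monotone_transform_spearman_r1(self):
        d = _random_distance(np.random.default_rng(1))
        d2 = DistanceMatrix(d.sample_ids, d.values**2)
        res = mantel(d, d2, n_perm=199, seed=1, method="spearman")
        assert res.r == pytest.approx(1.0)

    def test_observed_r_matches_brute_force(self):
        """r equals the plain correlation of lower-triangle vectors (6 samples)."""
        rng = np.random.default_rng(2)
        for _ in range(5):
            d1 = _random_distance(rng, n=6)
            d2 = _random_distance(rng, n=6)
            res = mantel(d1, d2, n_perm=99, seed=0)
            v1 = [d1.values[i, j] for i in range(6) for j in range(i + 1, 6)]
            v2 = [d2.values[i, j] for i in range(6) for j in range(i + 1, 6)]
            assert res.r == pytest.approx(stats.pearsonr(v1, v2).statistic, abs=1e-12)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        d1, d2 = _random_distance(rng), _random_distance(rng)
        a = mantel(d1, d2, n_perm=199, seed=7)
        b = mantel(d1, d2, n_perm=199, seed=7)
        assert a == b

    def test_mismatched_ids_rejected(self):
        d1 = _random_distance(np.random.default_rng(0), 5)
        d2 = DistanceMatrix(tuple("vwxyz"), d1.values)
        with pytest.raises(ValidationError):
            mantel(d1, d2)

    def test_zero_variance_rejected(self):
        ids = tuple("abcd")
        flat = DistanceMatrix(ids, np.ones((4, 4)) - np.eye(4))
        other = _random_distance(np.random.default_rng(1), 4)
        other = DistanceMatrix(ids, other.values)
        with pytest.raises(ValidationError):
            mantel(flat, other, n_perm=99, seed=0)

    def test_null_p_values_uniform(self):
        """Independent matrices give approximately uniform p-values."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(300):
            d1 = _random_distance(rng, n=8)
            d2 = _random_distance(rng, n=8)
            ps.append(mantel(d1, d2, n_perm=99, seed=int(rng.integers(2**31))).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMRPP:
    def test_separated_clusters_min_p(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.05, (8, 2)), rng.normal(10, 0.05, (8, 2))])
        d = DistanceMatrix(tuple(f"s{i}" for i in range(16)), squareform(pdist(pts)))
        groups = ["a"] * 8 + ["b"] * 8
        res = mrpp(d, groups, n_perm=199, seed=1)
        assert res.p == pytest.approx(1 / 200)
        assert res.extra["A"] > 0.5

    def test_strata_never_crossed(self, monkeypatch):
        """Structural audit: permutations move labels only within strata."""
        import phycoactivity.association as assoc
        rng = np.random.default_rng(4)
        d = _random_distance(rng, n=12)
        groups = np.array(["x", "y"] * 6)
        strata = np.repeat([f"d{i}" for i in range(6)], 2)
        seen = []
        orig = assoc._mrpp_delta

        def spy(dist, labels):
            seen.append(labels.copy())
            return orig(dist, labels)

        monkeypatch.setattr(assoc, "_mrpp_delta", spy)
        mrpp(d, groups, strata=strata, n_perm=50, seed=2)
        by_stratum = {s: {groups[i] for i in range(12) if strata[i] == s}
                      for s in set(strata)}
        for labels in seen[1:]:
            for s, allowed in by_stratum.items():
                idx = [i for i in range(12) if strata[i] == s]
                assert set(labels[idx]) <= allowed
                # multiset within each stratum preserved
                assert sorted(labels[idx]) == sorted(groups[idx])

    def test_type_one_error_calibrated(self):
        """Random labels within strata reject at roughly the nominal rate."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            d = _random_distance(rng, n=24)
            strata = np.repeat([f"d{i}" for i in range(6)], 4)
            groups = np.concatenate([
                rng.permutation(["x", "x", "y", "y"]) for _ in range(6)
            ])
            res = mrpp(d, groups, strata=strata, n_perm=99,
                       seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        assert 0.02 <= rejections / n_sim <= 0.08

    def test_small_group_rejected(self):
        d = _random_distance(np.random.default_rng(0), 5)
        with pytest.raises(ValidationError):
            mrpp(d, ["a", "a", "a", "a", "b"], n_perm=99)

    def test_all_degenerate_strata_rejected(self):
        d = _random_distance(np.random.default_rng(0), 4)
        with pytest.raises(ValidationError):
            mrpp(d, ["a", "a", "b", "b"], strata=["s1", "s1", "s2", "s2"],
                 n_perm=99)


class TestPairedWilcoxon:
    def test_identical_pairs_give_p_one(self):
        x = {f"p{i}": float(i) for i in range(8)}
        res = paired_wilcoxon(x, x)
        assert res.p == 1.0

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(1)
        x = {f"p{i}": v for i, v in enumerate(rng.normal(size=20))}
        y = {k: v + 1.5 for k, v in x.items()}
        res = paired_wilcoxon(x, y)
        assert res.p < 0.01

    def test_incomplete_pairs_excluded_and_counted(self):
        x = {f"p{i}": float(i) for i in range(8)}
        y = {f"p{i}": float(i) + (0.5 if i % 2 else -0.5) for i in range(6)}
        res = paired_wilcoxon(x, y)
        assert res.extra["n_pairs"] == 6
        assert res.extra["n_missing"] == 2

    def test_too_few_pairs_rejected(self):
        x = {f"p{i}": float(i) for i in range(4)}
        with pytest.raises(ValidationError):
            paired_wilcoxon(x, x)

    def test_matches_scipy_exact_distribution(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = x + rng.normal(0.3, 0.5, size=12)
        keys = [f"p{i}" for i in range(12)]
        res = paired_wilcoxon(dict(zip(keys, x)), dict(zip(keys, y)))
        ref = stats.wilcoxon(x, y, zero_method="wilcox")
        assert res.p == pytest.approx(ref.pvalue)


class TestSpearmanPanel:
    def test_monotone_and_antimonotone(self):
        samples = [f"s{i}" for i in range(10)]
        base = np.arange(10, dtype=float)
        rows = pd.DataFrame([base], index=["up"], columns=samples)
        cols = pd.DataFrame([base**2, -base], index=["sq", "down"], columns=samples)
        panel = spearman_panel(rows, cols)
        assert panel.rho.loc["up", "sq"] == pytest.approx(1.0)
        assert panel.rho.loc["up", "down"] == pytest.approx(-1.0)

    def test_constant_feature_flagged_missing(self):
        samples = [f"s{i}" for i in range(8)]
        rows = pd.DataFrame([np.ones(8)], index=["flat"], columns=samples)
        cols = pd.DataFrame([np.arange(8.0)], index=["up"], columns=samples)
        panel = spearman_panel(rows, cols)
        assert np.isnan(panel.rho.loc["flat", "up"])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(12)]
        rows = pd.DataFrame(rng.normal(size=(4, 12)),
                            index=[f"r{i}" for i in range(4)], columns=samples)
        cols = pd.DataFrame(rng.normal(size=(5, 12)),
                            index=[f"c{i}" for i in range(5)], columns=samples)
        panel = spearman_panel(rows, cols)
        assert (panel.p_adjusted.to_numpy() >= panel.p_raw.to_numpy() - 1e-12).all()

    def test_null_false_positive_rate(self):
        """Independent noise panel: raw p < 0.05 in roughly 5% of cells."""
        rng = np.random.default_rng(7)
        samples = [f"s{i}" for i in range(30)]
        rows = pd.DataFrame(rng.normal(size=(25, 30)),
                            index=[f"r{i}" for i in range(25)], columns=samples)
        cols = pd.DataFrame(rng.normal(size=(40, 30)),
                            index=[f"c{i}" for i in range(40)], columns=samples)
        panel = spearman_panel(rows, cols)
        frac = (panel.p_raw.to_numpy() < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_stars_thresholds(self):
        from phycoactivity.association import significance_stars
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == ""
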