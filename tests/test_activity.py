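import numpy as np
import pandas as pd
import pytest

from phycoactivity import (
    ActivityRecord,
    SimConfig,
    ValidationError,
    compute_activity,
    fit_abundance_activity,
    pair_samples,
    paired_wilcoxon,
    rank_env_importance,
    records_to_frame,
    relative_abundance,
    residual_env_regression,
    simulate_paired_dataset,
    split_host_nonhost,
    taxon_activity_profile,
)
from phycoactivity.activity import pair_group_ratios
from phycoactivity.io import RelAbundanceTable


def _rel(dct):
    return RelAbundanceTable(pd.DataFrame(dct))


def _record(taxon="t", ratio=2.0, rdna=0.01, **kw):
    defaults = dict(taxon_id=taxon, pair_key="p0", date="2021-05-04",
                    condition="daytime", rdna_prop=rdna, rrna_prop=rdna * ratio)
    defaults.update(kw)
    return ActivityRecord(**defaults)


class TestComputeActivity:
    def test_ratio_and_classification(self):
        rec = _record(ratio=2.0)
        assert rec.ratio == pytest.approx(2.0)
        assert rec.active
        # the 1:1 line itself is NOT active (strict inequality)
        assert not _record(ratio=1.0).active

    def test_zero_pairs_excluded(self, paired_meta):
        rdna = _rel({"p0_rDNA": [0.5, 0.5, 0.0], "p1_rDNA": [0.2, 0.3, 0.5]})
        rrna = _rel({"p0_rRNA": [0.4, 0.1, 0.5], "p1_rRNA": [0.5, 0.5, 0.0]})
        rdna.data.index = rrna.data.index = ["a", "b", "c"]
        records = compute_activity(rdna, rrna, pair_samples(paired_meta))
        kept = {(r.taxon_id, r.pair_key) for r in records}
        assert ("c", "p0") not in kept  # rDNA zero
        assert ("c", "p1") not in kept  # rRNA zero
        assert len(records) == 4

    def test_classification_consistent_with_log_space(self, small_records):
        """Above the 1:1 line in log-log space <=> ratio > 1 <=> log ratio > 0."""
        records, _, _ = small_records
        for r in records:
            above = np.log10(r.rrna_prop) > np.log10(r.rdna_prop)
            assert r.active == above == (r.log10_ratio > 0)

    def test_mismatched_taxa_rejected(self, paired_meta):
        rdna = _rel({"p0_rDNA": [0.5, 0.5]})
        rrna = _rel({"p0_rRNA": [0.5, 0.5]})
        rdna.data.index = ["a", "b"]
        rrna.data.index = ["a", "c"]
        with pytest.raises(ValidationError):
            compute_activity(rdna, rrna, pair_samples(paired_meta))


class TestSplitHostNonhost:
    TAXONOMY = {"t1": "Bacteria;Cyanobacteria;x;y;z;Microcystis",
                "t2": "Bacteria;Bacteroidota;a;b;c;Flavobacterium",
                "t3": "Bacteria;Proteobacteria;d;e;f;Rhodobacter"}

    def test_partition_exhaustive_and_disjoint(self):
        records = [_record(t) for t in ("t1", "t2", "t3", "t1")]
        host, nonhost = split_host_nonhost(records, self.TAXONOMY, "Microcystis")
        assert len(host) + len(nonhost) == len(records)
        assert {r.taxon_id for r in host} == {"t1"}
        assert {r.taxon_id for r in nonhost} == {"t2", "t3"}

    def test_absent_label_gives_empty_host(self):
        records = [_record("t2"), _record("t3")]
        host, nonhost = split_host_nonhost(records, self.TAXONOMY, "Synechococcus")
        assert host == [] and len(nonhost) == 2

    def test_missing_taxon_listed(self):
        with pytest.raises(ValidationError, match="t9"):
            split_host_nonhost([_record("t9")], self.TAXONOMY, "Microcystis")


class TestAbundanceActivityFit:
    def test_slope_recovery_on_synthetic_records(self):
        """OLS recovers a planted slope of -0.6 with sigma=0.3 at n=1000."""
        rng = np.random.default_rng(0)
        records = []
        for i in range(1000):
            log_a = rng.uniform(-5, -1)
            log_r = -0.6 * log_a + rng.normal(0, 0.3)
            records.append(_record(f"t{i}", rdna=10**log_a,
                                   rrna_prop=10**log_a * 10**log_r))
        fit = fit_abundance_activity(records)
        assert -0.66 <= fit.slope <= -0.54
        assert abs(fit.residuals.sum()) < 1e-9

    def test_constant_response_flagged(self):
        records = [_record(f"t{i}", ratio=1.0, rdna=10**-(i % 7 + 1))
                   for i in range(12)]
        fit = fit_abundance_activity(records)
        assert fit.constant_response
        assert fit.slope == 0.0 and fit.r2 == 0.0

    def test_too_few_records_rejected(self):
        with pytest.raises(ValidationError):
            fit_abundance_activity([_record(f"t{i}") for i in range(5)])

    def test_zero_x_variance_rejected(self):
        records = [_record(f"t{i}", rdna=0.01, rrna_prop=0.01 * (i + 1))
                   for i in range(12)]
        with pytest.raises(ValidationError):
            fit_abundance_activity(records)


class TestResidualEnvRegression:
    def test_planted_effect_recovered(self, env_table):
        """Residuals built as 0.5 * DO_z + noise recover slope near 0.5."""
        rng = np.random.default_rng(1)
        do = env_table.data["DO"].to_numpy()
        do_z = (do - do.mean()) / do.std(ddof=0)
        records, resid = [], []
        for rep in range(30):
            for i, date in enumerate(env_table.data["date"]):
                records.append(_record(f"t{rep}_{i}", date=date,
                                       pair_key=f"p{rep}_{i}",
                                       rdna=10 ** rng.uniform(-4, -1)))
                resid.append(0.5 * do_z[i] + rng.normal(0, 0.2))
        from phycoactivity.activity import RegressionFit
        fit = RegressionFit(group="test", slope=0.0, intercept=0.0, r2=0.0,
                            n=len(records), residuals=np.array(resid),
                            records=tuple(records))
        atts = {a.factor: a for a in residual_env_regression(fit, env_table)}
        assert 0.4 <= atts["DO"].slope <= 0.6
        assert atts["DO"].p < 0.01

    def test_missing_date_named(self, env_table):
        from phycoactivity.activity import RegressionFit
        rec = _record("t1", date="1999-01-01")
        fit = RegressionFit(group="g", slope=0, intercept=0, r2=0, n=1,
                            residuals=np.zeros(1), records=(rec,))
        with pytest.raises(ValidationError, match="1999-01-01"):
            residual_env_regression(fit, env_table)


class TestRankEnvImportance:
    def test_informative_factor_ranked_first(self, env_table):
        rng = np.random.default_rng(2)
        do = env_table.data["DO"].to_numpy()
        do_z = (do - do.mean()) / do.std(ddof=0)
        records, resid = [], []
        for rep in range(20):
            for i, date in enumerate(env_table.data["date"]):
                records.append(_record(f"t{rep}_{i}", date=date,
                                       pair_key=f"p{rep}_{i}",
                                       rdna=10 ** rng.uniform(-4, -1)))
                resid.append(0.8 * do_z[i] + rng.normal(0, 0.1))
        from phycoactivity.activity import RegressionFit
        fit = RegressionFit(group="g", slope=0, intercept=0, r2=0,
                            n=len(records), residuals=np.array(resid),
                            records=tuple(records))
        atts = rank_env_importance(fit, env_table, seed=0, n_estimators=100)
        ranks = [a.rank for a in atts]
        assert sorted(ranks) == list(range(1, len(atts) + 1))
        assert atts[0].factor == "DO" and atts[0].rank == 1


class TestTaxonActivityProfile:
    TAXONOMY = {
        "t1": "Bacteria;Bacteroidota;Flavobacteriia;Flavobacteriales;F;G",
        "t2": "Bacteria;Bacteroidota;Flavobacteriia;Flavobacteriales;F;H",
        "t3": "Bacteria;Proteobacteria;Alpha;Rhodobacterales;R;S",
    }

    def test_single_order_median(self):
        records = [_record("t1", ratio=0.5), _record("t1", ratio=1.0, pair_key="p1"),
                   _record("t1", ratio=2.0, pair_key="p2")]
        prof = taxon_activity_profile(records, self.TAXONOMY, rank="order",
                                      group_by="condition")
        assert prof["ratio_median"].iloc[0] == pytest.approx(1.0)

    def test_record_counts_conserved(self, small_records):
        records, truth, _ = small_records
        prof = taxon_activity_profile(records, truth.taxonomy, rank="order",
                                      group_by="date")
        assert prof["n_records"].sum() == len(records)

    def test_anoxia_boosted_order_detected(self):
        """An order with boosted anoxic ratios shows a paired Wilcoxon shift."""
        rng = np.random.default_rng(3)
        records = []
        for d in range(17):
            date = f"2021-06-{d + 1:02d}"
            for cond, boost in (("daytime", 1.0), ("anoxic", 3.0)):
                pk = f"d{d}_{cond}"
                for t in ("t1", "t2"):
                    ratio = boost * np.exp(rng.normal(0, 0.2))
                    records.append(_record(t, ratio=ratio, date=date,
                                           pair_key=pk, condition=cond))
        per_pair = pair_group_ratios(records, self.TAXONOMY, "order",
                                     "Flavobacteriales")
        wide = per_pair.pivot_table(index="date", columns="condition",
                                    values="group_ratio")
        assert wide["anoxic"].median() > wide["daytime"].median()
        res = paired_wilcoxon(wide["daytime"], wide["anoxic"])
        assert res.p < 0.05


class TestEndToEndRecovery:
    def test_pipeline_recovers_negative_slope(self):
        """Generated slope of -0.6 recovered through sequencing + fitting."""
        cfg = SimConfig(n_taxa=200, n_dates=10, depth=8000,
                        activity_slope=-0.6, seed=21)
        rdna, rrna, meta, env, tree, truth = simulate_paired_dataset(cfg)
        records = compute_activity(relative_abundance(rdna),
                                   relative_abundance(rrna),
                                   pair_samples(meta))
        fit = fit_abundance_activity(records)
        assert -0.75 <= fit.slope <= -0.45
        assert abs(fit.r2 - truth.generative_r2(records)) < 0.15

    def test_abundance_only_env_effect_leaves_residuals_clean(self):
        """Seasonal abundance structure alone must not fake env effects.

        Mirrors the host finding: when environment shapes abundances but not
        the activity residuals, no factor should be significant beyond noise.
        """
        fp, total = 0, 0
        for seed in range(12):
            cfg = SimConfig(n_taxa=100, n_dates=12, depth=4000,
                            turnover_sd=0.0, seed=300 + seed)
            rdna, rrna, meta, env, tree, truth = simulate_paired_dataset(cfg)
            records = compute_activity(relative_abundance(rdna),
                                       relative_abundance(rrna),
                                       pair_samples(meta))
            fit = fit_abundance_activity(records)
            for a in residual_env_regression(fit, env):
                total += 1
                fp += a.p < 0.05
        assert fp / total < 0.15
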