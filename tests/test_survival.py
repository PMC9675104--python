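import numpy as np
import pandas as pd
import pytest

from methsplice import stepminer
from methsplice.io import ClinicalTable
from methsplice.simulate import SimConfig, simulate_dataset
from methsplice.survival import (
    binarize_methylation,
    enrichment_from_counts,
    fold_enrichment,
    logrank,
    overlap_enrichment,
    stratify_by_cpg_panel,
    survival_scan,
)


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Plain per-event-time observed/expected/variance summation."""
    records = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, g in records if e})
    o_minus_e = var = 0.0
    for t in event_times:
        at_risk = [(tt, ee, gg) for tt, ee, gg in records if tt >= t]
        n = len(at_risk)
        na = sum(1 for tt, ee, gg in at_risk if gg == 0)
        d = sum(1 for tt, ee, gg in at_risk if tt == t and ee)
        da = sum(1 for tt, ee, gg in at_risk if tt == t and ee and gg == 0)
        o_minus_e += da - d * na / n
        if n > 1:
            var += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0]
        e = [1, 1, 0]
        chi2, p = logrank(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # A dies at 1,2; B dies at 3,4: O-E = 7/6, V = 17/36, chi2 = 49/17
        chi2, p = logrank([1, 2], [1, 1], [3, 4], [1, 1])
        assert chi2 == pytest.approx(49 / 17, abs=1e-10)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(5, 12), rng.exponential(8, 15)
        ea, eb = rng.integers(0, 2, 12), rng.integers(0, 2, 15)
        assert logrank(ta, ea, tb, eb) == pytest.approx(logrank(tb, eb, ta, ea))

    def test_zero_events_flagged_null(self):
        assert logrank([1, 2], [0, 0], [3], [0]) == (0.0, 1.0)

    def test_matches_oracle_on_random_datasets(self):
        rng = np.random.default_rng(9)
        for _ in range(40):
            na, nb = rng.integers(3, 11, 2)
            ta = np.round(rng.exponential(5, na), 1)
            tb = np.round(rng.exponential(5, nb), 1)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            chi2, _ = logrank(ta, ea, tb, eb)
            assert chi2 == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-8)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(2)
        ta, tb = np.round(rng.exponential(5, 20), 1), np.round(rng.exponential(3, 25), 1)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        chi2, p = logrank(ta, ea, tb, eb)
        ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(float(ref.test_statistic), abs=1e-10)
        assert p == pytest.approx(float(ref.p_value), abs=1e-10)


class TestBinarizeMethylation:
    def test_perfect_split(self):
        labels = binarize_methylation([0.1] * 5 + [0.9] * 5)
        assert list(labels) == [False] * 5 + [True] * 5

    def test_constant_skipped(self):
        assert binarize_methylation([0.4] * 10) is None

    def test_bimodal_recovery(self):
        rng = np.random.default_rng(4)
        b = np.clip(
            np.concatenate([rng.normal(0.2, 0.05, 25), rng.normal(0.8, 0.05, 25)]), 0, 1
        )
        labels = binarize_methylation(b)
        assert (labels == np.array([False] * 25 + [True] * 25)).mean() >= 0.95


class TestSurvivalScan:
    def test_driver_detection_power(self):
        # one driver CpG per replicate (HR=3, cohort ~100); pooled recall >= 0.8
        hits = total = 0
        for seed in range(41, 51):
            cfg = SimConfig(
                n_genes=5, n_cancers=1, samples_per_cancer=125, frac_expressed=0.8,
                cpgs_per_gene=6, exons_per_gene=6, frac_planted=0.1,
                frac_driver_cpgs=0.05, hazard_ratio=3.0, censor_rate=0.005,
                baseline_hazard=0.03, beta_latent_sd=2.5, seed=seed,
            )
            d = simulate_dataset(cfg)
            drivers = {c for g, c in d.truth.driver_cpgs}
            assert drivers
            labels, _ = stepminer.stratify_matrix(d.gene_expr)
            cohorts = stepminer.cohorts_from_labels(labels)
            scan = survival_scan(d.samples, d.meth, d.clinical, cohorts, d.feature_map)
            sub = scan[scan["cpg"].isin(drivers)]
            total += len(sub)
            hits += int(sub["significant"].sum())
        assert total >= 10
        assert hits / total >= 0.8

    def test_small_cohort_skipped(self, small_dataset):
        d = small_dataset
        cohorts = {g: set(d.meth.sample_ids[:9]) for g in d.feature_map.genes}
        scan = survival_scan(d.samples, d.meth, d.clinical, cohorts, d.feature_map)
        assert scan.empty


class TestEnrichment:
    def test_rate_and_fold_arithmetic(self):
        res = enrichment_from_counts(
            n_sig_survival=31045, n_cpg_total=485577, n_cancers=33,
            n_exon_correlated=65949, observed_overlap=643,
        )
        assert res.rate == pytest.approx(31045 / 16024041)
        assert res.expected_overlap == pytest.approx(127.8, abs=0.1)
        assert res.fold == pytest.approx(643 / res.expected_overlap)

    def test_fold_edge_cases(self):
        assert fold_enrichment(0, 0.0) == 0.0
        assert np.isinf(fold_enrichment(3, 0.0))

    def test_observed_bounded_by_set_sizes(self):
        exon = {("c1", "cg1"), ("c1", "cg2"), ("c2", "cg1")}
        surv = {("c1", "cg2"), ("c2", "cg9")}
        res = overlap_enrichment(exon, surv, n_cpg_total=100, n_cancers=2)
        assert res.observed_overlap == 1
        assert res.observed_overlap <= min(len(exon), len(surv))
        assert res.n_exon_correlated_unique == 2
        assert res.observed_overlap_unique == 1  # cg2 shared


class TestPanelStratification:
    def _clinical(self, samples, rng, hazard):
        t = rng.exponential(1 / hazard)
        return pd.DataFrame(
            {"sample_id": samples, "time": t, "event": np.ones(len(samples), dtype=int)}
        )

    def test_recovers_methylation_blocks(self):
        rng = np.random.default_rng(8)
        samples = [f"s{i}" for i in range(40)]
        block = np.concatenate([np.full(20, 0.1), np.full(20, 0.9)])
        betas = pd.DataFrame(
            np.clip(block + rng.normal(0, 0.03, (4, 40)), 0, 1),
            index=[f"cg{i}" for i in range(4)],
            columns=samples,
        )
        hazards = np.where(block > 0.5, 0.1, 0.02)
        clin = ClinicalTable(
            pd.DataFrame(
                {"sample_id": samples, "time": rng.exponential(1 / hazards), "event": 1}
            )
        )
        strat = stratify_by_cpg_panel(betas, clin)
        labels = strat.labels
        # partition property: everyone assigned, groups disjoint and non-trivial
        assert set(labels.index) == set(samples)
        assert set(labels.unique()) == {1, 2}
        # clusters match the planted blocks exactly (up to label swap)
        first, second = labels.iloc[:20], labels.iloc[20:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]
        assert strat.p < 0.05
        assert {"group1", "group2"} == set(strat.km_curves["group"])

    def test_identical_profiles_rejected(self):
        samples = [f"s{i}" for i in range(12)]
        betas = pd.DataFrame(0.5, index=["cg1", "cg2"], columns=samples)
        clin = ClinicalTable(
            pd.DataFrame({"sample_id": samples, "time": np.arange(12) + 1.0, "event": 1})
        )
        with pytest.raises(ValueError):
            stratify_by_cpg_panel(betas, clin)
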