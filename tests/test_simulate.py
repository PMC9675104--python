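import numpy as np
import pandas as pd
import pytest

from methsplice.correlation import pearson
from methsplice.simulate import SimConfig, read_truth, simulate_dataset, write_truth


def _planted_cohort_r(data, cancer, gene, cpg, exon):
    expressed = data.truth.mode_labels.loc[gene]
    cols = [s for s in data.meth.sample_ids if s.startswith(cancer) and expressed[s]]
    return pearson(data.meth.values.loc[cpg, cols], data.exon_expr.values.loc[exon, cols])[0]


class TestConfigValidation:
    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(frac_expressed=1.5)
        with pytest.raises(ValueError):
            SimConfig(effect_r=1.0)
        with pytest.raises(ValueError):
            SimConfig(n_genes=0)
        with pytest.raises(ValueError):
            SimConfig(driver_mode="nope")


class TestDeterminismAndRanges:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_genes=6, samples_per_cancer=20, cpgs_per_gene=5, exons_per_gene=4, seed=1)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        pd.testing.assert_frame_equal(d1.meth.values, d2.meth.values)
        pd.testing.assert_frame_equal(d1.exon_expr.values, d2.exon_expr.values)
        pd.testing.assert_frame_equal(d1.clinical.table, d2.clinical.table)
        assert d1.truth.planted_pairs == d2.truth.planted_pairs
        assert d1.truth.driver_cpgs == d2.truth.driver_cpgs

    def test_value_ranges(self, small_dataset):
        d = small_dataset
        betas = d.meth.values.to_numpy()
        assert ((betas >= 0) & (betas <= 1)).all()
        for mat in (d.gene_expr, d.exon_expr, d.isoform_expr):
            assert (mat.values.to_numpy() >= 0).all()

    def test_truth_consistent_with_map(self, small_dataset):
        small_dataset.truth.validate(small_dataset.feature_map)


class TestNullAndPlantedStructure:
    def test_null_pvalue_calibration(self):
        # no planted effects: CpG-exon p-values behave as uniform draws
        cfg = SimConfig(
            n_cancers=1, samples_per_cancer=60, n_genes=20, cpgs_per_gene=10,
            exons_per_gene=10, frac_expressed=1.0, frac_planted=0.0, seed=3,
        )
        d = simulate_dataset(cfg)
        ps = []
        for gene in d.feature_map.genes:
            cols = d.meth.sample_ids
            X = d.meth.values.loc[d.feature_map.gene_cpgs[gene], cols].to_numpy()
            Y = d.exon_expr.values.loc[d.feature_map.gene_exons[gene], cols].to_numpy()
            for x in X:
                for y in Y:
                    ps.append(pearson(x, y)[1])
        ps = np.array(ps)
        assert ps.size == 2000
        # binomial(2000, 0.05) -> sd ~ 0.0049; allow ~3.5 sd
        assert abs((ps < 0.05).mean() - 0.05) < 0.017

    def test_planted_correlation_magnitude(self):
        cfg = SimConfig(
            n_cancers=1, samples_per_cancer=100, n_genes=25, cpgs_per_gene=6,
            exons_per_gene=6, frac_expressed=1.0, frac_planted=0.12, effect_r=0.8, seed=4,
        )
        d = simulate_dataset(cfg)
        rs = [
            _planted_cohort_r(d, ca, g, c, e) * s
            for ca, g, c, e, s in d.truth.planted_pairs
        ]
        assert len(rs) >= 100
        assert abs(np.mean(rs) - 0.8) < 0.1

    def test_sign_consistency_one_means_same_sign_everywhere(self):
        cfg = SimConfig(
            n_cancers=3, samples_per_cancer=30, n_genes=10, cpgs_per_gene=6,
            exons_per_gene=6, frac_planted=0.2, sign_consistency=1.0, seed=5,
        )
        d = simulate_dataset(cfg)
        by_pair = {}
        for ca, g, c, e, s in d.truth.planted_pairs:
            by_pair.setdefault((g, c, e), set()).add(s)
        assert all(len(signs) == 1 for signs in by_pair.values())

    def test_isoform_dilution(self):
        # an isoform averages its member exons plus noise, so the planted
        # CpG signal is strictly weaker at the isoform level
        cfg = SimConfig(
            n_cancers=1, samples_per_cancer=300, n_genes=15, cpgs_per_gene=6,
            exons_per_gene=6, isoforms_per_gene=3, frac_expressed=1.0,
            frac_planted=0.15, effect_r=0.8, seed=6,
        )
        d = simulate_dataset(cfg)
        stronger = weaker = 0
        for ca, g, c, e, s in d.truth.planted_pairs:
            r_exon = _planted_cohort_r(d, ca, g, c, e)
            for iso in d.feature_map.isoforms_containing(g, e):
                cols = d.meth.sample_ids
                r_iso = pearson(
                    d.meth.values.loc[c, cols], d.isoform_expr.values.loc[iso, cols]
                )[0]
                if abs(r_exon) > abs(r_iso):
                    stronger += 1
                else:
                    weaker += 1
        assert stronger > 0
        assert stronger / (stronger + weaker) > 0.9


class TestTruthIO:
    def test_round_trip(self, small_dataset, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(small_dataset.truth, path, small_dataset.feature_map)
        back = read_truth(path)
        assert back.planted_pairs == small_dataset.truth.planted_pairs
        assert back.driver_cpgs == small_dataset.truth.driver_cpgs
        pd.testing.assert_frame_equal(
            back.mode_labels.sort_index().sort_index(axis=1),
            small_dataset.truth.mode_labels.sort_index().sort_index(axis=1),
        )

    def test_empty_truth_writes_header(self, tmp_path):
        from methsplice.simulate import SimTruth

        path = tmp_path / "truth.tsv"
        write_truth(SimTruth(), path)
        back = read_truth(path)
        assert back.planted_pairs == set() and back.driver_cpgs == set()

    def test_unknown_gene_rejected(self, small_dataset, tmp_path):
        from methsplice.simulate import SimTruth

        truth = SimTruth(planted_pairs={("c", "ghost", "cg", "ex", 1)})
        with pytest.raises(ValueError, match="ghost"):
            write_truth(truth, tmp_path / "t.tsv", small_dataset.feature_map)
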