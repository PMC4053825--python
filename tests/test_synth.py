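"""Generator contracts: determinism, invariants and degenerate cases."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from rbpscape.datatypes import ValidationError
from rbpscape.synth import (CANCER_TISSUE, PlantSpec, choose_sur_genes,
                            couple_noise_to_degree, generate_cancer_cohorts,
                            generate_complex_catalog, generate_gene_universe,
                            generate_healthy_expression, generate_ppi_network,
                            stage_rng)


class TestGeneUniverse:
    def test_rounded_class_counts(self):
        spec = PlantSpec(n_genes=1000, n_sur=25, seed=1,
                         class_proportions={"RBP": 0.2, "other": 0.8})
        ann = generate_gene_universe(spec)
        counts = ann["regulator_class"].value_counts()
        assert counts["RBP"] == 200 and counts["other"] == 800

    def test_deterministic_given_seed(self):
        spec = PlantSpec(n_genes=200, n_sur=10, seed=1)
        a = generate_gene_universe(spec)
        b = generate_gene_universe(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValidationError):
            PlantSpec(class_proportions={"RBP": 0.5, "other": 0.6}).validate()

    def test_fold_ranges_must_straddle_threshold(self):
        with pytest.raises(ValidationError):
            PlantSpec(sur_fold_range=(8.0, 50.0)).validate()
        with pytest.raises(ValidationError):
            PlantSpec(background_fold_range=(0.5, 9.5)).validate()


class TestHealthyExpression:
    def _ann(self, seed=1, n=400):
        spec = PlantSpec(n_genes=n, n_sur=10, seed=seed,
                         class_proportions={"RBP": 0.5, "other": 0.5})
        return generate_gene_universe(spec)

    def test_all_values_positive(self):
        ann = self._ann()
        m = generate_healthy_expression(ann, 5, {"RBP": 0.0}, seed=2)
        assert (m.values.to_numpy() > 0).all()

    def test_planted_shift_gives_power_in_every_tissue(self):
        from rbpscape.profiling import rank_sum_test
        ann = self._ann(seed=7, n=1000)
        m = generate_healthy_expression(ann, 16, {"RBP": np.log(4.0)}, seed=7)
        rbp = ann.index[ann["regulator_class"] == "RBP"]
        other = ann.index[ann["regulator_class"] == "other"]
        for tissue in m.sample_ids:
            p = rank_sum_test(m.values.loc[rbp, tissue],
                              m.values.loc[other, tissue]).p_value
            assert p < 0.01

    def test_null_shift_calibrated(self):
        """Zero shift: per-tissue rank-sum rejection near alpha (many seeds)."""
        from rbpscape.profiling import rank_sum_test
        rej = trials = 0
        for seed in range(60):
            ann = self._ann(seed=seed, n=80)
            m = generate_healthy_expression(ann, 1, {}, seed=seed)
            rbp = ann.index[ann["regulator_class"] == "RBP"]
            other = ann.index[ann["regulator_class"] == "other"]
            p = rank_sum_test(m.values.loc[rbp].iloc[:, 0],
                              m.values.loc[other].iloc[:, 0]).p_value
            rej += p < 0.05
            trials += 1
        assert 0.0 <= rej / trials < 0.13


class TestCancerCohorts:
    def _pieces(self, seed=1, noise_cv=0.3, **kw):
        spec = PlantSpec(n_genes=120, n_sur=6, seed=seed,
                         patients_per_cancer={c: 8 for c in CANCER_TISSUE},
                         patient_noise_cv=noise_cv, **kw)
        ann = generate_gene_universe(spec)
        sur = choose_sur_genes(ann, spec)
        healthy = generate_healthy_expression(
            ann, 16, spec.class_location_shift, stage_rng(seed, "healthy"))
        return spec, ann, sur, healthy

    def test_no_noise_gives_identical_patient_ratios(self):
        spec, ann, sur, healthy = self._pieces(noise_cv=0.0)
        cohorts, folds = generate_cancer_cohorts(healthy, spec, sur_genes=sur)
        tumor, _ = cohorts["colon_ad"]
        h = healthy.values["colon"]
        ratios = tumor.values.div(h, axis=0)
        assert np.allclose(ratios.std(axis=1), 0.0)
        np.testing.assert_allclose(ratios.iloc[:, 0], folds["colon_ad"])

    def test_matched_normals_recover_fold_exactly_without_noise(self):
        spec, ann, sur, healthy = self._pieces(noise_cv=0.0)
        cohorts, folds = generate_cancer_cohorts(healthy, spec, sur_genes=sur)
        tumor, normal = cohorts["liver_hcc"]
        paired = tumor.values.iloc[:, :normal.values.shape[1]].to_numpy() \
            / normal.values.to_numpy()
        np.testing.assert_allclose(
            paired, np.tile(folds["liver_hcc"].to_numpy()[:, None],
                            (1, normal.values.shape[1])))

    def test_sur_genes_get_sur_folds_in_exact_cancer_count(self):
        spec, ann, sur, healthy = self._pieces()
        _c, folds = generate_cancer_cohorts(healthy, spec, sur_genes=sur)
        for g in sur:
            assert (folds.loc[g] >= spec.sur_fold_range[0]).sum() == \
                spec.sur_cancers_per_gene
        background = folds.drop(index=sorted(sur))
        assert (background <= spec.background_fold_range[1] + 1e-12).all().all()

    def test_unmapped_cancer_rejected(self):
        spec, ann, sur, healthy = self._pieces()
        bad = PlantSpec(n_genes=120, n_sur=6, seed=1,
                        patients_per_cancer={"mystery_ca": 5}, n_cancers=1,
                        sur_cancers_per_gene=1, min_cancers=1)
        with pytest.raises(ValidationError, match="mystery_ca"):
            generate_cancer_cohorts(healthy, bad, sur_genes=sur)

    def test_deterministic(self):
        spec, ann, sur, healthy = self._pieces()
        a, _ = generate_cancer_cohorts(healthy, spec, sur_genes=sur)
        b, _ = generate_cancer_cohorts(healthy, spec, sur_genes=sur)
        pd.testing.assert_frame_equal(a["breast_ca"][0].values,
                                      b["breast_ca"][0].values)


class TestPPINetwork:
    def _pieces(self, seed=3, **kw):
        spec = PlantSpec(n_genes=300, n_sur=20, seed=seed, **kw)
        ann = generate_gene_universe(spec)
        sur = choose_sur_genes(ann, spec)
        return spec, ann, sur

    def test_simple_graph_invariants(self):
        spec, ann, sur = self._pieces()
        g = generate_ppi_network(ann, sur, spec)
        assert not any(u == v for u, v in g.edges)
        assert all(g.has_edge(v, u) for u, v in g.edges)

    def test_heavy_tailed_degrees(self):
        spec, ann, sur = self._pieces()
        g = generate_ppi_network(ann, sur, spec)
        degs = np.array([d for _v, d in g.degree()])
        assert degs.max() > 5 * np.median(degs)

    def test_planted_module_shortens_within_sur_paths(self):
        from rbpscape.network import group_pairwise_distances
        spec, ann, sur = self._pieces()
        g = generate_ppi_network(ann, sur, spec)
        d_sur, _ = group_pairwise_distances(g, sur)
        d_non, _ = group_pairwise_distances(g, set(ann.index) - sur)
        assert np.median(d_sur) < np.median(d_non)

    def test_noise_degree_coupling_hits_target_rho(self):
        spec, ann, sur = self._pieces(mad_degree_rho=0.6)
        g = generate_ppi_network(ann, sur, spec)
        deg = pd.Series(dict(g.degree()), dtype=float).loc[ann.index]
        rhos = []
        for sub in range(5):
            cv = couple_noise_to_degree(
                deg, spec, rng=np.random.default_rng(sub))
            rhos.append(spearmanr(cv, deg).statistic)
        assert abs(np.mean(rhos) - 0.6) < 0.1

    def test_zero_rho_uncoupled(self):
        spec, ann, sur = self._pieces(mad_degree_rho=0.0)
        g = generate_ppi_network(ann, sur, spec)
        deg = pd.Series(dict(g.degree()), dtype=float).loc[ann.index]
        cv = couple_noise_to_degree(deg, spec)
        assert abs(spearmanr(cv, deg).statistic) < 0.15


class TestComplexCatalog:
    def test_requested_number_of_complexes(self):
        spec = PlantSpec(n_genes=200, n_sur=10, seed=1)
        ann = generate_gene_universe(spec)
        cat = generate_complex_catalog(ann, 57, seed=1)
        assert len(cat) == 57
        assert all(len(m) >= 2 for m in cat["members"])

    def test_constant_size_distribution(self):
        spec = PlantSpec(n_genes=50, n_sur=5, seed=1)
        ann = generate_gene_universe(spec)
        cat = generate_complex_catalog(
            ann, 10, {"kind": "constant", "size": 2}, seed=2)
        assert all(len(m) == 2 for m in cat["members"])

    def test_deterministic(self):
        spec = PlantSpec(n_genes=50, n_sur=5, seed=1)
        ann = generate_gene_universe(spec)
        a = generate_complex_catalog(ann, 20, seed=3)
        b = generate_complex_catalog(ann, 20, seed=3)
        assert all(a.loc[c, "members"] == b.loc[c, "members"] for c in a.index)


class TestFullDataset:
    def test_same_seed_identical(self, small_spec):
        from rbpscape.synth import simulate_all
        a = simulate_all(small_spec, n_complexes=15)
        b = simulate_all(small_spec, n_complexes=15)
        assert a.sur_genes == b.sur_genes
        pd.testing.assert_frame_equal(a.healthy.values, b.healthy.values)
        assert set(a.network.edges) == set(b.network.edges)
        pd.testing.assert_frame_equal(a.survival.data, b.survival.data)

    def test_sur_recovery_on_small_study(self, small_dataset):
        from rbpscape import dysreg
        d = small_dataset
        ratios = {c: dysreg.patient_fold_changes(
            t, d.healthy.values[CANCER_TISSUE[c]])
            for c, (t, _n) in d.cohorts.items()}
        call = dysreg.classify_sur(dysreg.summarize_fold_changes(ratios))
        assert call.sur_genes == d.sur_genes
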