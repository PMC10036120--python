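import numpy as np
import pytest

from normbench.benchmarks import task3_bbs_regression
from normbench.features import vectorize_upper_triangle
from normbench.synthetic import (
    CohortConfig,
    SyntheticTruth,
    generate_cognition,
    generate_cohort,
    generate_connectome_runs,
)


@pytest.mark.parametrize(
    "bad",
    [
        {"n_sites": 0},
        {"subjects_per_site": 1},
        {"n_features": 0},
        {"patient_fraction": 1.5},
        {"patient_fraction": -0.1},
        {"site_offset_sd": -1.0},
        {"age_range_per_site": ((50.0, 20.0),), "n_sites": 1},
        {"hetero_feature_count": -1},
        {"hetero_feature_count": 99},
        {"patient_site_shares": (1.0,)},
    ],
)
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        CohortConfig(**bad)


def test_zero_patient_fraction_is_all_controls():
    cov, _, truth = generate_cohort(CohortConfig(patient_fraction=0.0, seed=1))
    assert (cov["group"] == "control").all()
    assert truth.per_patient_perturbations == {}


@pytest.mark.parametrize("fraction", [0.1, 0.25, 0.4])
def test_patient_count_matches_rounded_fraction(fraction):
    cfg = CohortConfig(patient_fraction=fraction, seed=2)
    cov, _, truth = generate_cohort(cfg)
    expected = int(round(fraction * cfg.n_subjects))
    assert int((cov["group"] == "patient").sum()) == expected
    assert len(truth.per_patient_perturbations) == expected


def test_generation_is_deterministic():
    cfg = CohortConfig(seed=3)
    cov1, feat1, _ = generate_cohort(cfg)
    cov2, feat2, _ = generate_cohort(cfg)
    assert cov1.to_csv() == cov2.to_csv()
    assert feat1.to_csv() == feat2.to_csv()


def test_perturbed_feature_indices_are_valid_columns():
    cfg = CohortConfig(seed=4)
    cov, feat, truth = generate_cohort(cfg)
    for subject, (idx, shifts) in truth.per_patient_perturbations.items():
        assert cov.loc[subject, "group"] == "patient"
        assert len(idx) == cfg.hetero_feature_count == len(shifts)
        assert all(0 <= j < cfg.n_features for j in idx)
    assert all(0 <= j < cfg.n_features for j in truth.group_effect_features)


def test_site_offsets_recovered_from_per_site_means():
    """Oracle check: per-site means of the de-trended features estimate the
    generating site offsets to within 3 standard errors."""
    cfg = CohortConfig(
        n_sites=4,
        subjects_per_site=500,
        n_features=3,
        site_offset_sd=2.0,
        noise_skew=0.0,
        patient_fraction=0.0,
        seed=5,
    )
    cov, feat, truth = generate_cohort(cfg)
    resid = feat.to_numpy() - truth.mean_function(cov["age"], cov["sex"], cov["qc"])
    for site in cfg.site_labels:
        rows = (cov["site"] == site).to_numpy()
        scale = truth.site_scales[site]
        sem = scale / np.sqrt(rows.sum())
        est = resid[rows].mean(axis=0)
        assert np.all(np.abs(est - truth.site_offsets[site]) < 3 * sem)


def test_control_residuals_normal_when_unskewed():
    from scipy.stats import skew

    cfg = CohortConfig(
        n_sites=2, subjects_per_site=1000, n_features=2, noise_skew=0.0,
        patient_fraction=0.0, seed=6,
    )
    cov, feat, truth = generate_cohort(cfg)
    resid = feat.to_numpy() - truth.mean_function(cov["age"], cov["sex"], cov["qc"])
    for site in cfg.site_labels:
        rows = (cov["site"] == site).to_numpy()
        unscaled = (resid[rows] - truth.site_offsets[site]) / truth.site_scales[site]
        assert np.all(np.abs(skew(unscaled, axis=0)) < 0.2)


def test_skewed_noise_is_standardized_but_skewed():
    from scipy.stats import skew

    cfg = CohortConfig(
        n_sites=1, subjects_per_site=4000, n_features=1, noise_skew=0.8,
        site_offset_sd=0.0, site_scale_sd=0.0, patient_fraction=0.0, seed=7,
    )
    cov, feat, truth = generate_cohort(cfg)
    resid = (feat.to_numpy() - truth.mean_function(cov["age"], cov["sex"], cov["qc"])).ravel()
    resid -= truth.site_offsets["site01"]
    assert abs(resid.mean()) < 0.06 and abs(resid.std() - 1.0) < 0.06
    assert skew(resid) > 0.3


def test_truth_json_roundtrip(tmp_path):
    _, _, truth = generate_cohort(CohortConfig(seed=8))
    truth.to_json(tmp_path / "truth.json")
    back = SyntheticTruth.from_json(tmp_path / "truth.json")
    assert np.allclose(back.amplitude, truth.amplitude)
    assert back.site_offsets == truth.site_offsets
    assert back.per_patient_perturbations == truth.per_patient_perturbations
    age = np.linspace(10, 80, 9)
    assert np.allclose(
        back.mean_function(age, np.zeros(9), np.ones(9)),
        truth.mean_function(age, np.zeros(9), np.ones(9)),
    )


class TestConnectomeRuns:
    def test_matrices_symmetric_unit_diagonal_bounded(self):
        cfg = CohortConfig(n_sites=2, subjects_per_site=5, seed=9)
        _, runs, _ = generate_connectome_runs(cfg, n_networks=6, n_runs=3)
        for mats in runs.values():
            assert len(mats) == 3
            for m in mats:
                assert np.array_equal(m, m.T)
                assert np.array_equal(np.diag(m), np.ones(6))
                off = m[~np.eye(6, dtype=bool)]
                assert np.all(np.abs(off) < 1.0)

    def test_zero_run_noise_reproduces_subject_truth(self):
        cfg = CohortConfig(n_sites=1, subjects_per_site=4, seed=10)
        _, runs, truth = generate_connectome_runs(cfg, n_networks=5, n_runs=2, run_noise_sd=0.0)
        for subject, mats in runs.items():
            for m in mats:
                assert np.allclose(m, truth.true_matrices[subject], atol=1e-12)

    def test_17_networks_vectorize_to_136_edges(self):
        cfg = CohortConfig(n_sites=1, subjects_per_site=2, seed=11)
        _, runs, _ = generate_connectome_runs(cfg, n_networks=17, n_runs=1)
        values, _ = vectorize_upper_triangle(next(iter(runs.values()))[0])
        assert len(values) == 136

    def test_too_few_networks_rejected(self):
        with pytest.raises(ValueError):
            generate_connectome_runs(CohortConfig(seed=1), n_networks=1)

    def test_covariates_match_structural_generator(self):
        cfg = CohortConfig(n_sites=2, subjects_per_site=10, seed=12)
        cov_struct, _, _ = generate_cohort(cfg)
        cov_conn, _, _ = generate_connectome_runs(cfg, n_networks=4)
        assert cov_struct.equals(cov_conn)


class TestCognition:
    def test_noiseless_cognition_collinear_with_projection(self):
        cfg = CohortConfig(cognition_noise_sd=0.0, seed=13)
        cov, feat, truth = generate_cohort(cfg)
        cog = generate_cognition(feat, truth, seed=99)
        proj = feat.to_numpy() @ truth.cognition_loadings
        assert abs(np.corrcoef(cog, proj)[0, 1] - 1.0) < 1e-12
        values = cog.to_numpy()
        assert abs(values.mean()) < 1e-12 and abs(values.std() - 1.0) < 1e-12

    def test_fixed_seed_reproduces_vector(self):
        cfg = CohortConfig(seed=14)
        _, feat, truth = generate_cohort(cfg)
        a = generate_cognition(feat, truth, seed=5)
        b = generate_cognition(feat, truth, seed=5)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_loading_length_mismatch_rejected(self):
        cfg = CohortConfig(seed=15)
        _, feat, truth = generate_cohort(cfg)
        truth.cognition_loadings = truth.cognition_loadings[:-1]
        with pytest.raises(ValueError, match="loadings length"):
            generate_cognition(feat, truth, seed=0)

    def test_null_loadings_give_no_predictable_signal(self):
        """With zero loadings cognition is pure noise: out-of-sample BBS
        prediction explains (essentially) none of its variance."""
        cfg = CohortConfig(
            n_sites=2, subjects_per_site=1000, n_features=20,
            patient_fraction=0.0, cognition_noise_sd=1.0, seed=16,
        )
        _, feat, truth = generate_cohort(cfg)
        truth.cognition_loadings = np.zeros(cfg.n_features)
        cog = generate_cognition(feat, truth, seed=17).to_numpy()
        x = feat.to_numpy()
        res = task3_bbs_regression(x[:1000], cog[:1000], x[1000:], cog[1000:], k=15)
        r2 = 1.0 - res.mse / cog[1000:].var()
        assert abs(r2) < 0.05
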