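"""Connectome abnormality tests: normative fit, z-scoring, regional means."""

import numpy as np
import pytest

from ezmap.connectivity import (
    ConnectivityMatrix,
    combat_harmonize,
    connection_abnormalities,
    fit_normative_connectome,
    regional_abnormality,
)
from ezmap.synthetic import (
    SimulationConfig,
    generate_connection_mask,
    generate_control_connectomes,
    generate_control_population_params,
    generate_parcellation,
)


def make_cm(weights, mask=None, subject_id="s", age=40.0, sex=0, batch="a", ids=None):
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if mask is None:
        mask = np.ones((n, n), dtype=bool)
        np.fill_diagonal(mask, False)
    ids = ids or [f"r{i}" for i in range(n)]
    return ConnectivityMatrix(subject_id, ids, w, mask, age, sex, batch)


def simple_cohort(rng, n=20, n_regions=6, age_slope=0.0, sex_effect=0.0, noise=0.02):
    """Cohort with flat baseline 0.5 and controllable covariate effects."""
    mask = np.ones((n_regions, n_regions), dtype=bool)
    np.fill_diagonal(mask, False)
    out = []
    for j in range(n):
        age = float(rng.uniform(20, 60))
        sex = int(rng.integers(0, 2))
        w = 0.5 + age_slope * (age - 40.0) + sex_effect * sex
        w = w + rng.normal(0, noise, (n_regions, n_regions))
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        out.append(make_cm(np.clip(w, 0, 1), mask, subject_id=f"c{j}", age=age, sex=sex))
    return out


class TestValidation:
    def test_asymmetric_weights_rejected(self):
        w = np.zeros((4, 4))
        w[0, 1] = 0.5  # transpose entry missing
        with pytest.raises(ValueError, match="asymmetric"):
            make_cm(w)

    def test_nonzero_diagonal_rejected(self):
        w = np.eye(4) * 0.3
        with pytest.raises(ValueError, match="diagonal"):
            make_cm(w)


class TestHarmonize:
    def test_single_batch_identity(self, rng):
        cohort = simple_cohort(rng, n=8)
        out = combat_harmonize(cohort)
        for a, b in zip(out, cohort):
            np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)

    def test_two_batch_shift_reduced_and_slope_kept(self, rng):
        slope = -0.002
        cohort = simple_cohort(rng, n=200, age_slope=slope)
        shifted = []
        for j, cm in enumerate(cohort):
            batch = "site_b" if j >= 100 else "site_a"
            w = cm.weights + (0.05 if batch == "site_b" else 0.0)
            np.fill_diagonal(w, 0.0)
            shifted.append(
                make_cm(np.clip(w, 0, 1), cm.present_mask, cm.subject_id, cm.age, cm.sex, batch)
            )
        out = combat_harmonize(shifted)

        def edges(cms):
            iu, ju = np.triu_indices(6, k=1)
            return np.stack([c.weights[iu, ju] for c in cms])

        gap_before = np.abs(
            edges(shifted[:100]).mean(0) - edges(shifted[100:]).mean(0)
        ).mean()
        gap_after = np.abs(edges(out[:100]).mean(0) - edges(out[100:]).mean(0)).mean()
        assert gap_after <= 0.1 * gap_before

        ages = np.array([c.age for c in out])
        x = np.c_[np.ones_like(ages), ages]
        fitted = np.linalg.lstsq(x, edges(out), rcond=None)[0][1].mean()
        assert abs(fitted - slope) <= 0.25 * abs(slope)


class TestNormativeFit:
    def test_requires_enough_controls(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            fit_normative_connectome(simple_cohort(rng, n=5))

    def test_null_covariates_recover_sample_mean(self, rng):
        cohort = simple_cohort(rng, n=40)
        model = fit_normative_connectome(cohort)
        assert np.abs(model.beta_age).max() < 5e-4
        iu, ju = np.triu_indices(6, k=1)
        sample_mean = np.stack([c.weights[iu, ju] for c in cohort]).mean(0)
        np.testing.assert_allclose(model.mu, sample_mean, atol=5e-3)

    def test_planted_age_slope_recovered(self):
        rng = np.random.default_rng(7)
        slope = -0.002
        cohort = simple_cohort(rng, n=96, age_slope=slope)
        model = fit_normative_connectome(cohort)
        assert np.abs(model.beta_age - slope).mean() < 5e-4

    def test_robust_fit_resists_outlier(self, rng):
        cohort = simple_cohort(rng, n=30)
        # corrupt one subject's connectome to the ceiling
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0.0)
        cohort[0] = make_cm(w, cohort[0].present_mask, "outlier", cohort[0].age, cohort[0].sex)
        model = fit_normative_connectome(cohort)
        iu, ju = np.triu_indices(6, k=1)
        plain_mean = np.stack([c.weights[iu, ju] for c in cohort]).mean(0)
        # robust centre stays nearer the clean 0.5 than the contaminated mean
        assert np.abs(model.mu - 0.5).mean() < np.abs(plain_mean - 0.5).mean()

    def test_constant_connection_flagged_degenerate(self, rng):
        cohort = simple_cohort(rng, n=15)
        for cm in cohort:
            cm.weights[0, 1] = cm.weights[1, 0] = 0.42
        model = fit_normative_connectome(cohort)
        assert model.degenerate.sum() == 1


class TestConnectionAbnormalities:
    def test_patient_at_control_mean_scores_zero(self, rng):
        cohort = simple_cohort(rng, n=30)
        model = fit_normative_connectome(cohort)
        iu, ju = np.triu_indices(6, k=1)
        w = np.zeros((6, 6))
        w[iu, ju] = model.mu
        w += w.T
        patient = make_cm(w, cohort[0].present_mask, "p", model.age_ref, 0, "a")
        # sex code 0 vs fractional sex_ref: undo the adjustment analytically
        patient_w = w.copy()
        patient_w[iu, ju] += (0 - model.sex_ref) * model.beta_sex
        patient_w[ju, iu] = patient_w[iu, ju]
        patient = make_cm(patient_w, cohort[0].present_mask, "p", model.age_ref, 0, "a")
        a = connection_abnormalities(patient, model)
        assert np.nanmax(np.abs(a.z)) < 1e-8

    def test_two_sigma_below_mean_scores_minus_two(self, rng):
        cohort = simple_cohort(rng, n=30)
        model = fit_normative_connectome(cohort)
        iu, ju = np.triu_indices(6, k=1)
        w = np.zeros((6, 6))
        w[iu, ju] = model.mu - 2.0 * model.sigma + (0 - model.sex_ref) * model.beta_sex
        w += w.T
        patient = make_cm(w, cohort[0].present_mask, "p", model.age_ref, 0, "a")
        a = connection_abnormalities(patient, model)
        iu2, ju2 = np.triu_indices(6, k=1)
        np.testing.assert_allclose(a.z[iu2, ju2], -2.0, atol=1e-8)

    def test_self_normalization_of_controls(self):
        config = SimulationConfig(n_regions=16, n_controls=96, seed=3)
        parc = generate_parcellation(config)
        mask = generate_connection_mask(config)
        params = generate_control_population_params(config, mask)
        controls = generate_control_connectomes(config, parc, mask, params)
        controls = combat_harmonize(controls)
        model = fit_normative_connectome(controls)
        z = np.stack(
            [
                connection_abnormalities(c, model).z[mask]
                for c in controls
            ]
        )  # (n_controls, n_directed_edges)
        mean_z = z.mean(axis=0)
        sd_z = z.std(axis=0, ddof=1)
        assert np.abs(mean_z).max() < 0.1
        assert sd_z.min() > 0.8 and sd_z.max() < 1.2

    def test_mask_mismatch_raises(self, rng):
        cohort = simple_cohort(rng, n=15)
        model = fit_normative_connectome(cohort)
        other_mask = cohort[0].present_mask.copy()
        other_mask[0, 1] = other_mask[1, 0] = False
        patient = make_cm(cohort[0].weights, other_mask)
        with pytest.raises(ValueError, match="mask"):
            connection_abnormalities(patient, model)


class TestRegionalAbnormality:
    def _map(self, z, mask, ids=None):
        from ezmap.connectivity import ConnectionAbnormalityMap

        n = z.shape[0]
        return ConnectionAbnormalityMap(
            subject_id="p",
            region_ids=ids or [f"r{i}" for i in range(n)],
            z=z,
            present_mask=mask,
        )

    def test_mean_of_two_incident_scores(self):
        z = np.full((3, 3), np.nan)
        mask = np.zeros((3, 3), dtype=bool)
        for (i, j), v in (((0, 1), -1.0), ((0, 2), -3.0)):
            z[i, j] = z[j, i] = v
            mask[i, j] = mask[j, i] = True
        reg = regional_abnormality(self._map(z, mask))
        assert reg.r[0] == pytest.approx(-2.0)
        assert reg.score[0] == pytest.approx(2.0)
        assert reg.n_connections[0] == 2

    def test_all_zero_map_gives_zero_regions(self):
        mask = ~np.eye(4, dtype=bool)
        z = np.zeros((4, 4))
        reg = regional_abnormality(self._map(z, mask))
        np.testing.assert_allclose(reg.r, 0.0)

    def test_matches_double_loop_oracle(self, rng):
        n = 6
        mask = ~np.eye(n, dtype=bool)
        z = rng.normal(size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        reg = regional_abnormality(self._map(z.copy(), mask))
        for k in range(n):
            vals = [z[k, j] for j in range(n) if j != k]
            assert reg.r[k] == pytest.approx(np.mean(vals))

    def test_region_without_connections_is_missing(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        z = np.full((3, 3), np.nan)
        z[0, 1] = z[1, 0] = 1.5
        reg = regional_abnormality(self._map(z, mask))
        assert np.isnan(reg.r[2]) and reg.n_connections[2] == 0

    def test_permutation_equivariance(self, rng):
        n = 5
        mask = ~np.eye(n, dtype=bool)
        z = rng.normal(size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0.0)
        reg = regional_abnormality(self._map(z.copy(), mask))
        perm = rng.permutation(n)
        zp = z[np.ix_(perm, perm)]
        ids = [f"r{i}" for i in perm]
        regp = regional_abnormality(self._map(zp, mask, ids=ids))
        for new_pos, old_idx in enumerate(perm):
            assert regp.r[new_pos] == pytest.approx(reg.r[old_idx])

    def test_lowering_one_weight_raises_that_regions_score(self, rng):
        cohort = simple_cohort(rng, n=30)
        model = fit_normative_connectome(cohort)
        patient = cohort[5]
        a1 = regional_abnormality(connection_abnormalities(patient, model))
        w = patient.weights.copy()
        w[0, 1] -= 0.1
        w[1, 0] -= 0.1
        patient2 = make_cm(
            w, patient.present_mask, "p2", patient.age, patient.sex, patient.batch
        )
        a2 = regional_abnormality(connection_abnormalities(patient2, model))
        assert a2.score[0] > a1.score[0]
        assert a2.score[1] > a1.score[1]
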