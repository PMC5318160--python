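"""Circular-response PLSR: closed-form recovery, deployment formula,
differential construction, and trait invariance."""

import numpy as np
import pandas as pd
import pytest

from circaphase import (
    ExpressionDataset,
    PLSRPhaseModel,
    aggregate_consecutive,
    angle_difference,
    build_differential_dataset,
    circular_r2,
    fit_plsr_phase,
    predict_phase,
    predict_phases,
)
from circaphase.plsr import differential_to_frames, predict_phase_from_z
from circaphase.preprocess import FeatureScaler

from conftest import noiseless_cosine_dataset


def _manual_model(wc, ws, wc0=0.0, ws0=0.0):
    features = [f"F{i}" for i in range(len(wc))]
    scaler = FeatureScaler(
        mean=pd.Series(0.0, index=features), sd=pd.Series(1.0, index=features)
    )
    return PLSRPhaseModel(
        mode="one_sample",
        features=features,
        scaler=scaler,
        latent_factors=1,
        coef_cos=np.asarray(wc, dtype=float),
        intercept_cos=wc0,
        coef_sin=np.asarray(ws, dtype=float),
        intercept_sin=ws0,
    )


class TestDeploymentFormula:
    def test_identity_map(self):
        model = _manual_model([1, 0], [0, 1])
        z = np.array([np.cos(np.deg2rad(45)), np.sin(np.deg2rad(45))])
        assert predict_phase_from_z(model, z) == pytest.approx(45.0)

    def test_quadrant_three(self):
        model = _manual_model([1, 0], [0, 1])
        assert predict_phase_from_z(model, np.array([-0.5, -0.5])) == pytest.approx(225.0)

    def test_intercept_only(self):
        model = _manual_model([0, 0], [0, 0], wc0=0.3, ws0=-0.3)
        for z in (np.zeros(2), np.ones(2), np.array([5.0, -2.0])):
            assert predict_phase_from_z(model, z) == pytest.approx(315.0)


class TestFitPlsrPhase:
    def test_noiseless_two_feature_toy_recovers_phases(self):
        """X = [cos theta, sin theta] predicts every phase near-exactly."""
        theta = np.arange(0.0, 360.0, 15.0)
        values = pd.DataFrame(
            np.vstack([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))]),
            index=["Fc", "Fs"],
            columns=[f"s{i}" for i in range(theta.size)],
        )
        meta = pd.DataFrame(
            {
                "participant_id": "p",
                "condition": "in_phase",
                "batch": "B0",
                "clock_time_h": theta / 15.0,
                "phase_deg": theta,
            },
            index=values.columns,
        )
        data = ExpressionDataset(values=values, samples=meta)
        model = fit_plsr_phase(data, latent_factors=2, n_features=2)
        preds = predict_phases(model, data)
        err = np.abs(angle_difference(preds.to_numpy(), theta))
        assert err.max() < 0.01

    def test_full_feature_fit_skips_ranking(self, small_cohort):
        data, _, _ = small_cohort
        m = fit_plsr_phase(data, latent_factors=3, n_features=data.n_features)
        assert len(m.features) == data.n_features

    def test_invalid_parameters(self, small_cohort):
        data, _, _ = small_cohort
        with pytest.raises(ValueError):
            fit_plsr_phase(data, latent_factors=0, n_features=10)
        with pytest.raises(ValueError):
            fit_plsr_phase(data, latent_factors=2, n_features=10**6)

    def test_deterministic_coefficients(self, small_cohort):
        data, _, _ = small_cohort
        m1 = fit_plsr_phase(data, latent_factors=3, n_features=40)
        m2 = fit_plsr_phase(data, latent_factors=3, n_features=40)
        assert m1.features == m2.features
        assert np.array_equal(m1.coef_cos, m2.coef_cos)
        assert np.array_equal(m1.coef_sin, m2.coef_sin)

    @pytest.mark.parametrize("n_features,tol", [(None, 1e-6), (40, 1.0)])
    def test_rotation_equivariance(self, small_cohort, n_features, tol):
        """Rotating every training phase by 90 degrees rotates every
        prediction by 90 degrees.

        Exact without feature selection (the PLS objective is invariant
        under orthogonal response rotations); with selection, near-tied
        loading ranks can swap borderline features, so the property holds
        only to a fraction of a degree.
        """
        data, _, _ = small_cohort
        n = n_features or data.n_features
        m1 = fit_plsr_phase(data, latent_factors=3, n_features=n)
        rotated = ExpressionDataset(
            values=data.values.copy(), samples=data.samples.copy()
        )
        rotated.samples["phase_deg"] = (rotated.samples["phase_deg"] + 90.0) % 360.0
        m2 = fit_plsr_phase(rotated, latent_factors=3, n_features=n)
        p1 = predict_phases(m1, data).to_numpy()
        p2 = predict_phases(m2, data).to_numpy()
        deltas = angle_difference(p2, p1)
        assert np.allclose(deltas, 90.0, atol=tol)

    def test_json_roundtrip_preserves_predictions(self, small_cohort, tmp_path):
        data, _, _ = small_cohort
        model = fit_plsr_phase(data, latent_factors=3, n_features=40)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = PLSRPhaseModel.from_json(path)
        s = data.values[data.sample_ids[0]]
        assert predict_phase(back, s) == pytest.approx(predict_phase(model, s))


class TestBuildDifferential:
    def _dataset(self, times, phases, participant="p1", cond="in_phase"):
        n = len(times)
        values = pd.DataFrame(
            np.arange(2 * n, dtype=float).reshape(2, n),
            index=["F0", "F1"],
            columns=[f"s{i}" for i in range(n)],
        )
        meta = pd.DataFrame(
            {
                "participant_id": participant,
                "condition": cond,
                "batch": "B0",
                "clock_time_h": times,
                "phase_deg": phases,
            },
            index=values.columns,
        )
        return ExpressionDataset(values=values, samples=meta)

    def test_eight_samples_three_hour_spacing(self):
        times = [0, 3, 6, 9, 12, 15, 18, 21]
        phases = [0, 45, 90, 135, 180, 225, 270, 315]
        obs = build_differential_dataset(self._dataset(times, phases))
        assert len(obs) == 4
        assert [(o.response_phase_deg, (o.response_phase_deg + 180) % 360)
                for o in obs] == [(0, 180), (45, 225), (90, 270), (135, 315)]

    def test_seven_samples_four_hour_spacing(self):
        times = [0, 4, 8, 12, 16, 20, 24]
        phases = [(15 * t) % 360 for t in times]
        obs = build_differential_dataset(self._dataset(times, phases))
        assert len(obs) == 4
        assert [o.sample1_id for o in obs] == ["s0", "s1", "s2", "s3"]

    def test_short_span_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no 12-h"):
            obs = build_differential_dataset(self._dataset([0, 3, 6], [0, 45, 90]))
        assert obs == []

    def test_delta_is_sample1_minus_sample2(self):
        times = [0, 12]
        obs = build_differential_dataset(self._dataset(times, [0, 180]))
        d = obs[0].delta_values
        assert d["F0"] == -1.0  # 0 - 1
        assert d["F1"] == -1.0  # 2 - 3


def _shift_per_participant(data, offsets):
    shifted_values = data.values.copy()
    for sid in data.sample_ids:
        shifted_values[sid] += offsets[data.samples.loc[sid, "participant_id"]]
    return ExpressionDataset(values=shifted_values, samples=data.samples.copy())


class TestTraitInvariance:
    def test_exact_offsets_cancel_bitwise(self, small_cohort):
        """When the participant offsets add exactly (integer-valued data),
        every differential observation, coefficient and prediction is
        bit-identical: the offsets cancel before any scaling."""
        data, _, _ = small_cohort
        int_data = ExpressionDataset(
            values=np.round(data.values * 4), samples=data.samples.copy()
        )
        offsets = {p: float(7 * i - 12) for i, p in enumerate(int_data.participants)}
        shifted = _shift_per_participant(int_data, offsets)

        d1 = differential_to_frames(build_differential_dataset(int_data))
        d2 = differential_to_frames(build_differential_dataset(shifted))
        assert d1.values.equals(d2.values)

        m1 = fit_plsr_phase(build_differential_dataset(int_data), 3, 40)
        m2 = fit_plsr_phase(build_differential_dataset(shifted), 3, 40)
        assert np.array_equal(m1.coef_cos, m2.coef_cos)
        assert predict_phases(m1, d1).equals(predict_phases(m2, d2))

    def test_float_offsets_cancel_to_rounding_and_change_one_sample(
        self, small_cohort
    ):
        """Arbitrary float offsets cancel in the differential pipeline up to
        one rounding ulp of the addition, while one-sample predictions are
        visibly perturbed."""
        data, _, _ = small_cohort
        rng = np.random.default_rng(31)
        offsets = {p: rng.normal(0, 5) for p in data.participants}
        shifted = _shift_per_participant(data, offsets)

        d1 = differential_to_frames(build_differential_dataset(data))
        d2 = differential_to_frames(build_differential_dataset(shifted))
        assert np.allclose(d1.values, d2.values, atol=1e-12)

        m1 = fit_plsr_phase(build_differential_dataset(data), 3, 40)
        m2 = fit_plsr_phase(build_differential_dataset(shifted), 3, 40)
        p1 = predict_phases(m1, d1).to_numpy()
        p2 = predict_phases(m2, d2).to_numpy()
        assert np.abs(angle_difference(p2, p1)).max() < 1e-6

        one1 = fit_plsr_phase(data, 3, 40)
        one2 = fit_plsr_phase(shifted, 3, 40)
        q1 = predict_phases(one1, data).to_numpy()
        q2 = predict_phases(one2, shifted).to_numpy()
        assert np.abs(angle_difference(q2, q1)).max() > 1.0


class TestAggregateConsecutive:
    def _cosine_model_and_data(self):
        data = noiseless_cosine_dataset(n_participants=3, n_features=8)
        model = fit_plsr_phase(data, latent_factors=2, n_features=8)
        return model, data

    def test_wrap_around_mean(self):
        model, data = self._cosine_model_and_data()
        # pick two samples; predictions are near-perfect so the aggregated
        # error against the observed directional mean is tiny
        sids = data.sample_ids[:2]
        res = aggregate_consecutive(
            model,
            data.values[sids],
            data.samples.loc[sids, "phase_deg"].to_numpy(),
        )
        assert abs(res["error_deg"]) < 0.5

    def test_directional_mean_of_three(self):
        model, data = self._cosine_model_and_data()
        sids = data.sample_ids[:3]
        res = aggregate_consecutive(
            model,
            data.values[sids],
            data.samples.loc[sids, "phase_deg"].to_numpy(),
        )
        from circaphase import directional_mean

        assert res["predicted_mean_deg"] == pytest.approx(
            directional_mean(res["predicted_phases_deg"])
        )

    def test_rejects_wrong_count(self):
        model, data = self._cosine_model_and_data()
        with pytest.raises(ValueError):
            aggregate_consecutive(
                model, data.values[data.sample_ids[:1]], [0.0]
            )


def test_noiseless_cohort_lopo_r2_near_one():
    """With zero noise and several informative features, leave-one-
    participant-out predictions are essentially exact."""
    from circaphase import cv_evaluate

    data = noiseless_cosine_dataset(n_participants=5, n_features=12)
    res = cv_evaluate("plsr", {"latent_factors": 2, "n_features": 12}, data)
    assert res["r2"] >= 0.99
    errs = angle_difference(
        res["predicted"].to_numpy(), res["observed"].to_numpy()
    )
    assert np.abs(errs).mean() < 5.0
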