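import json

import numpy as np
import pytest

from thermocal import (
    AnnModel,
    AnnTrainConfig,
    CalibrationDataset,
    CalibrationRecord,
    ModelForm,
    PolynomialModel,
    SensorSimConfig,
    SplitSpec,
    ThermalFrame,
    apply_model,
    fit_polynomial,
    load_model,
    predict_ann,
    predict_polynomial,
    save_model,
    simulate_blackbody_campaign,
    split_dataset,
    train_ann,
    validation_rmse,
)
from thermocal.calibrate import term_names
from thermocal.errors import FormatError, SingularFitError
from thermocal.io import CAL_LABEL, VAL_LABEL


def _grid_dataset(tbbs, tcs, fn):
    records = []
    for i, tbb in enumerate(tbbs):
        for j, tc in enumerate(tcs):
            dl = fn(tbb, tc)
            records.append(CalibrationRecord(f"g{i}_{j}", dl, tc, tbb))
    return CalibrationDataset(tuple(records))


class TestSplit:
    def test_counts_and_coverage(self):
        # 100 records over 10 setpoints: stratification forces every
        # setpoint into both subsets and 65 calibration labels overall
        tbbs = np.repeat(np.arange(10) * 5.0 + 5.0, 10)
        recs = tuple(
            CalibrationRecord(f"r{i}", 1000.0 + i, 20.0, t) for i, t in enumerate(tbbs)
        )
        ds = CalibrationDataset(recs)
        out = split_dataset(ds, SplitSpec(seed=1))
        labels = np.array(out.split_labels)
        assert (labels == CAL_LABEL).sum() == 65
        for t in np.unique(tbbs):
            sel = tbbs == t
            assert CAL_LABEL in labels[sel] and VAL_LABEL in labels[sel]

    def test_deterministic_given_seed(self):
        ds = simulate_blackbody_campaign(SensorSimConfig(seed=3))
        a = split_dataset(ds, SplitSpec(seed=5))
        b = split_dataset(ds, SplitSpec(seed=5))
        assert a.split_labels == b.split_labels

    def test_266_records_both_subsets_span_full_range(self, rng):
        # independent enumeration: total calibration count must be
        # round(0.65*266) +- 1 and each subset's TBB range the full range
        tbbs = rng.choice(np.arange(5.0, 66.0, 5.0), size=266)
        recs = tuple(
            CalibrationRecord(f"r{i}", float(rng.uniform(4000, 10000)),
                              float(rng.uniform(5, 31)), float(t))
            for i, t in enumerate(tbbs)
        )
        out = split_dataset(CalibrationDataset(recs), SplitSpec(seed=2))
        n_cal = sum(1 for lab in out.split_labels if lab == CAL_LABEL)
        assert n_cal in {172, 173, 174}
        cal, val = out.subset(CAL_LABEL), out.subset(VAL_LABEL)
        assert cal.tbb.min() == val.tbb.min() == 5.0
        assert cal.tbb.max() == val.tbb.max() == 65.0

    def test_single_record_bin_goes_to_calibration_with_warning(self):
        recs = tuple(
            CalibrationRecord(f"r{i}", 1000.0 + i, 20.0, t)
            for i, t in enumerate([10.0] * 5 + [20.0] * 5 + [30.0])
        )
        with pytest.warns(UserWarning, match="single record"):
            out = split_dataset(CalibrationDataset(recs), SplitSpec(seed=0))
        assert out.split_labels[-1] == CAL_LABEL


class TestFitPolynomial:
    def test_exact_recovery_of_linear_truth(self):
        ds = _grid_dataset(
            (20.0, 40.0, 60.0), (2.0, 4.0),
            lambda tbb, tc: (tbb - 1 - 0.5 * tc) / 0.001,
        )
        model = fit_polynomial(ds, ModelForm.P1)
        np.testing.assert_allclose(model.coeffs, (1.0, 0.001, 0.5), atol=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        recs = tuple(
            CalibrationRecord(f"r{i}", float(rng.uniform(4000, 10000)),
                              float(rng.uniform(5, 31)), float(rng.uniform(5, 65)))
            for i in range(12)
        )
        ds = CalibrationDataset(recs)
        model = fit_polynomial(ds, ModelForm.P2)
        # independent normal-equations solve on explicitly built columns
        dl, tc, y = ds.dl, ds.tc, ds.tbb
        X = np.column_stack(
            [np.ones_like(dl), dl, tc, dl**2, dl * tc, tc**2]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.coeffs, beta, rtol=1e-6, atol=1e-6)

    def test_constant_tc_raises_singular(self):
        recs = tuple(
            CalibrationRecord(f"r{i}", 1000.0 * (i + 1), 20.0, 10.0 * (i + 1))
            for i in range(3)
        )
        with pytest.raises(SingularFitError) as exc:
            fit_polynomial(CalibrationDataset(recs), ModelForm.P1)
        assert any("p0" in t for t in exc.value.collinear_terms)

    def test_uses_calibration_subset_when_labelled(self, split_campaign):
        model = fit_polynomial(split_campaign, ModelForm.P2)
        cal_only = fit_polynomial(split_campaign.subset(CAL_LABEL), ModelForm.P2)
        np.testing.assert_allclose(model.coeffs, cal_only.coeffs, rtol=1e-12)

    def test_nested_forms_training_rmse_monotone(self, split_campaign):
        cal = split_campaign.subset(CAL_LABEL)
        rmses = []
        for form in (ModelForm.P1, ModelForm.P2, ModelForm.P3, ModelForm.P4):
            m = fit_polynomial(cal, form)
            resid = cal.tbb - m.predict(cal.dl, cal.tc)
            rmses.append(np.sqrt(np.mean(resid**2)))
        assert all(b <= a + 1e-9 for a, b in zip(rmses, rmses[1:]))


class TestPredictPolynomial:
    def test_hand_arithmetic(self):
        m = PolynomialModel(ModelForm.P1, (1.0, 0.001, 0.5))
        assert predict_polynomial(m, 1000.0, 20.0) == pytest.approx(12.0)

    def test_constant_model(self):
        m = PolynomialModel(ModelForm.P2, (7.0, 0, 0, 0, 0, 0))
        assert predict_polynomial(m, 12345.0, -3.0) == pytest.approx(7.0)

    def test_residuals_match_term_by_term_evaluation(self, small_dataset):
        m = fit_polynomial(small_dataset, ModelForm.P2)
        names = term_names(ModelForm.P2)
        coeffs = m.coefficients
        for rec in small_dataset.records:
            expected = sum(
                coeffs[f"p{i}{j}"] * rec.dl**i * rec.tc**j
                for (i, j), nm in zip(
                    ((0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)), names
                )
            )
            assert m.predict(rec.dl, rec.tc) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_input_rejected(self):
        m = PolynomialModel(ModelForm.LINEAR_DL, (0.0, 1.0))
        with pytest.raises(ValueError):
            predict_polynomial(m, np.nan, 20.0)


class TestAnn:
    def test_learns_linear_response(self):
        # dense grid with an exactly planar response; interleaved labels so
        # validation interpolates rather than extrapolates
        recs = []
        for i, tbb in enumerate(np.linspace(5, 65, 7)):
            for j, tc in enumerate(np.linspace(8, 30, 5)):
                recs.append(
                    CalibrationRecord(f"r{i}_{j}", 1000.0 + 80.0 * tbb - 5.0 * tc, tc, tbb)
                )
        labels = tuple(CAL_LABEL if k % 3 != 1 else VAL_LABEL for k in range(len(recs)))
        ds = CalibrationDataset(tuple(recs), labels)
        model = train_ann(
            ds, AnnTrainConfig(hidden_size=4, seed=0, max_epochs=30000, patience=5000)
        )
        assert validation_rmse(ds, model) < 0.05

    def test_deterministic_given_seed(self, split_campaign):
        cfg = AnnTrainConfig(seed=11, max_epochs=300)
        a = train_ann(split_campaign, cfg)
        b = train_ann(split_campaign, cfg)
        np.testing.assert_array_equal(a.input_weights, b.input_weights)
        np.testing.assert_array_equal(a.output_weights, b.output_weights)
        assert a.output_bias == b.output_bias

    def test_beats_dl_only_baseline_on_nonlinear_sensor(self):
        ds = simulate_blackbody_campaign(SensorSimConfig(noise_sd=5.0, seed=4))
        split = split_dataset(ds, SplitSpec(seed=4))
        ann = train_ann(split, AnnTrainConfig(seed=4, max_epochs=2000))
        lin = fit_polynomial(split, ModelForm.LINEAR_DL)
        assert validation_rmse(split, ann) < validation_rmse(split, lin)

    def test_one_hidden_unit_closed_form(self):
        model = AnnModel(
            hidden_size=1,
            input_weights=np.array([[0.3], [-0.2]]),
            input_bias=np.array([0.1]),
            output_weights=np.array([2.0]),
            output_bias=0.5,
            input_center=np.array([5000.0, 20.0]),
            input_scale=np.array([1000.0, 10.0]),
            output_center=30.0,
            output_scale=15.0,
        )
        dl, tc = 6000.0, 25.0
        s = 0.3 * (dl - 5000) / 1000 - 0.2 * (tc - 20) / 10 + 0.1
        expected = (2.0 * np.tanh(s) + 0.5) * 15.0 + 30.0
        assert predict_ann(model, dl, tc) == pytest.approx(expected, abs=1e-12)

    def test_zero_weights_return_output_center(self):
        model = AnnModel(
            hidden_size=3,
            input_weights=np.zeros((2, 3)),
            input_bias=np.zeros(3),
            output_weights=np.zeros(3),
            output_bias=0.0,
            input_center=np.zeros(2),
            input_scale=np.ones(2),
            output_center=42.0,
            output_scale=5.0,
        )
        assert predict_ann(model, 9999.0, -5.0) == pytest.approx(42.0)

    def test_forward_pass_matches_independent_implementation(self, split_campaign, rng):
        model = train_ann(split_campaign, AnnTrainConfig(seed=2, max_epochs=200))
        dl = rng.uniform(4000, 10000, 1000)
        tc = rng.uniform(5, 31, 1000)
        # reimplemented forward pass, scalar loop
        got = predict_ann(model, dl, tc)
        for i in range(0, 1000, 97):
            x = np.array([dl[i], tc[i]])
            xs = (x - model.input_center) / model.input_scale
            acc = model.output_bias
            for j in range(model.hidden_size):
                s = model.input_bias[j] + xs[0] * model.input_weights[0, j] \
                    + xs[1] * model.input_weights[1, j]
                acc += model.output_weights[j] * np.tanh(s)
            expected = acc * model.output_scale + model.output_center
            assert got[i] == pytest.approx(expected, abs=1e-10)


class TestApplyModel:
    def test_constant_frame(self):
        m = PolynomialModel(ModelForm.P1, (0.0, 0.001, 0.1))
        frame = ThermalFrame(np.full((4, 4), 5000, dtype=np.uint16), 20.0, "f1")
        tmap = apply_model(frame, m)
        np.testing.assert_allclose(tmap.temps, 7.0)
        assert "P1" in tmap.provenance and "f1" in tmap.provenance

    def test_shape_preserved(self, rng):
        m = PolynomialModel(ModelForm.LINEAR_DL, (0.0, 0.001))
        frame = ThermalFrame(
            rng.integers(0, 16000, (64, 51)).astype(np.uint16), 22.0
        )
        assert apply_model(frame, m).temps.shape == (64, 51)

    def test_matches_per_pixel_loop(self, rng):
        m = PolynomialModel(
            ModelForm.P2, (1.0, 2e-3, 0.1, -1e-8, 1e-6, -1e-3)
        )
        px = rng.integers(3000, 12000, (8, 9)).astype(np.uint16)
        frame = ThermalFrame(px, 24.0)
        tmap = apply_model(frame, m)
        for r in range(8):
            for c in range(9):
                assert tmap.temps[r, c] == pytest.approx(
                    m.predict(float(px[r, c]), 24.0), abs=1e-9
                )


class TestSerialization:
    def test_polynomial_round_trip(self, small_dataset, tmp_path):
        m = fit_polynomial(small_dataset, ModelForm.P2)
        save_model(m, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert back.form == ModelForm.P2
        np.testing.assert_allclose(back.coeffs, m.coeffs, rtol=0, atol=0)

    def test_ann_round_trip_predictions(self, split_campaign, tmp_path, rng):
        m = train_ann(split_campaign, AnnTrainConfig(seed=9, max_epochs=200))
        save_model(m, tmp_path / "ann.json")
        back = load_model(tmp_path / "ann.json")
        dl = rng.uniform(4000, 10000, 100)
        tc = rng.uniform(5, 31, 100)
        np.testing.assert_allclose(
            predict_ann(back, dl, tc), predict_ann(m, dl, tc), atol=1e-12
        )

    def test_corrupted_json_raises_format_error(self, tmp_path):
        (tmp_path / "bad.json").write_text("{not json")
        with pytest.raises(FormatError):
            load_model(tmp_path / "bad.json")

    def test_unknown_form_tag_rejected(self, tmp_path):
        (tmp_path / "odd.json").write_text(json.dumps({"form": "P9"}))
        with pytest.raises(FormatError, match="P9"):
            load_model(tmp_path / "odd.json")
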