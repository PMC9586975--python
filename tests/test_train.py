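import numpy as np
import pytest

from stackbox import (
    ConfigurationError,
    TrainingError,
    build_coordinate_datasets,
    fit,
    impute_and_filter,
    make_regressor,
    match_to_ground_truth,
)
from stackbox.train import COORDS, OLSRegressor
from conftest import make_det, make_gt

ROSTER = ["A", "B", "C"]


def three_model_fixture():
    """One GT matched by A (IoU .8) and C (IoU .6) but missed by B,
    one GT missed by everyone, one GT matched by all three."""
    gt_partial = make_gt(0, 0, 100, 100, image=0)
    gt_orphan = make_gt(300, 300, 400, 400, image=0)
    gt_full = make_gt(0, 0, 100, 100, image=1)
    det_a = make_det(0, 0, 100, 80, 0.9, model="A", image=0)  # IoU 0.8
    det_c = make_det(0, 0, 100, 60, 0.8, model="C", image=0)  # IoU 0.6
    dets = {
        "A": [det_a, make_det(0, 0, 100, 100, 0.9, "A", image=1)],
        "B": [make_det(500, 500, 510, 510, 0.9, "B", image=0),
              make_det(0, 0, 100, 100, 0.9, "B", image=1)],
        "C": [det_c, make_det(0, 0, 100, 100, 0.9, "C", image=1)],
    }
    return [gt_partial, gt_orphan, gt_full], dets, det_a, det_c


class TestMatching:
    def test_all_models_match_when_overlapping(self):
        gts = [make_gt(0, 0, 10, 10)]
        dets = {m: [make_det(1, 1, 11, 11, 0.9, model=m)] for m in ROSTER}
        (row,) = match_to_ground_truth(gts, dets, ROSTER)
        assert all(d is not None for d in row.slots)
        assert all(v == pytest.approx(81 / 119) for v in row.ious)

    def test_disjoint_model_leaves_slot_empty(self):
        gts = [make_gt(0, 0, 10, 10)]
        dets = {
            "A": [make_det(0, 0, 10, 10, 0.9, "A")],
            "B": [make_det(50, 50, 60, 60, 0.9, "B")],
            "C": [make_det(1, 1, 11, 11, 0.9, "C")],
        }
        (row,) = match_to_ground_truth(gts, dets, ROSTER)
        assert row.slots[1] is None and row.ious[1] == 0.0

    def test_non_exclusive_matching(self):
        # one detection straddling two GTs serves both rows
        gts = [make_gt(0, 0, 10, 10), make_gt(6, 0, 16, 10)]
        shared = make_det(2, 0, 12, 10, 0.9, "A")
        dets = {"A": [shared], "B": [], "C": []}
        rows = match_to_ground_truth(gts, dets, ROSTER)
        # brute-force argmax over all (gt, det) IoU pairs picks the same det
        assert rows[0].slots[0] == shared and rows[1].slots[0] == shared

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            match_to_ground_truth([], {"Z": []}, ROSTER)


class TestImputation:
    def test_missing_slot_filled_from_highest_iou_match(self):
        gts, dets, det_a, det_c = three_model_fixture()
        rows = impute_and_filter(match_to_ground_truth(gts, dets, ROSTER))
        assert len(rows) == 2  # orphan GT dropped
        partial = rows[0]
        assert partial.fill_flags == (False, True, False)
        assert partial.slots[1] == det_a  # A's det: highest IoU (0.8 > 0.6)
        assert partial.slots[2] == det_c

    def test_fully_matched_row_unchanged(self):
        gts, dets, *_ = three_model_fixture()
        rows = impute_and_filter(match_to_ground_truth(gts, dets, ROSTER))
        full = rows[1]
        assert full.fill_flags == (False, False, False)
        assert all(d.box == full.target_box for d in full.slots)

    def test_imputation_never_invents_coordinates(self):
        gts, dets, *_ = three_model_fixture()
        rows = impute_and_filter(match_to_ground_truth(gts, dets, ROSTER))
        for row in rows:
            matched = {d.box.coords for d, f in zip(row.slots, row.fill_flags) if not f}
            for d in row.slots:
                assert d.box.coords in matched


class TestCoordinateDatasets:
    def test_shapes_and_alignment(self):
        gts = [make_gt(i * 50, 0, i * 50 + 20, 20, image=i) for i in range(10)]
        dets = {m: [make_det(i * 50, 0, i * 50 + 20, 20, 0.9, m, image=i) for i in range(10)]
                for m in ROSTER}
        rows = impute_and_filter(match_to_ground_truth(gts, dets, ROSTER))
        ds = build_coordinate_datasets(rows)
        for c in COORDS:
            X, y = ds[c]
            assert X.shape == (10, 3) and y.shape == (10,)

    def test_predictor_row_construction(self):
        gt = make_gt(4, 6, 19, 21)
        dets = {m: [make_det(5, 5, 20, 20, 0.9, m)] for m in ROSTER}
        rows = impute_and_filter(match_to_ground_truth([gt], dets, ROSTER))
        X, y = build_coordinate_datasets(rows)["x_min"]
        assert X.tolist() == [[5, 5, 5]] and y.tolist() == [4]

    def test_roster_permutation_permutes_columns(self):
        gts = [make_gt(10, 10, 60, 60)]
        dets = {m: [make_det(10 + i, 10, 60 + i, 60, 0.9, m)] for i, m in enumerate(ROSTER)}
        ds1 = build_coordinate_datasets(
            impute_and_filter(match_to_ground_truth(gts, dets, ROSTER)))
        perm = ["C", "A", "B"]
        ds2 = build_coordinate_datasets(
            impute_and_filter(match_to_ground_truth(gts, dets, perm)))
        for c in COORDS:
            assert ds2[c][0].tolist() == [[ds1[c][0][0][2], ds1[c][0][0][0], ds1[c][0][0][1]]]

    def test_empty_rows_error(self):
        with pytest.raises(TrainingError):
            build_coordinate_datasets([])


class TestFit:
    def _identity_data(self, n=20):
        rng = np.random.default_rng(0)
        gts, dets = [], {m: [] for m in ROSTER}
        for i in range(n):
            x0, y0 = rng.uniform(0, 500, 2)
            w, h = rng.uniform(20, 100, 2)
            gts.append(make_gt(x0, y0, x0 + w, y0 + h, image=i))
            for m in ROSTER:
                dets[m].append(make_det(x0, y0, x0 + w, y0 + h, 0.9, m, image=i))
        return gts, dets

    def test_identity_inputs_reproduced(self):
        gts, dets = self._identity_data()
        model = fit(gts, dets, ROSTER, regressor_kind="lr")
        ds = build_coordinate_datasets(
            impute_and_filter(match_to_ground_truth(gts, dets, ROSTER)))
        for c in COORDS:
            X, y = ds[c]
            assert model.regressors[c].predict(X) == pytest.approx(y, abs=1e-9)

    def test_lr_corrects_constant_shift(self):
        gts, dets = self._identity_data(50)
        shifted = {
            "A": [make_det(d.box.x_min + 5, d.box.y_min, d.box.x_max, d.box.y_max,
                           0.9, "A", d.image_id) for d in dets["A"]],
            "B": dets["B"],
            "C": dets["C"],
        }
        model = fit(gts, shifted, ROSTER, regressor_kind="lr")
        ds = build_coordinate_datasets(
            impute_and_filter(match_to_ground_truth(gts, shifted, ROSTER)))
        X, y = ds["x_min"]
        resid = model.regressors["x_min"].predict(X) - y
        assert np.abs(resid).max() < 1e-8

    def test_zero_noise_rmse_below_tolerance(self):
        gts, dets = self._identity_data(100)
        model = fit(gts, dets, ROSTER)
        ds = build_coordinate_datasets(
            impute_and_filter(match_to_ground_truth(gts, dets, ROSTER)))
        for c in COORDS:
            X, y = ds[c]
            rmse = float(np.sqrt(np.mean((model.regressors[c].predict(X) - y) ** 2)))
            assert rmse < 1e-6

    def test_single_model_rejected(self):
        gts, dets = self._identity_data(5)
        with pytest.raises(ConfigurationError):
            fit(gts, {"A": dets["A"]}, ["A"])

    def test_unknown_regressor_rejected(self):
        gts, dets = self._identity_data(5)
        with pytest.raises(ConfigurationError):
            fit(gts, dets, ROSTER, regressor_kind="deep-net")

    @pytest.mark.parametrize("kind", ["adaboost", "rf", "gb"])
    def test_tree_backends_fit_and_predict(self, kind):
        gts, dets = self._identity_data(30)
        model = fit(gts, dets, ROSTER, regressor_kind=kind, seed=3)
        ds = build_coordinate_datasets(
            impute_and_filter(match_to_ground_truth(gts, dets, ROSTER)))
        X, _ = ds["x_min"]
        pred = model.regressors["x_min"].predict(X)
        assert np.all(np.isfinite(pred))


class TestOLS:
    def test_recovers_affine_map_with_standard_errors(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 600, size=500)
        y = 1.03 * x - 4.0 + rng.normal(0, 2.0, size=500)
        reg = OLSRegressor().fit(x[:, None], y)
        se_b, se_a = reg.standard_errors_
        assert abs(reg.coef_[0] - 1.03) < 3 * se_a
        assert abs(reg.intercept_ + 4.0) < 3 * se_b

    def test_predict_before_fit_raises(self):
        with pytest.raises(TrainingError):
            OLSRegressor().predict(np.zeros((2, 3)))


def test_model_roundtrip_via_json(tmp_path):
    gts = [make_gt(i * 30, 10, i * 30 + 20, 40, image=i) for i in range(10)]
    dets = {m: [make_det(i * 30 + 1, 11, i * 30 + 21, 41, 0.9, m, image=i) for i in range(10)]
            for m in ROSTER}
    model = fit(gts, dets, ROSTER)
    path = tmp_path / "model.json"
    model.save(path)
    loaded = type(model).load(path)
    assert loaded.roster == model.roster and loaded.regressor_kind == "lr"
    X = np.array([[10.0, 11.0, 12.0]])
    for c in COORDS:
        assert loaded.regressors[c].predict(X) == pytest.approx(model.regressors[c].predict(X))


def test_make_regressor_is_seeded():
    r1 = make_regressor("rf", seed=5)
    assert r1.random_state == 5
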