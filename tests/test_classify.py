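import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, confusion_matrix as sk_confusion

import genpol as g
from genpol.classify import (ClassifierConfig, FeatureStack, confusion_matrix,
                             trend_flags)
from genpol.exceptions import DomainError


def _two_class_mask(shape=(40, 40)):
    """Two labeled blocks with two parcels each, split train/verify."""
    labels = np.zeros(shape, np.int32)
    parcels = np.zeros(shape, np.int32)
    blocks = [((slice(0, 20), slice(0, 20)), 1, 1),
              ((slice(0, 20), slice(20, 40)), 1, 2),
              ((slice(20, 40), slice(0, 20)), 2, 3),
              ((slice(20, 40), slice(20, 40)), 2, 4)]
    for sl, cid, pid in blocks:
        labels[sl] = cid
        parcels[sl] = pid
    split = {1: "train", 2: "verify", 3: "train", 4: "verify"}
    return g.LabelMask(labels, ["a", "b"], parcel_ids=parcels, split=split)


class TestDifferenceDegree:
    def test_identical_distributions_score_zero(self):
        mask = _two_class_mask()
        feat = np.ones(mask.shape)
        assert g.difference_degree(feat, mask, 1, 2) == 0.0

    def test_unit_separation_formula(self, rng):
        mask = _two_class_mask()
        feat = np.zeros(mask.shape)
        a = rng.normal(0.0, np.sqrt(0.5), (20, 20))
        b = rng.normal(1.0, np.sqrt(0.5), (20, 20))
        feat[:20, :20], feat[20:, :20] = a, b
        feat[:20, 20:], feat[20:, 20:] = a, b
        va, vb = feat[mask.class_mask(1, "train")], \
            feat[mask.class_mask(2, "train")]
        expected = abs(va.mean() - vb.mean()) / np.sqrt(va.var() + vb.var())
        got = g.difference_degree(feat, mask, 1, 2)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(1.0, abs=0.15)

    def test_affine_invariance(self, rng):
        mask = _two_class_mask()
        feat = rng.normal(0, 1, mask.shape) + (mask.labels == 2) * 0.8
        base = g.difference_degree(feat, mask, 1, 2)
        rescaled = g.difference_degree(-3.0 * feat + 17.0, mask, 1, 2)
        assert rescaled == pytest.approx(base, rel=1e-12)

    def test_empty_class_named_in_error(self):
        mask = _two_class_mask()
        mask.labels[mask.labels == 2] = 0
        with pytest.raises(DomainError, match="'b'"):
            g.difference_degree(np.ones(mask.shape), mask, 1, 2)


class TestFeatureSelection:
    def _stack(self, rng, signal_name="alpha_B_1103"):
        mask = _two_class_mask()
        feats = {}
        for name in ["alpha_B_0612", "dalpha_B_0730", signal_name]:
            feats[name] = rng.normal(0, 1, mask.shape)
        feats[signal_name] += (mask.labels == 2) * 5.0
        return FeatureStack(feats, dates=["0612", "0730", "1103"],
                            mode="pi4"), mask

    def test_single_separating_feature_ranked_first(self, rng):
        stack, mask = self._stack(rng)
        names = g.select_optimal_features(stack, mask, 1, 2, k=1)
        assert names == ["alpha_B_1103"]

    def test_k_equal_to_stack_size_is_permutation(self, rng):
        stack, mask = self._stack(rng)
        names = g.select_optimal_features(stack, mask, 1, 2, k=3)
        assert sorted(names) == sorted(stack.names)

    def test_ranking_invariant_to_feature_order(self, rng):
        stack, mask = self._stack(rng)
        reordered = FeatureStack(dict(reversed(list(stack.features.items()))),
                                 stack.dates, stack.mode)
        a = g.rank_features(stack, mask, 1, 2).ranking
        b = g.rank_features(reordered, mask, 1, 2).ranking
        assert a == b

    def test_bad_k_rejected(self, rng):
        stack, mask = self._stack(rng)
        with pytest.raises(DomainError):
            g.select_optimal_features(stack, mask, 1, 2, k=0)
        with pytest.raises(DomainError):
            g.select_optimal_features(stack, mask, 1, 2, k=99)


class TestSvmClassification:
    def _gaussian_stack(self, rng, sep=6.0):
        mask = _two_class_mask()
        f1 = rng.normal(0, 1, mask.shape) + (mask.labels == 2) * sep
        f2 = rng.normal(0, 1, mask.shape) - (mask.labels == 2) * sep
        return FeatureStack({"f1": f1, "f2": f2}, ["d0"], "fp"), mask

    def test_separable_classes_perfect_verify_oa(self, rng):
        stack, mask = self._gaussian_stack(rng)
        pred = g.train_and_classify(stack, ["f1", "f2"], mask, seed=0)
        rep = g.accuracy_report(pred, mask)
        assert rep.oa == 100.0 and rep.kappa == 1.0

    def test_permuted_labels_near_chance(self, rng):
        # uninformative features: the null model must sit at chance level
        stack, mask = self._gaussian_stack(rng, sep=0.0)
        perm = mask.labels.copy()
        train = mask.train_mask()
        vals = perm[train]
        perm[train] = rng.permutation(vals)
        shuffled = g.LabelMask(perm, mask.class_names,
                               parcel_ids=mask.parcel_ids, split=mask.split)
        pred = g.train_and_classify(stack, ["f1", "f2"], shuffled, seed=0)
        rep = g.accuracy_report(pred, shuffled)
        assert abs(rep.oa - 50.0) < 10.0    # 1/K chance for K = 2

    def test_fixed_seed_deterministic(self, rng):
        stack, mask = self._gaussian_stack(rng, sep=1.0)
        a = g.train_and_classify(stack, ["f1", "f2"], mask, seed=3)
        b = g.train_and_classify(stack, ["f1", "f2"], mask, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_single_class_training_rejected(self, rng):
        stack, mask = self._gaussian_stack(rng)
        only = mask.labels.copy()
        only[only == 2] = 0
        m = g.LabelMask(only, mask.class_names, parcel_ids=mask.parcel_ids,
                        split=mask.split)
        with pytest.raises(DomainError):
            g.train_and_classify(stack, ["f1", "f2"], m, seed=0)

    def test_config_validation(self):
        with pytest.raises(Exception):
            ClassifierConfig(C=-1.0)


class TestAccuracyReport:
    def test_perfect_prediction(self):
        mask = _two_class_mask()
        rep = g.accuracy_report(mask.labels.copy(), mask)
        assert rep.oa == 100.0 and rep.kappa == 1.0

    def test_average_accuracy_worked_example(self):
        """A PA/UA pair of 91.07/88.92 averages to 90.0 at one decimal."""
        assert round(g.average_accuracy(91.07, 88.92), 1) == 90.0

    def test_hand_computed_confusion(self):
        cm = np.array([[50, 10], [10, 30]])
        n = cm.sum()
        oa = np.trace(cm) / n
        pe = (cm.sum(1) * cm.sum(0)).sum() / n**2
        assert oa == 0.8
        # brute-force kappa from chance agreement
        kappa = (oa - pe) / (1 - pe)
        ref = np.repeat([1, 1, 2, 2], [50, 10, 10, 30])
        hat = np.repeat([1, 2, 1, 2], [50, 10, 10, 30])
        np.testing.assert_array_equal(confusion_matrix(ref, hat, 2), cm)
        assert kappa == pytest.approx(cohen_kappa_score(ref, hat))

    def test_matches_sklearn_on_random_labels(self, rng):
        mask = _two_class_mask()
        pred = rng.integers(1, 3, mask.shape).astype(np.int32)
        rep = g.accuracy_report(pred, mask)
        verify = mask.verify_mask()
        ref, hat = mask.labels[verify], pred[verify]
        np.testing.assert_array_equal(
            rep.confusion, sk_confusion(ref, hat, labels=[1, 2]))
        assert rep.kappa == pytest.approx(cohen_kappa_score(ref, hat))
        assert rep.oa == pytest.approx(100.0 * (ref == hat).mean())

    def test_oa_is_reference_weighted_pa(self, rng):
        mask = _two_class_mask()
        pred = rng.integers(1, 3, mask.shape).astype(np.int32)
        rep = g.accuracy_report(pred, mask)
        w = rep.confusion.sum(axis=1)
        assert rep.oa == pytest.approx((rep.pa * w).sum() / w.sum())

    def test_absent_class_reported_as_nan(self):
        mask = _two_class_mask()
        pred = np.ones(mask.shape, np.int32)      # never predicts class 2
        rep = g.accuracy_report(pred, mask)
        assert np.isnan(rep.ua[1])
        assert rep.pa[1] == 0.0


class TestSweep:
    def test_surface_scene_flat_near_zero(self):
        img = g.constant_scene(g.canonical_target("trihedral"), (24, 24))
        labels = np.zeros((24, 24), np.int32)
        labels[4:20, 4:20] = 1
        parcels = labels.copy()
        mask = g.LabelMask(labels, ["surf"], parcel_ids=parcels,
                           split={1: "train"})
        res = g.parameter_sweep(img, mask, "chi_at_fixed_theta",
                                np.pi / 4, step=np.radians(15), window=3)
        assert res.table["alpha_mean"].abs().max() < 1e-9

    def test_theta_sweep_excludes_singular_points(self, default_scene_stack):
        imgs, mask, _, _ = default_scene_stack
        res = g.parameter_sweep(imgs[5], mask, "theta_at_fixed_chi", 0.0,
                                step=np.radians(30), window=7)
        # theta = -90, 0, +90 deg all give a pure H or V transmit at chi=0
        assert len(res.excluded) == 3

    def test_chi_sweep_continuity_and_circular_endpoints(self,
                                                        default_scene_stack):
        imgs, mask, _, _ = default_scene_stack
        res = g.parameter_sweep(imgs[1], mask, "chi_at_fixed_theta",
                                np.pi / 4, step=np.radians(1), window=7)
        rice = res.table[res.table["class"] == "T-H"].sort_values("chi")
        jumps = np.abs(np.diff(rice["alpha_mean"].to_numpy()))
        assert jumps.max() < 5.0
        # circular transmit is orientation-independent: chi = -pi/4 at any
        # theta matches the dedicated circular computation
        circ = g.decompose_cp_from_fp(imgs[1], 1.234, -np.pi / 4, window=7)
        endpoint = rice.iloc[0]
        m = mask.class_mask(4)
        assert endpoint["alpha_mean"] == pytest.approx(
            np.nanmean(circ.alpha.masked()[m]), abs=1e-9)


class TestTemporalCurves:
    def test_constant_scene_flat_trajectory(self):
        img = g.constant_scene(g.canonical_target("trihedral"), (20, 20))
        labels = np.zeros((20, 20), np.int32)
        labels[5:15, 5:15] = 1
        mask = g.LabelMask(labels, ["surf"], parcel_ids=labels,
                           split={1: "train"})
        results = [g.decompose_fp(img, 3) for _ in range(6)]
        curves = g.temporal_curves({"fp": results}, mask)
        assert set(curves["alpha_trend"][1:]) == {"flat"}

    def test_rice_trend_flags_on_default_scene(self, default_scene_stack):
        imgs, mask, _, _ = default_scene_stack
        results = {"pi4": [g.decompose_mode(im, "pi4", 7) for im in imgs]}
        curves = g.temporal_curves(results, mask,
                                   dates=[im.date_tag for im in imgs])
        th = curves[curves["class"] == "T-H"].reset_index()
        dj = curves[curves["class"] == "D-J"].reset_index()
        # both rice classes rise from seedling to elongation
        assert th.loc[1, "alpha_trend"] == "rise"
        assert dj.loc[1, "alpha_trend"] == "rise"
        # harvest: T-H drops, D-J does not
        assert th.loc[5, "alpha_trend"] == "drop"
        assert dj.loc[5, "alpha_trend"] != "drop"

    def test_trend_flags_thresholds(self):
        assert trend_flags([0, 5, 4, 4.5, -10]) == \
            ["rise", "flat", "flat", "drop"]


class TestTwoStage:
    def test_two_stage_smoke(self, default_scene_stack):
        imgs, mask, _, _ = default_scene_stack
        stack = g.feature_stack(imgs[:2] + imgs[5:], "pi4", 7)
        names = stack.names
        pred = g.two_stage_classify(stack, names, mask, rice_classes=(4, 5),
                                    seed=1)
        rep = g.accuracy_report(pred, mask)
        assert rep.oa > 80.0
        assert set(np.unique(pred[pred > 0])) <= {1, 2, 3, 4, 5}
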