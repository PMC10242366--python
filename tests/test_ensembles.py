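"""Ensemble algebra, the registry of member lists, stacking-head contracts
and the leave-one-out ablation."""

import numpy as np
import pytest

from spineseg.core_io import IntegrityError, ScoreMap
from spineseg.ensembles import (
    ENSEMBLE_MEMBERS,
    NAD,
    TCD,
    StackingConfig,
    ablate_ensemble,
    average_ensemble,
    build_stacking_head,
    geometric_mean_raw,
    get_ensemble_config,
    train_stacking,
)
from spineseg.topologies import build_topology
from tests.conftest import random_labelmask, random_scoremap


class TestAveraging:
    @pytest.mark.parametrize("mode", ["arith", "geo"])
    def test_identical_members_are_idempotent(self, make_scoremap, mode):
        sm = make_scoremap(8, 8, 4)
        out = average_ensemble([sm, sm, sm], mode)
        np.testing.assert_allclose(out.scores, sm.scores, atol=1e-6)

    def test_two_member_hand_example(self):
        a = ScoreMap(np.array([[[0.8, 0.2]]]))
        b = ScoreMap(np.array([[[0.4, 0.6]]]))
        arith = average_ensemble([a, b], "arith")
        np.testing.assert_allclose(arith.scores[0, 0], [0.6, 0.4], atol=1e-7)
        geo = average_ensemble([a, b], "geo")
        raw = np.sqrt([0.8 * 0.4, 0.2 * 0.6])
        np.testing.assert_allclose(geo.scores[0, 0], raw / raw.sum(), atol=1e-6)
        # normalized hand values
        np.testing.assert_allclose(geo.scores[0, 0], [0.6202, 0.3798], atol=1e-4)

    def test_zero_member_score_is_absorbing_in_geo(self):
        a = ScoreMap(np.array([[[1.0, 0.0]]]))
        b = ScoreMap(np.array([[[0.5, 0.5]]]))
        geo = average_ensemble([a, b], "geo")
        assert geo.scores[0, 0, 1] == 0.0

    def test_arithmetic_preserves_normalization_exactly(self, rng):
        members = [random_scoremap(rng, 16, 16, 5) for _ in range(4)]
        out = average_ensemble(members, "arith")
        np.testing.assert_allclose(out.scores.sum(axis=2), 1.0, atol=1e-6)

    def test_geometric_leq_arithmetic_before_renormalization(self, rng):
        members = [random_scoremap(rng, 12, 12, 6) for _ in range(5)]
        arith = average_ensemble(members, "arith").scores
        geo_raw = geometric_mean_raw(members).scores
        assert (geo_raw <= arith + 1e-7).all()
        assert not geo_raw.sum(axis=2) == pytest.approx(1.0)  # raw is unnormalized

    @pytest.mark.parametrize("mode", ["arith", "geo"])
    def test_permutation_invariance(self, rng, mode):
        members = [random_scoremap(rng, 8, 8, 3) for _ in range(4)]
        a = average_ensemble(members, mode).scores
        b = average_ensemble(members[::-1], mode).scores
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            average_ensemble([], "arith")

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(IntegrityError):
            average_ensemble(
                [random_scoremap(rng, 8, 8, 3), random_scoremap(rng, 4, 4, 3)]
            )


class TestEnsembleRegistry:
    def test_member_lists_match_published_compositions(self):
        assert ENSEMBLE_MEMBERS["E4"] == ("UAD", "UMD", "UQD", "UDD")
        assert ENSEMBLE_MEMBERS["E13"] == (
            "FCN", "U1", "UA", "UD", "UAD", "UMD", "UAMD", "UVMD", "UVDD",
            "UQD", "UDD", "UMDD", "UDD2",
        )
        assert len(ENSEMBLE_MEMBERS) == 10  # E4..E13

    def test_fcn_only_in_e8_and_e13(self):
        with_fcn = {eid for eid, members in ENSEMBLE_MEMBERS.items() if "FCN" in members}
        assert with_fcn == {"E8", "E13"}

    def test_sizes_grow_from_4_to_13(self):
        sizes = [len(ENSEMBLE_MEMBERS[f"E{i}"]) for i in range(4, 14)]
        assert sizes == list(range(4, 14))

    def test_config_lookup(self):
        cfg = get_ensemble_config("E12", mode="stacking")
        assert cfg.r == 12
        with pytest.raises(KeyError):
            get_ensemble_config("E99")


@pytest.fixture(scope="module")
def small_members():
    return [build_topology(t, m=8, num_classes=4, seed=i)
            for i, t in enumerate(["U1", "UD", "UA"])]


class TestStacking:
    def test_named_configs(self):
        assert NAD.name == "NAD" and NAD.input_kind == "N" and NAD.merge == "A"
        assert TCD.name == "TCD" and TCD.input_kind == "T" and TCD.merge == "C"
        assert NAD.epochs == 50 and NAD.learning_rate == 0.00033

    def test_nad_merge_width_is_num_classes(self, small_members):
        head = build_stacking_head(small_members, NAD, num_classes=4, seed=0)
        assert head.merged_width == 4

    def test_tcd_merge_width_is_r_times_feature_width(self, small_members):
        head = build_stacking_head(small_members, TCD, num_classes=4, seed=0)
        assert head.merged_width == 3 * 8  # R * m

    def test_untrained_head_output_normalized(self, small_members, rng):
        head = build_stacking_head(small_members, NAD, num_classes=4, seed=0)
        x = rng.normal(size=(1, 32, 32, 2)).astype(np.float32)
        scores = head.predict_scores(x)
        np.testing.assert_allclose(scores.sum(axis=-1), 1.0, atol=1e-5)

    def test_t_input_with_fcn_member_rejected(self):
        fcn = build_topology("FCN", m=8, num_classes=4, seed=0)
        u1 = build_topology("U1", m=8, num_classes=4, seed=1)
        with pytest.raises(ValueError):
            build_stacking_head([fcn, u1], TCD, num_classes=4)

    def test_concat_merge_is_order_sensitive(self, small_members, rng):
        x = rng.normal(size=(1, 16, 16, 2)).astype(np.float32)
        a = build_stacking_head(small_members, TCD, num_classes=4, seed=7)
        b = build_stacking_head(small_members[::-1], TCD, num_classes=4, seed=7)
        assert not np.allclose(a.predict_scores(x), b.predict_scores(x))

    def test_average_merge_is_order_invariant(self, small_members, rng):
        x = rng.normal(size=(1, 16, 16, 2)).astype(np.float32)
        a = build_stacking_head(small_members, NAD, num_classes=4, seed=7)
        b = build_stacking_head(small_members[::-1], NAD, num_classes=4, seed=7)
        np.testing.assert_allclose(a.predict_scores(x), b.predict_scores(x), atol=1e-6)

    def test_training_leaves_member_weights_untouched(self, small_members):
        from spineseg.synthdata import PhantomConfig, generate_cohort
        from spineseg.training import TrainConfig, make_patient_splits

        cfg = PhantomConfig(n_patients=5, slices_per_patient=(1, 1),
                            image_sizes=(64,), num_classes=4, seed=3)
        data = {p.patient_id: p.slices for p in generate_cohort(cfg)}
        split = make_patient_splits(sorted(data), seed=0)[0]
        head = build_stacking_head(small_members, NAD, num_classes=4, seed=0)
        before = [m.state_dict() for m in small_members]
        tc = TrainConfig(epochs=2, batch_size=4, seed=0, patch_size=32,
                         patch_stride=24, augment=None)
        head, log = train_stacking(head, split, data, tc)
        assert len(log) == 2 and all(np.isfinite(e["train_loss"]) for e in log)
        for m, state in zip(small_members, before):
            after = m.state_dict()
            assert all(np.array_equal(after[k], state[k]) for k in state)

    def test_bad_merge_kind_rejected(self):
        with pytest.raises(ValueError):
            StackingConfig("N", "X")


class TestAblation:
    def _scores(self, rng, n_slices=3, r=4, k=4):
        return (
            [[random_scoremap(rng, 8, 8, k) for _ in range(r)] for _ in range(n_slices)],
            [random_labelmask(rng, 8, 8, k) for _ in range(n_slices)],
        )

    def test_removing_identical_member_gives_zero_delta(self, rng):
        sm = random_scoremap(rng, 8, 8, 4)
        scores = [[sm, sm, sm]]
        truths = [random_labelmask(rng, 8, 8, 4)]
        result = ablate_ensemble(scores, truths, 1)
        np.testing.assert_allclose(result["delta"], 0.0, atol=1e-12)

    def test_two_member_ablation_equals_remaining_model(self, rng):
        scores, truths = self._scores(rng, r=2)
        result = ablate_ensemble(scores, truths, 0)
        from spineseg.ensembles import ensemble_class_iou

        solo = ensemble_class_iou([[maps[1]] for maps in scores], truths)
        np.testing.assert_allclose(result["ablated_iou"], solo, atol=1e-12)

    def test_deltas_match_brute_force_recomputation(self, rng):
        from spineseg.ensembles import ensemble_class_iou

        scores, truths = self._scores(rng, r=4)
        for drop in range(4):
            result = ablate_ensemble(scores, truths, drop)
            rebuilt = ensemble_class_iou(
                [[m for i, m in enumerate(maps) if i != drop] for maps in scores],
                truths,
            )
            full = ensemble_class_iou(scores, truths)
            np.testing.assert_allclose(result["delta"], rebuilt - full, atol=1e-12)

    def test_unknown_member_rejected(self, rng):
        scores, truths = self._scores(rng, r=2)
        with pytest.raises(ValueError):
            ablate_ensemble(scores, truths, 5)
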