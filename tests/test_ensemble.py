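"""Stage-3 fusion and ensemble: combo enumeration, input assembly, head
behavior, training dynamics, grid search, and ensemble averaging."""

import dataclasses

import numpy as np
import pytest

from datprog._nn import FusionHead
from datprog.ensemble import (
    FULL_ABLATION,
    ConfigurationError,
    EnsembleModel,
    FeatureSetCombo,
    InputAblation,
    TrainedNetwork,
    TrainingConfig,
    assemble_inputs,
    build_table1_ensemble,
    desk_scale_config,
    ensemble_predict,
    fusion_forward,
    grid_search,
    table1_combos,
    table2_ablations,
    train_network,
)


class TestComboEnumeration:
    def test_eleven_combos_with_expected_structure(self):
        combos = table1_combos()
        assert [c.id for c in combos] == list(range(1, 12))
        # the 7 non-empty subsets of the three feature families ...
        families = ["datscan_convlstm", "semiquant", "all_imagenet"]
        subset_rows = {c.members for c in combos[:7]}
        expected = {
            frozenset(f for i, f in enumerate(families) if mask & (1 << i))
            for mask in range(1, 8)
        }
        assert subset_rows == expected
        # ... plus the four individual backbones
        assert [sorted(c.members) for c in combos[7:]] == [
            ["vgg16"], ["resnet50"], ["densenet121"], ["inceptionv3"]
        ]

    def test_semiquant_row_has_no_volume_or_backbone_blocks(self):
        combo = table1_combos()[5]
        assert combo.members == frozenset({"semiquant"})
        assert combo.blocks == ("semiquant_lstm",)

    def test_four_ablation_rows(self):
        abls = table2_ablations()
        assert [(a.use_datscan, a.use_updrs, a.use_clinical) for a in abls] == [
            (True, True, True),
            (True, True, False),
            (False, True, True),
            (True, False, True),
        ]

    def test_empty_combo_rejected(self):
        with pytest.raises(ValueError):
            FeatureSetCombo(1, frozenset())


@pytest.fixture(scope="module")
def full_combo():
    return table1_combos()[0]


class TestAssembleInputs:
    def test_no_clinical_drops_four_columns(self, small_assembler, small_blocks, full_combo):
        tb, _, _ = small_blocks
        full = small_assembler.assemble(tb, full_combo, FULL_ABLATION)
        no_clin = small_assembler.assemble(tb, full_combo, InputAblation(2, True, True, False))
        assert full.shape[1] - no_clin.shape[1] == 4

    def test_no_datscan_removes_all_imaging(self, small_assembler, small_blocks, full_combo):
        layout = small_assembler.block_layout(full_combo, InputAblation(3, False, True, True))
        assert layout == ("updrs_lstm", "clinical")

    def test_assembly_deterministic(self, small_assembler, small_partitions, full_combo):
        train, _, _ = small_partitions
        v1 = assemble_inputs(train[0], small_assembler, full_combo)
        v2 = assemble_inputs(train[0], small_assembler, full_combo)
        assert np.array_equal(v1, v2)

    def test_missing_block_raises_configuration_error(self, small_assembler, small_blocks, full_combo):
        tb, _, _ = small_blocks
        partial = {k: v for k, v in tb.items() if not k.startswith("backbone")}
        with pytest.raises(ConfigurationError):
            small_assembler.assemble(partial, full_combo, FULL_ABLATION)


class TestFusionHead:
    def test_inference_independent_of_batch_composition(self):
        rng = np.random.default_rng(0)
        head = FusionHead(6, 8, 0.5, seed=1)
        X = rng.random((32, 6))
        alone = head.forward(X[:1])
        batched = head.forward(X)[:1]
        assert np.allclose(alone, batched, atol=1e-12)
        assert np.array_equal(head.forward(X), head.forward(X))

    def test_extreme_dropout_leaves_bias_pathway(self):
        head = FusionHead(4, 16, 0.99999, seed=2)
        rng = np.random.default_rng(3)
        out = head.forward(np.ones((8, 4)), training=True, rng=rng)
        assert np.allclose(out, head.params["b2"][0], atol=1e-9)

    def test_raw_scale_prediction_via_fusion_forward(self, small_assembler, small_partitions,
                                                     small_blocks, full_combo):
        train, val, _ = small_partitions
        tb, vb, _ = small_blocks
        net = train_network(train, val, full_combo, FULL_ABLATION,
                            desk_scale_config(seed=4, epochs=3), small_assembler, tb, vb)
        x = small_assembler.assemble(tb, full_combo, FULL_ABLATION)[:5]
        assert np.allclose(fusion_forward(x, net), net.predict_blocks(tb)[:5])

    def test_length_mismatch_rejected(self):
        head = FusionHead(6, 8, 0.0, seed=1)
        with pytest.raises(ValueError):
            head.forward(np.zeros((3, 5)))


class TestTrainNetwork:
    def test_overfits_eight_records(self, small_assembler, small_partitions, full_combo):
        """Optimization sanity: 200 epochs on 8 records shrinks training MAE
        below a quarter of its epoch-1 value."""
        train, val, _ = small_partitions
        cfg = desk_scale_config(seed=0, epochs=200)
        net = train_network(train[:8], val, full_combo, FULL_ABLATION, cfg, small_assembler)
        first = net.training_history[0][0]
        last = net.training_history[-1][0]
        assert last < 0.25 * first

    def test_seeded_reproducibility(self, small_assembler, small_partitions, small_blocks,
                                    full_combo):
        train, val, test = small_partitions
        tb, vb, teb = small_blocks
        cfg = desk_scale_config(seed=9, epochs=5)
        n1 = train_network(train, val, full_combo, FULL_ABLATION, cfg, small_assembler, tb, vb)
        n2 = train_network(train, val, full_combo, FULL_ABLATION, cfg, small_assembler, tb, vb)
        assert n1.training_history == n2.training_history
        assert np.array_equal(n1.predict_blocks(teb), n2.predict_blocks(teb))

    def test_backbones_frozen_through_training(self, small_assembler, small_partitions,
                                               small_blocks, full_combo):
        train, val, _ = small_partitions
        tb, vb, _ = small_blocks
        before = small_assembler.imaging.backbone_checksums()
        train_network(train, val, full_combo, FULL_ABLATION,
                      desk_scale_config(seed=1, epochs=3), small_assembler, tb, vb)
        assert small_assembler.imaging.backbone_checksums() == before

    def test_overlapping_partitions_rejected(self, small_assembler, small_partitions, full_combo):
        train, val, _ = small_partitions
        with pytest.raises(ValueError):
            train_network(train, train, full_combo, FULL_ABLATION,
                          TrainingConfig(epochs=1), small_assembler)


class TestGridSearch:
    def test_singleton_grid_returns_that_configuration(self, small_assembler, small_partitions,
                                                       full_combo):
        train, val, _ = small_partitions
        cfg = desk_scale_config(seed=2, epochs=2)
        best, results = grid_search({"hidden_width": [16]}, train, val, full_combo,
                                    FULL_ABLATION, cfg, small_assembler)
        assert best.hidden_width == 16
        assert len(results) == 1

    def test_degenerate_candidate_loses(self, small_assembler, small_partitions, full_combo):
        """A learning rate too small to move the head from its random init
        must lose to a working one."""
        train, val, _ = small_partitions
        cfg = desk_scale_config(seed=2, epochs=10)
        best, results = grid_search({"learning_rate": [2e-2, 1e-12]}, train, val,
                                    full_combo, FULL_ABLATION, cfg, small_assembler)
        assert best.learning_rate == 2e-2
        assert len(results) == 2

    def test_fit_count_is_grid_product(self, small_assembler, small_partitions, full_combo):
        train, val, _ = small_partitions
        cfg = desk_scale_config(seed=2, epochs=1)
        _, results = grid_search({"hidden_width": [8, 16], "dropout_p": [0.0, 0.25, 0.5]},
                                 train, val, full_combo, FULL_ABLATION, cfg, small_assembler)
        assert len(results) == 6

    def test_empty_grid_rejected(self, small_assembler, small_partitions, full_combo):
        train, val, _ = small_partitions
        with pytest.raises(ValueError):
            grid_search({}, train, val, full_combo, FULL_ABLATION,
                        TrainingConfig(), small_assembler)


def _constant_network(value: float, width: int) -> TrainedNetwork:
    head = FusionHead(width, 4, 0.0, seed=0)
    head.params["W1"][:] = 0.0
    head.params["W2"][:] = 0.0
    head.params["b2"][:] = value
    return TrainedNetwork(
        combo=None, ablation=InputAblation(3, False, True, True), head=head,
        block_names=("updrs_lstm", "clinical"), feature_widths={}, training_history=[],
        seed=0, y_mean=0.0, y_sd=1.0,
    )


class TestEnsemble:
    def test_eleven_members_with_derived_seeds(self, small_assembler, small_partitions,
                                               small_blocks):
        train, val, _ = small_partitions
        tb, vb, _ = small_blocks
        cfg = desk_scale_config(seed=50, epochs=2)
        model = build_table1_ensemble(train, val, cfg, small_assembler, tb, vb)
        assert len(model.members) == 11
        assert [m.seed for m in model.members] == [50 + c.id for c in table1_combos()]

    def test_single_member_identity_and_forced_mean(self, small_blocks):
        _, _, teb = small_blocks
        width = teb["updrs_lstm"].shape[1] + teb["clinical"].shape[1]
        ten, twenty = _constant_network(10.0, width), _constant_network(20.0, width)
        assert np.allclose(EnsembleModel([ten]).predict_blocks(teb), 10.0)
        assert np.allclose(EnsembleModel([ten, twenty]).predict_blocks(teb), 15.0)

    def test_per_record_squared_error_convexity(self, small_assembler, small_partitions,
                                                small_blocks):
        train, val, test = small_partitions
        tb, vb, teb = small_blocks
        cfg = desk_scale_config(seed=7, epochs=3)
        model = build_table1_ensemble(train, val, cfg, small_assembler, tb, vb)
        obs = np.array([r.outcome_y4 for r in test])
        member_preds = np.array([m.predict_blocks(teb) for m in model.members])
        ens_sq = (model.predict_blocks(teb) - obs) ** 2
        mean_member_sq = ((member_preds - obs) ** 2).mean(axis=0)
        assert np.all(ens_sq <= mean_member_sq + 1e-9)

    def test_ensemble_predict_matches_member_mean(self, small_assembler, small_partitions,
                                                  small_blocks):
        train, val, test = small_partitions
        tb, vb, teb = small_blocks
        cfg = desk_scale_config(seed=3, epochs=2)
        model = build_table1_ensemble(train, val, cfg, small_assembler, tb, vb)
        manual = np.mean([m.predict_blocks(teb) for m in model.members], axis=0)
        assert np.allclose(ensemble_predict(model, test, small_assembler), manual)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            EnsembleModel([])
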