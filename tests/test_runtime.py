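"""Training loop, checkpointing, evaluation, Grad-CAM, ablation and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from skinformer.ablation import ablation_table, run_ablation
from skinformer.cli import main as cli_main
from skinformer.gradcam import grad_cam, lesion_focus
from skinformer.model import HybridSkinFormer
from skinformer.model import test_scale_config as scale_config
from skinformer.preprocess import to_network_input
from skinformer.synthetic import DatasetManifest, generate_dataset
from skinformer.train import (
    PRESETS,
    TrainConfig,
    evaluate,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)

from conftest import four_class_specs


class TestTrainLoop:
    def test_history_and_learnable_logging(self, trained_small):
        hist = trained_small.history
        assert len(hist) == 4
        assert [r.epoch for r in hist] == [1, 2, 3, 4]
        for r in hist:
            assert np.isfinite(r.train_loss) and np.isfinite(r.val_loss)
            assert 0.0 <= r.train_accuracy <= 1.0
            assert len(r.alpha_layers) == 2          # one per attention layer
            assert all(0.0 <= a <= 1.0 for a in r.alpha_layers)
            # full preset: StarPRelu triples present (stem + layers + head)
            assert len(r.star_prelu_params) > 0
            assert all(len(t) == 3 for t in r.star_prelu_params)

    def test_loss_decreases_on_separable_data(self, trained_small):
        hist = trained_small.history
        assert hist[-1].train_loss < hist[0].train_loss

    def test_best_val_tracked(self, trained_small):
        best = max(r.val_accuracy for r in trained_small.history)
        assert trained_small.best_val_accuracy == pytest.approx(best)

    def test_determinism(self, small_dataset, small_model_config):
        cfg = TrainConfig(epochs=1, batch_size=10, seed=3, preset="base1", augment=True)
        r1 = train(small_model_config, small_dataset, cfg)
        r2 = train(small_model_config, small_dataset, cfg)
        for k in r1.final_state:
            np.testing.assert_array_equal(r1.final_state[k], r2.final_state[k])

    def test_seed_changes_outcome(self, small_dataset, small_model_config):
        base = TrainConfig(epochs=1, batch_size=10, seed=3, preset="base1")
        other = TrainConfig(epochs=1, batch_size=10, seed=4, preset="base1")
        r1 = train(small_model_config, small_dataset, base)
        r2 = train(small_model_config, small_dataset, other)
        assert any(
            not np.array_equal(r1.final_state[k], r2.final_state[k]) for k in r1.final_state
        )

    @pytest.mark.parametrize("preset,act,loss", [
        ("base1", "relu", "ce"), ("base2", "relu", "efloss"),
        ("base3", "starprelu", "ce"), ("full", "starprelu", "efloss"),
    ])
    def test_preset_mapping(self, preset, act, loss):
        cfg = TrainConfig(preset=preset)
        assert PRESETS[preset] == (act, loss)
        assert cfg.activation == act and cfg.loss_name == loss

    def test_ce_preset_uses_unit_beta_zero_gamma(self, small_dataset, small_model_config):
        cfg = TrainConfig(epochs=1, batch_size=10, seed=0, preset="base1")
        r = train(small_model_config, small_dataset, cfg)
        assert r.loss_config.beta == 1.0 and r.loss_config.gamma == 0.0

    def test_efloss_scaling_from_train_counts(self, small_dataset, small_model_config):
        cfg = TrainConfig(epochs=1, batch_size=10, seed=0, preset="full")
        r = train(small_model_config, small_dataset, cfg)
        counts = small_dataset.class_counts("train")
        np.testing.assert_allclose(
            r.loss_config.class_scaling, 1.0 - counts / counts.sum()
        )

    def test_json_lines_log(self, tmp_path, small_dataset, small_model_config):
        log = tmp_path / "run.jsonl"
        train(small_model_config, small_dataset,
              TrainConfig(epochs=2, batch_size=10, seed=0, preset="full"), log_path=log)
        lines = [json.loads(l) for l in log.read_text().splitlines()]
        assert len(lines) == 2
        assert {"epoch", "train_loss", "val_accuracy", "alpha_layers"} <= lines[0].keys()

    def test_missing_split_rejected(self, small_model_config):
        ds = generate_dataset(
            four_class_specs(),
            DatasetManifest(counts=(4, 4, 4, 4), seed=0, split_fractions=(1.0, 0.0, 0.0)),
        )
        with pytest.raises(ValueError, match="validation"):
            train(small_model_config, ds, TrainConfig(epochs=1))

    def test_invalid_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            TrainConfig(preset="base9")


class TestEvaluatePredict:
    def test_report_matches_manual_predictions(self, trained_small, small_dataset):
        report, cm = evaluate(trained_small.model, small_dataset, split="test")
        images, labels = small_dataset.subset("test")
        preds = predict(trained_small.model, images)
        assert report.overall_accuracy == pytest.approx(float((preds == labels).mean()))
        assert cm.total == len(labels)

    def test_deterministic(self, trained_small, small_dataset):
        r1, _ = evaluate(trained_small.model, small_dataset, split="validation")
        r2, _ = evaluate(trained_small.model, small_dataset, split="validation")
        assert r1.to_dict() == r2.to_dict()

    def test_argmax_tie_breaks_to_lowest_index(self, small_model_config, small_dataset):
        model = HybridSkinFormer(small_model_config, seed=0)
        # zero the final projection: all logits equal, so every row ties
        model.head.proj_out.weight.value[...] = 0
        model.head.proj_out.bias.value[...] = 0
        images, _ = small_dataset.subset("test")
        assert (predict(model, images[:4]) == 0).all()

    def test_empty_input(self, trained_small):
        assert predict(trained_small.model, []).shape == (0,)


class TestCheckpoints:
    def test_round_trip_preserves_outputs(self, tmp_path, trained_small, small_dataset):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, trained_small.model)
        clone = load_checkpoint(path)
        images, _ = small_dataset.subset("test")
        x = to_network_input(images[:3])
        np.testing.assert_array_equal(trained_small.model.forward(x), clone.forward(x))

    def test_best_state_differs_from_final_when_saved(self, tmp_path, trained_small):
        path = tmp_path / "best.npz"
        save_checkpoint(path, trained_small.model, state=trained_small.best_state)
        clone = load_checkpoint(path)
        for k, v in trained_small.best_state.items():
            np.testing.assert_array_equal(clone.state_dict()[k], v)

    def test_config_mismatch_refused(self, tmp_path, trained_small):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, trained_small.model)
        with pytest.raises(ValueError, match="different model configuration"):
            load_checkpoint(path, expected_config=scale_config(classes_num=5))

    def test_tampered_config_refused(self, tmp_path, trained_small):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, trained_small.model)
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        meta = json.loads(bytes(arrays["__meta__"]).decode())
        meta["config"]["hidden_dim"] += 1      # edit config, keep stale hash
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="hash mismatch"):
            load_checkpoint(path)


class TestGradCam:
    def test_heatmap_contract(self, trained_small, small_dataset):
        images, labels = small_dataset.subset("train")
        sal = grad_cam(trained_small.model, images[0], int(labels[0]), target_layer=1)
        assert sal.heatmap.shape == images[0].shape[:2]
        assert np.isfinite(sal.heatmap).all()
        assert sal.heatmap.min() >= 0.0 and sal.heatmap.max() <= 1.0

    def test_on_lesion_focus_at_first_conv(self, trained_small, small_dataset):
        """Saliency mass concentrates on the lesion (alpha>0) region."""
        images, labels = small_dataset.subset("train")
        for i in (0, 15, 30, 45):
            sal = grad_cam(trained_small.model, images[i], int(labels[i]), target_layer=1)
            inside, area = lesion_focus(sal, images[i])
            assert inside > area, f"image {i}: {inside:.3f} <= {area:.3f}"

    def test_third_layer_degenerate_at_test_scale(self, trained_small, small_dataset):
        """At 64x96 the third conv output is 1x1: the normalized map is flat."""
        images, labels = small_dataset.subset("train")
        sal = grad_cam(trained_small.model, images[0], int(labels[0]), target_layer=3)
        assert np.ptp(sal.heatmap) == 0.0

    def test_invalid_arguments(self, trained_small, small_dataset):
        images, _ = small_dataset.subset("train")
        with pytest.raises(ValueError, match="target_layer"):
            grad_cam(trained_small.model, images[0], 0, target_layer=4)
        with pytest.raises(ValueError, match="target_class"):
            grad_cam(trained_small.model, images[0], 9)

    def test_png_written(self, tmp_path, trained_small, small_dataset):
        images, labels = small_dataset.subset("train")
        sal = grad_cam(trained_small.model, images[0], int(labels[0]), target_layer=1)
        out = tmp_path / "cam.png"
        sal.to_png(out)
        assert out.stat().st_size > 0


class TestAblation:
    def test_two_preset_comparison(self, small_dataset, small_model_config):
        cfg = TrainConfig(epochs=1, batch_size=10, seed=0, augment=False)
        entries = run_ablation(small_dataset, ["base1", "full"], small_model_config, cfg)
        assert set(entries) == {"base1", "full"}
        for e in entries.values():
            assert 0.0 <= e.report.overall_accuracy <= 1.0
        table = ablation_table(entries, minority_class=3)
        assert "base1" in table and "full" in table and "min.recall" in table

    def test_requires_two_presets(self, small_dataset, small_model_config):
        with pytest.raises(ValueError):
            run_ablation(small_dataset, ["full"], small_model_config, TrainConfig(epochs=1))

    def test_unknown_preset(self, small_dataset, small_model_config):
        with pytest.raises(ValueError, match="base9"):
            run_ablation(small_dataset, ["full", "base9"], small_model_config,
                         TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def cli_workspace(tmp_path_factory):
    """A simulated dataset directory plus a test-scale YAML config."""
    root = tmp_path_factory.mktemp("cli")
    cfg_path = root / "c.yaml"
    cfg_path.write_text(
        "model:\n"
        "  hidden_dim: 4\n  embed_dim: 12\n  head_num: 3\n"
        "  attention_layer_num: 2\n  input_height: 64\n  input_width: 96\n"
        "train:\n  epochs: 1\n  seed: 0\n"
        "data:\n  counts: [10, 10, 10, 10, 10, 10, 10, 10, 10]\n"
        "augment:\n  enabled: false\n"
    )
    runner = CliRunner()
    res = runner.invoke(cli_main, ["simulate", "--config", str(cfg_path),
                                   "--out", str(root / "data"), "--separable"])
    assert res.exit_code == 0, res.output
    return root, cfg_path


class TestCli:
    def test_simulate_wrote_dataset(self, cli_workspace):
        root, _ = cli_workspace
        assert (root / "data" / "manifest.json").is_file()
        assert (root / "data" / "resolved_config.yaml").is_file()

    def test_train_evaluate_gradcam(self, cli_workspace):
        root, cfg = cli_workspace
        runner = CliRunner()
        ckpt = root / "model.npz"
        res = runner.invoke(cli_main, [
            "train", "--config", str(cfg), "--data", str(root / "data"),
            "--preset", "full", "--ckpt", str(ckpt),
            "--log", str(root / "log.jsonl"),
        ])
        assert res.exit_code == 0, res.output
        assert ckpt.is_file() and (root / "log.jsonl").is_file()

        res = runner.invoke(cli_main, [
            "evaluate", "--ckpt", str(ckpt), "--data", str(root / "data"),
            "--split", "test", "--report", str(root / "report.json"),
        ])
        assert res.exit_code == 0, res.output
        payload = json.loads((root / "report.json").read_text())
        assert "overall_accuracy" in payload

        png = next((root / "data" / "test").rglob("img_*.png"))
        res = runner.invoke(cli_main, [
            "gradcam", "--ckpt", str(ckpt), "--image", str(png),
            "--class", "0", "--layer", "1", "--out", str(root / "cam.png"),
        ])
        assert res.exit_code == 0, res.output
        assert (root / "cam.png").stat().st_size > 0

    def test_ablate(self, cli_workspace):
        root, cfg = cli_workspace
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "ablate", "--config", str(cfg), "--data", str(root / "data"),
            "--presets", "base1,full", "--report", str(root / "ablate.json"),
        ])
        assert res.exit_code == 0, res.output
        payload = json.loads((root / "ablate.json").read_text())
        assert set(payload) == {"base1", "full"}
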