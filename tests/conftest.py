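"""Shared fixtures: synthetic datasets and trained models.

Trainings are expensive relative to the rest of the suite, so every
trained model is a lazily-built session-scoped fixture shared by the
pipeline tests and the end-to-end acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from pestfusion.pipeline import evaluate, fit
from pestfusion.synthetic import SyntheticSpec, generate_dataset

# study conditions for the end-to-end run: 5 classes, 200 training images
# (58 per class at a 70/30 split), 10% label errors, 10% target-absent,
# 10% blurred, 5 epochs
E2E_SPEC = dict(n_classes=5, images_per_class=58, image_side=64,
                label_error_rate=0.1, no_target_rate=0.1, blur_rate=0.1)
E2E_EPOCHS = 5
E2E_SEEDS = (1, 2, 3)

@pytest.fixture(scope="session")
def e2e_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("e2e_data")
    spec = SyntheticSpec(**E2E_SPEC, seed=11)
    manifest, gt = generate_dataset(spec, out)
    return {"manifest": manifest, "ground_truth": gt, "spec": spec}


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_data")
    spec = SyntheticSpec(n_classes=5, images_per_class=10, seed=5)
    manifest, gt = generate_dataset(spec, out)
    return {"manifest": manifest, "ground_truth": gt, "spec": spec}


def train_and_score(manifest, config: dict, seed: int, n_test: int = 5):
    """Train once; return (log rows, general acc, improving group acc)."""
    model, log = fit(manifest, config, seed=seed)
    gen = evaluate(manifest, model, mode="general", seed=seed)
    imp = evaluate(manifest, model, mode="improving", n_test=n_test, seed=seed)
    return log, gen.accuracy, imp.accuracy


@pytest.fixture(scope="session")
def e2e_runs(e2e_dataset):
    """Full-model runs at the study conditions, one per seed."""
    cfg = {"optim": {"epochs": E2E_EPOCHS}}
    runs = {}
    for seed in E2E_SEEDS:
        runs[seed] = train_and_score(e2e_dataset["manifest"], cfg, seed)
    return runs


@pytest.fixture(scope="session")
def ablation_runs(e2e_dataset, e2e_runs):
    """Full / no-AFFM / no-EFLM improving accuracies per seed at the same
    study conditions; the full-model runs are shared with `e2e_runs`."""
    manifest = e2e_dataset["manifest"]
    base = {"optim": {"epochs": E2E_EPOCHS}}
    variants = {
        "no_affm": {**base, "affm": {"enabled": False}},
        "no_eflm": {**base, "eflm": {"enabled": False}},
    }
    out: dict[str, dict[int, float]] = {v: {} for v in variants}
    out["full"] = {seed: e2e_runs[seed][2] for seed in E2E_SEEDS}
    for seed in E2E_SEEDS:
        for name, cfg in variants.items():
            _, _, imp_acc = train_and_score(manifest, cfg, seed)
            out[name][seed] = imp_acc
    return out
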