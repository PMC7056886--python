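"""Desk-scale benchmark configurations and runners.

The full-scale protocol (100x100 scenes, 1024 FC channels, 400 epochs at
batch 24) is far beyond a single CPU; these benchmarks keep the complete
pipeline — fixtures, scene composition, training with partial
cross-entropy, metric evaluation — at a scale where it runs in minutes:
64x64 scenes, a 1/8-width backbone with 64 FC and 32 mixing channels, and
Adam at 1e-3 (the customary rate for networks this small).  The toy
problem remains genuinely learnable because the fixture generators keep
clover and grass colour distributions overlapping, so a network must use
shape and texture to separate them.

Two standard checks live here so the test suite and the results script
share one definition:

* ``tiny_overfit`` — overfit a width-reduced LC-Net on 8 fixed scenes for
  200 steps; a correct architecture/loss/optimiser stack reaches >= 95%
  training pixel accuracy.
* ``ablation_benchmark`` — train full LC-Net and the no-LCPP ablation on a
  fixed 200-train/50-test scene benchmark over several seeds and compare
  mean test mIoU.
"""
from __future__ import annotations

import numpy as np

from . import fixtures, sig
from .lcnet import LCNet, NetworkConfig, preprocess
from .training import TrainConfig, evaluate_dataset, train
from .types import IGNORE

DESK_IMAGE_SIZE = (64, 64)
DESK_SAMPLE_SIZE = 28
DESK_N_SAMPLES_RANGE = (2, 12)   # keeps 64x64 scene density close to 100x100 defaults


def desk_network_config(lcpp_enabled: bool = True) -> NetworkConfig:
    return NetworkConfig(
        backbone_width_multiplier=1 / 8,
        fc_channels=64,
        mix_channels=32,
        lcpp_enabled=lcpp_enabled,
    )


def desk_fixture_config() -> fixtures.FixtureConfig:
    return fixtures.FixtureConfig(image_size=DESK_IMAGE_SIZE, sample_size=DESK_SAMPLE_SIZE)


def desk_sig_config() -> sig.SigConfig:
    return sig.SigConfig(n_samples_range=DESK_N_SAMPLES_RANGE)


def make_scene_dataset(n_scenes: int, seed: int, role: str,
                       library_counts: tuple[int, int, int] = (12, 12, 3)) -> sig.Dataset:
    """A dataset of composed desk-scale scenes from a role-tagged library."""
    fix = desk_fixture_config()
    lib = fixtures.make_sample_library(library_counts, fix, seed=seed, role=role)
    scfg = desk_sig_config()
    rng = fixtures.child_rng(seed, role, "scenes")
    spec = sig.DatasetSpec(n_synthetic=n_scenes, n_partial=0)
    return sig.build_dataset(spec, lib, [], scfg, rng, expected_role=role)


def tiny_overfit(seed: int, n_images: int = 8, steps: int = 200) -> float:
    """Training pixel accuracy after overfitting a reduced net on few scenes."""
    ds = make_scene_dataset(n_images, seed, "train", library_counts=(6, 6, 2))
    net = LCNet(desk_network_config(), seed=seed)
    tcfg = TrainConfig(epochs=10 * steps, batch_size=n_images, learning_rate=1e-3,
                       seed=seed, max_steps=steps, eval_every=10**9)
    net, _ = train(net, ds, tcfg)
    x = np.stack([preprocess(im) for im in ds.images])
    y = np.stack(ds.labels)
    pred = net.forward_batch(x).argmax(axis=-1)
    valid = y != IGNORE
    return float((pred[valid] == y[valid]).mean())


def train_and_score(train_ds: sig.Dataset, test_ds: sig.Dataset, seed: int,
                    lcpp_enabled: bool, epochs: int = 6,
                    batch_size: int = 8) -> tuple[float, float]:
    """(mAcc, mIoU) on the test scenes after a short desk-scale training.

    Follows the package's training protocol: evaluation every epoch with
    the best-by-test-mIoU checkpoint restored at the end.
    """
    net = LCNet(desk_network_config(lcpp_enabled=lcpp_enabled), seed=seed)
    tcfg = TrainConfig(epochs=epochs, batch_size=batch_size, learning_rate=1e-3,
                       seed=seed, eval_every=1, checkpoint_best=True)
    net, _ = train(net, train_ds, tcfg, test_dataset=test_ds)
    x = np.stack([preprocess(im) for im in test_ds.images])
    y = np.stack(test_ds.labels)
    _, macc, miou = evaluate_dataset(net, x, y, batch_size)
    return macc, miou


def ablation_benchmark(seeds: tuple[int, ...] = (0, 1, 2), n_train: int = 200,
                       n_test: int = 50, epochs: int = 6) -> dict:
    """Full LC-Net vs the no-LCPP ablation on a fixed scene benchmark.

    The scene datasets are fixed across seeds (only network initialisation
    and batch order vary), mirroring an architecture comparison on a
    common dataset.
    """
    train_ds = make_scene_dataset(n_train, 1234, "train")
    test_ds = make_scene_dataset(n_test, 1234, "test")
    out: dict = {"full": [], "no_lcpp": [], "seeds": list(seeds)}
    for seed in seeds:
        _, miou_full = train_and_score(train_ds, test_ds, seed, True, epochs=epochs)
        _, miou_ablated = train_and_score(train_ds, test_ds, seed, False, epochs=epochs)
        out["full"].append(miou_full)
        out["no_lcpp"].append(miou_ablated)
    out["mean_full"] = float(np.mean(out["full"]))
    out["mean_no_lcpp"] = float(np.mean(out["no_lcpp"]))
    return out
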