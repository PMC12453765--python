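"""Reference experiment protocols on the synthetic benchmark.

The synthetic benchmark is the package's CPU-scale study: 200 synthetic
smear images (100 per class) at 64 x 64, stratified 70:20:10 into
train/test/validation, 10 training epochs, repeated over three seeds.  The
reduced-width PIDSAN4 and the depth-2 tiny ViT each have a fixed SGDM
recipe; held-out accuracy is reported as the median over seeds.
"""

from __future__ import annotations

import numpy as np

from .pidsan4 import Pidsan4, Pidsan4Config
from .synth import synthetic_dataset
from .train_eval import DataBundle, SplitSpec, evaluate, stratified_split, train_loop
from .vit import TinyViT, VitConfig

__all__ = [
    "PIDSAN4_BENCH_HP", "TINYVIT_BENCH_HP", "BENCH_IMAGE_SIZE",
    "BENCH_N_PER_CLASS", "build_bench_model", "run_synthetic_benchmark",
]

BENCH_IMAGE_SIZE = 64
BENCH_N_PER_CLASS = 100

#: SGDM recipe for the reduced-width PIDSAN4
PIDSAN4_BENCH_HP = {"learning_rate": 0.005, "batch_size": 16, "epochs": 10,
                    "clip_norm": 5.0}
#: SGDM recipe for the depth-2 tiny ViT (transformers need the larger step
#: with a tight gradient-norm clip to move their head in 10 epochs)
TINYVIT_BENCH_HP = {"learning_rate": 0.05, "batch_size": 16, "epochs": 10,
                    "clip_norm": 0.5}


def build_bench_model(kind: str, seed: int, image_size: int = BENCH_IMAGE_SIZE):
    if kind == "pidsan4":
        return Pidsan4(Pidsan4Config.reduced(input_size=image_size, seed=seed))
    if kind == "tinyvit":
        return TinyViT(VitConfig(input_size=image_size, depth=2, dtype="float32",
                                 seed=seed))
    raise ValueError(f"unknown model kind {kind!r}")


def run_synthetic_benchmark(kind: str, seeds=(1, 2, 3),
                            n_per_class: int = BENCH_N_PER_CLASS,
                            image_size: int = BENCH_IMAGE_SIZE,
                            noise_levels=(0.0,), verbose: bool = False):
    """Train per seed and return {"accuracies": [...], "reports": [...]}.

    ``reports[i]`` maps each noise level (% of dynamic range) to the
    held-out MetricReport for that seed's model.
    """
    hp = PIDSAN4_BENCH_HP if kind == "pidsan4" else TINYVIT_BENCH_HP
    accuracies, reports = [], []
    for seed in seeds:
        images, labels, _ = synthetic_dataset(n_per_class, n_per_class,
                                              image_size=image_size, seed=seed)
        tr, te, va = stratified_split(labels, SplitSpec(seed=seed))
        bundle = DataBundle(images[tr], labels[tr], images[va], labels[va])
        model = build_bench_model(kind, seed, image_size)
        model, history = train_loop(model, bundle, hp, seed=seed)
        seed_reports = evaluate(model, images[te], labels[te],
                                noise_levels=noise_levels, positive_label=1,
                                seed=seed)
        accuracies.append(seed_reports[0.0].accuracy)
        reports.append(seed_reports)
        if verbose:
            print(f"{kind} seed {seed}: held-out accuracy "
                  f"{accuracies[-1]:.3f} (final train "
                  f"{history.train_accuracy[-1]:.3f})")
    return {"accuracies": accuracies, "median_accuracy": float(np.median(accuracies)),
            "reports": reports}
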