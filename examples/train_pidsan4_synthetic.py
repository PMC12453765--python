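"""Train the reduced-width PIDSAN4 on synthetic smear images.

Builds 200 synthetic images (100 per class) at 64 x 64, splits 70:20:10,
trains for 10 epochs with class-weighted cross-entropy and SGDM, then
reports the six evaluation metrics on the held-out test set, clean and
under 3% Gaussian noise.  Takes a minute or two on one CPU.
"""

import warnings

from pidsan import (
    DataBundle, Pidsan4, Pidsan4Config, SplitSpec, evaluate,
    stratified_split, synthetic_dataset, train_loop,
)
from pidsan.protocols import PIDSAN4_BENCH_HP

warnings.filterwarnings("ignore")

images, labels, _ = synthetic_dataset(100, 100, image_size=64, seed=2)
train_idx, test_idx, val_idx = stratified_split(labels, SplitSpec(70, 20, 10, seed=2))
bundle = DataBundle(images[train_idx], labels[train_idx],
                    images[val_idx], labels[val_idx])

model = Pidsan4(Pidsan4Config.reduced(input_size=64, seed=2))
print(f"model: {model.describe()['parameters']:,} trainable parameters")
model, history = train_loop(model, bundle, PIDSAN4_BENCH_HP, seed=2, verbose=True)

reports = evaluate(model, images[test_idx], labels[test_idx],
                   noise_levels=(0.0, 3.0), positive_label=1, seed=2)
for level, rep in reports.items():
    print(f"noise {level:.0f}%: accuracy {rep.accuracy:.3f}  "
          f"sensitivity {rep.sensitivity:.3f}  specificity {rep.specificity:.3f}  "
          f"precision {rep.precision:.3f}  F {rep.f_measure:.3f}  G {rep.g_mean:.3f}")

# Sensitivity is the blast-detection rate (label 1 is the blast class);
# G-mean = sqrt(sensitivity * specificity) summarises the class balance.
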