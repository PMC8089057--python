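"""Train both tiny branches briefly and score the ensemble on held-out chains.

Training follows the two-phase protocol (Adam then SGD with momentum at the
switch epoch; here the run stops before the switch) with one protein per
step; the checkpoint with the best validation top-L/2 long-range precision
is selected. Scoring is CASP-style top-L/n precision by separation range.
"""

import tempfile
from pathlib import Path

import numpy as np

import contactattn as ca
from contactattn.training import TrainSchedule, train

make = lambda n, seed: ca.make_dataset(ca.SynthConfig(
    n_proteins=n, L_min=24, L_max=48, signal_to_noise=5.0, seed=seed))
train_set, val_set, test_set = make(15, 101), make(4, 102), make(6, 103)

models = {}
with tempfile.TemporaryDirectory() as ckpt:
    for module in ("sequence", "regional"):
        state = train(train_set, val_set, ca.ModelConfig.tiny(module),
                      TrainSchedule(stop_epoch=6), seed=1,
                      out_dir=Path(ckpt) / module)
        best = state.epochs[state.best_epoch]
        print(f"{module}: best epoch {state.best_epoch}, "
              f"loss {best.loss:.3f}, val top-L/2 long {best.val_precision:.3f}")
        models[module] = ca.load_model(state.best_checkpoint)

preds, truths, densities = [], [], []
for _, fs, contacts in test_set:
    seq = ca.symmetrize(models["sequence"].predict(fs).contacts)
    reg = ca.symmetrize(models["regional"].predict(fs).contacts)
    preds.append(ca.ensemble_predict(seq, reg))
    truths.append(contacts)
    d = ca.contact_density(contacts, "long")
    if d is not None:
        densities.append(d)

result = ca.evaluate_dataset(preds, truths)
print("\nensemble mean precision (ranges x depths):")
print(result.table().to_string(float_format=lambda v: f"{v:.3f}"))
print(f"\nrandom-ranking baseline (long-range contact density): "
      f"{np.mean(densities):.3f}")
print("Precision well above the density baseline means the model recovered"
      "\nthe planted coupling signal rather than guessing.")
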