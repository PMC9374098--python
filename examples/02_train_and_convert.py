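"""Train a small conversion model and convert a held-out case.

This is a miniature of the full pipeline: simulate a handful of cases, train
the desk-scale HD U-Net on most of them, convert the held-out case per beam
(rotate to the default orientation, normalize, predict, invert both), and
compare PB vs converted against the reference dose.

Runtime is a few minutes on one CPU. For the full desk-scale experiment use
`protondl demo --out <dir>` or scripts/acceptance.py.

Run:  python examples/02_train_and_convert.py
"""

from protondl import (
    DESK_TRAIN_CONFIG,
    GammaCriteria,
    convert_case,
    gamma_index_3d,
    generate_dataset,
    mse_above_threshold,
    train_model,
)

cases = generate_dataset(8, {"lung_like": 0.5, "prostate_like": 0.5}, seed=11)
train_cases, test_case = cases[:-1], cases[-1]

print(f"training on {len(train_cases)} cases ...")
model, history = train_model(train_cases, DESK_TRAIN_CONFIG, seed=0)
print(f"best validation loss {history.best_val_loss:.5f} "
      f"at epoch {history.best_epoch}")

converted = convert_case(model, test_case, method="per_beam")

crit = GammaCriteria()  # 1%/1 mm, 10% threshold
mc = test_case.mc_composite
pb = test_case.pb_composite
g_pb = gamma_index_3d(mc, pb, crit).passing_rate
g_cv = gamma_index_3d(mc, converted, crit).passing_rate
print(f"held-out case {test_case.case_id} ({test_case.site}):")
print(f"  gamma passing  PB {g_pb:5.1f}%  ->  converted {g_cv:5.1f}%")
print(f"  masked MSE     PB {mse_above_threshold(mc, pb):.4f} Gy^2  ->  "
      f"converted {mse_above_threshold(mc, converted):.4f} Gy^2")
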