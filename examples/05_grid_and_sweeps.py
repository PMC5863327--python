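"""Run the full experimental grid and the published sweep axes, in miniature.

The grid covers {original image, K-Means, Mean-Shift} x {Model 1, 2, 3} x
{softmax, SVM}: 18 rows, the shape of the complete evaluation surface.
The (TS, ID) sweep shows the stacked-LSTM parameter budget falling as ID
shrinks.  Tiny sizes and epoch counts keep this script fast — it
demonstrates structure, not accuracy.
"""

from histoclust import (
    ExperimentConfig,
    ModelSpec,
    SyntheticParams,
    TrainConfig,
    run_grid,
    sweep,
)

base = ExperimentConfig(
    synthetic=SyntheticParams(n_images=40, seed=0),
    train=TrainConfig(epochs=1, batch_size=16),
    seed=9,
)

grid = run_grid(base, models=(1, 2, 3), ts=64, id_dim=48, ts3=32, id3=16)
print(f"grid rows: {len(grid)} (3 cluster arms x 3 models x 2 decision heads)")
print(grid[["cluster", "model", "decision", "accuracy_pct", "mcc"]].to_string(index=False))

lstm_base = ExperimentConfig(
    synthetic=SyntheticParams(n_images=40, seed=0),
    model=ModelSpec(model_id=2, ts=24, id_dim=128),
    train=TrainConfig(epochs=0),
    seed=1,
)
df = sweep(lstm_base, axis="ts_id")
print("\n(TS, ID) sweep, parameter column:")
print(df[["value", "parameters"]].to_string(index=False))
print("-> more time steps with fewer features per step costs fewer parameters")
print("   (only ID enters the LSTM input projection).")
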