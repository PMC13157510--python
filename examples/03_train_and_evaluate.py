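"""Train the heat-kernel GIN on a small synthetic cohort.

Simulates a 120-subject two-modality cohort with a planted age effect,
trains the model on an 80/20 split, and reports held-out age metrics.
Takes about half a minute on one CPU.
"""

import logging

from heatconn import (HkdMgin, HkdMginConfig, SimConfig, TrainConfig,
                      evaluate_regression, make_graph_batch, make_splits,
                      simulate_cohort, train)

logging.disable(logging.WARNING)

sim = SimConfig(n_subjects=120, seed=42)
cohort, truth = simulate_cohort(sim)
print(f"simulated {len(cohort)} subjects, {cohort.n_rois} ROIs, "
      f"modalities {cohort.modalities}")

batch = make_graph_batch(cohort)
train_idx, test_idx = make_splits(len(cohort), "holdout_80_20",
                                  repeats=1, seed=42)[0][0]

config = HkdMginConfig(n_rois=cohort.n_rois, modalities=cohort.modalities,
                       hidden_dim=16, beta=0.05, learn_beta=False,
                       task="age", seed=7)
tc = TrainConfig.desk(epochs=100, learning_rate=1e-2)
model, history = train(HkdMgin(config), batch.subset(train_idx), tc)
print(f"trained {tc.epochs} epochs; loss {history[0]:.0f} -> {history[-1]:.0f}")

pred = model.forward(batch.subset(test_idx))
rmse, mae, r = evaluate_regression(pred.age_estimate, batch.ages[test_idx])
print(f"held-out age prediction: RMSE={rmse:.2f} yr  MAE={mae:.2f} yr  "
      f"r={r:.3f}")
print("r well above 0 means the model recovered the planted monotone "
      "age effect from the connectivity blocks.")
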