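# heatconn

Heat-kernel diffused multimodal graph isomorphism networks for functional
connectomes.

## What problem this solves

Developmental neuroimaging studies ask how functional brain organization
changes through adolescence: can a subject's age or sex be predicted from
their functional connectivity (FC), and which connections carry that
signal?  The inputs are per-subject ROI×ROI Pearson correlation matrices,
one per fMRI paradigm (e.g. an emotion-identification task and a
working-memory task), plus a subject table and an atlas mapping ROIs to
functional systems (DMN, SAL, FRNT, ...).  `heatconn` is for researchers
who have such ROI-level data (or want to prototype on its bundled
synthetic cohorts) and want a graph-based predictive model whose decisions
can be traced back to specific connections.

## The model

Per subject and modality *m*, the FC matrix supplies node features
X (rows = connectivity profiles) and a cosine-similarity adjacency
A^(m).  With L = D − A the graph Laplacian, the heat kernel

    K^(m) = exp(−β L^(m))

diffuses node features (H₀ = K X) and supplies a smooth weighting for GIN
message passing

    h_v' = MLP((1 + ε)·h_v + Σ_u K_vu h_u),

followed by sum readouts per layer, concatenation across layers and
modalities, and a dense head for age regression and/or sex classification.
Training minimizes

    L = Σ_m ‖K^(m) − A^(m)‖_F² + λ Σ_i loss(y_i, ŷ_i),

where the reconstruction term regularizes the learnable diffusion scale β
against over-smoothing.  Setting β = 0 disables the kernel (identity
diffusion, adjacency aggregation) — the plain-GIN ablation baseline.
A GNNExplainer-style module then learns edge and feature masks that
preserve a frozen model's prediction, yielding ranked connections and
per-network-pair counts.  Everything runs on an in-repo numpy autodiff
engine; see `docs/methods.md` for assumptions and numerical choices.

## Worked example

`examples/03_train_and_evaluate.py` simulates a 120-subject two-modality
cohort with a planted monotone age effect, trains the model on an 80/20
split and prints:

```
simulated 120 subjects, 60 ROIs, modalities ('emoid', 'nback')
trained 100 epochs; loss 43218 -> 41859
held-out age prediction: RMSE=1.94 yr  MAE=1.42 yr  r=0.841
```

The held-out correlation of 0.84 means the model recovered the planted
age trend from the designated inter-network blocks; RMSE/MAE are in years.
(Most of the printed loss is the constant kernel-reconstruction term; the
supervised component is what shrinks.)
The other examples walk the remaining capabilities: FC and graph
construction (`01`), heat-kernel diffusion and its smoothing action
(`02`), the kernel/modality ablation grid (`04`), and explanation-based
recovery of the planted edges with per-network aggregation (`05`).

The same pipeline is scriptable from the shell, driven by a TOML (or
YAML) config:

```toml
seed = 5

[simulate]
n_subjects = 120

[model]
hidden_dim = 16
beta = 0.05
learn_beta = false

[train]
epochs = 100
learning_rate = 1e-2

[eval]
scheme = "holdout_80_20"
repeats = 2
```

```bash
heatconn simulate --config run.toml --out cohort/
heatconn train    --config run.toml --data cohort/ --out model/
heatconn evaluate --config run.toml --data cohort/ --out eval/
heatconn explain  --config run.toml --data cohort/ \
                  --checkpoint model/checkpoint.npz --out expl/
heatconn report   --run eval/
```

Each output directory carries a `run.json` with the exact config, seed and
package version; identical config + seed reproduces results byte for byte.

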