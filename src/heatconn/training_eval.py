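"""Training loop, split protocols, metrics, significance tests, baselines
and the ablation grid.

Evaluation follows the repeated-resampling protocols standard for cohort
prediction: 80/20 holdout repeated with bootstrap-style reshuffles, or
10-fold cross-validation repeated independently (the default headline
protocol).  Age regression is scored by RMSE, MAE and Pearson r; sex
classification by accuracy at threshold 0.5, rank-based AUC and F1 for the
positive class.  Model comparisons use two-sided paired t-tests on the
per-repeat metric series.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .autodiff import Adam, Tensor
from .model import GraphBatch, HkdMgin, HkdMginConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "EvalResult", "make_splits", "train",
    "evaluate_regression", "evaluate_classification", "paired_t_test",
    "run_experiment", "run_ablation", "default_ablation_grid",
    "fit_linear_regression", "fit_mlp", "fit_plain_gin", "MlpPredictor",
]


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults mirror the reference full-scale setting (adaptive-moment
    optimizer, 3000 epochs, learning rate 1e-5, decoupled weight decay 0.2).
    :meth:`desk` returns the reduced desk-scale preset used by the test
    suite and the bundled synthetic experiments.
    """

    learning_rate: float = 1e-5
    optimizer: str = "adam"
    epochs: int = 3000
    weight_decay: float = 0.2
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise TrainingError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise TrainingError("learning_rate must be >= 0")
        if self.weight_decay < 0:
            raise TrainingError("weight_decay must be >= 0")

    @classmethod
    def desk(cls, epochs: int = 300, **kw) -> "TrainConfig":
        kw.setdefault("learning_rate", 3e-3)
        kw.setdefault("weight_decay", 1e-3)
        return cls(epochs=epochs, **kw)


@dataclass
class EvalResult:
    """Per repeat x fold x configuration metric table with summaries."""

    table: pd.DataFrame

    COLUMNS = ("config", "repeat", "fold", "task",
               "rmse", "mae", "r", "acc", "auc", "f1")

    def __post_init__(self):
        t = self.table
        reg = t["rmse"].dropna()
        if len(reg):
            if (t["rmse"].dropna() < 0).any() or (t["mae"].dropna() < 0).any():
                raise ValueError("RMSE/MAE must be nonnegative")
            both = t.dropna(subset=["rmse", "mae"])
            if (both["rmse"] + 1e-12 < both["mae"]).any():
                raise ValueError("RMSE must be >= MAE")
            r = t["r"].dropna()
            if ((r < -1) | (r > 1)).any():
                raise ValueError("r must be in [-1, 1]")
        for col in ("acc", "auc", "f1"):
            v = t[col].dropna()
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{col} must be in [0, 1]")

    def summary(self) -> pd.DataFrame:
        metrics = ["rmse", "mae", "r", "acc", "auc", "f1"]
        return self.table.groupby("config")[metrics].agg(["mean", "std"])

    def metric_series(self, metric: str, config: str | None = None) -> np.ndarray:
        """Per-repeat means of one metric (the unit for paired t-tests)."""
        t = self.table
        if config is not None:
            t = t[t["config"] == config]
        return t.groupby("repeat")[metric].mean().to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json_summary(self, path) -> None:
        out: dict[str, dict[str, dict[str, float]]] = {}
        for cfg, grp in self.table.groupby("config"):
            out[str(cfg)] = {}
            for metric in ("rmse", "mae", "r", "acc", "auc", "f1"):
                v = grp[metric].dropna()
                if len(v):
                    out[str(cfg)][metric] = {
                        "mean": float(v.mean()),
                        "std": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                    }
        with open(path, "w") as f:
            json.dump(out, f, indent=2, sort_keys=True)


# -------------------------------------------------------------------- splits

def make_splits(n_subjects: int, scheme: str = "kfold_10", repeats: int = 10,
                seed: int = 0, stratify: np.ndarray | None = None
                ) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Deterministic train/test index sets, one list of folds per repeat.

    ``holdout_80_20`` gives one (train, test) pair per repeat; ``kfold_10``
    gives ten folds per repeat that partition the cohort.  When ``stratify``
    labels are given the folds are stratified (used for sex classification).
    """
    if scheme == "kfold_10" and n_subjects < 10:
        raise TrainingError("need at least 10 subjects for 10-fold CV")
    if scheme == "holdout_80_20" and n_subjects < 5:
        raise TrainingError("need at least 5 subjects for an 80/20 holdout")
    all_idx = np.arange(n_subjects)
    out: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for r in range(repeats):
        rs = (seed * 1009 + r) % (2 ** 31)  # distinct stream per repeat
        if scheme == "holdout_80_20":
            tr, te = train_test_split(all_idx, test_size=0.2, random_state=rs,
                                      stratify=stratify)
            out.append([(np.sort(tr), np.sort(te))])
        elif scheme == "kfold_10":
            if stratify is not None:
                kf = StratifiedKFold(n_splits=10, shuffle=True, random_state=rs)
                folds = kf.split(all_idx, stratify)
            else:
                kf = KFold(n_splits=10, shuffle=True, random_state=rs)
                folds = kf.split(all_idx)
            out.append([(np.sort(tr), np.sort(te)) for tr, te in folds])
        else:
            raise TrainingError(f"unknown split scheme {scheme!r}")
    return out


# ------------------------------------------------------------------ training

def train(model: HkdMgin, batch: GraphBatch, tc: TrainConfig
          ) -> tuple[HkdMgin, list[float]]:
    """Full-batch optimization of the total objective; returns loss history.

    The age head's affine output scaling is set from the training targets so
    optimization starts in the right range.  Deterministic given the model
    seed and config.  Aborts with the epoch index if the loss goes
    non-finite.
    """
    if batch.n_subjects == 0:
        raise TrainingError("empty training set")
    if tc.optimizer not in ("adam", "adaptive-moment"):
        raise TrainingError(f"unknown optimizer {tc.optimizer!r}")
    cfg = model.config
    if cfg.task in ("age", "joint") and batch.ages is not None:
        model.target_mean = float(np.mean(batch.ages))
        sd = float(np.std(batch.ages))
        model.target_scale = sd if sd > 0 else 1.0
    opt = Adam(model.parameters(), lr=tc.learning_rate,
               weight_decay=tc.weight_decay)
    history: list[float] = []
    for epoch in range(tc.epochs):
        loss = model.loss(batch)
        val = float(loss.value)
        if not np.isfinite(val):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        history.append(val)
        if tc.learning_rate > 0:
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model, history


# ------------------------------------------------------------------- metrics

def evaluate_regression(pred: np.ndarray, true: np.ndarray
                        ) -> tuple[float, float, float]:
    """(RMSE, MAE, Pearson r); r is NaN when either vector is constant."""
    p = np.asarray(pred, dtype=float)
    y = np.asarray(true, dtype=float)
    if p.shape != y.shape or p.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    rmse = float(np.sqrt(np.mean((p - y) ** 2)))
    mae = float(np.mean(np.abs(p - y)))
    if np.std(p) == 0 or np.std(y) == 0:
        r = float("nan")  # undefined, reported as NaN rather than a silent 0
    else:
        r = float(stats.pearsonr(p, y).statistic)
    return rmse, mae, r


def evaluate_classification(probabilities: np.ndarray, labels: np.ndarray
                            ) -> tuple[float, float, float]:
    """(ACC at 0.5, rank AUC with ties counted half, F1 of positive class)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be in {0, 1}")
    hard = (p >= 0.5).astype(int)
    acc = float(accuracy_score(y, hard))
    f1 = float(f1_score(y, hard, zero_division=0))
    if len(np.unique(y)) < 2:
        auc = float("nan")  # undefined with a single class
    else:
        auc = float(roc_auc_score(y, p))
    return acc, auc, f1


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on the per-repeat differences a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two aligned series of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t-test is degenerate")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------- experiment plumbing

def _metrics_row(model_or_pred, test_batch: GraphBatch, task: str,
                 config_name: str, repeat: int, fold: int) -> dict:
    if isinstance(model_or_pred, HkdMgin):
        pred = model_or_pred.forward(test_batch)
    else:
        pred = model_or_pred
    row = dict(config=config_name, repeat=repeat, fold=fold, task=task,
               rmse=np.nan, mae=np.nan, r=np.nan,
               acc=np.nan, auc=np.nan, f1=np.nan)
    if task in ("age", "joint"):
        rmse, mae, r = evaluate_regression(pred.age_estimate, test_batch.ages)
        row.update(rmse=rmse, mae=mae, r=r)
    if task in ("sex", "joint"):
        acc, auc, f1 = evaluate_classification(pred.sex_probability,
                                               test_batch.sexes)
        row.update(acc=acc, auc=auc, f1=f1)
    return row


def _restrict(batch: GraphBatch, modalities: Sequence[str]) -> GraphBatch:
    mods = tuple(modalities)
    missing = [m for m in mods if m not in batch.modalities]
    if missing:
        raise TrainingError(f"batch lacks modalities {missing}")
    return GraphBatch(
        modalities=mods,
        features={m: batch.features[m] for m in mods},
        adjacency={m: batch.adjacency[m] for m in mods},
        eigvals={m: batch.eigvals[m] for m in mods},
        eigvecs={m: batch.eigvecs[m] for m in mods},
        ages=batch.ages, sexes=batch.sexes, subject_ids=batch.subject_ids)


def run_experiment(batch: GraphBatch, model_config: HkdMginConfig,
                   tc: TrainConfig, scheme: str = "kfold_10",
                   repeats: int = 10, seed: int = 0,
                   config_name: str = "hkd-mgin",
                   splits: list | None = None) -> EvalResult:
    """Train/evaluate the model over a repeated split protocol."""
    task = model_config.task
    stratify = batch.sexes if task in ("sex", "joint") else None
    if splits is None:
        splits = make_splits(batch.n_subjects, scheme, repeats, seed, stratify)
    rows = []
    for r, folds in enumerate(splits):
        for f, (tr, te) in enumerate(folds):
            mcfg = replace(model_config, seed=model_config.seed + 7919 * r + f)
            model = HkdMgin(mcfg)
            model, _ = train(model, batch.subset(tr), tc)
            rows.append(_metrics_row(model, batch.subset(te), task,
                                     config_name, r, f))
    return EvalResult(pd.DataFrame(rows, columns=list(EvalResult.COLUMNS)))


def default_ablation_grid(modalities: Sequence[str]
                          ) -> list[tuple[str, bool, tuple[str, ...]]]:
    """Kernel on/off x modality subsets: the standard six-row ablation."""
    mods = tuple(modalities)
    subsets = [(m,) for m in mods] + [mods]
    grid = []
    for use_kernel in (False, True):
        for subset in subsets:
            tag = "hkd-mgin" if use_kernel else "plain-gin"
            grid.append((f"{tag}/{'+'.join(subset)}", use_kernel, subset))
    return grid


def run_ablation(batch: GraphBatch, model_config: HkdMginConfig,
                 tc: TrainConfig, grid=None, scheme: str = "kfold_10",
                 repeats: int = 10, seed: int = 0) -> EvalResult:
    """Run every grid cell on identical splits (fairness contract)."""
    if grid is None:
        grid = default_ablation_grid(batch.modalities)
    task = model_config.task
    stratify = batch.sexes if task in ("sex", "joint") else None
    splits = make_splits(batch.n_subjects, scheme, repeats, seed, stratify)
    frames = []
    for name, use_kernel, subset in grid:
        sub_batch = _restrict(batch, subset)
        # the kernel-off arm keeps lam: its reconstruction term is constant
        # (K = I), so training is driven by the supervised loss alone
        mcfg = replace(model_config, modalities=tuple(subset),
                       use_kernel=use_kernel,
                       beta=model_config.beta if use_kernel else 0.0,
                       learn_beta=model_config.learn_beta and use_kernel)
        res = run_experiment(sub_batch, mcfg, tc, scheme, repeats, seed,
                             config_name=name, splits=splits)
        frames.append(res.table)
    return EvalResult(pd.concat(frames, ignore_index=True))


# ----------------------------------------------------------------- baselines

@dataclass
class FittedBaseline:
    """Uniform predict interface over the sklearn-backed baselines."""

    kind: str
    task: str
    _predict: Callable[[np.ndarray], np.ndarray]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._predict(np.asarray(x, dtype=float))


def fit_linear_regression(vectors: np.ndarray, targets: np.ndarray,
                          task: str = "age") -> FittedBaseline:
    """Least-squares (age) or logistic (sex) fit on vectorized upper-tri FC.

    A rank-deficient design triggers a ridge fallback with a logged warning.
    """
    x = np.asarray(vectors, dtype=float)
    y = np.asarray(targets, dtype=float)
    if task == "age":
        if x.shape[0] <= x.shape[1] or np.linalg.matrix_rank(x) < min(x.shape):
            logger.warning("singular design for linear regression; "
                           "falling back to ridge")
            est = Ridge(alpha=1.0).fit(x, y)
        else:
            est = LinearRegression().fit(x, y)
        return FittedBaseline("lr", task, est.predict)
    est = LogisticRegression(max_iter=2000).fit(x, y.astype(int))
    return FittedBaseline("lr", task, lambda v: est.predict_proba(v)[:, 1])


class MlpPredictor:
    """Fully connected net with ReLU, L2 weight decay and dropout.

    Input is the vectorized upper-triangular FC; runs on the package's
    autodiff engine so dropout and decoupled L2 behave as configured.
    """

    def __init__(self, hidden: int = 64, l2: float = 1e-3, dropout: float = 0.2,
                 epochs: int = 200, learning_rate: float = 1e-3, task: str = "age",
                 seed: int = 0):
        if hidden < 1:
            raise TrainingError("MLP needs at least one hidden unit")
        if not 0.0 <= dropout < 1.0:
            raise TrainingError("dropout must be in [0, 1)")
        self.hidden, self.l2, self.dropout = hidden, l2, dropout
        self.epochs, self.lr, self.task, self.seed = epochs, learning_rate, task, seed
        self._params: list[Tensor] | None = None
        self._mean = None
        self._scale = None

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None) -> Tensor:
        w1, b1, w2, b2 = self._params
        h = (Tensor(x) @ w1 + b1).relu()
        if rng is not None and self.dropout > 0:
            keep = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
            h = h * Tensor(keep)
        return h @ w2 + b2

    def fit(self, x: np.ndarray, y: np.ndarray) -> "MlpPredictor":
        rng = np.random.default_rng(self.seed)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = x.shape[1]

        def glorot(fi, fo):
            s = np.sqrt(6.0 / (fi + fo))
            return Tensor(rng.uniform(-s, s, size=(fi, fo)), requires_grad=True)

        self._params = [glorot(d, self.hidden),
                        Tensor(np.zeros(self.hidden), requires_grad=True),
                        glorot(self.hidden, 1),
                        Tensor(np.zeros(1), requires_grad=True)]
        if self.task == "age":
            self._mean, self._scale = float(y.mean()), float(y.std() or 1.0)
        else:
            self._mean, self._scale = 0.0, 1.0
        opt = Adam(self._params, lr=self.lr, weight_decay=self.l2)
        n = x.shape[0]
        for _ in range(self.epochs):
            out = self._forward(x, rng).reshape(n)
            if self.task == "age":
                yhat = out * self._scale + self._mean
                diff = yhat - Tensor(y)
                loss = (diff * diff).mean()
            else:
                p = out.sigmoid().clamp(1e-12, 1 - 1e-12)
                loss = -(Tensor(y) * p.log()
                         + Tensor(1 - y) * (1.0 - p).log()).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = self._forward(x, None).reshape(x.shape[0]).value
        if self.task == "age":
            return out * self._scale + self._mean
        return 1.0 / (1.0 + np.exp(-out))


def fit_mlp(vectors: np.ndarray, targets: np.ndarray, task: str = "age",
            **kw) -> MlpPredictor:
    """Train the dense baseline on vectorized upper-triangular FC."""
    return MlpPredictor(task=task, **kw).fit(vectors, targets)


def fit_plain_gin(batch: GraphBatch, task: str, tc: TrainConfig,
                  model_config: HkdMginConfig | None = None
                  ) -> tuple[HkdMgin, list[float]]:
    """Kernel-off baseline: identical architecture with beta = 0.

    With the kernel disabled the reconstruction term is a constant, so the
    configured lam only scales the (purely supervised) gradient; the forward
    map coincides with the full model at beta = 0, lam = 0 by construction.
    """
    if model_config is None:
        model_config = HkdMginConfig(n_rois=batch.n_rois,
                                     modalities=batch.modalities, task=task)
    cfg = replace(model_config, task=task, use_kernel=False, beta=0.0,
                  learn_beta=False)
    return train(HkdMgin(cfg), batch, tc)
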