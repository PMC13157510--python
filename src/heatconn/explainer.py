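"""Mask-based explanation of trained models, top-k%% edge extraction and
functional-network aggregation.

Following the GNNExplainer recipe, a soft edge mask (symmetric N x N in
[0, 1], zero diagonal) and a node-feature mask (in [0, 1]^d) are
parameterized through sigmoids and optimized so that the masked graph still
reproduces the frozen model's prediction, subject to sparsity ("size", the
mean mask value) and sharpness ("element", the elementwise binary entropy)
penalties on both masks.  The edge mask multiplies the off-diagonal entries
of the diffusion kernels the model aggregates with (the model's message-
passing edges); the feature mask multiplies node features.  An optional
mean-squared-error variant of the feature penalties (deviation of masked
from unmasked features) is selectable via config.

Edge scores are read from the upper triangle of the optimized edge mask;
edges can then be ranked per subject, intersected within developmental
stages, or averaged over a cohort, and tallied per functional-network pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .data_io import AtlasMap
from .model import GraphBatch, HkdMgin, Prediction

logger = logging.getLogger(__name__)

__all__ = ["ExplainerConfig", "MaskSet", "EdgeRanking", "optimize_explanation",
           "top_percent_edges", "common_connections", "aggregate_networks"]


class ExplainerError(ValueError):
    pass


@dataclass
class ExplainerConfig:
    """Mask-optimization hyperparameters (reference defaults)."""

    prediction: float = 1.0
    feature_size: float = 200.0
    feature_element: float = 20.0
    population_size: float = 0.0
    population_element: float = 1000.0
    weight_decay: float = 0.0
    epochs: int = 100
    learning_rate: float = 0.5
    feature_loss_form: str = "entropy"  # "entropy" | "mse"
    seed: int = 0

    def __post_init__(self):
        for name in ("prediction", "feature_size", "feature_element",
                     "population_size", "population_element", "weight_decay"):
            if getattr(self, name) < 0:
                raise ExplainerError(f"{name} must be >= 0")
        if self.epochs < 1:
            raise ExplainerError("epochs must be >= 1")
        if self.feature_loss_form not in ("entropy", "mse"):
            raise ExplainerError("feature_loss_form must be 'entropy' or 'mse'")


@dataclass
class MaskSet:
    """Optimized masks plus the objective trace."""

    edge_mask: np.ndarray       # symmetric (N, N), zero diagonal, in [0, 1]
    feature_mask: np.ndarray    # (d,), in [0, 1]
    objective_trace: list[float]
    subject_id: str | None = None

    def __post_init__(self):
        e = self.edge_mask
        if np.max(np.abs(e - e.T)) > 1e-10:
            raise ExplainerError("edge mask must be symmetric")
        if np.abs(np.diag(e)).max() > 0:
            raise ExplainerError("edge mask diagonal must be zero")
        if e.min() < 0 or e.max() > 1:
            raise ExplainerError("edge mask must lie in [0, 1]")
        f = self.feature_mask
        if f.min() < 0 or f.max() > 1:
            raise ExplainerError("feature mask must lie in [0, 1]")


@dataclass
class EdgeRanking:
    """Ranked (i, j, score) list, i < j, scores non-increasing."""

    edges: list[tuple[int, int, float]]
    scope: str = "cohort"  # subject | stage | cohort

    def __post_init__(self):
        seen = set()
        prev = np.inf
        for i, j, s in self.edges:
            if not i < j:
                raise ExplainerError("edges must be stored with i < j")
            if (i, j) in seen:
                raise ExplainerError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))
            if s > prev + 1e-12:
                raise ExplainerError("scores must be non-increasing")
            prev = s

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}

    def to_frame(self, atlas: AtlasMap | None = None) -> pd.DataFrame:
        rows = []
        for i, j, s in self.edges:
            row = {"roi_i": i, "roi_j": j, "score": s}
            if atlas is not None:
                row["network_i"] = atlas.label(i)
                row["network_j"] = atlas.label(j)
            rows.append(row)
        cols = ["roi_i", "roi_j"] + (
            ["network_i", "network_j"] if atlas is not None else []) + ["score"]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path, atlas: AtlasMap | None = None) -> None:
        self.to_frame(atlas).to_csv(path, sep="\t", index=False,
                                    float_format="%.8g")


def _binary_entropy(m: Tensor, eps: float = 1e-8) -> Tensor:
    p = m.clamp(eps, 1.0 - eps)
    return -(p * p.log() + (1.0 - p) * (1.0 - p).log())


def optimize_explanation(model: HkdMgin, batch: GraphBatch,
                         target: Mapping[str, np.ndarray] | None = None,
                         cfg: ExplainerConfig | None = None) -> MaskSet:
    """Learn edge and feature masks for one subject's prediction.

    The model is treated as frozen; only the mask logits are optimized.
    The fidelity term compares the masked-graph prediction with the frozen
    model's unmasked prediction (squared error for the age head, binary
    cross-entropy against the hard label for the sex head), weighted by
    ``cfg.prediction``; the remaining terms are the size/element penalties.
    Fully deterministic (zero-initialized mask logits, full-batch updates).
    """
    cfg = cfg or ExplainerConfig()
    if batch.n_subjects != 1:
        raise ExplainerError("explanations are per subject: pass a 1-subject batch")
    n = batch.n_rois
    d = batch.features[batch.modalities[0]].shape[2]
    iu = np.triu_indices(n, k=1)

    # zero-init logits (masks start at exactly 0.5): keeps the optimization
    # deterministic and permutation-equivariant; the fidelity gradient, not
    # symmetry breaking, drives mask divergence
    edge_logits = Tensor(np.zeros(iu[0].size), requires_grad=True)
    feat_logits = Tensor(np.zeros(d), requires_grad=True)
    scatter = np.zeros((iu[0].size, n * n))
    scatter[np.arange(iu[0].size), iu[0] * n + iu[1]] = 1.0
    scatter[np.arange(iu[0].size), iu[1] * n + iu[0]] = 1.0
    scatter_t = Tensor(scatter)

    baseline = model.forward(batch)  # frozen reference prediction
    task = model.config.task
    opt = Adam([edge_logits, feat_logits], lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        em_upper = edge_logits.sigmoid()
        edge_mask = (em_upper @ scatter_t).reshape(n, n)
        feat_mask = feat_logits.sigmoid()
        heads, _ = model.forward_tensors(batch, edge_mask=edge_mask,
                                         feature_mask=feat_mask)
        obj = None

        def add(term):
            nonlocal obj
            obj = term if obj is None else obj + term

        if "age" in heads:
            diff = heads["age"] - Tensor(np.asarray(baseline.age_estimate))
            add(cfg.prediction * (diff * diff).mean())
        if "sex" in heads:
            label = float(np.round(baseline.sex_probability[0]))
            p = heads["sex"].clamp(1e-8, 1 - 1e-8)
            add(cfg.prediction * -(label * p.log()
                                   + (1.0 - label) * (1.0 - p).log()).mean())
        if cfg.feature_loss_form == "entropy":
            add(cfg.feature_size * feat_mask.mean())
            add(cfg.feature_element * _binary_entropy(feat_mask).mean())
        else:
            x = batch.features[batch.modalities[0]][0]
            dx = Tensor(x) * (feat_mask - 1.0)
            add(cfg.feature_size * (dx * dx).mean())
            add(cfg.feature_element * _binary_entropy(feat_mask).mean())
        add(cfg.population_size * em_upper.mean())
        add(cfg.population_element * _binary_entropy(em_upper).mean())

        val = float(obj.value)
        if not np.isfinite(val):
            raise ExplainerError(f"non-finite explainer objective at epoch {epoch}")
        trace.append(val)
        opt.zero_grad()
        obj.backward()
        opt.step()

    final_upper = 1.0 / (1.0 + np.exp(-edge_logits.value))
    edge = np.zeros((n, n))
    edge[iu] = final_upper
    edge = edge + edge.T
    feat = 1.0 / (1.0 + np.exp(-feat_logits.value))
    sid = batch.subject_ids[0] if batch.subject_ids else None
    return MaskSet(edge_mask=edge, feature_mask=feat, objective_trace=trace,
                   subject_id=sid)


def top_percent_edges(masks: Sequence[MaskSet], pct: float,
                      scope: str = "cohort") -> EdgeRanking:
    """Top ``pct`` percent of edges by mean mask score across subjects.

    With N ROIs there are N(N-1)/2 candidate edges and
    floor(pct / 100 * N(N-1)/2) are returned, ties broken by (i, j)
    lexicographic order.
    """
    if not masks:
        raise ExplainerError("need at least one mask")
    if not 0.0 < pct <= 100.0:
        raise ExplainerError("pct must be in (0, 100]")
    n = masks[0].edge_mask.shape[0]
    if any(m.edge_mask.shape[0] != n for m in masks):
        raise ExplainerError("masks must share N")
    mean_mask = np.mean([m.edge_mask for m in masks], axis=0)
    iu, ju = np.triu_indices(n, k=1)
    scores = mean_mask[iu, ju]
    k = int(np.floor(pct / 100.0 * scores.size))
    k = max(k, 0)
    order = np.lexsort((ju, iu, -scores))[:k]
    edges = [(int(iu[o]), int(ju[o]), float(scores[o])) for o in order]
    return EdgeRanking(edges, scope=scope)


def common_connections(rankings: Mapping[str, EdgeRanking],
                       stages: Mapping[str, int]
                       ) -> dict[int, set[tuple[int, int]]]:
    """Per-stage intersection of member subjects' top-k edge sets."""
    missing = sorted(set(rankings) - set(stages))
    if missing:
        raise ExplainerError(f"subjects without a stage: {missing}")
    out: dict[int, set[tuple[int, int]]] = {}
    for stage in sorted(set(stages.values())):
        members = [s for s, st in stages.items() if st == stage and s in rankings]
        if not members:
            warnings.warn(f"stage {stage} has no subjects; empty edge set")
            out[stage] = set()
            continue
        common = rankings[members[0]].edge_set()
        for s in members[1:]:
            common &= rankings[s].edge_set()
        out[stage] = common
    return out


def aggregate_networks(ranking: EdgeRanking, atlas: AtlasMap) -> pd.DataFrame:
    """Counts of ranked edges per unordered functional-network pair.

    The diagonal holds intra-network counts; the total over the upper
    triangle (plus diagonal) equals the ranking length.
    """
    labels = sorted(set(atlas.networks))
    table = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    n = len(atlas)
    for i, j, _ in ranking.edges:
        if i >= n or j >= n:
            raise ExplainerError(f"ROI {max(i, j)} not covered by the atlas")
        a, b = sorted((atlas.label(i), atlas.label(j)))
        table.loc[a, b] += 1
        if a != b:
            table.loc[b, a] += 1
    return table
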