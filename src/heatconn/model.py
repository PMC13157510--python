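"""Heat-kernel diffused multimodal GIN for connectome phenotype prediction.

Each fMRI modality m contributes, per subject, a node-feature matrix X (the
rows of the functional-connectivity matrix), an adjacency A built from
cosine similarity of those rows, and a heat kernel K = exp(-beta L) of the
graph Laplacian.  The forward pass per modality is

    H0      = K X                               (diffused node features)
    H_k     = MLP_k((1 + eps_k) H_{k-1} + W~ H_{k-1})   k = 1..n_layers
    z_m     = concat(sum_nodes H0, sum_nodes H1, ..., sum_nodes H_K)

where W~ is the kernel with its diagonal zeroed: the heat kernel supplies a
smooth neighbourhood weighting for the GIN sum aggregation, and the self
term is always carried by (1 + eps).  Modality embeddings are concatenated
and passed through a ReLU dense head for age regression and/or sex
classification.  The training objective is

    L = sum_m ||K^(m) - A^(m)||_F^2  +  lambda * sum_i loss(y_i, yhat_i)

with the diffusion scale beta^(m) learnable so the reconstruction term
regularizes the amount of smoothing (it keeps exp(-beta L) from drifting
toward the over-smoothed constant kernel).  Setting beta = 0 disables the
kernel entirely: diffusion becomes the identity and the aggregation reverts
to the original adjacency weights — the plain-GIN ablation arm, which
relies solely on the raw connectivity structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "GinLayerParams", "HkdMginConfig", "GraphBatch", "Prediction", "HkdMgin",
    "gin_update", "readout_sum", "concat_layer_readouts", "fuse_modalities",
    "reconstruction_loss", "supervised_loss", "total_loss", "make_graph_batch",
]


class ModelError(ValueError):
    pass


# ------------------------------------------------------------------- configs

@dataclass
class HkdMginConfig:
    """Architecture and loss configuration.

    ``hidden_dim`` follows the reference setting of 100 units; desk-scale
    runs may shrink it.  ``beta`` is the per-modality diffusion scale (one
    value broadcast to all modalities, or a mapping); with ``learn_beta`` the
    scale is optimized jointly with the network under the reconstruction
    penalty.  ``use_kernel=False`` forces beta = 0 (identity kernel), the
    plain-GIN ablation arm.
    """

    n_rois: int
    modalities: tuple[str, ...] = ("emoid", "nback")
    n_gin_layers: int = 2
    hidden_dim: int = 100
    input_dim: int | None = None  # defaults to n_rois (FC-profile features)
    beta: float | Mapping[str, float] = 1.0
    learn_beta: bool = True
    use_kernel: bool = True
    lam: float = 1.0
    task: str = "age"  # age | sex | joint
    head_hidden: int | None = None
    share_weights: bool = False
    seed: int = 0

    def __post_init__(self):
        self.modalities = tuple(self.modalities)
        if self.n_gin_layers < 1:
            raise ModelError("n_gin_layers must be >= 1")
        if self.hidden_dim < 1:
            raise ModelError("hidden_dim must be >= 1")
        if self.lam < 0:
            raise ModelError("lam must be >= 0")
        if self.task not in ("age", "sex", "joint"):
            raise ModelError(f"unknown task {self.task!r}")
        if self.input_dim is None:
            self.input_dim = self.n_rois
        if self.head_hidden is None:
            self.head_hidden = self.hidden_dim
        if not self.use_kernel:
            self.beta = 0.0
            self.learn_beta = False

    def beta_for(self, modality: str) -> float:
        if isinstance(self.beta, Mapping):
            return float(self.beta[modality])
        return float(self.beta)


@dataclass
class GinLayerParams:
    """One GIN layer: learnable eps plus a 2-layer MLP (ReLU between).

    ``bypass=True`` replaces the MLP with the identity (requires matching
    dimensions); this exists for unit-level verification of the update rule.
    """

    eps: Tensor
    w1: Tensor | None
    b1: Tensor | None
    w2: Tensor | None
    b2: Tensor | None
    layer_index: int = 0
    bypass: bool = False

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, hidden: int,
             out_dim: int, layer_index: int) -> "GinLayerParams":
        def glorot(fan_in, fan_out):
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return Tensor(rng.uniform(-s, s, size=(fan_in, fan_out)),
                          requires_grad=True)

        return cls(eps=Tensor(0.0, requires_grad=True),
                   w1=glorot(in_dim, hidden),
                   b1=Tensor(np.zeros(hidden), requires_grad=True),
                   w2=glorot(hidden, out_dim),
                   b2=Tensor(np.zeros(out_dim), requires_grad=True),
                   layer_index=layer_index)

    @classmethod
    def identity(cls, layer_index: int = 0, eps: float = 0.0) -> "GinLayerParams":
        return cls(eps=Tensor(float(eps)), w1=None, b1=None, w2=None, b2=None,
                   layer_index=layer_index, bypass=True)

    def tensors(self) -> list[Tensor]:
        ts = [self.eps]
        if not self.bypass:
            ts += [self.w1, self.b1, self.w2, self.b2]
        return ts


# --------------------------------------------------------------------- batch

@dataclass
class GraphBatch:
    """Stacked per-subject multimodal graphs plus targets.

    ``features[m]`` is (S, N, d), ``adjacency[m]`` is (S, N, N); the
    Laplacian eigendecompositions (per subject) are precomputed so kernels
    at any diffusion scale are two batched matrix products away.
    """

    modalities: tuple[str, ...]
    features: dict[str, np.ndarray]
    adjacency: dict[str, np.ndarray]
    eigvals: dict[str, np.ndarray]   # (S, N)
    eigvecs: dict[str, np.ndarray]   # (S, N, N)
    ages: np.ndarray | None = None
    sexes: np.ndarray | None = None
    subject_ids: list[str] | None = None
    _kernel_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_subjects(self) -> int:
        return self.features[self.modalities[0]].shape[0]

    @property
    def n_rois(self) -> int:
        return self.features[self.modalities[0]].shape[1]

    def kernels(self, modality: str, beta: float) -> np.ndarray:
        """Heat kernels exp(-beta L) for all subjects, (S, N, N), cached."""
        key = (modality, float(beta))
        if key not in self._kernel_cache:
            if beta == 0.0:
                s, n = self.n_subjects, self.n_rois
                k = np.broadcast_to(np.eye(n), (s, n, n)).copy()
            else:
                u = self.eigvecs[modality]
                w = np.exp(-beta * np.clip(self.eigvals[modality], 0.0, None))
                k = (u * w[:, None, :]) @ np.swapaxes(u, -1, -2)
                k = (k + np.swapaxes(k, -1, -2)) / 2.0
            self._kernel_cache[key] = k
        return self._kernel_cache[key]

    def diffused(self, modality: str, beta: float) -> np.ndarray:
        """Cached K X for a fixed diffusion scale (layer-0 representation)."""
        key = ("diff", modality, float(beta))
        if key not in self._kernel_cache:
            k = self.kernels(modality, beta)
            self._kernel_cache[key] = k @ self.features[modality]
        return self._kernel_cache[key]

    def recon_const(self, modality: str, beta: float) -> float:
        """Cached ||K - A||_F^2 (a constant whenever beta is not learned)."""
        key = ("recon", modality, float(beta))
        if key not in self._kernel_cache:
            d = self.kernels(modality, beta) - self.adjacency[modality]
            self._kernel_cache[key] = float(np.sum(d * d))
        return self._kernel_cache[key]

    def agg0(self, modality: str, beta: float) -> np.ndarray:
        """Cached hollow-kernel aggregation of the diffused features."""
        key = ("agg0", modality, float(beta))
        if key not in self._kernel_cache:
            if beta == 0.0:
                # kernel off: aggregation runs over the original adjacency
                hollow = self.adjacency[modality]
            else:
                k = self.kernels(modality, beta)
                hollow = k * (1.0 - np.eye(self.n_rois))
            self._kernel_cache[key] = hollow @ self.diffused(modality, beta)
        return self._kernel_cache[key]

    def subset(self, indices: np.ndarray) -> "GraphBatch":
        idx = np.asarray(indices)
        return GraphBatch(
            modalities=self.modalities,
            features={m: v[idx] for m, v in self.features.items()},
            adjacency={m: v[idx] for m, v in self.adjacency.items()},
            eigvals={m: v[idx] for m, v in self.eigvals.items()},
            eigvecs={m: v[idx] for m, v in self.eigvecs.items()},
            ages=None if self.ages is None else self.ages[idx],
            sexes=None if self.sexes is None else self.sexes[idx],
            subject_ids=None if self.subject_ids is None
            else [self.subject_ids[i] for i in idx],
        )


def make_graph_batch(cohort, density: float = 0.15,
                     variant: str = "combinatorial") -> GraphBatch:
    """Build a :class:`GraphBatch` from a cohort of FC matrices.

    Node features are FC rows; adjacency is the clipped-cosine graph at the
    given density; Laplacian eigendecompositions are computed per subject.
    """
    from . import data_io
    from .diffusion import graph_laplacian

    features: dict[str, np.ndarray] = {}
    adjacency: dict[str, np.ndarray] = {}
    eigvals: dict[str, np.ndarray] = {}
    eigvecs: dict[str, np.ndarray] = {}
    for m in cohort.modalities:
        fc = cohort.stacked(m)
        adjs = np.empty_like(fc)
        laps = np.empty_like(fc)
        for i in range(fc.shape[0]):
            a = data_io.build_edge_weights(fc[i], density=density)
            adjs[i] = a
            laps[i] = graph_laplacian(a, variant=variant).values
        lam, u = np.linalg.eigh(laps)
        features[m] = fc
        adjacency[m] = adjs
        eigvals[m] = lam
        eigvecs[m] = u
    return GraphBatch(
        modalities=cohort.modalities, features=features, adjacency=adjacency,
        eigvals=eigvals, eigvecs=eigvecs, ages=cohort.ages(),
        sexes=cohort.sexes().astype(float),
        subject_ids=[s.id for s in cohort.subjects])


@dataclass
class Prediction:
    age_estimate: np.ndarray | None = None
    sex_probability: np.ndarray | None = None

    def __post_init__(self):
        def raw(v):
            return v.value if isinstance(v, Tensor) else np.asarray(v)

        if self.age_estimate is not None and not np.all(np.isfinite(raw(self.age_estimate))):
            raise ModelError("non-finite age estimates")
        if self.sex_probability is not None:
            p = raw(self.sex_probability)
            if np.any(p < 0) or np.any(p > 1):
                raise ModelError("sex probabilities outside [0, 1]")


# ------------------------------------------------------- stand-alone ops

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def gin_update(h, neighbor_weights, params: GinLayerParams):
    """One GIN layer: MLP((1 + eps) h_v + sum_u w_vu h_u).

    ``neighbor_weights`` must be symmetric, nonnegative and hollow; with
    binary 0/1 weights this is the textbook GIN update, with heat-kernel
    weights it is the smooth kernel-weighted aggregation.  Accepts (N, d) or
    batched (S, N, d) features.
    """
    w = np.asarray(neighbor_weights.value if isinstance(neighbor_weights, Tensor)
                   else neighbor_weights, dtype=float)
    if np.max(np.abs(w - np.swapaxes(w, -1, -2))) > 1e-8:
        raise ModelError("neighbor weights must be symmetric")
    if w.min() < -1e-12:
        raise ModelError("neighbor weights must be nonnegative")
    if np.abs(np.diagonal(w, axis1=-2, axis2=-1)).max() > 1e-12:
        raise ModelError("neighbor weights must have zero diagonal")
    out = _gin_layer(_as_tensor(h), _as_tensor(neighbor_weights), params)
    if not np.all(np.isfinite(out.value)):
        raise ModelError(f"non-finite activations in GIN layer {params.layer_index}")
    return out if isinstance(h, Tensor) else out.value


def _gin_layer(h: Tensor, w: Tensor, params: GinLayerParams) -> Tensor:
    agg = (params.eps + 1.0) * h + w @ h
    if params.bypass:
        return agg
    return (agg @ params.w1 + params.b1).relu() @ params.w2 + params.b2


def readout_sum(h):
    """Graph-level readout: coordinate-wise sum over nodes (axis -2)."""
    if isinstance(h, Tensor):
        return h.sum(axis=h.ndim - 2)
    return np.asarray(h).sum(axis=-2)


def concat_layer_readouts(vectors: Sequence):
    """Concatenate per-layer graph vectors in layer order 0..K."""
    if len(vectors) == 0:
        raise ModelError("need at least one layer readout")
    if isinstance(vectors[0], Tensor):
        return concat(vectors, axis=-1)
    return np.concatenate([np.asarray(v) for v in vectors], axis=-1)


def fuse_modalities(embeddings: Mapping[str, np.ndarray],
                    modalities: Sequence[str]) -> np.ndarray:
    """Concatenate per-modality embeddings in declared modality order."""
    missing = [m for m in modalities if m not in embeddings]
    if missing:
        raise ModelError(f"missing modality embeddings: {missing}")
    parts = [embeddings[m] for m in modalities]
    if isinstance(parts[0], Tensor):
        return concat(parts, axis=-1)
    return np.concatenate([np.asarray(p) for p in parts], axis=-1)


def reconstruction_loss(kernels: Mapping[str, np.ndarray],
                        adjacencies: Mapping[str, np.ndarray]):
    """Sum over modalities of the squared Frobenius distance ||K - A||_F^2."""
    total = None
    for m, k in kernels.items():
        a = adjacencies[m]
        ka = np.asarray(k.value if isinstance(k, Tensor) else k)
        aa = np.asarray(a.value if isinstance(a, Tensor) else a)
        if ka.shape != aa.shape:
            raise ModelError(f"shape mismatch for modality {m!r}: "
                             f"{ka.shape} vs {aa.shape}")
        d = _as_tensor(k) - _as_tensor(a)
        term = (d * d).sum()
        total = term if total is None else total + term
    if total is None:
        raise ModelError("no modalities supplied")
    return total if any(isinstance(v, Tensor) for v in kernels.values()) else float(total.value)


def _bce(p: Tensor, y: np.ndarray, eps: float = 1e-12) -> Tensor:
    pc = p.clamp(eps, 1.0 - eps)
    return -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log())


def supervised_loss(pred: Prediction, targets: Mapping[str, np.ndarray],
                    task: str = "age", reduction: str = "mean"):
    """Mean squared error (age), binary cross-entropy (sex), or their sum.

    ``reduction='mean'`` averages over subjects; ``'sum'`` matches the
    summed per-subject form used inside the total training objective.
    """
    terms = []
    if task in ("age", "joint"):
        y = np.asarray(targets["age"], dtype=float)
        yhat = _as_tensor(pred.age_estimate)
        d = yhat - Tensor(y)
        terms.append(d * d)
    if task in ("sex", "joint"):
        y = np.asarray(targets["sex"], dtype=float)
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ModelError("sex labels must be in {0, 1}")
        terms.append(_bce(_as_tensor(pred.sex_probability), y))
    if not terms:
        raise ModelError(f"unknown task {task!r}")
    per_subject = terms[0]
    for t in terms[1:]:
        per_subject = per_subject + t
    out = per_subject.sum() if reduction == "sum" else per_subject.mean()
    tensor_in = isinstance(pred.age_estimate, Tensor) or isinstance(
        pred.sex_probability, Tensor)
    return out if tensor_in else float(out.value)


def total_loss(kernels, adjacencies, pred: Prediction, targets, lam: float,
               task: str = "age"):
    """Reconstruction + lam * summed per-subject supervised loss."""
    if lam < 0:
        raise ModelError("lam must be >= 0")
    rec = reconstruction_loss(kernels, adjacencies)
    sup = supervised_loss(pred, targets, task=task, reduction="sum")
    if isinstance(rec, Tensor) or isinstance(sup, Tensor):
        return _as_tensor(rec) + lam * _as_tensor(sup)
    return float(rec) + lam * float(sup)


# ----------------------------------------------------------------- the model

def _softplus(x: Tensor) -> Tensor:
    return (x.exp() + 1.0).log()


class HkdMgin:
    """The heat-kernel diffused multimodal GIN with task head(s).

    Parameters are initialized from ``config.seed`` (Glorot-uniform weights,
    zero biases, eps = 0).  ``forward`` is deterministic given (parameters,
    batch).  Age output is an affine rescaling of the head output
    (``target_mean`` + ``target_scale`` * raw); training sets the affine
    from the training targets so the head starts near the target range.
    """

    def __init__(self, config: HkdMginConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.layers: dict[str, list[GinLayerParams]] = {}
        stacks = ["shared"] if c.share_weights else list(c.modalities)
        for name in stacks:
            layers = []
            in_dim = c.input_dim
            for k in range(1, c.n_gin_layers + 1):
                layers.append(GinLayerParams.init(
                    rng, in_dim, c.hidden_dim, c.hidden_dim, layer_index=k))
                in_dim = c.hidden_dim
            self.layers[name] = layers
        emb_dim = c.input_dim + c.n_gin_layers * c.hidden_dim
        fused_dim = emb_dim * len(c.modalities)
        out_dim = 2 if c.task == "joint" else 1

        def glorot(fi, fo):
            s = np.sqrt(6.0 / (fi + fo))
            return Tensor(rng.uniform(-s, s, size=(fi, fo)), requires_grad=True)

        self.head_w1 = glorot(fused_dim, c.head_hidden)
        self.head_b1 = Tensor(np.zeros(c.head_hidden), requires_grad=True)
        # zero-init output layer: predictions start at the target mean
        # (age) / probability 0.5 (sex), which keeps early steps well-scaled
        self.head_w2 = Tensor(np.zeros((c.head_hidden, out_dim)),
                              requires_grad=True)
        self.head_b2 = Tensor(np.zeros(out_dim), requires_grad=True)
        # sum readouts grow with N; a fixed 1/N factor keeps head inputs O(1)
        self._embed_scale = 1.0 / c.n_rois

        self.beta_raw: dict[str, Tensor] = {}
        for m in c.modalities:
            b0 = c.beta_for(m)
            if c.learn_beta:
                raw = np.log(np.expm1(max(b0, 1e-6)))
                self.beta_raw[m] = Tensor(raw, requires_grad=True)
        self.target_mean = 0.0
        self.target_scale = 1.0
        self.last_kernels: dict[str, np.ndarray] = {}  # introspection hook

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layers in self.layers.values():
            for lp in layers:
                ps.extend(lp.tensors())
        ps += [self.head_w1, self.head_b1, self.head_w2, self.head_b2]
        ps += list(self.beta_raw.values())
        return ps

    def _stack_for(self, modality: str) -> list[GinLayerParams]:
        return self.layers["shared" if self.config.share_weights else modality]

    def beta_value(self, modality: str):
        """Current diffusion scale for a modality (Tensor if learnable)."""
        if modality in self.beta_raw:
            return _softplus(self.beta_raw[modality])
        return self.config.beta_for(modality)

    # -- forward ------------------------------------------------------------
    def _modality_embedding(self, batch: GraphBatch, m: str,
                            edge_mask: Tensor | None,
                            feature_mask: Tensor | None) -> tuple[Tensor, Tensor]:
        """Graph embedding and kernel tensor for one modality."""
        c = self.config
        n = batch.n_rois
        hollow = 1.0 - np.eye(n)
        x = Tensor(batch.features[m])
        if feature_mask is not None:
            x = x * feature_mask  # (d,) broadcast over (S, N, d)

        beta = self.beta_value(m)
        masked = edge_mask is not None or feature_mask is not None
        fast = not isinstance(beta, Tensor) and not masked
        if isinstance(beta, Tensor):
            u = Tensor(batch.eigvecs[m])
            lam = np.clip(batch.eigvals[m], 0.0, None)
            w = (Tensor(-lam) * beta).exp()           # (S, N)
            s, nn = lam.shape
            k = (u * w.reshape(s, 1, nn)) @ u.swap_last()
        else:
            k = Tensor(batch.kernels(m, float(beta)))

        if edge_mask is not None:
            # mask off-diagonal kernel entries; keep the self entry intact
            k = k * (edge_mask * hollow) + k * Tensor(np.eye(n))
        self.last_kernels[m] = k.value

        if not isinstance(beta, Tensor) and float(beta) == 0.0:
            # kernel off: diffusion is the identity and the GIN aggregates
            # over the original adjacency (the plain-GIN baseline arm)
            w_agg = Tensor(batch.adjacency[m])
            if edge_mask is not None:
                w_agg = w_agg * (edge_mask * hollow)
        else:
            w_agg = k * Tensor(hollow)
        readouts = []
        h: Tensor
        for j, lp in enumerate(self._stack_for(m)):
            if j == 0:
                if fast:
                    # K X and the hollow-kernel aggregation of it are
                    # constants at fixed beta; reuse the batch caches
                    h = Tensor(batch.diffused(m, float(beta)))
                    readouts.append(h.sum(axis=1))
                    agg = (lp.eps + 1.0) * h + Tensor(batch.agg0(m, float(beta)))
                else:
                    h = k @ x  # diffused node features, layer-0 representation
                    readouts.append(h.sum(axis=1))
                    agg = (lp.eps + 1.0) * h + w_agg @ h
            else:
                agg = (lp.eps + 1.0) * h + w_agg @ h
            if lp.bypass:
                h = agg
            else:
                h = (agg @ lp.w1 + lp.b1).relu() @ lp.w2 + lp.b2
            if not np.all(np.isfinite(h.value)):
                raise ModelError(f"non-finite activations in GIN layer "
                                 f"{lp.layer_index} (modality {m!r})")
            readouts.append(h.sum(axis=1))
        return concat(readouts, axis=-1), k

    def forward_tensors(self, batch: GraphBatch, edge_mask: Tensor | None = None,
                        feature_mask: Tensor | None = None
                        ) -> tuple[dict[str, Tensor], dict[str, Tensor]]:
        """Raw head outputs plus the kernel tensors used (per modality)."""
        c = self.config
        embeddings: dict[str, Tensor] = {}
        kernels: dict[str, Tensor] = {}
        for m in c.modalities:
            z, k = self._modality_embedding(batch, m, edge_mask, feature_mask)
            embeddings[m] = z
            kernels[m] = k
        fused = fuse_modalities(embeddings, c.modalities) * self._embed_scale
        hidden = (fused @ self.head_w1 + self.head_b1).relu()
        out = hidden @ self.head_w2 + self.head_b2  # (S, out_dim)
        heads: dict[str, Tensor] = {}
        if c.task == "age":
            heads["age"] = out.reshape(out.shape[0]) * self.target_scale + self.target_mean
        elif c.task == "sex":
            heads["sex"] = out.reshape(out.shape[0]).sigmoid()
        else:
            s = out.shape[0]
            age_col = (out @ Tensor(np.array([[1.0], [0.0]]))).reshape(s)
            sex_col = (out @ Tensor(np.array([[0.0], [1.0]]))).reshape(s)
            heads["age"] = age_col * self.target_scale + self.target_mean
            heads["sex"] = sex_col.sigmoid()
        return heads, kernels

    def forward(self, batch: GraphBatch) -> Prediction:
        heads, _ = self.forward_tensors(batch)
        return Prediction(
            age_estimate=heads["age"].value if "age" in heads else None,
            sex_probability=heads["sex"].value if "sex" in heads else None)

    def loss(self, batch: GraphBatch, targets: Mapping[str, np.ndarray] | None = None
             ) -> Tensor:
        """Total training objective (reconstruction + lam * supervised sum)."""
        c = self.config
        if targets is None:
            targets = {"age": batch.ages, "sex": batch.sexes}
        heads, kernels = self.forward_tensors(batch)
        pred = Prediction(age_estimate=heads.get("age"),
                          sex_probability=heads.get("sex"))
        if not c.learn_beta:
            # kernels are constants: reuse the cached reconstruction value
            rec = sum(batch.recon_const(m, c.beta_for(m)) for m in c.modalities)
            sup = supervised_loss(pred, targets, task=c.task, reduction="sum")
            return Tensor(rec) + c.lam * sup
        return total_loss(kernels, {m: batch.adjacency[m] for m in c.modalities},
                          pred, targets, lam=c.lam, task=c.task)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: parameters + config + target affine."""
        arrays = {}
        for m, layers in self.layers.items():
            for lp in layers:
                pre = f"layer/{m}/{lp.layer_index}"
                arrays[f"{pre}/eps"] = lp.eps.value
                for nm in ("w1", "b1", "w2", "b2"):
                    arrays[f"{pre}/{nm}"] = getattr(lp, nm).value
        for nm in ("head_w1", "head_b1", "head_w2", "head_b2"):
            arrays[nm] = getattr(self, nm).value
        for m, t in self.beta_raw.items():
            arrays[f"beta_raw/{m}"] = t.value
        cfg = asdict(self.config)
        cfg["modalities"] = list(cfg["modalities"])
        arrays["config_json"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8)
        arrays["target_affine"] = np.array([self.target_mean, self.target_scale])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "HkdMgin":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config_json"]).decode())
            cfg["modalities"] = tuple(cfg["modalities"])
            model = cls(HkdMginConfig(**cfg))
            for m, layers in model.layers.items():
                for lp in layers:
                    pre = f"layer/{m}/{lp.layer_index}"
                    lp.eps.value = data[f"{pre}/eps"]
                    for nm in ("w1", "b1", "w2", "b2"):
                        getattr(lp, nm).value = data[f"{pre}/{nm}"]
            for nm in ("head_w1", "head_b1", "head_w2", "head_b2"):
                getattr(model, nm).value = data[nm]
            for m in list(model.beta_raw):
                model.beta_raw[m].value = data[f"beta_raw/{m}"]
            model.target_mean, model.target_scale = data["target_affine"]
        return model
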