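"""Synthetic multimodal connectome cohorts with planted ground truth.

The simulator emulates the statistical shape of a task-fMRI developmental
cohort: for each subject and each of two modalities it builds a planted
correlation matrix from a block model (ROIs grouped into functional
networks, elevated within-network correlation), plants a monotone age
effect on designated inter-network blocks (FRNT-MEM and FRNT-SAL by
default) and an additive sex effect on a designated edge subset, projects
the target to the nearest valid correlation matrix, and then samples BOLD
time series from a zero-mean multivariate normal with that correlation.
Functional connectivity is recomputed from the sampled series through the
same Pearson pipeline used for real data, so the empirical FC carries
realistic sampling noise at the configured number of time points.

Effects are planted in the correlation domain rather than the time domain
so that recovery tests have exact oracles: the planted matrices, and the
boolean indicators of age-signal and sex-signal edges, are returned as
:class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import data_io
from .data_io import (AtlasMap, Cohort, ConnectivityMatrix, RoiTimeSeries,
                      SubjectRecord, compute_pearson_fc)

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort",
           "planted_block_correlation", "make_atlas", "age_to_stage"]


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Simulator parameters; defaults define the reference study conditions.

    Ages are uniform on ``age_range`` with five equal-width developmental
    stages; sexes are balanced.  ``age_slope`` is the per-year increase of
    the planted correlation in the designated inter-network blocks;
    ``sex_shift`` is added (M) / subtracted (F) on the designated sex edges.
    ``subject_sd`` is the standard deviation of a per-subject random effect
    on the signal blocks whose two modality components are correlated at
    ``cross_modality_corr``.  ``noise_sd`` is white observation noise added
    to the unit-variance BOLD series.
    """

    n_subjects: int = 400
    n_rois: int = 60
    n_networks: int = 8
    timepoints: int = 124
    age_range: tuple[float, float] = (8.0, 22.0)
    base_corr: float = 0.35
    age_slope: float = 0.015
    age_networks: tuple[tuple[str, str], ...] = (("FRNT", "MEM"), ("FRNT", "SAL"))
    sex_shift: float = 0.08
    n_sex_edges: int = 40
    subject_sd: float = 0.02
    cross_modality_corr: float = 0.6
    noise_sd: float = 0.25
    modalities: tuple[str, ...] = ("emoid", "nback")
    seed: int = 0

    def __post_init__(self):
        if self.n_networks > self.n_rois:
            raise SimulationError("n_networks must be <= n_rois")
        if self.timepoints < 3:
            raise SimulationError("need at least 3 time points")
        if self.n_networks > len(data_io.NETWORK_LABELS):
            raise SimulationError("more networks than available labels")


@dataclass
class GroundTruth:
    """Planted matrices and signal-edge indicators for recovery oracles."""

    planted: dict[str, dict[str, np.ndarray]]  # subject -> modality -> (N, N)
    age_edges: np.ndarray                       # boolean (N, N), symmetric
    sex_edges: np.ndarray                       # boolean (N, N), symmetric
    atlas: AtlasMap
    ages: np.ndarray = field(default=None)
    sexes: np.ndarray = field(default=None)    # M=1 / F=0


def make_atlas(cfg: SimConfig) -> AtlasMap:
    """Contiguous, near-equal-size network assignment over the ROIs."""
    required: list[str] = []
    for a, b in cfg.age_networks:
        for name in (a, b):
            if name not in required:
                required.append(name)
    if len(required) > cfg.n_networks:
        raise SimulationError("n_networks too small for the designated blocks")
    labels = required + [l for l in data_io.NETWORK_LABELS
                         if l not in required][: cfg.n_networks - len(required)]
    bounds = np.linspace(0, cfg.n_rois, cfg.n_networks + 1).astype(int)
    networks = []
    for i, lab in enumerate(labels):
        networks.extend([lab] * (bounds[i + 1] - bounds[i]))
    return AtlasMap(networks)


def age_to_stage(age: float, age_range: tuple[float, float] = (8.0, 22.0)) -> int:
    """Five equal-width developmental stages over the age range."""
    lo, hi = age_range
    s = int(np.floor((age - lo) / (hi - lo) * 5.0)) + 1
    return int(np.clip(s, 1, 5))


def _block_masks(cfg: SimConfig, atlas: AtlasMap) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(atlas.networks)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    age_mask = np.zeros((cfg.n_rois, cfg.n_rois), dtype=bool)
    for a, b in cfg.age_networks:
        in_a = labels == a
        in_b = labels == b
        age_mask |= np.outer(in_a, in_b) | np.outer(in_b, in_a)
    return same, age_mask


def _sex_edge_mask(cfg: SimConfig, atlas: AtlasMap, age_mask: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """A fixed random subset of inter-network edges disjoint from age blocks."""
    labels = np.asarray(atlas.networks)
    same = labels[:, None] == labels[None, :]
    iu, ju = np.triu_indices(cfg.n_rois, k=1)
    eligible = ~same[iu, ju] & ~age_mask[iu, ju]
    pool = np.flatnonzero(eligible)
    if pool.size < cfg.n_sex_edges:
        raise SimulationError("not enough eligible edges for the sex effect")
    pick = rng.choice(pool, size=cfg.n_sex_edges, replace=False)
    mask = np.zeros((cfg.n_rois, cfg.n_rois), dtype=bool)
    mask[iu[pick], ju[pick]] = True
    return mask | mask.T


def _nearest_correlation(target: np.ndarray, eig_floor: float = 1e-6
                         ) -> np.ndarray:
    """Eigenvalue clipping followed by diagonal renormalization."""
    t = (target + target.T) / 2.0
    lam, u = np.linalg.eigh(t)
    lam = np.clip(lam, eig_floor, None)
    c = (u * lam) @ u.T
    d = np.sqrt(np.diag(c))
    c = c / np.outer(d, d)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def planted_block_correlation(cfg: SimConfig, subject: SubjectRecord,
                              atlas: AtlasMap | None = None,
                              subject_effect: float = 0.0,
                              _masks=None) -> np.ndarray:
    """Planted correlation target for one subject (before sampling noise).

    Within-network blocks sit at ``base_corr``; the designated inter-network
    blocks at ``age_slope * (age - age_min) + subject_effect``; designated
    sex edges are shifted by +/- ``sex_shift``.  The target is projected to
    the nearest valid correlation matrix.  Raises if the projection moves
    any planted entry by more than 0.05 (infeasible effect sizes).
    """
    if atlas is None:
        atlas = make_atlas(cfg)
    if _masks is None:
        same, age_mask = _block_masks(cfg, atlas)
        sex_mask = _sex_edge_mask(cfg, atlas, age_mask,
                                  np.random.default_rng(cfg.seed))
    else:
        same, age_mask, sex_mask = _masks
    n = cfg.n_rois
    target = np.zeros((n, n))
    target[same] = cfg.base_corr
    target[age_mask] = (cfg.age_slope * (subject.age - cfg.age_range[0])
                        + subject_effect)
    shift = cfg.sex_shift if subject.sex == "M" else -cfg.sex_shift
    target[sex_mask] += shift
    np.fill_diagonal(target, 1.0)
    target = np.clip(target, -0.99, 0.99)
    c = _nearest_correlation(target)
    offdiag = ~np.eye(n, dtype=bool)
    drift = np.max(np.abs(c - target)[offdiag])
    if drift > 0.05:
        raise SimulationError(
            f"projection moved a planted correlation by {drift:.3f} > 0.05; "
            "use smaller effect sizes")
    return c


def simulate_cohort(cfg: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Draw a full multimodal cohort; deterministic given ``cfg.seed``.

    Returns the cohort (with empirical Pearson FC per subject and modality)
    and the ground truth (planted matrices + signal-edge indicators).
    """
    rng = np.random.default_rng(cfg.seed)
    atlas = make_atlas(cfg)
    same, age_mask = _block_masks(cfg, atlas)
    sex_mask = _sex_edge_mask(cfg, atlas, age_mask, rng)
    masks = (same, age_mask, sex_mask)

    lo, hi = cfg.age_range
    ages = rng.uniform(lo, hi, size=cfg.n_subjects)
    n_m = cfg.n_subjects // 2
    sexes = np.array(["M"] * (cfg.n_subjects - n_m) + ["F"] * n_m)
    rng.shuffle(sexes)

    # per-subject effects, correlated across the two modalities
    rho = cfg.cross_modality_corr
    n_mod = len(cfg.modalities)
    cov = np.full((n_mod, n_mod), rho)
    np.fill_diagonal(cov, 1.0)
    chol_eff = np.linalg.cholesky(cov)
    effects = (rng.standard_normal((cfg.n_subjects, n_mod)) @ chol_eff.T
               ) * cfg.subject_sd

    subjects: list[SubjectRecord] = []
    matrices: dict[str, dict[str, ConnectivityMatrix]] = {}
    planted: dict[str, dict[str, np.ndarray]] = {}
    width = len(str(cfg.n_subjects))
    for i in range(cfg.n_subjects):
        sid = f"sub-{i + 1:0{width}d}"
        rec = SubjectRecord(sid, float(ages[i]), str(sexes[i]),
                            age_to_stage(ages[i], cfg.age_range),
                            age_range=cfg.age_range)
        subjects.append(rec)
        matrices[sid] = {}
        planted[sid] = {}
        for j, m in enumerate(cfg.modalities):
            c = planted_block_correlation(cfg, rec, atlas,
                                          subject_effect=float(effects[i, j]),
                                          _masks=masks)
            planted[sid][m] = c
            chol = np.linalg.cholesky(c + 1e-10 * np.eye(cfg.n_rois))
            z = rng.standard_normal((cfg.timepoints, cfg.n_rois)) @ chol.T
            if cfg.noise_sd > 0:
                z = z + cfg.noise_sd * rng.standard_normal(z.shape)
            ts = RoiTimeSeries(sid, m, z.T)
            matrices[sid][m] = compute_pearson_fc(ts)

    cohort = Cohort(subjects, cfg.modalities, matrices)
    gt = GroundTruth(planted=planted, age_edges=age_mask, sex_edges=sex_mask,
                     atlas=atlas,
                     ages=np.asarray(ages),
                     sexes=(sexes == "M").astype(int))
    return cohort, gt
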