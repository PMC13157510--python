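"""Domain types, file I/O and connectivity-graph construction.

The package operates on region-of-interest (ROI) level data: per-subject BOLD
time series (N ROIs x M time points), the Pearson functional-connectivity
(FC) matrices derived from them, a subject table (id, age, sex, optional
developmental stage) and an atlas map assigning each ROI to a functional
network (DMN, SAL, FRNT, ...).  On disk, matrices are plain TSV (no header)
or HDF5 datasets named ``<subject>/<modality>``; tables are TSV with headers.
ROI indices are 0-based in memory; atlas files are 1-based by default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: Functional-network vocabulary (Power-atlas style systems).
NETWORK_LABELS = (
    "SM Hand", "SM Mouth", "VIS", "DMN", "FRNT", "CB", "SAL", "MEM", "other",
)

SYMMETRY_TOL = 1e-10


class DataError(ValueError):
    """Raised when an input violates a documented contract."""


# --------------------------------------------------------------------- types

@dataclass
class RoiTimeSeries:
    """Per-subject, per-modality BOLD signal matrix (N ROIs x M time points)."""

    subject_id: str
    modality: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("time series must be a 2-D (ROI x time) matrix")
        n, m = self.values.shape
        if n < 2:
            raise DataError("need at least 2 ROIs")
        if m < 3:
            raise DataError("need at least 3 time points")
        if not np.all(np.isfinite(self.values)):
            raise DataError("time series contains non-finite values")
        sd = self.values.std(axis=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise DataError(f"zero-variance ROI rows at indices {dead.tolist()}")

    @property
    def roi_count(self) -> int:
        return self.values.shape[0]

    @property
    def timepoint_count(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Pearson correlation matrix with unit diagonal."""

    subject_id: str
    modality: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("connectivity matrix must be square")
        if np.max(np.abs(v - v.T)) > SYMMETRY_TOL:
            raise DataError("connectivity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=0, rtol=0):
            raise DataError("connectivity diagonal must be exactly 1")
        if v.min() < -1.0 or v.max() > 1.0:
            raise DataError("correlations must lie in [-1, 1]")
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class AtlasMap:
    """ROI index -> functional-network label (plus optional MNI coordinates)."""

    networks: Sequence[str]
    coordinates: np.ndarray | None = None

    def __post_init__(self):
        self.networks = list(self.networks)
        unknown = sorted({n for n in self.networks} - set(NETWORK_LABELS))
        if unknown:
            raise DataError(f"unknown network labels: {unknown}")
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
            if self.coordinates.shape != (len(self.networks), 3):
                raise DataError("coordinates must be (N, 3)")

    def __len__(self) -> int:
        return len(self.networks)

    def label(self, roi: int) -> str:
        return self.networks[roi]


@dataclass
class SubjectRecord:
    id: str
    age: float
    sex: str  # "F" or "M"
    stage: int | None = None
    age_range: tuple[float, float] = (8.0, 22.0)

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise DataError(f"sex must be 'F' or 'M', got {self.sex!r}")
        lo, hi = self.age_range
        if not lo <= self.age <= hi:
            raise DataError(f"age {self.age} outside configured range [{lo}, {hi}]")
        if self.stage is not None and self.stage not in (1, 2, 3, 4, 5):
            raise DataError(f"stage must be in 1..5, got {self.stage}")


@dataclass
class Cohort:
    """Subjects plus one connectivity matrix per declared modality each."""

    subjects: list[SubjectRecord]
    modalities: tuple[str, ...]
    matrices: dict[str, dict[str, ConnectivityMatrix]] = field(default_factory=dict)

    def __post_init__(self):
        self.modalities = tuple(self.modalities)
        n_ref = None
        for s in self.subjects:
            per_subject = self.matrices.get(s.id, {})
            for m in self.modalities:
                if m not in per_subject:
                    raise DataError(f"subject {s.id} is missing modality {m!r}")
                n = per_subject[m].n_rois
                if n_ref is None:
                    n_ref = n
                elif n != n_ref:
                    raise DataError("all connectivity matrices must share N")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_rois(self) -> int:
        first = self.subjects[0]
        return self.matrices[first.id][self.modalities[0]].n_rois

    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.subjects], dtype=float)

    def sexes(self) -> np.ndarray:
        """Binary sex labels, M=1 / F=0."""
        return np.array([1 if s.sex == "M" else 0 for s in self.subjects])

    def stages(self) -> np.ndarray:
        return np.array([-1 if s.stage is None else s.stage for s in self.subjects])

    def stacked(self, modality: str) -> np.ndarray:
        """All subjects' FC matrices for one modality as an (S, N, N) array."""
        return np.stack([self.matrices[s.id][modality].values for s in self.subjects])


# ---------------------------------------------------------------- operations

def compute_pearson_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between every pair of ROI time courses.

    Entry (i, j) is the sample correlation of rows i and j; the diagonal is
    forced to exactly 1 and symmetry is enforced against round-off.
    """
    with np.errstate(invalid="raise"):
        c = np.corrcoef(ts.values)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(ts.subject_id, ts.modality, c)


def vectorize_upper(fc: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Strictly-upper-triangular entries in row-major order.

    For N ROIs the result has length N(N-1)/2, ordered
    (0,1), (0,2), ..., (0,N-1), (1,2), ... — the standard stable ordering
    used for vectorized-FC baselines.
    """
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc)
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def build_node_features(fc: ConnectivityMatrix) -> np.ndarray:
    """Node feature matrix: row i is ROI i's connectivity profile (row i of FC)."""
    return fc.values.copy()


def build_edge_weights(features: np.ndarray, density: float = 0.15,
                       method: str = "cosine") -> np.ndarray:
    """Adjacency from pairwise cosine similarity of node-feature rows.

    Negative similarities are clipped to 0 (diffusion needs nonnegative
    weights), the diagonal is zeroed, and only the top ``density`` fraction
    of upper-triangular weights is kept; ties are broken by (i, j)
    lexicographic order.  Logs a warning if the result is disconnected.
    """
    if method != "cosine":
        raise DataError(f"unsupported edge-weight method {method!r}")
    if not 0.0 < density <= 1.0:
        raise DataError("density must be in (0, 1]")
    f = np.asarray(features, dtype=float)
    norms = np.linalg.norm(f, axis=1)
    if np.any(norms == 0):
        raise DataError(f"zero-norm feature rows at {np.flatnonzero(norms == 0).tolist()}")
    sim = (f / norms[:, None]) @ (f / norms[:, None]).T
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(sim, 0.0)

    n = sim.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = sim[iu, ju]
    k = max(1, int(round(density * w.size)))
    # sort by (-weight, i, j): stable lexicographic tie-break
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    adj = np.zeros_like(sim)
    adj[iu[keep], ju[keep]] = w[keep]
    adj = adj + adj.T

    n_comp, _ = connected_components((adj > 0).astype(np.int8), directed=False)
    if n_comp > 1:
        logger.warning("sparsified graph has %d connected components", n_comp)
    return adj


# ----------------------------------------------------------------- matrix IO

def write_matrix(path: str | Path, values: np.ndarray, *,
                 subject: str | None = None, modality: str | None = None) -> None:
    """Write a matrix as headerless TSV, or into HDF5 as ``subject/modality``."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        if subject is None or modality is None:
            raise DataError("HDF5 output needs subject and modality names")
        with h5py.File(path, "a") as f:
            key = f"{subject}/{modality}"
            if key in f:
                del f[key]
            f.create_dataset(key, data=np.asarray(values, dtype=float))
    else:
        np.savetxt(path, np.asarray(values, dtype=float), delimiter="\t", fmt="%.17g")


def read_matrix(path: str | Path, *, subject: str | None = None,
                modality: str | None = None) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix file not found: {path}")
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            key = f"{subject}/{modality}"
            if key not in f:
                raise DataError(f"dataset {key!r} not found in {path}")
            return np.asarray(f[key][()], dtype=float)
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", dtype=float))


def write_subject_table(path: str | Path, subjects: Sequence[SubjectRecord]) -> None:
    rows = [{"id": s.id, "age": s.age, "sex": s.sex,
             "stage": "" if s.stage is None else s.stage} for s in subjects]
    pd.DataFrame(rows, columns=["id", "age", "sex", "stage"]).to_csv(
        path, sep="\t", index=False)


def read_subject_table(path: str | Path,
                       age_range: tuple[float, float] = (8.0, 22.0)
                       ) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "age", "sex"}
    if not required.issubset(df.columns):
        raise DataError(f"subject table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        stage = None
        if "stage" in df.columns and not pd.isna(row["stage"]):
            stage = int(row["stage"])
        out.append(SubjectRecord(str(row["id"]), float(row["age"]),
                                 str(row["sex"]), stage, age_range=age_range))
    return out


def write_atlas(path: str | Path, atlas: AtlasMap, one_based: bool = True) -> None:
    offset = 1 if one_based else 0
    rows = []
    for i, net in enumerate(atlas.networks):
        row = {"roi": i + offset, "network": net}
        if atlas.coordinates is not None:
            row.update(zip("xyz", atlas.coordinates[i]))
        rows.append(row)
    cols = ["roi", "network"] + (["x", "y", "z"] if atlas.coordinates is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_atlas(path: str | Path, one_based: bool = True) -> AtlasMap:
    df = pd.read_csv(path, sep="\t")
    if not {"roi", "network"}.issubset(df.columns):
        raise DataError("atlas must have columns roi, network")
    offset = 1 if one_based else 0
    idx = df["roi"].to_numpy(dtype=int) - offset
    n = len(df)
    if sorted(idx.tolist()) != list(range(n)):
        raise DataError("atlas ROI indices must be contiguous 0..N-1 (after offset)")
    networks = [""] * n
    for i, net in zip(idx, df["network"]):
        networks[i] = str(net)
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = np.zeros((n, 3))
        coords[idx] = df[["x", "y", "z"]].to_numpy(dtype=float)
    return AtlasMap(networks, coords)


def write_cohort(directory: str | Path, cohort: Cohort) -> None:
    """Write a cohort as subjects.tsv + one TSV matrix per subject/modality."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_subject_table(directory / "subjects.tsv", cohort.subjects)
    for s in cohort.subjects:
        for m in cohort.modalities:
            write_matrix(directory / f"{s.id}_{m}.tsv",
                         cohort.matrices[s.id][m].values)


def read_cohort(directory: str | Path, modalities: Sequence[str],
                atlas: AtlasMap | None = None,
                age_range: tuple[float, float] = (8.0, 22.0)) -> Cohort:
    """Load a cohort written by :func:`write_cohort`.

    Raises a distinct error for a missing modality file, a dimension
    mismatch, or an atlas whose size disagrees with the matrices.
    """
    directory = Path(directory)
    subjects = read_subject_table(directory / "subjects.tsv", age_range=age_range)
    matrices: dict[str, dict[str, ConnectivityMatrix]] = {}
    n_ref: int | None = None
    for s in subjects:
        matrices[s.id] = {}
        for m in modalities:
            f = directory / f"{s.id}_{m}.tsv"
            if not f.exists():
                raise DataError(f"subject {s.id} is missing modality {m!r} ({f})")
            vals = read_matrix(f)
            if n_ref is None:
                n_ref = vals.shape[0]
            elif vals.shape[0] != n_ref:
                raise DataError(f"dimension mismatch for subject {s.id}/{m}: "
                                f"{vals.shape[0]} vs {n_ref}")
            matrices[s.id][m] = ConnectivityMatrix(s.id, m, vals)
    if atlas is not None and n_ref is not None and len(atlas) != n_ref:
        raise DataError(f"atlas has {len(atlas)} entries but matrices have {n_ref} ROIs")
    return Cohort(subjects, tuple(modalities), matrices)
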