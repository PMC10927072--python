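"""The clusterness/trajectoriness score landscape.

Many simulated datasets are scored, their five-score vectors z-standardized
column-wise and embedded in 2-D with UMAP (Euclidean metric, 30 neighbors,
min_dist 0.6). A new dataset is scored, standardized with the stored
parameters, projected out-of-sample onto the embedding and classified
cluster-like vs trajectory-like by the sim-type majority among its k nearest
embedded neighbors.

Standardization before UMAP is deliberate: the five scores live on very
different scales (entropies around 0-2.3, the homology log down to its -27.6
floor, AUCs in [0, 1]) and unstandardized Euclidean distances would be
dominated by a single column. The stored location/scale make projection of
new score vectors consistent with the training landscape.
"""

from __future__ import annotations

import json
import os
import pickle
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import DegenerateInputError, StateError
from .metrics import ScoreConfigs, ScoreVector, score_all
from .preprocess import PointCloud
from .simulate import SIM_TYPES, TRAJECTORY_TYPES, SimulatedDataset

__all__ = ["Landscape", "Classification", "build_landscape", "project", "classify",
           "score_subsets", "save_landscape", "load_landscape"]

_MIN_SIMS = 40
_MIN_SUBSET = 10


@dataclass
class Landscape:
    """Scores, labels, standardization and fitted 2-D embedding of many sims."""

    scores: np.ndarray            # N x 5 raw score matrix
    labels: Sequence[str]         # sim_type per row
    loc: np.ndarray               # per-column mean used for standardization
    scale: np.ndarray             # per-column std (never zero)
    embedding: np.ndarray         # N x 2 UMAP coordinates
    embedder: object = None       # fitted UMAP transform (None after partial load)
    knn_k: int = 15

    def __post_init__(self):
        N = self.scores.shape[0]
        if len(self.labels) != N or self.embedding.shape[0] != N:
            raise DegenerateInputError("scores, labels and embedding must align")
        if np.any(self.scale == 0):
            raise DegenerateInputError("zero standardization scale")

    def standardize(self, scores: np.ndarray) -> np.ndarray:
        return (np.asarray(scores, dtype=float) - self.loc) / self.scale


@dataclass
class Classification:
    """kNN vote of a projected dataset on the landscape."""

    label: str                          # "cluster_like" or "trajectory_like"
    trajectory_neighbor_fraction: float
    embedding_coords: np.ndarray


def build_landscape(
    sims: Sequence[SimulatedDataset],
    seed: int = 0,
    configs: Optional[ScoreConfigs] = None,
    knn_k: int = 15,
    standardize: bool = True,
) -> Landscape:
    """Score all sims and fit the standardized UMAP landscape.

    Each sim is scored with its own generation seed, so the score matrix is
    a pure function of the sims; *seed* drives UMAP only. ``standardize``
    can be disabled for fidelity experiments on the raw score scales.
    """
    if len(sims) < _MIN_SIMS:
        raise DegenerateInputError(f"need at least {_MIN_SIMS} sims, got {len(sims)}")
    present = {s.sim_type for s in sims}
    if present != set(SIM_TYPES):
        raise DegenerateInputError(f"all four sim types required, missing {set(SIM_TYPES) - present}")

    rows, labels = [], []
    for ds in sims:
        try:
            sv = score_all(ds.points, configs, seed=ds.seed)
        except Exception as exc:
            raise RuntimeError(f"scoring failed for sim seed={ds.seed} type={ds.sim_type}: {exc}") from exc
        rows.append(sv.as_array())
        labels.append(ds.sim_type)
    scores = np.array(rows)

    if standardize:
        loc = scores.mean(axis=0)
        scale = scores.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        loc = np.zeros(scores.shape[1])
        scale = np.ones(scores.shape[1])
    Z = (scores - loc) / scale

    import umap  # deferred: numba JIT import is slow

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that random_state disables parallelism
        reducer = umap.UMAP(
            n_components=2, n_neighbors=30, min_dist=0.6,
            metric="euclidean", random_state=seed,
        ).fit(Z)
    return Landscape(
        scores=scores, labels=list(labels), loc=loc, scale=scale,
        embedding=np.asarray(reducer.embedding_, dtype=float),
        embedder=reducer, knn_k=knn_k,
    )


def project(ls: Landscape, sv: ScoreVector) -> np.ndarray:
    """Standardize a score vector and project it onto the fitted embedding."""
    if ls.embedder is None:
        raise StateError("landscape has no fitted embedder (partial load?)")
    z = ls.standardize(sv.as_array())[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = np.asarray(ls.embedder.transform(z), dtype=float)[0]
    if not np.all(np.isfinite(coords)):
        raise StateError("projection produced non-finite coordinates")
    return coords


def classify(ls: Landscape, sv: ScoreVector) -> Classification:
    """Label a score vector by majority sim-type among embedded neighbors.

    trajectory_neighbor_fraction counts neighbors of either trajectory type;
    a tie at exactly 0.5 resolves to cluster_like.
    """
    coords = project(ls, sv)
    d = np.linalg.norm(ls.embedding - coords, axis=1)
    k = min(ls.knn_k, len(d))
    nearest = np.argsort(d, kind="stable")[:k]
    frac = float(np.mean([ls.labels[i] in TRAJECTORY_TYPES for i in nearest]))
    label = "trajectory_like" if frac > 0.5 else "cluster_like"
    return Classification(label=label, trajectory_neighbor_fraction=frac, embedding_coords=coords)


def score_subsets(
    pc: PointCloud,
    labels: Sequence,
    ls: Landscape,
    seed: int = 0,
    configs: Optional[ScoreConfigs] = None,
):
    """Score and classify each labeled subset of a cloud independently.

    Subsets with fewer than 10 points are skipped with a warning. Returns a
    list of (subset id, ScoreVector, Classification) in order of each id's
    first appearance. Every subset is scored with the same *seed*, so a
    single all-identical labeling reproduces ``score_all`` on the full cloud
    exactly, and subsets inherit nothing from the parent beyond it.
    """
    labels = np.asarray(labels)
    if len(labels) != pc.n:
        raise DegenerateInputError(f"{len(labels)} labels for {pc.n} points")
    ids = list(dict.fromkeys(labels.tolist()))
    results = []
    for sid in ids:
        idx = np.flatnonzero(labels == sid)
        if len(idx) < _MIN_SUBSET:
            warnings.warn(f"subset {sid!r} has {len(idx)} < {_MIN_SUBSET} points; skipped")
            continue
        sub = PointCloud(coords=pc.coords[idx])
        sv = score_all(sub, configs, seed=seed)
        results.append((sid, sv, classify(ls, sv)))
    if not results:
        raise DegenerateInputError("every subset was below the minimum size")
    return results


# ---------------------------------------------------------------------------
# persistence


def save_landscape(ls: Landscape, directory: str) -> None:
    """Persist a landscape as a directory of plain tables + a pickled embedder."""
    os.makedirs(directory, exist_ok=True)
    header = ",".join(("label",) + ScoreVector.FIELDS)
    with open(os.path.join(directory, "scores.csv"), "w") as fh:
        fh.write(header + "\n")
        for lab, row in zip(ls.labels, ls.scores):
            fh.write(lab + "," + ",".join(f"{v:.12g}" for v in row) + "\n")
    np.savetxt(os.path.join(directory, "embedding.csv"), ls.embedding, delimiter=",", fmt="%.12g")
    with open(os.path.join(directory, "standardization.json"), "w") as fh:
        json.dump(
            {"loc": ls.loc.tolist(), "scale": ls.scale.tolist(), "knn_k": ls.knn_k},
            fh, sort_keys=True, indent=1,
        )
    with open(os.path.join(directory, "embedder.pkl"), "wb") as fh:
        pickle.dump(ls.embedder, fh)


def load_landscape(directory: str) -> Landscape:
    import pandas as pd

    tab = pd.read_csv(os.path.join(directory, "scores.csv"))
    with open(os.path.join(directory, "standardization.json")) as fh:
        std = json.load(fh)
    embedding = np.loadtxt(os.path.join(directory, "embedding.csv"), delimiter=",", ndmin=2)
    embedder_path = os.path.join(directory, "embedder.pkl")
    embedder = None
    if os.path.exists(embedder_path):
        with open(embedder_path, "rb") as fh:
            embedder = pickle.load(fh)
    return Landscape(
        scores=tab[list(ScoreVector.FIELDS)].to_numpy(dtype=float),
        labels=tab["label"].tolist(),
        loc=np.asarray(std["loc"], dtype=float),
        scale=np.asarray(std["scale"], dtype=float),
        embedding=embedding,
        embedder=embedder,
        knn_k=int(std["knn_k"]),
    )
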