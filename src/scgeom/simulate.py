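"""Seeded 2-D simulators for the four benchmark geometries.

Four dataset types anchor the score landscape: clear clusters (well-separated
isotropic Gaussian mixture), clear trajectory (a sine-curve belt with little
noise), noisy clusters (weakly separated mixture) and noisy trajectory (wide
belt, possibly bifurcating into two branches).

The clear and noisy variants of a type share every structural draw (component
means, mixing proportions, curve amplitude/frequency/phase, rotation): for a
fixed seed, toggling the ``noisy`` flag changes only the dispersion, which
keeps ablation comparisons honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import GenerationError
from .preprocess import PointCloud

__all__ = ["SimConfig", "SimulatedDataset", "SIM_TYPES", "sim_clusters", "sim_trajectory", "sim_batch"]

SIM_TYPES = ("clear_clusters", "clear_trajectory", "noisy_clusters", "noisy_trajectory")
TRAJECTORY_TYPES = ("clear_trajectory", "noisy_trajectory")

_BOX = 10.0  # side of the square in which cluster means / trajectories live
_MIN_MEAN_SEP = 1.0  # reject mean draws closer than this (degenerate overlap)
_MAX_RETRIES = 200


@dataclass
class SimConfig:
    """Ranges from which each dataset's generation parameters are drawn.

    Separation ratio = (minimum pairwise distance between component means) /
    (largest component standard deviation); trajectory noise levels are
    fractions of the drawn sine amplitude.
    """

    n_points_range: Tuple[int, int] = (200, 1000)
    n_clusters_range: Tuple[int, int] = (2, 8)
    clear_separation_ratio: float = 6.0
    noisy_separation_ratio: Tuple[float, float] = (2.0, 4.0)
    trajectory_noise_clear: float = 0.05
    trajectory_noise_noisy: Tuple[float, float] = (0.2, 0.5)
    bifurcation_prob: float = 0.5
    amplitude_range: Tuple[float, float] = (1.0, 3.0)
    frequency_range: Tuple[float, float] = (0.75, 2.0)
    branch_fraction_range: Tuple[float, float] = (0.15, 0.35)

    def __post_init__(self):
        for name in ("n_points_range", "n_clusters_range", "noisy_separation_ratio",
                     "trajectory_noise_noisy", "amplitude_range", "frequency_range",
                     "branch_fraction_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: {lo}..{hi}")
        if self.clear_separation_ratio <= 0:
            raise ValueError("clear_separation_ratio must be positive")
        if not 0 <= self.bifurcation_prob <= 1:
            raise ValueError("bifurcation_prob must be in [0, 1]")


@dataclass
class SimulatedDataset:
    """A generated 2-D point cloud with its type label, seed and drawn params."""

    points: PointCloud
    sim_type: str
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sim_type not in SIM_TYPES:
            raise ValueError(f"unknown sim_type {self.sim_type!r}")
        if self.points.d != 2:
            raise ValueError("simulated datasets are two-dimensional")

    @property
    def is_trajectory(self) -> bool:
        return self.sim_type in TRAJECTORY_TYPES


def sim_clusters(cfg: SimConfig = SimConfig(), noisy: bool = False, seed: int = 0) -> SimulatedDataset:
    """Sample a Gaussian-mixture cluster dataset.

    Component means are drawn uniformly in the box (re-drawn, up to a bounded
    number of times, while any two means are degenerately close); mixing
    proportions come from a flat Dirichlet; component standard deviations are
    scaled so that the separation ratio equals the clear value (default 6) or
    a draw from the noisy range (default 2-4). ``params['labels']`` records
    each point's component.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(cfg.n_points_range[0], cfg.n_points_range[1] + 1))
    k = int(rng.integers(cfg.n_clusters_range[0], cfg.n_clusters_range[1] + 1))
    means = None
    for _ in range(_MAX_RETRIES):
        cand = rng.uniform(0.0, _BOX, size=(k, 2))
        if k == 1 or pdist(cand).min() >= _MIN_MEAN_SEP:
            means = cand
            break
    if means is None:
        raise GenerationError(f"could not place {k} separated means in {_MAX_RETRIES} tries")
    props = rng.dirichlet(np.ones(k))
    sigma_rel = rng.uniform(0.5, 1.0, size=k)
    noisy_ratio = float(rng.uniform(*cfg.noisy_separation_ratio))
    ratio = noisy_ratio if noisy else cfg.clear_separation_ratio

    min_sep = pdist(means).min() if k > 1 else _BOX
    sigmas = sigma_rel / sigma_rel.max() * (min_sep / ratio)
    counts = rng.multinomial(n, props)
    parts, labels = [], []
    for c in range(k):
        parts.append(means[c] + sigmas[c] * rng.standard_normal((counts[c], 2)))
        labels.extend([c] * counts[c])
    points = np.concatenate(parts, axis=0)
    return SimulatedDataset(
        points=PointCloud(points),
        sim_type="noisy_clusters" if noisy else "clear_clusters",
        seed=seed,
        params={
            "n": n,
            "n_components": k,
            "means": means.tolist(),
            "proportions": props.tolist(),
            "sigmas": sigmas.tolist(),
            "separation_ratio": float(ratio),
            "labels": labels,
        },
    )


def sim_trajectory(cfg: SimConfig = SimConfig(), noisy: bool = False, seed: int = 0) -> SimulatedDataset:
    """Sample a sine-belt trajectory dataset.

    Points sit at uniform arc parameters s in [0, 1] on
    (s * 10, A sin(2 pi f s + phi)), carry isotropic Gaussian noise whose
    standard deviation is a fraction of the amplitude A, and are rotated by a
    random planar angle. In noisy mode, with probability ``bifurcation_prob``
    a second branch with its own amplitude and phase splits off at a branch
    point drawn from the middle of the arc, continuously attached to the
    trunk; a fixed fraction of points (default 15-35%) populates it.
    ``params['labels']`` records the branch (0 = trunk, 1 = second branch)
    and ``params['arc']`` the arc parameters.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(cfg.n_points_range[0], cfg.n_points_range[1] + 1))
    amp = float(rng.uniform(*cfg.amplitude_range))
    freq = float(rng.uniform(*cfg.frequency_range))
    phase = float(rng.uniform(0.0, 2.0 * np.pi))
    u = rng.uniform(0.0, 1.0, size=n)
    noisy_frac = float(rng.uniform(*cfg.trajectory_noise_noisy))
    # structural draws happen regardless of mode so the stream stays aligned
    bif_u = float(rng.uniform())
    s_branch = float(rng.uniform(0.2, 0.8))
    branch_frac = float(rng.uniform(*cfg.branch_fraction_range))
    amp2 = float(rng.uniform(*cfg.amplitude_range))
    phase2 = float(rng.uniform(0.0, 2.0 * np.pi))
    theta = float(rng.uniform(0.0, 2.0 * np.pi))
    noise_unit = rng.standard_normal((n, 2))

    bifurcated = bool(noisy and bif_u < cfg.bifurcation_prob)
    labels = np.zeros(n, dtype=int)
    s = u.copy()
    if bifurcated:
        n2 = int(round(branch_frac * n))
        branch_idx = rng.permutation(n)[:n2]
        labels[branch_idx] = 1
        s[branch_idx] = s_branch + (1.0 - s_branch) * u[branch_idx]

    def trunk_y(ss):
        return amp * np.sin(2.0 * np.pi * freq * ss + phase)

    y = trunk_y(s)
    if bifurcated:
        mask = labels == 1
        y2 = amp2 * np.sin(2.0 * np.pi * freq * s[mask] + phase2)
        y2_at_branch = amp2 * np.sin(2.0 * np.pi * freq * s_branch + phase2)
        y[mask] = y2 - y2_at_branch + trunk_y(s_branch)
    base = np.column_stack([s * _BOX, y])

    frac = noisy_frac if noisy else cfg.trajectory_noise_clear
    sigma = frac * amp
    points = base + sigma * noise_unit
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    points = points @ rot.T
    return SimulatedDataset(
        points=PointCloud(points),
        sim_type="noisy_trajectory" if noisy else "clear_trajectory",
        seed=seed,
        params={
            "n": n,
            "amplitude": amp,
            "frequency": freq,
            "phase": phase,
            "noise_sigma": float(sigma),
            "rotation": theta,
            "bifurcated": bifurcated,
            "branch_point": s_branch if bifurcated else None,
            "branch_fraction": branch_frac if bifurcated else None,
            "amplitude2": amp2 if bifurcated else None,
            "phase2": phase2 if bifurcated else None,
            "labels": labels.tolist(),
            "arc": s.tolist(),
        },
    )


def sim_batch(counts_per_type: int, master_seed: int = 0, cfg: SimConfig = SimConfig()):
    """Generate ``counts_per_type`` datasets of each of the four types.

    Each dataset gets a distinct sub-seed derived from *master_seed*; the
    result is an exactly type-balanced list in fixed type order per round.
    """
    if counts_per_type < 1:
        raise ValueError("counts_per_type must be >= 1")
    ss = np.random.SeedSequence(int(master_seed))
    seeds = ss.generate_state(4 * counts_per_type) % (2**31)
    out = []
    i = 0
    for _ in range(counts_per_type):
        for sim_type in SIM_TYPES:
            sub = int(seeds[i])
            i += 1
            if sim_type.endswith("clusters"):
                ds = sim_clusters(cfg, noisy=sim_type.startswith("noisy"), seed=sub)
            else:
                ds = sim_trajectory(cfg, noisy=sim_type.startswith("noisy"), seed=sub)
            out.append(ds)
    return out
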