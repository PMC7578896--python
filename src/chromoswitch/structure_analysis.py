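"""Conformation-level order parameters.

Shape is measured from the (mass-uniform) gyration tensor: the radius of
gyration Rg, the asphericity

    Delta = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1+l2+l3)^2],

which is 0 for a spherically symmetric mass distribution and 1 for a rod,
and the extensions along the three principal axes (PA1 >= PA2 >= PA3).
Contact similarity to a reference state uses the fraction of native
contacts Q: the fraction of pairs in a genomic-separation category whose
instantaneous distance is below a tolerance factor times the reference
ensemble's mean pairwise distance.  Radial density profiles position loci
relative to the chromosome's center of mass, optionally rescaled by the
frame's Rg so differently sized chromosomes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np

from . import _kernels

__all__ = ["ShapeDescriptors", "QReference", "RadialDensity",
           "shape", "q_fraction", "radial_density", "pathway_average",
           "PathwayAverage"]

#: native-contact distance tolerance (protein-folding convention)
DEFAULT_LAMBDA_Q = 1.2


@dataclass(frozen=True)
class ShapeDescriptors:
    rg: float
    eigenvalues: tuple       # l1 >= l2 >= l3 (length^2)
    asphericity: float       # in [0, 1]
    pa_extensions: tuple     # PA1 >= PA2 >= PA3 (max - min projections)


def shape(conf: np.ndarray) -> ShapeDescriptors:
    """Gyration-tensor shape descriptors of one conformation."""
    x = np.asarray(conf, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 2:
        raise ValueError("need an (n>=2, 3) conformation")
    centered = x - x.mean(axis=0)
    gyr = centered.T @ centered / x.shape[0]
    eigvals, eigvecs = np.linalg.eigh(gyr)   # ascending
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tr = eigvals.sum()
    l1, l2, l3 = eigvals
    asph = ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2) / (2.0 * tr * tr)
    proj = centered @ eigvecs
    ext = tuple(float(proj[:, k].max() - proj[:, k].min()) for k in range(3))
    return ShapeDescriptors(float(np.sqrt(tr)), tuple(map(float, eigvals)),
                            float(asph), ext)


@dataclass
class QReference:
    """Native mean pairwise distances plus genomic-separation categories."""

    native_distances: np.ndarray                  # (n, n) ensemble means
    categories: Dict[str, tuple]                  # name -> (s_min, s_max) bins
    lambda_q: float = DEFAULT_LAMBDA_Q

    def __post_init__(self) -> None:
        d = np.asarray(self.native_distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("native_distances must be square")
        off = ~np.eye(d.shape[0], dtype=bool)
        if np.any(d[off] <= 0):
            raise ValueError("native distances must be positive off-diagonal")
        self.native_distances = d

    @classmethod
    def from_ensemble(cls, frames: np.ndarray,
                      categories: Optional[Dict[str, tuple]] = None,
                      lambda_q: float = DEFAULT_LAMBDA_Q) -> "QReference":
        """Reference distances as the ensemble-mean pairwise distances."""
        frames = np.ascontiguousarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        d = _kernels.mean_pairwise_distances(frames)
        if categories is None:
            n = d.shape[0]
            categories = {"local": (2, min(20, n - 1)),
                          "long": (min(100, n // 2), min(150, n - 1))}
        return cls(d, categories, lambda_q)

    def category_pairs(self, category: str):
        if category not in self.categories:
            raise KeyError(f"unknown category {category!r}; "
                           f"have {sorted(self.categories)}")
        s_min, s_max = self.categories[category]
        n = self.native_distances.shape[0]
        iu = np.triu_indices(n, k=max(int(s_min), 2))
        sep = iu[1] - iu[0]
        keep = sep <= s_max
        return iu[0][keep], iu[1][keep]


def q_fraction(conf: np.ndarray, ref: QReference, category: str) -> float:
    """Fraction of category pairs with r_ij < lambda_q * r_native_ij."""
    x = np.asarray(conf, dtype=float)
    n = ref.native_distances.shape[0]
    if x.shape != (n, 3):
        raise ValueError(f"conformation shape {x.shape} != ({n}, 3)")
    ii, jj = ref.category_pairs(category)
    if ii.size == 0:
        raise ValueError(f"category {category!r} selects no pairs")
    d = np.linalg.norm(x[ii] - x[jj], axis=1)
    return float(np.mean(d < ref.lambda_q * ref.native_distances[ii, jj]))


@dataclass
class RadialDensity:
    edges: np.ndarray                     # radial bin edges
    densities: Dict[str, np.ndarray]      # per-group, each integrates to 1
    normalized_by_rg: bool


def radial_density(frames: np.ndarray, groups: Dict[str, Sequence[int]],
                   n_radial_bins: int = 30,
                   normalize_by_rg: bool = True) -> RadialDensity:
    """Per-group radial distribution of loci about the center of mass.

    Radii are pooled over frames; with ``normalize_by_rg`` each frame's radii
    are divided by that frame's Rg.  Each group's histogram is normalized to
    unit integral.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] == 0:
        raise ValueError("empty ensemble")
    for name, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {name!r} is empty")
    centered = frames - frames.mean(axis=1, keepdims=True)
    radii = np.linalg.norm(centered, axis=2)            # (F, n)
    if normalize_by_rg:
        rg = np.sqrt((radii ** 2).mean(axis=1, keepdims=True))
        radii = radii / rg
    r_max = radii.max() * (1 + 1e-12)
    edges = np.linspace(0.0, r_max, n_radial_bins + 1)
    densities = {}
    for name, idx in groups.items():
        pooled = radii[:, np.asarray(idx, dtype=int)].ravel()
        hist, _ = np.histogram(pooled, bins=edges, density=True)
        densities[name] = hist
    return RadialDensity(edges, densities, normalize_by_rg)


@dataclass
class PathwayAverage:
    times: np.ndarray
    mean_x: np.ndarray
    se_x: np.ndarray
    mean_y: np.ndarray
    se_y: np.ndarray
    stage_labels: Optional[np.ndarray] = None


def pathway_average(ens, observable_x: Callable[[np.ndarray], float],
                    observable_y: Callable[[np.ndarray], float],
                    stages=None, min_trajectories: int = 5) -> PathwayAverage:
    """Trajectory-averaged pathway in a 2-D order-parameter plane.

    ``ens`` is a :class:`~chromoswitch.switching.SwitchEnsemble`; the
    observables map one conformation to a scalar (e.g. Rg and asphericity).
    Returns per-recorded-time means and standard errors, with optional stage
    markers from a :class:`~chromoswitch.map_analysis.StageClustering`.
    """
    trajs = ens.trajectories
    if len(trajs) < min_trajectories:
        raise ValueError(f"need >= {min_trajectories} trajectories")
    times = ens.times
    n_t = times.size
    obs_x = np.empty((len(trajs), n_t))
    obs_y = np.empty((len(trajs), n_t))
    for k, tr in enumerate(trajs):
        if tr.frames.shape[0] != n_t:
            raise ValueError("trajectory observables of mismatched length")
        for ti in range(n_t):
            obs_x[k, ti] = observable_x(tr.frames[ti])
            obs_y[k, ti] = observable_y(tr.frames[ti])
    m = len(trajs)
    se = np.sqrt(m) if m > 1 else 1.0
    return PathwayAverage(
        times, obs_x.mean(axis=0), obs_x.std(axis=0, ddof=1) / se if m > 1
        else np.zeros(n_t),
        obs_y.mean(axis=0), obs_y.std(axis=0, ddof=1) / se if m > 1
        else np.zeros(n_t),
        stage_labels=None if stages is None else stages.labels)
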