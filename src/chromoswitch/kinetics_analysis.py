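"""Time-dependent analyses: MSD sub-diffusion, per-locus compartment
time courses, k-means kinetic classes with exponential relaxation times,
and PCA of compartment-profile trajectories against reference profiles.

Genomic loci in the restrained chromosome model move sub-diffusively:
MSD(t) ~ t^beta with beta < 1 (free diffusion gives beta = 1; an ideal
Rouse chain beta = 1/2 at intermediate times).  beta is measured as the
log-log slope of the trajectory/bead-averaged MSD over an intermediate lag
window; beads near the chain ends are excluded to suppress end effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["MsdCurve", "KineticClasses", "msd_exponent",
           "compartment_timecourses", "kinetic_clusters", "profile_pca",
           "ProfilePca"]


@dataclass
class MsdCurve:
    lags: np.ndarray          # tau units
    msd: np.ndarray           # reduced length^2 (MSD(0) = 0 excluded)
    beta: float               # log-log slope over fit_range
    fit_range: tuple          # (lag_min, lag_max) in tau


def msd_exponent(trajectories: Sequence, lags: Optional[Sequence[float]] = None,
                 fit_range: tuple = (1.0, 30.0),
                 interior_fraction: float = 0.9,
                 remove_com: bool = True) -> MsdCurve:
    """Ensemble/time-averaged MSD of interior beads and its exponent beta.

    ``trajectories`` are equilibrium (non-switching) trajectories recorded on
    a *uniform* time grid.  The central ``interior_fraction`` of beads enters
    the average (5% at each chain end excluded by default).  The lag grid
    must span at least two decades; ``fit_range`` (in tau) selects the
    intermediate-lag fit window.

    By default displacements are measured in the chain's center-of-mass
    frame (``remove_com``): a nucleus cages a chromosome's center of mass,
    so the caged frame — not the freely diffusing one of an isolated
    simulated chain — is what locus-tracking experiments observe.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    times = trajectories[0].times
    dt_grid = np.diff(times)
    if not np.allclose(dt_grid, dt_grid[0], rtol=1e-6):
        raise ValueError("MSD requires a uniform recording grid")
    step = dt_grid[0]
    n_frames = times.size
    n_beads = trajectories[0].frames.shape[1]
    margin = int(round(0.5 * (1 - interior_fraction) * n_beads))
    sel = slice(margin, n_beads - margin if margin else n_beads)
    if lags is None:
        max_lag = (n_frames - 1) // 2
        lag_idx = np.unique(np.geomspace(1, max_lag, 40).round().astype(int))
    else:
        lag_idx = np.unique(np.round(np.asarray(lags) / step).astype(int))
        lag_idx = lag_idx[(lag_idx >= 1) & (lag_idx < n_frames)]
    lag_t = lag_idx * step
    if lag_t.max() / lag_t.min() < 100 - 1e-9:
        raise ValueError("lag grid must span at least two decades")
    msd = np.zeros(lag_idx.size)
    for tr in trajectories:
        frames = tr.frames
        if remove_com:
            frames = frames - frames.mean(axis=1, keepdims=True)
        x = frames[:, sel, :]
        for k, li in enumerate(lag_idx):
            disp = x[li:] - x[:-li]
            msd[k] += np.mean(np.sum(disp ** 2, axis=2))
    msd /= len(trajectories)
    lo, hi = fit_range
    mask = (lag_t >= lo) & (lag_t <= hi)
    if mask.sum() < 3:
        raise ValueError("fit range outside the available lag grid")
    beta = float(np.polyfit(np.log(lag_t[mask]), np.log(msd[mask]), 1)[0])
    return MsdCurve(lag_t, msd, beta, (lo, hi))


@dataclass
class KineticClasses:
    """Per-locus compartment-value courses and their kinetic clustering."""

    times: np.ndarray
    courses: Dict[str, np.ndarray]          # switch class -> (n_loci, T)
    assignments: Optional[np.ndarray] = None
    tau_r: Optional[np.ndarray] = None      # per cluster (NaN if fit failed)
    populations: Optional[np.ndarray] = None
    cluster_means: Optional[np.ndarray] = None
    cluster_sds: Optional[np.ndarray] = None


def compartment_timecourses(profiles: Sequence, times: Sequence[float],
                            switch_class: Sequence[str]) -> KineticClasses:
    """Group per-locus PC1 time courses by compartment switch class.

    ``profiles`` is one CompartmentProfile (or PC1 vector) per time frame on
    a consistent binning; ``switch_class`` labels each locus 'A->B', 'B->A',
    'A->A' or 'B->B'.  Classes with zero loci are omitted with a warning.
    """
    vecs = []
    for p in profiles:
        v = p.pc1.values if hasattr(p, "pc1") else np.asarray(p, dtype=float)
        vecs.append(v)
    mat = np.stack(vecs)                    # (T, n_loci)
    if len({v.shape[0] for v in vecs}) != 1:
        raise ValueError("profiles have inconsistent binning")
    switch_class = np.asarray(switch_class)
    if switch_class.shape[0] != mat.shape[1]:
        raise ValueError("switch_class length does not match profile bins")
    courses: Dict[str, np.ndarray] = {}
    for cls in ("A->B", "B->A", "A->A", "B->B"):
        idx = np.flatnonzero(switch_class == cls)
        if idx.size == 0:
            warnings.warn(f"switch class {cls} has zero loci; omitted")
            continue
        courses[cls] = mat[:, idx].T        # (n_loci, T)
    return KineticClasses(np.asarray(times, dtype=float), courses)


def _exp_relax(t, y_inf, dy, tau_r):
    return y_inf + dy * np.exp(-t / tau_r)


def kinetic_clusters(courses: np.ndarray, times: Sequence[float], k: int = 4,
                     seed: int = 0, n_restarts: int = 50) -> KineticClasses:
    """k-means over time-course vectors plus per-cluster exponential fits.

    Each cluster's mean course is fitted to y(t) = y_inf + (y0 - y_inf)
    exp(-t / tau_r); a non-convergent fit flags that cluster's tau_r as NaN.
    Population fractions sum to 1.
    """
    courses = np.asarray(courses, dtype=float)
    times = np.asarray(times, dtype=float)
    if courses.ndim != 2 or courses.shape[1] != times.size:
        raise ValueError("courses must be (n_loci, T) matching times")
    if courses.shape[0] < k:
        raise ValueError(f"need >= {k} courses for k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed)
    labels = km.fit_predict(courses)
    tau_r = np.full(k, np.nan)
    pops = np.zeros(k)
    means = np.zeros((k, times.size))
    sds = np.zeros((k, times.size))
    for c in range(k):
        members = courses[labels == c]
        pops[c] = members.shape[0] / courses.shape[0]
        if members.shape[0] == 0:
            means[c] = np.nan
            continue
        means[c] = members.mean(axis=0)
        sds[c] = members.std(axis=0)
        y = means[c]
        if np.allclose(y, y[0]):
            continue  # degenerate: constant course, tau_r stays NaN
        try:
            span = max(times.max() - times.min(), 1e-9)
            popt, _ = curve_fit(
                _exp_relax, times, y, p0=[y[-1], y[0] - y[-1], span / 5],
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=10000)
            tau_r[c] = popt[2]
        except RuntimeError:
            pass
    return KineticClasses(times, {"all": courses}, labels, tau_r, pops,
                          means, sds)


@dataclass
class ProfilePca:
    projections: np.ndarray             # (T, 2) trajectory frames in PC space
    reference_projections: Dict[str, np.ndarray]
    explained_variance_ratio: np.ndarray
    tree: Optional[np.ndarray] = None   # average linkage over stages + refs
    tree_labels: Optional[list] = None


def profile_pca(profiles: np.ndarray, references: Dict[str, np.ndarray],
                stage_labels: Optional[np.ndarray] = None) -> ProfilePca:
    """PCA of a compartment-profile time series with reference projections.

    The PCA basis is fitted on the (T, n_bins) time-series profiles; the
    reference profiles (same binning) are projected into that space.  An
    average-linkage tree is built over the per-stage mean profiles (or each
    frame, if no stages are given) together with the references.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be (T, n_bins)")
    n_bins = profiles.shape[1]
    for name, ref in references.items():
        if np.asarray(ref).shape != (n_bins,):
            raise ValueError(f"reference {name!r} does not share the binning")
    pca = PCA(n_components=2)
    proj = pca.fit_transform(profiles)
    ref_proj = {name: pca.transform(np.asarray(ref, dtype=float)[None])[0]
                for name, ref in references.items()}
    if stage_labels is not None:
        stage_labels = np.asarray(stage_labels)
        rows = [profiles[stage_labels == s].mean(axis=0)
                for s in np.unique(stage_labels)]
        labels = [f"stage{s}" for s in np.unique(stage_labels)]
    else:
        rows = list(profiles)
        labels = [f"frame{i}" for i in range(profiles.shape[0])]
    rows += [np.asarray(references[name], dtype=float) for name in references]
    labels += list(references)
    tree = linkage(np.stack(rows), method="average") if len(rows) > 1 else None
    return ProfilePca(proj, ref_proj, pca.explained_variance_ratio_,
                      tree, labels)
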