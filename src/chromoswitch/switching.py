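"""Non-equilibrium landscape switching: excite under one fitted restraint
landscape, instantaneously replace it by the other, and relax.

The protocol has three steps: (i) equilibrate briefly under the source
landscape; (ii) replace the potential in a single integration step while
retaining velocities (the instantaneous-excitation idealization of the
cell-state transition trigger); (iii) relax under the destination landscape
for a long period, recording frames on a log-spaced schedule whose time
origin is the switch instant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .hic_io import normalize_to_probability
from .maxent import ContactModel, RestraintField, contact_probability
from .polymer import PolymerConfig, Trajectory, langevin_run

__all__ = ["SwitchEnsemble", "log_schedule", "select_initial_structures",
           "run_switch", "switch_ensemble", "ensemble_maps"]


@dataclass
class SwitchEnsemble:
    """A set of switching trajectories sharing config and schedule."""

    trajectories: list              # list[Trajectory], times relative to switch
    direction: str                  # e.g. "A->B"
    cluster_ids: np.ndarray         # initial-structure provenance

    def __post_init__(self) -> None:
        if len(self.trajectories) == 0:
            raise ValueError("empty switch ensemble")
        t0 = self.trajectories[0].times
        for tr in self.trajectories[1:]:
            if tr.times.shape != t0.shape or not np.allclose(tr.times, t0):
                raise ValueError("trajectories do not share a recording schedule")
        self.cluster_ids = np.asarray(self.cluster_ids)
        if self.cluster_ids.shape[0] != len(self.trajectories):
            raise ValueError("one cluster id per trajectory required")

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    def frames_at(self, time_index: int) -> np.ndarray:
        """(n_traj, n, 3) stack of all trajectories at one recorded time."""
        return np.stack([tr.frames[time_index] for tr in self.trajectories])


def log_schedule(t_min: float = 0.1, t_max: float = 1000.0,
                 per_decade: int = 20) -> np.ndarray:
    """Log-spaced recording times in tau (default 20/decade over 4 decades)."""
    n_dec = np.log10(t_max / t_min)
    n_pts = int(round(n_dec * per_decade)) + 1
    return np.unique(np.geomspace(t_min, t_max, n_pts))


def select_initial_structures(
    ensemble: np.ndarray,
    n_sample: int = 2400,
    distance_cutoff: Optional[float] = None,
    min_population: float = 0.003,
    per_cluster: int = 2,
    model: Optional[ContactModel] = None,
    seed: int = 0,
):
    """Pick switching start structures by clustering an equilibrium ensemble.

    ``n_sample`` randomly chosen conformations are clustered hierarchically
    (average linkage) by contact-map distance (mean |w_a - w_b| over pairs);
    every cluster whose population fraction exceeds ``min_population``
    contributes ``per_cluster`` randomly chosen members.  With the default
    cutoff the tree is cut at half its maximum merge height.

    Returns ``(conformations (M, n, 3), cluster ids (M,))``.
    """
    ensemble = np.asarray(ensemble, dtype=float)
    if ensemble.ndim != 3:
        raise ValueError("ensemble must be (F, n, 3)")
    if ensemble.shape[0] < n_sample:
        raise ValueError(
            f"ensemble size {ensemble.shape[0]} < n_sample {n_sample}")
    model = model or ContactModel()
    rng = np.random.default_rng(seed)
    pick = rng.choice(ensemble.shape[0], size=n_sample, replace=False)
    confs = ensemble[pick]
    wmats = np.stack([contact_probability(c[None], model) for c in confs])
    flat = wmats.reshape(n_sample, -1)
    # condensed mean-absolute contact-map distance
    dists = np.zeros(n_sample * (n_sample - 1) // 2)
    k = 0
    for i in range(n_sample - 1):
        d = np.abs(flat[i + 1:] - flat[i]).mean(axis=1)
        dists[k:k + d.size] = d
        k += d.size
    if np.all(dists == 0):
        labels = np.ones(n_sample, dtype=int)
    else:
        z = linkage(dists, method="average")
        if distance_cutoff is None:
            distance_cutoff = 0.5 * z[-1, 2]
        labels = fcluster(z, t=distance_cutoff, criterion="distance")
    chosen, chosen_ids = [], []
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        if members.size / n_sample <= min_population:
            continue
        take = rng.choice(members, size=min(per_cluster, members.size),
                          replace=False)
        for t in take:
            chosen.append(confs[t])
            chosen_ids.append(cid)
    if not chosen:
        raise ValueError(
            f"no cluster exceeds min_population={min_population}; "
            "lower the threshold or the distance cutoff")
    return np.stack(chosen), np.asarray(chosen_ids)


def run_switch(
    initial: np.ndarray,
    config: PolymerConfig,
    field_from: Optional[RestraintField],
    field_to: Optional[RestraintField],
    record_times: Optional[Sequence[float]] = None,
    pre_switch_taus: float = 10.0,
    relax_taus: Optional[float] = None,
    seed: int = 0,
) -> Trajectory:
    """One excitation-relaxation trajectory; time 0 is the switch instant."""
    for f in (field_from, field_to):
        if f is not None and f.n_beads != config.n_beads:
            raise ValueError("field does not match n_beads")
    if record_times is None:
        record_times = log_schedule(0.1, 100.0)
    record_times = np.asarray(record_times, dtype=float)
    if relax_taus is None:
        relax_taus = float(record_times.max())
    if relax_taus < record_times.max():
        raise ValueError("relax_taus must cover the recording schedule")
    rng = np.random.default_rng(seed)
    pre = langevin_run(
        initial, config, field_from,
        n_steps=max(int(round(pre_switch_taus * config.steps_per_tau)),
                    config.steps_per_tau),
        record_times=[pre_switch_taus], seed=int(rng.integers(2**31)))
    # sudden switch: the potential is replaced, velocities retained
    relax = langevin_run(
        pre.final_position, config, field_to,
        n_steps=int(round(relax_taus * config.steps_per_tau)),
        record_times=record_times, seed=int(rng.integers(2**31)),
        velocities=pre.final_velocity)
    return relax


def switch_ensemble(
    initials: np.ndarray,
    cluster_ids: Sequence[int],
    config: PolymerConfig,
    field_from: Optional[RestraintField],
    field_to: Optional[RestraintField],
    direction: str,
    record_times: Optional[Sequence[float]] = None,
    pre_switch_taus: float = 10.0,
    seed: int = 0,
) -> SwitchEnsemble:
    """Run :func:`run_switch` from each initial structure (shared schedule)."""
    initials = np.asarray(initials, dtype=float)
    rng = np.random.default_rng(seed)
    trajs = [
        run_switch(initials[k], config, field_from, field_to,
                   record_times=record_times, pre_switch_taus=pre_switch_taus,
                   seed=int(rng.integers(2**31)))
        for k in range(initials.shape[0])
    ]
    return SwitchEnsemble(trajs, direction, np.asarray(cluster_ids))


def ensemble_maps(ens: SwitchEnsemble, model: Optional[ContactModel] = None,
                  binning=None) -> list:
    """Per recorded time, the contact map pooled over all trajectories."""
    if len(ens.trajectories) < 2:
        raise ValueError("need at least 2 trajectories for ensemble maps")
    model = model or ContactModel()
    maps = []
    for ti in range(ens.times.size):
        p = contact_probability(ens.frames_at(ti), model)
        maps.append(normalize_to_probability(p, binning))
    return maps
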