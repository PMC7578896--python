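"""Maximum-entropy restraint fitting of a polymer to a target contact map.

The restraint energy is V_HiC = sum_{|i-j|>1} alpha_ij w(r_ij), linearly
added to the generic polymer potential as the maximum-entropy principle
prescribes.  w is a smoothed contact step,

    w(r) = (1 + tanh(eta (r_c - r))) / 2,

so the simulated contact probability P_ij is the ensemble mean of w(r_ij).
The couplings alpha_ij are iterated with the standard first-order scheme

    alpha_ij <- alpha_ij + learning_rate (P_ij - f_ij),

raising alpha (penalizing contact) where contacts are over-formed relative
to the target f, until the mean absolute deviation |P - f| over restrained
pairs drops below tolerance.  Adjacent pairs |i - j| <= 1 carry no restraint
(their f = 1 is maintained by the bonds), and |alpha| is capped to prevent
runaway.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional

import numpy as np

from . import _kernels
from .hic_io import ContactMap
from .polymer import PolymerConfig, init_chain, langevin_run

__all__ = ["ContactModel", "RestraintField", "FitControls", "FitReport",
           "contact_probability", "update_alphas", "fit_state",
           "write_field", "read_field"]


@dataclass(frozen=True)
class ContactModel:
    """Smoothed contact step: cutoff r_c and switching sharpness eta."""

    r_c: float = 1.5
    eta: float = 5.0

    def __post_init__(self) -> None:
        if self.r_c <= 0 or self.eta <= 0:
            raise ValueError("r_c and eta must be positive")

    def w(self, r):
        """Contact weight of a distance (array-safe)."""
        return 0.5 * (1.0 + np.tanh(self.eta * (self.r_c - np.asarray(r))))


def _excluded_mask(n: int) -> np.ndarray:
    """Pairs |i - j| <= 1 (and the diagonal) carry no restraint."""
    idx = np.arange(n)
    return np.abs(idx[:, None] - idx[None, :]) <= 1


@dataclass
class RestraintField:
    """Symmetric coupling matrix alpha_ij defining one cell-state landscape."""

    alphas: np.ndarray
    contact_model: ContactModel = dc_field(default_factory=ContactModel)

    def __post_init__(self) -> None:
        a = np.asarray(self.alphas, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("alphas must be square")
        if not np.all(np.isfinite(a)):
            raise ValueError("alphas must be finite")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ValueError("alphas must be symmetric")
        a = a.copy()
        a[_excluded_mask(a.shape[0])] = 0.0
        self.alphas = a

    @property
    def n_beads(self) -> int:
        return self.alphas.shape[0]

    @classmethod
    def zeros(cls, n: int, contact_model: Optional[ContactModel] = None):
        return cls(np.zeros((n, n)), contact_model or ContactModel())


@dataclass
class FitReport:
    """Per-iteration fit diagnostics."""

    deviations: list         # mean |P_sim - f| over restrained pairs
    correlations: list       # Pearson corr(P_sim, f) over restrained pairs
    learning_rates: list
    converged: bool
    iterations: int
    message: str = ""


@dataclass(frozen=True)
class FitControls:
    """Engineering knobs of the iterative fit (all config-exposed).

    The fit anneals: early rounds use short sampling windows and an
    aggressive learning rate to shape the couplings; later rounds lengthen
    the window (sampling only its equilibrated second half) and damp the
    rate, so the couplings converge against near-equilibrium statistics
    rather than the post-update transient.  ``sampling_friction`` lowers
    the Langevin friction during fitting only: equilibrium averages are
    friction-independent, and a lighter thermostat shortens the chain
    relaxation time per integration step.
    """

    #: annealing schedule: (iterations, steps per iteration, learning rate)
    schedule: tuple = ((25, 1000, 8.0), (15, 2000, 3.0))
    tol: float = 0.005                # mean-|P - f| convergence threshold
    min_learning_rate: float = 0.5
    alpha_max: float = 10.0           # |alpha| bound, units of T
    n_replicas: int = 16
    equil_steps: int = 3000
    frames_per_replica: int = 10
    production_taus: int = 12         # production frames per replica, stride tau
    sampling_friction: Optional[float] = 0.05
    seed: int = 0

    @property
    def max_iters(self) -> int:
        return sum(block[0] for block in self.schedule)


def contact_probability(frames: np.ndarray, model: ContactModel) -> np.ndarray:
    """Ensemble-mean contact probability P_ij = <w(r_ij)> over frames."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("need a non-empty (F, n, 3) conformation stack")
    return _kernels.contact_step_matrix(
        np.ascontiguousarray(frames), model.r_c, model.eta)


def update_alphas(field: RestraintField, p_sim: np.ndarray, f_target,
                  learning_rate: float, alpha_max: float = 10.0) -> RestraintField:
    """One proportional update step; clipped to |alpha| <= alpha_max."""
    f = f_target.values if isinstance(f_target, ContactMap) else np.asarray(f_target)
    p_sim = np.asarray(p_sim, dtype=float)
    if p_sim.shape != f.shape or p_sim.shape != field.alphas.shape:
        raise ValueError("shape mismatch between field, P_sim and target")
    if np.any(np.isnan(p_sim)) or np.any(np.isnan(f)):
        raise ValueError("NaN in P_sim or target")
    delta = learning_rate * (p_sim - f)
    new = field.alphas + np.where(_excluded_mask(f.shape[0]), 0.0, delta)
    new = np.clip(new, -alpha_max, alpha_max)
    return RestraintField(new, field.contact_model)


def _fit_metrics(p_sim, f, mask):
    dev = float(np.mean(np.abs(p_sim[mask] - f[mask])))
    corr = float(np.corrcoef(p_sim[mask], f[mask])[0, 1])
    return dev, corr


def fit_state(
    f_target: ContactMap,
    config: PolymerConfig,
    model: Optional[ContactModel] = None,
    controls: Optional[FitControls] = None,
):
    """Iterate simulate -> measure -> update until P_sim matches the target.

    Keeps ``n_replicas`` persistent chains that are advanced under the
    current field each iteration (warm restarts), following the annealing
    ``schedule`` in the controls (see :class:`FitControls`).  Returns
    ``(RestraintField, production ensemble (F, n, 3), FitReport)``; the
    production ensemble is sampled at stride tau after the last update.
    """
    model = model or ContactModel()
    controls = controls or FitControls()
    f = f_target.values
    n = f.shape[0]
    if config.n_beads != n:
        raise ValueError(f"config.n_beads ({config.n_beads}) != target bins ({n})")
    mask = ~_excluded_mask(n)
    rng = np.random.default_rng(controls.seed)
    field = RestraintField.zeros(n, model)
    if controls.sampling_friction is not None:
        config = replace(config, friction=controls.sampling_friction)

    # persistent replicas, equilibrated under the bare polymer
    state = []
    for _ in range(controls.n_replicas):
        x0 = init_chain(config, seed=int(rng.integers(2**31)))
        traj = langevin_run(x0, config, None, controls.equil_steps,
                            record_times=[controls.equil_steps * config.dt
                                          / config.tau],
                            seed=int(rng.integers(2**31)))
        state.append((traj.final_position, traj.final_velocity))

    def advance(current_field, n_steps, n_frames, stride_steps=None):
        all_frames = []
        for k in range(controls.n_replicas):
            x0, v0 = state[k]
            if stride_steps is None:
                # frames from the equilibrated second half of the window
                rec = np.linspace(0.5 * n_steps, n_steps, n_frames)
            else:
                rec = np.arange(stride_steps, n_steps + 1, stride_steps)
            traj = langevin_run(
                x0, config, current_field, n_steps,
                record_times=rec * config.dt / config.tau,
                seed=int(rng.integers(2**31)), velocities=v0)
            state[k] = (traj.final_position, traj.final_velocity)
            all_frames.append(traj.frames)
        return np.concatenate(all_frames, axis=0)

    devs, corrs, lrs = [], [], []
    converged = False
    message = ""
    bad_streak = 0
    it = 0
    iterations = 0
    plan = [(steps, lr0)
            for n_it, steps, lr0 in controls.schedule for _ in range(n_it)]
    plan.append((plan[-1][0], 0.0))  # final measurement, no update
    lr_scale = 1.0
    for steps_this, lr_base in plan:
        lr = max(lr_base * lr_scale, controls.min_learning_rate if lr_base
                 else 0.0)
        frames = advance(field if np.any(field.alphas) else None,
                         steps_this, controls.frames_per_replica)
        p_sim = contact_probability(frames, model)
        dev, corr = _fit_metrics(p_sim, f, mask)
        devs.append(dev)
        corrs.append(corr)
        lrs.append(lr)
        iterations = it
        if dev <= controls.tol:
            converged = True
            message = f"converged at iteration {it} (dev={dev:.4g})"
            break
        if lr_base == 0.0:
            message = f"max_iters reached (dev={dev:.4g})"
            break
        if len(devs) >= 2 and dev > devs[-2]:
            bad_streak += 1
            if bad_streak >= 5 and dev > 2.0 * min(devs):
                report = FitReport(devs, corrs, lrs, False, it,
                                   "aborted: deviation grew over 5 "
                                   "consecutive iterations")
                return field, frames, report
        else:
            bad_streak = 0
        if len(devs) >= 2 and dev > 1.25 * devs[-2]:
            # a >25% one-step jump is overshoot, not sampling noise
            lr_scale *= 0.5
            lr = max(lr_base * lr_scale, controls.min_learning_rate)
        field = update_alphas(field, p_sim, f, lr, controls.alpha_max)
        it += 1

    # production ensemble at stride tau
    production = advance(field if np.any(field.alphas) else None,
                         controls.production_taus * config.steps_per_tau,
                         controls.production_taus,
                         stride_steps=config.steps_per_tau)
    report = FitReport(devs, corrs, lrs, converged, iterations, message)
    return field, production, report


# ---------------------------------------------------------------------------
# persistence


def write_field(field: RestraintField, path, binning=None, header: str = "") -> None:
    """Persist a restraint field as dense text with a descriptive header."""
    lines = [header] if header else []
    lines.append(f"restraint field: n_beads={field.n_beads} "
                 f"r_c={field.contact_model.r_c} eta={field.contact_model.eta}")
    if binning is not None:
        lines.append(f"binning: {binning.chrom}:{binning.start}-{binning.end} "
                     f"@{binning.bin_size}")
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"# {line}\n")
        np.savetxt(fh, field.alphas, fmt="%.8g")


def read_field(path) -> RestraintField:
    """Read a restraint field written by :func:`write_field`."""
    r_c, eta = 1.5, 5.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "r_c=" in line:
                for tok in line.split():
                    if tok.startswith("r_c="):
                        r_c = float(tok[4:])
                    elif tok.startswith("eta="):
                        eta = float(tok[4:])
    alphas = np.loadtxt(path, comments="#")
    return RestraintField(alphas, ContactModel(r_c, eta))


def write_fit_report(report: FitReport, path) -> None:
    """FitReport as a TSV iteration log."""
    with open(path, "w") as fh:
        fh.write(f"# converged={report.converged} iterations={report.iterations} "
                 f"{report.message}\n")
        fh.write("iteration\tmean_abs_dev\tpearson\tlearning_rate\n")
        for i, (d, c, lr) in enumerate(
                zip(report.deviations, report.correlations, report.learning_rates)):
            fh.write(f"{i}\t{d:.6g}\t{c:.6g}\t{lr:.6g}\n")
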