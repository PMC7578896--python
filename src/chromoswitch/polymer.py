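"""Generic coarse-grained polymer with soft-core repulsion, in reduced units.

One bead represents one genomic bin.  The chain is held together by harmonic
bonds; non-bonded beads interact through a finite soft-core repulsion that
allows strand crossing (an effective topoisomerase: the energy at full
overlap is the finite cap ``softcore_cap``).  Optional maximum-entropy
restraints (see :mod:`chromoswitch.maxent`) supply all sequence-specific
structure.  Dynamics are BAOAB Langevin at reduced temperature T with bead
mass 1.

The trajectory time unit is tau = ``steps_per_tau * dt``; all recorded times
are expressed in multiples of tau.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels

__all__ = ["PolymerConfig", "Trajectory", "init_chain", "energy_and_forces",
           "langevin_run", "write_xyz", "read_xyz"]


@dataclass(frozen=True)
class PolymerConfig:
    """Reduced-unit parameters of the polymer model and integrator."""

    n_beads: int
    bond_length: float = 1.0
    bond_k: float = 100.0
    softcore_cap: float = 4.0      # 4 T at the default temperature
    softcore_range: float = 1.1
    temperature: float = 1.0
    friction: float = 0.1
    dt: float = 0.01
    steps_per_tau: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 2:
            raise ValueError("n_beads must be >= 2")
        for name in ("bond_length", "bond_k", "softcore_cap", "softcore_range",
                     "temperature", "friction", "dt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt <= 0 or self.steps_per_tau < 10:
            raise ValueError("dt must be positive and tau must span many steps")

    @property
    def tau(self) -> float:
        """The trajectory time unit in reduced time."""
        return self.steps_per_tau * self.dt


@dataclass
class Trajectory:
    """Time-ordered conformations with recording times in units of tau."""

    frames: np.ndarray          # (F, n, 3)
    times: np.ndarray           # (F,) in units of tau, strictly increasing
    config: PolymerConfig
    potential_energies: Optional[np.ndarray] = None
    kinetic_energies: Optional[np.ndarray] = None
    final_position: Optional[np.ndarray] = None
    final_velocity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("frame count must equal times count")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def init_chain(config: PolymerConfig, seed: Optional[int] = None) -> np.ndarray:
    """Random-walk initial conformation with step length ``bond_length``."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    steps = rng.standard_normal((config.n_beads - 1, 3))
    steps *= config.bond_length / np.linalg.norm(steps, axis=1)[:, None]
    x = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return x - x.mean(axis=0)


def _field_alphas(field, n: int):
    if field is None:
        return np.zeros((1, 1)), False
    alphas = np.ascontiguousarray(field.alphas, dtype=float)
    if alphas.shape != (n, n):
        raise ValueError(f"restraint field shape {alphas.shape} does not match "
                         f"{n} beads")
    return alphas, True


def energy_and_forces(conf: np.ndarray, config: PolymerConfig, field=None,
                      contact_model=None):
    """Total potential energy and per-bead forces (exact negative gradient)."""
    x = np.ascontiguousarray(conf, dtype=float)
    if x.shape != (config.n_beads, 3):
        raise ValueError(f"conformation shape {x.shape} != ({config.n_beads}, 3)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    alphas, has_field = _field_alphas(field, config.n_beads)
    r_c, eta = _contact_params(contact_model, field)
    forces = np.zeros_like(x)
    e = _kernels.energy_forces(
        x, alphas, has_field, config.bond_length, config.bond_k,
        config.softcore_range, config.softcore_cap, r_c, eta, forces)
    return float(e), forces


def _contact_params(contact_model, field):
    if contact_model is not None:
        return float(contact_model.r_c), float(contact_model.eta)
    model = getattr(field, "contact_model", None)
    if model is not None:
        return float(model.r_c), float(model.eta)
    return 1.5, 5.0  # module defaults: r_c = 1.5 b, eta = 5 / b


def langevin_run(
    conf: np.ndarray,
    config: PolymerConfig,
    field=None,
    n_steps: int = 1000,
    record_times: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
    velocities: Optional[np.ndarray] = None,
    contact_model=None,
) -> Trajectory:
    """Integrate BAOAB Langevin dynamics; deterministic given the seed.

    ``record_times`` are in units of tau and are snapped to the nearest
    integration step; they must lie within [0, n_steps * dt].  If omitted,
    10 uniformly spaced frames (excluding t=0) are recorded.
    """
    x = np.array(conf, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    n = config.n_beads
    if x.shape != (n, 3):
        raise ValueError(f"conformation shape {x.shape} != ({n}, 3)")
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    if velocities is None:
        v = rng.standard_normal((n, 3)) * np.sqrt(config.temperature)
    else:
        v = np.array(velocities, dtype=float)
    if record_times is None:
        record_steps = np.unique(
            np.linspace(1, n_steps, 10).round().astype(np.int64))
    else:
        record_steps = np.unique(
            np.round(np.asarray(record_times, dtype=float)
                     * config.steps_per_tau).astype(np.int64))
        if record_steps.size and (record_steps[0] < 0 or record_steps[-1] > n_steps):
            raise ValueError("record_times outside [0, n_steps * dt]")
    alphas, has_field = _field_alphas(field, n)
    r_c, eta = _contact_params(contact_model, field)
    n_rec = record_steps.size
    frames = np.zeros((n_rec, n, 3))
    pot = np.zeros(n_rec)
    kin = np.zeros(n_rec)
    kernel_seed = int(rng.integers(2**31))
    bad = _kernels.baoab_run(
        x, v, alphas, has_field, config.bond_length, config.bond_k,
        config.softcore_range, config.softcore_cap, r_c, eta,
        config.dt, config.friction, config.temperature,
        int(n_steps), record_steps, kernel_seed, frames, pot, kin)
    if bad < 0:
        # the kernel's in-loop check can be elided under fastmath; re-verify
        finite = np.isfinite(pot) & np.isfinite(frames).all(axis=(1, 2))
        if not finite.all():
            bad = int(record_steps[np.argmin(finite)])
    if bad >= 0:
        raise FloatingPointError(
            f"integration became unstable at step {bad} (non-finite energy); "
            "reduce dt or the restraint magnitudes")
    times = record_steps.astype(float) / config.steps_per_tau
    # a frame exactly at t=0 breaks strict monotonicity only if duplicated
    return Trajectory(frames, times, config, pot, kin,
                      final_position=x, final_velocity=v)


def write_xyz(traj: Trajectory, path, times_path=None) -> None:
    """Multi-frame XYZ (bead id = genomic bin index) + sidecar times file."""
    n = traj.frames.shape[1]
    with open(path, "w") as fh:
        for fi in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"t={traj.times[fi]:.6g} tau\n")
            for i in range(n):
                x, y, z = traj.frames[fi, i]
                fh.write(f"{i} {x:.6f} {y:.6f} {z:.6f}\n")
    if times_path is not None:
        np.savetxt(times_path, traj.times, fmt="%.6g")


def read_xyz(path, config: PolymerConfig, times_path=None) -> Trajectory:
    """Read a multi-frame XYZ written by :func:`write_xyz`."""
    frames = []
    times = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        comment = lines[i + 1]
        t = float(comment.split("t=")[1].split()[0]) if "t=" in comment else len(times)
        coords = np.array(
            [[float(v) for v in lines[i + 2 + k].split()[1:4]] for k in range(n)])
        frames.append(coords)
        times.append(t)
        i += 2 + n
    if times_path is not None:
        times = np.loadtxt(times_path).ravel().tolist()
    return Trajectory(np.array(frames), np.array(times), config)
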