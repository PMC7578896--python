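"""Shared fixtures.

Expensive simulation fixtures are session-scoped and lazy: the two-state
fit at desk scale (n=60) backs the switching tests, and the n=200 fit backs
the scaling/fit-quality checks.  Sizes are chosen so the whole suite runs
on one CPU in minutes while leaving enough sampling for the statistical
assertions.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromoswitch import maxent, polymer, switching, synthetic_data


@pytest.fixture(scope="session")
def small_pair():
    """Synthetic two-state pair at n=60 (pure power-law backbones)."""
    n = 60
    spec_a = synthetic_data.SyntheticStateSpec(
        n, -1.5, (), tuple(["A"] * n), 0.0, 0.0, 11)
    spec_b = synthetic_data.SyntheticStateSpec(
        n, -1.0, (), tuple(["A"] * n), 0.0, 0.0, 12)
    return (synthetic_data.make_target_map(spec_a),
            synthetic_data.make_target_map(spec_b))


@pytest.fixture(scope="session")
def fitted_small_pair(small_pair):
    """Max-ent fits of both n=60 states (field, ensemble, report) each."""
    map_a, map_b = small_pair
    cfg = polymer.PolymerConfig(n_beads=60, seed=1)
    ctl = dict(schedule=((15, 800, 8.0), (10, 1600, 3.0)), n_replicas=12,
               equil_steps=2000, frames_per_replica=10, production_taus=12)
    fit_a = maxent.fit_state(map_a, cfg,
                             controls=maxent.FitControls(seed=21, **ctl))
    fit_b = maxent.fit_state(map_b, cfg,
                             controls=maxent.FitControls(seed=22, **ctl))
    return cfg, fit_a, fit_b


@pytest.fixture(scope="session")
def switch_ensembles(fitted_small_pair):
    """Forward and backward switching ensembles on the n=60 fitted pair."""
    cfg, (field_a, ens_a, _), (field_b, ens_b, _) = fitted_small_pair
    schedule = switching.log_schedule(0.1, 30.0, per_decade=8)
    rng = np.random.default_rng(5)

    def build(src_ens, f_from, f_to, direction, seed):
        pick = rng.choice(src_ens.shape[0], size=12, replace=False)
        return switching.switch_ensemble(
            src_ens[pick], np.zeros(12, dtype=int), cfg, f_from, f_to,
            direction, record_times=schedule, pre_switch_taus=3.0, seed=seed)

    fwd = build(ens_a, field_a, field_b, "A->B", 101)
    bwd = build(ens_b, field_b, field_a, "B->A", 102)
    return cfg, fwd, bwd


@pytest.fixture(scope="session")
def fit200():
    """Max-ent fit to an n=200 power-law target (stem-cell-like exponent)."""
    n = 200
    spec = synthetic_data.SyntheticStateSpec(
        n, -1.5, (), tuple(["A"] * n), 0.0, 0.0, 1)
    target = synthetic_data.make_target_map(spec)
    cfg = polymer.PolymerConfig(n_beads=n, seed=1)
    ctl = maxent.FitControls(seed=2)
    field, ensemble, report = maxent.fit_state(target, cfg, controls=ctl)
    return target, cfg, field, ensemble, report
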