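"""Initial-structure selection, the switch protocol, and ensemble maps."""

import numpy as np
import pytest

from chromoswitch import maxent, polymer, switching
from chromoswitch.maxent import ContactModel, contact_probability
from chromoswitch.switching import (SwitchEnsemble, ensemble_maps,
                                    log_schedule, run_switch,
                                    select_initial_structures)


class TestLogSchedule:
    def test_default_density(self):
        t = log_schedule(0.1, 1000.0, per_decade=20)
        assert t[0] == pytest.approx(0.1)
        assert t[-1] == pytest.approx(1000.0)
        assert len(t) == 81  # 20 per decade over 4 decades, inclusive

    def test_strictly_increasing(self):
        t = log_schedule(0.5, 50.0, per_decade=7)
        assert np.all(np.diff(t) > 0)


class TestSelectInitialStructures:
    def _blob(self, center, n, seed, spread=0.01):
        rng = np.random.default_rng(seed)
        base = np.cumsum(rng.standard_normal((12, 3)), axis=0) + center
        return np.stack([base + spread * rng.standard_normal((12, 3))
                         for _ in range(n)])

    def test_identical_conformations_one_cluster(self):
        conf = self._blob(0.0, 1, 0, spread=0)[0]
        ens = np.stack([conf] * 50)
        chosen, ids = select_initial_structures(ens, n_sample=20, seed=1)
        assert chosen.shape[0] == 2  # per_cluster default
        assert len(set(ids.tolist())) == 1

    def test_two_separated_clusters_contribute_two_each(self):
        # two structurally distinct families, populations 0.6 / 0.4
        compact = self._blob(0.0, 30, 1)
        extended = self._blob(0.0, 20, 2) * 4.0
        ens = np.concatenate([compact, extended])
        chosen, ids = select_initial_structures(ens, n_sample=50,
                                                min_population=0.1, seed=3)
        assert chosen.shape[0] == 4
        values, counts = np.unique(ids, return_counts=True)
        assert len(values) == 2
        assert np.all(counts == 2)

    def test_small_cluster_below_threshold_excluded(self):
        compact = self._blob(0.0, 99, 4)
        outlier = self._blob(0.0, 1, 5) * 10.0
        ens = np.concatenate([compact, outlier])
        chosen, ids = select_initial_structures(
            ens, n_sample=100, min_population=0.05, seed=6)
        assert len(set(ids.tolist())) == 1  # outlier contributed nothing

    def test_sample_larger_than_ensemble_rejected(self):
        with pytest.raises(ValueError, match="n_sample"):
            select_initial_structures(np.zeros((5, 4, 3)), n_sample=10)

    def test_no_cluster_passes_raises(self):
        ens = np.stack([self._blob(0.0, 1, s, spread=0)[0] * (1 + s)
                        for s in range(10)])
        with pytest.raises(ValueError, match="min_population"):
            select_initial_structures(ens, n_sample=10, min_population=0.5,
                                      distance_cutoff=1e-9, seed=0)


class TestRunSwitch:
    def test_null_switch_preserves_contact_statistics(self, fitted_small_pair):
        """Switching a landscape onto itself leaves the ensemble map alone."""
        cfg, (field_a, ens_a, _), _ = fitted_small_pair
        model = field_a.contact_model
        rng = np.random.default_rng(0)
        pick = rng.choice(ens_a.shape[0], size=12, replace=False)
        before = contact_probability(ens_a, model)
        trajs = [run_switch(ens_a[k], cfg, field_a, field_a,
                            record_times=[4.0, 6.0, 8.0, 10.0],
                            pre_switch_taus=2.0,
                            seed=int(rng.integers(2**31))) for k in pick]
        after = contact_probability(
            np.concatenate([tr.frames for tr in trajs]), model)
        mask = np.abs(np.subtract.outer(*[np.arange(cfg.n_beads)] * 2)) > 1
        corr = np.corrcoef(before[mask], after[mask])[0, 1]
        assert corr >= 0.95

    def test_relaxation_energy_decreases(self, fitted_small_pair):
        """Mean potential energy under the new landscape relaxes downward
        from the switch instant over the first decade."""
        cfg, (field_a, ens_a, _), (field_b, _, _) = fitted_small_pair
        rng = np.random.default_rng(3)
        pick = rng.choice(ens_a.shape[0], size=10, replace=False)
        pots = []
        for k in pick:
            tr = run_switch(ens_a[k], cfg, field_a, field_b,
                            record_times=[0.0, 0.3, 1.0], relax_taus=1.0,
                            pre_switch_taus=2.0,
                            seed=int(rng.integers(2**31)))
            pots.append(tr.potential_energies)
        pot = np.mean(pots, axis=0)
        assert pot[-1] < pot[0]

    def test_end_state_reaches_target(self, fitted_small_pair,
                                      switch_ensembles):
        """After relaxation the ensemble map matches the destination state."""
        _, (_, ens_a, _), (_, ens_b, _) = fitted_small_pair
        cfg, fwd, bwd = switch_ensembles
        model = ContactModel()
        mask = np.abs(np.subtract.outer(*[np.arange(cfg.n_beads)] * 2)) > 1
        late = [fwd.times.size - 1 - k for k in range(3)]
        for ens, dest in ((fwd, ens_b), (bwd, ens_a)):
            final = contact_probability(
                np.concatenate([ens.frames_at(t) for t in late]), model)
            target = contact_probability(dest, model)
            corr = np.corrcoef(final[mask], target[mask])[0, 1]
            assert corr >= 0.9

    def test_time_zero_matches_source_state(self, fitted_small_pair,
                                            switch_ensembles):
        _, (_, ens_a, _), _ = fitted_small_pair
        cfg, fwd, _ = switch_ensembles
        model = ContactModel()
        mask = np.abs(np.subtract.outer(*[np.arange(cfg.n_beads)] * 2)) > 1
        # pool the earliest recorded times (all well within the first tau)
        early = np.flatnonzero(fwd.times <= 0.5)
        t0_map = contact_probability(
            np.concatenate([fwd.frames_at(t) for t in early]), model)
        src = contact_probability(ens_a, model)
        assert np.corrcoef(t0_map[mask], src[mask])[0, 1] >= 0.9

    def test_mismatched_field_rejected(self):
        cfg = polymer.PolymerConfig(n_beads=10)
        bad = maxent.RestraintField.zeros(8)
        with pytest.raises(ValueError, match="n_beads"):
            run_switch(np.zeros((10, 3)), cfg, bad, None)


class TestEnsembleMaps:
    def test_single_frame_equals_w_matrix(self, switch_ensembles):
        cfg, fwd, _ = switch_ensembles
        model = ContactModel()
        maps = ensemble_maps(fwd, model)
        pooled = contact_probability(fwd.frames_at(0), model)
        from chromoswitch.hic_io import normalize_to_probability
        expected = normalize_to_probability(pooled)
        np.testing.assert_allclose(maps[0].values, expected.values, atol=1e-12)

    def test_mismatched_schedules_rejected(self, switch_ensembles):
        cfg, fwd, _ = switch_ensembles
        tr = fwd.trajectories[0]
        other = polymer.Trajectory(tr.frames[:3], tr.times[:3], cfg)
        with pytest.raises(ValueError, match="schedule"):
            SwitchEnsemble([tr, other], "A->B", np.zeros(2))

    def test_needs_two_trajectories(self, switch_ensembles):
        cfg, fwd, _ = switch_ensembles
        solo = SwitchEnsemble(fwd.trajectories[:1], "A->B", np.zeros(1))
        with pytest.raises(ValueError, match="2 trajectories"):
            ensemble_maps(solo)


class TestIrreversibility:
    def test_forward_backward_pathways_do_not_coincide(self, switch_ensembles):
        """Averaged A->B and B->A pathways in the (Rg, asphericity) plane
        separate by more than 3x the pathway standard error somewhere."""
        from chromoswitch.structure_analysis import pathway_average, shape
        _, fwd, bwd = switch_ensembles
        pf = pathway_average(fwd, lambda c: shape(c).rg,
                             lambda c: shape(c).asphericity)
        pb = pathway_average(bwd, lambda c: shape(c).rg,
                             lambda c: shape(c).asphericity)
        # compare at the same time points; direction is reversed so compare
        # forward at t with backward at (T - t) along the schedule
        gap = np.abs(pf.mean_x - pb.mean_x[::-1])
        se = np.sqrt(pf.se_x**2 + pb.se_x[::-1] ** 2)
        assert np.any(gap > 3 * se)

    def test_overexpansion_in_backward_direction(self, fitted_small_pair,
                                                 switch_ensembles):
        """Some expanding (B->A) trajectories overshoot the A-state mean Rg."""
        from chromoswitch.structure_analysis import shape
        _, (_, ens_a, _), _ = fitted_small_pair
        _, _, bwd = switch_ensembles
        rg_a = np.mean([shape(fr).rg for fr in ens_a])
        max_rg = [max(shape(fr).rg for fr in tr.frames)
                  for tr in bwd.trajectories]
        assert np.any(np.asarray(max_rg) > rg_a)
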