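"""Synthetic cohort generator: structure, noise model, determinism."""

import filecmp
import json

import numpy as np
import pytest

import clonetrack as ct
from clonetrack.synthetic import (InvalidConfigError, _pairwise_separation,
                                  simulate_mutations,
                                  simulate_null_locus_counts)


class TestForestTopology:
    def test_single_topology_is_one_root(self, rng):
        cfg = ct.SimulationConfig(seed=1, n_clones=1, topology="single")
        forest = ct.simulate_clone_forest(cfg, rng)
        assert len(forest.nodes) == 1 and len(forest.roots) == 1

    def test_linear_topology_is_path(self, rng):
        cfg = ct.SimulationConfig(seed=1, n_clones=3, topology="linear")
        forest = ct.simulate_clone_forest(cfg, rng)
        assert len(forest.roots) == 1
        assert all(len(forest.children(c)) <= 1 for c in forest.nodes)
        assert len(forest.root_path("C2")) == 3

    def test_certain_unrelated_clone_gives_two_roots(self, rng):
        cfg = ct.SimulationConfig(seed=1, n_clones=2, topology="linear",
                                  p_unrelated=1.0)
        forest = ct.simulate_clone_forest(cfg, rng)
        assert len(forest.roots) >= 2

    def test_invalid_clone_count_rejected(self):
        with pytest.raises(InvalidConfigError):
            ct.SimulationConfig(seed=1, n_clones=0)

    def test_every_mutation_belongs_to_one_clone(self, rng):
        cfg = ct.SimulationConfig(seed=5, n_clones=4, topology="random",
                                  p_unrelated=1.0)
        forest = ct.simulate_clone_forest(cfg, rng)
        assignment = forest.clone_of_mutation()  # raises on double-assignment
        total = sum(len(n.private_mutation_ids) for n in forest.nodes.values())
        assert len(assignment) == total


class TestTrajectories:
    @pytest.mark.parametrize("seed", range(8))
    def test_nesting_invariant_holds_exactly(self, seed):
        cfg = ct.SimulationConfig(seed=seed, n_clones=4, topology="random",
                                  p_unrelated=0.5, n_timepoints=5)
        rng = np.random.default_rng(seed)
        forest = ct.simulate_clone_forest(cfg, rng)
        traj = ct.simulate_trajectories(forest, cfg, rng)
        traj.check_nesting(forest)  # raises on violation

    def test_unit_suppression_factor_changes_nothing(self):
        cfg = ct.SimulationConfig(seed=7, n_clones=2, topology="linear")
        rng = np.random.default_rng(0)
        forest = ct.simulate_clone_forest(cfg, rng)
        base = ct.simulate_trajectories(forest, cfg, np.random.default_rng(1))
        cfg_tx = ct.SimulationConfig(
            seed=7, n_clones=2, topology="linear",
            treatment_windows=[ct.TreatmentWindow(0.0, 5000.0, 1.0)])
        treated = ct.simulate_trajectories(forest, cfg_tx,
                                           np.random.default_rng(1))
        assert np.allclose(base.ccf, treated.ccf)

    def test_suppression_multiplies_root_tree(self):
        cfg = ct.SimulationConfig(seed=7, n_clones=2, topology="linear",
                                  n_timepoints=4)
        rng = np.random.default_rng(0)
        forest = ct.simulate_clone_forest(cfg, rng)
        window = ct.TreatmentWindow(cfg.times[2], cfg.times[3], 0.01)
        cfg_tx = ct.SimulationConfig(
            seed=7, n_clones=2, topology="linear", n_timepoints=4,
            treatment_windows=[window])
        base = ct.simulate_trajectories(forest, cfg, np.random.default_rng(1))
        treated = ct.simulate_trajectories(forest, cfg_tx,
                                           np.random.default_rng(1))
        for cid in forest.nodes:
            assert np.allclose(treated.ccf.loc[cid].iloc[2:],
                               base.ccf.loc[cid].iloc[2:] * 0.01)
            assert np.allclose(treated.ccf.loc[cid].iloc[:2],
                               base.ccf.loc[cid].iloc[:2])

    def test_separation_enforced_by_patient_simulator(self):
        cfg = ct.SimulationConfig(seed=11, n_clones=3, topology="branching")
        bundle = ct.simulate_patient(cfg)
        assert _pairwise_separation(bundle.trajectories) >= cfg.min_separation
        assert (bundle.trajectories.ccf.max(axis=1)
                >= cfg.min_clone_ccf).all()


class TestReadCounts:
    def test_zero_vaf_zero_error_gives_zero_alt(self, rng):
        alts, _ = ct.simulate_read_counts(np.zeros(100), 1000, 0.0, rng)
        assert np.all(alts == 0)

    def test_unit_vaf_zero_error_gives_full_depth(self, rng):
        alts, depths = ct.simulate_read_counts(np.ones(100), 1000, 0.0, rng)
        assert np.all(alts == depths)

    def test_high_depth_concentrates_observed_vaf(self, rng):
        # binomial tail: at depth ~10,000 the observed VAF of a 0.5 locus
        # stays within +-0.02 virtually always
        alts, depths = ct.simulate_read_counts(
            np.full(2000, 0.5), 10_000, 0.0, rng)
        obs = alts / depths
        assert np.mean(np.abs(obs - 0.5) <= 0.02) >= 0.99

    def test_infinite_depth_limit_matches_expected_vaf(self, rng):
        vafs = np.linspace(0.01, 0.95, 25)
        alts, depths = ct.simulate_read_counts(vafs, 1_000_000, 0.0, rng)
        assert np.allclose(alts / depths, vafs, atol=1e-2)

    def test_null_loci_carry_full_base_composition(self, rng):
        loci = simulate_null_locus_counts(50, 10_000, 5e-4, rng)
        for counts in loci:
            assert set(counts) == {"A", "C", "G", "T"}
            assert counts["A"] > sum(counts[b] for b in "CGT")


class TestColonies:
    def test_pure_clone_colonies_carry_all_its_mutations(self, rng):
        cfg = ct.SimulationConfig(seed=2, n_clones=2, topology="linear")
        forest = ct.simulate_clone_forest(cfg, rng)
        import pandas as pd
        fractions = pd.Series({"C0": 1.0, "C1": 1.0})  # C1 exclusive owner
        table = ct.simulate_colonies(forest, fractions, 10, 0.0, rng,
                                     error_rate=0.0)
        # C1 founders carry both C0 (ancestral) and C1 mutations
        wide = table.pivot(index="colony_id", columns="mutation_id",
                           values="vaf")
        assert (wide > 0.4).all().all()

    def test_zero_fraction_clone_never_founds(self, rng):
        cfg = ct.SimulationConfig(seed=2, n_clones=2, topology="linear")
        forest = ct.simulate_clone_forest(cfg, rng)
        import pandas as pd
        fractions = pd.Series({"C0": 0.6, "C1": 0.0})
        table = ct.simulate_colonies(forest, fractions, 30, 0.0, rng)
        assert not (table["founder"] == "C1").any()

    def test_unmixed_colonies_never_span_unrelated_roots(self, rng):
        cfg = ct.SimulationConfig(seed=4, n_clones=2, topology="linear",
                                  p_unrelated=1.0)
        forest = ct.simulate_clone_forest(cfg, rng)
        import pandas as pd
        roots = forest.roots
        fractions = pd.Series({c: 0.0 for c in forest.nodes})
        fractions[roots[0]] = 0.45
        fractions[roots[1]] = 0.45
        table = ct.simulate_colonies(forest, fractions, 40, 0.0, rng,
                                     error_rate=0.0)
        wide = table.pivot(index="colony_id", columns="mutation_id",
                           values="vaf")
        muts_a = forest.nodes[roots[0]].private_mutation_ids
        muts_b = forest.nodes[roots[1]].private_mutation_ids
        both = (wide[muts_a].gt(0.4).any(axis=1)
                & wide[muts_b].gt(0.4).any(axis=1))
        assert not both.any()

    def test_colony_count_validated(self, rng):
        cfg = ct.SimulationConfig(seed=2, n_clones=1, topology="single")
        forest = ct.simulate_clone_forest(cfg, rng)
        import pandas as pd
        with pytest.raises(InvalidConfigError):
            ct.simulate_colonies(forest, pd.Series({"C0": 1.0}), 0, 0.0, rng)


class TestCohortSerialisation:
    def test_round_trip_reproduces_read_counts(self, tmp_path,
                                               branching_bundle):
        ct.write_cohort(branching_bundle, tmp_path / "p1")
        back = ct.read_cohort(tmp_path / "p1")
        assert back["counts"].equals(branching_bundle.counts)
        assert back["truth"]["assignment"] == \
            branching_bundle.true_assignment()

    def test_truth_clone_count_matches_forest(self, tmp_path,
                                              branching_bundle):
        ct.write_cohort(branching_bundle, tmp_path / "p1")
        truth = json.loads((tmp_path / "p1" / "truth.json").read_text())
        assert len(truth["clones"]) == len(branching_bundle.forest.nodes)

    def test_fixed_seed_fixes_every_byte(self, tmp_path):
        for d in ("a", "b"):
            cfg = ct.SimulationConfig(seed=42, n_clones=3,
                                      topology="branching")
            ct.write_cohort(ct.simulate_patient(cfg), tmp_path / d)
        files = [p.name for p in (tmp_path / "a").iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", files, shallow=False)
        assert sorted(match) == sorted(files) and not mismatch and not errors

    def test_mutation_annotations_are_consistent(self, rng):
        cfg = ct.SimulationConfig(seed=9, n_clones=3, topology="random")
        forest = ct.simulate_clone_forest(cfg, rng)
        muts = simulate_mutations(forest, cfg, rng)
        assert len({m.mutation_id for m in muts}) == len(muts)
        for m in muts:
            assert m.ref != m.alt
            assert m.clone_of_origin in forest.nodes
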