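"""Colony genotyping, forest enumeration, selection and classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

import clonetrack as ct
from clonetrack.config import PipelineConfig
from clonetrack.reconstruct import (Genotype, ROOT, CombinatorialLimitError,
                                    best_violating_forest,
                                    constraints_to_clusters, first_detection)


def forest_oracle(C, eps, detect=None):
    """Brute-force admissible parent vectors: try every assignment directly.

    C is an (n_clusters, n_samples) array; -1 denotes root. Checks, with a
    flat tolerance eps: acyclicity, per-edge pigeonhole, per-node sum rule,
    root bound, and temporal precedence when detection indices are given.
    """
    k = len(C)
    admissible = []
    for vec in itertools.product([-1] + list(range(k)), repeat=k):
        if any(vec[i] == i for i in range(k)):
            continue
        ok = True
        for i in range(k):  # acyclicity by walking up
            seen, cur = set(), i
            while cur != -1:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = vec[cur]
            if not ok:
                break
        if not ok:
            continue
        for c in range(k):
            p = vec[c]
            if p != -1 and np.any(C[c] > C[p] + eps):
                ok = False
            if p != -1 and detect is not None and detect[p] > detect[c]:
                ok = False
        if not ok:
            continue
        for p in range(-1, k):
            kids = [c for c in range(k) if vec[c] == p]
            if not kids:
                continue
            total = C[kids].sum(axis=0)
            bound = (1.0 if p == -1 else C[p]) + eps
            if np.any(total > bound):
                ok = False
                break
        if ok:
            admissible.append(vec)
    return sorted(admissible)


def _centroid_frame(rows):
    return pd.DataFrame(rows, dtype=float)


class TestGenotypeColony:
    @pytest.mark.parametrize("vaf, expected", [
        (0.45, Genotype.PRESENT),   # above the 40% positivity bar
        (0.04, Genotype.ABSENT),    # below the 5% absence bar
        (0.20, Genotype.AMBIGUOUS),  # possibly mixed colony
    ])
    def test_ternary_thresholds(self, vaf, expected):
        out = ct.genotype_colony(pd.Series({"m1": vaf}))
        assert out["m1"] is expected

    def test_invalid_vaf_rejected(self):
        with pytest.raises(ValueError):
            ct.genotype_colony(pd.Series({"m1": 1.2}))


class TestColonyConstraints:
    def _matrix(self, rows):
        frame = pd.DataFrame(rows, columns=["c1", "c2"]).T
        frame.columns = ["i", "j"][:frame.shape[1]]
        return frame.map(lambda v: Genotype(v))

    def test_containment_implies_ancestry(self):
        mat = pd.DataFrame([[1, 1], [1, 0]], columns=["i", "j"],
                           index=["c1", "c2"]).map(Genotype)
        cons = ct.colony_constraints(mat)
        assert ("i", "j") in cons.nested and not cons.exclusive

    def test_never_cooccurring_is_exclusive(self):
        mat = pd.DataFrame([[1, 0], [0, 1]], columns=["i", "j"],
                           index=["c1", "c2"]).map(Genotype)
        cons = ct.colony_constraints(mat)
        assert frozenset(("i", "j")) in cons.exclusive and not cons.nested

    def test_all_three_patterns_flag_violation(self):
        mat = pd.DataFrame([[1, 1], [1, 0], [0, 1]], columns=["i", "j"],
                           index=["c1", "c2", "c3"]).map(Genotype)
        cons = ct.colony_constraints(mat)
        assert frozenset(("i", "j")) in cons.violations

    def test_exhaustive_two_mutation_patterns(self):
        # every subset of {(1,1),(1,0),(0,1)} classified correctly
        for patterns in itertools.chain.from_iterable(
                itertools.combinations([(1, 1), (1, 0), (0, 1)], r)
                for r in (1, 2, 3)):
            mat = pd.DataFrame(list(patterns), columns=["i", "j"],
                               index=[f"c{n}" for n in
                                      range(len(patterns))]).map(Genotype)
            cons = ct.colony_constraints(mat)
            has = set(patterns)
            if has == {(1, 1), (1, 0), (0, 1)}:
                assert cons.violations
            elif (1, 1) in has and (1, 0) in has:
                assert ("i", "j") in cons.nested
            elif (1, 1) in has and (0, 1) in has:
                assert ("j", "i") in cons.nested
            elif has == {(1, 0), (0, 1)}:
                assert frozenset(("i", "j")) in cons.exclusive

    def test_ambiguous_colonies_excluded(self):
        mat = pd.DataFrame([[1, -1], [1, 0]], columns=["i", "j"],
                           index=["c1", "c2"]).map(Genotype)
        cons = ct.colony_constraints(mat)
        assert cons.n_colonies_used == 1


class TestEnumerateForests:
    def test_one_cluster_single_root(self):
        forests = ct.enumerate_forests(_centroid_frame({"A": [0.5]}).T)
        assert forests == [{"A": None}]

    def test_branching_forced_by_crossing_children(self):
        # B and C cross, so neither can parent the other; both fit under A
        cent = pd.DataFrame({"A": [0.9, 0.9], "B": [0.5, 0.2],
                             "C": [0.3, 0.6]}).T
        forests = ct.enumerate_forests(cent)
        assert {"A": None, "B": "A", "C": "A"} in forests
        for f in forests:
            assert f["B"] != "C" and f["C"] != "B"

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        k = int(rng.integers(1, 6))
        t = int(rng.integers(1, 5))
        C = rng.uniform(0, 1, size=(k, t))
        names = [f"K{i}" for i in range(k)]
        cent = pd.DataFrame(C, index=names)
        cfg = PipelineConfig(eps_floor=0.05)
        got = ct.enumerate_forests(cent, config=cfg)
        detect = first_detection(cent).to_numpy()
        expected = forest_oracle(C, eps=0.05, detect=detect)
        got_vecs = sorted(
            tuple(-1 if f[n] is None else names.index(f[n]) for n in names)
            for f in got)
        assert got_vecs == expected

    def test_cluster_cap_enforced(self):
        cent = pd.DataFrame(np.linspace(0.9, 0.1, 13)[:, None],
                            index=[f"K{i:02d}" for i in range(13)])
        with pytest.raises(CombinatorialLimitError):
            ct.enumerate_forests(cent)

    def test_exclusive_pair_never_on_one_path(self):
        cent = pd.DataFrame({"A": [0.6], "B": [0.35]}).T
        cons = ct.ColonyConstraints(exclusive={frozenset(("A", "B"))})
        forests = ct.enumerate_forests(cent, cluster_constraints=cons)
        assert forests == [{"A": None, "B": None}]


class TestScoreAndSelect:
    def test_unique_forest_returned_unchanged(self):
        cent = pd.DataFrame({"A": [0.8], "B": [0.4]}).T
        forests = [{"A": None, "B": "A"}]
        est = ct.score_and_select(forests, cent)
        assert est.parent == forests[0] and est.n_admissible == 1

    def test_linear_preferred_over_branch_on_ties(self):
        # both slack-free; branch penalty breaks the tie towards the chain
        cent = pd.DataFrame({"A": [0.9], "B": [0.5], "C": [0.3]}).T
        forests = [{"A": None, "B": "A", "C": "B"},
                   {"A": None, "B": "A", "C": "A"}]
        est = ct.score_and_select(forests, cent)
        assert est.parent == {"A": None, "B": "A", "C": "B"}

    def test_fewer_roots_preferred(self):
        cent = pd.DataFrame({"A": [0.5], "B": [0.3]}).T
        forests = [{"A": None, "B": None}, {"A": None, "B": "A"}]
        est = ct.score_and_select(forests, cent)
        assert est.parent == {"A": None, "B": "A"}

    def test_simulated_branching_topology_selected(self, branching_bundle,
                                                   branching_results):
        res = branching_results
        truth = branching_bundle.true_assignment()
        c2c = {res.assignment[m]: truth[m] for m in truth}
        tp = branching_bundle.true_parent_map()
        for c, p in res.estimate.parent.items():
            assert (None if p is None else c2c[p]) == tp[c2c[c]]

    def test_no_admissible_forest_reports_violations(self):
        # two clusters that cannot nest and cannot both be roots
        cent = pd.DataFrame({"A": [0.9, 0.2], "B": [0.8, 0.9]}).T
        forests = ct.enumerate_forests(cent)
        assert forests == []
        est = best_violating_forest(cent)
        assert est.violations and est.n_admissible == 0


class TestUnrelatedAndPattern:
    def test_single_root_no_unrelated(self):
        cent = pd.DataFrame({"A": [0.8], "B": [0.4]}).T
        est = ct.score_and_select([{"A": None, "B": "A"}], cent)
        assert ct.detect_unrelated_clones(est) == {}

    def test_pigeonhole_exclusivity_grade(self):
        cent = pd.DataFrame({"A": [0.7, 0.7], "B": [0.1, 0.6]}).T
        est = ct.score_and_select([{"A": None, "B": None}], cent)
        assert ct.detect_unrelated_clones(est) == {"B": "pigeonhole"}

    def test_colony_proof_outranks_pigeonhole(self):
        cent = pd.DataFrame({"A": [0.7, 0.7], "B": [0.1, 0.6]}).T
        est = ct.score_and_select([{"A": None, "B": None}], cent)
        cons = ct.ColonyConstraints(exclusive={frozenset(("A", "B"))})
        assert ct.detect_unrelated_clones(est, cons) == {"B": "colony-proven"}

    def test_topology_only_grade(self):
        cent = pd.DataFrame({"A": [0.5, 0.5], "B": [0.1, 0.3]}).T
        est = ct.score_and_select([{"A": None, "B": None}], cent)
        assert ct.detect_unrelated_clones(est) == {"B": "topology-only"}

    @pytest.mark.parametrize("parent, kind", [
        ({"A": None}, "single_clone"),
        ({"A": None, "B": "A", "C": "B"}, "linear"),
        ({"A": None, "B": "A", "C": "A"}, "branching"),
    ])
    def test_pattern_classes(self, parent, kind):
        cent = pd.DataFrame(
            {c: [0.9 - 0.2 * i] for i, c in enumerate(sorted(parent))}).T
        est = ct.score_and_select([parent], cent)
        assert ct.classify_pattern(est).kind == kind

    def test_unrelated_flag_set_for_second_root(self):
        cent = pd.DataFrame({"A": [0.6], "B": [0.2]}).T
        est = ct.score_and_select([{"A": None, "B": None}], cent)
        assert ct.classify_pattern(est).unrelated_clones


class TestCloneFractions:
    def test_root_exclusive_fraction(self):
        cent = pd.DataFrame({"A": [0.8], "B": [0.5]}).T
        est = ct.score_and_select([{"A": None, "B": "A"}], cent)
        fracs = ct.clone_fractions(est)
        assert fracs.loc["A"].iloc[0] == pytest.approx(0.3)
        assert fracs.loc["B"].iloc[0] == pytest.approx(0.5)
        assert fracs.loc["normal"].iloc[0] == pytest.approx(0.2)

    def test_childless_clone_keeps_full_ccf(self):
        cent = pd.DataFrame({"A": [0.4]}).T
        est = ct.score_and_select([{"A": None}], cent)
        assert ct.clone_fractions(est).loc["A"].iloc[0] == pytest.approx(0.4)

    def test_telescoping_sum_equals_root_ccf(self, rng):
        # per tree, exclusive fractions re-sum to the root CCF exactly
        for _ in range(10):
            k = int(rng.integers(2, 6))
            names = [f"K{i}" for i in range(k)]
            C = np.sort(rng.uniform(0, 1, size=(k, 3)), axis=0)[::-1]
            # force nesting so no clipping occurs
            cent = pd.DataFrame(C, index=names)
            parent = {names[0]: None}
            for i in range(1, k):
                parent[names[i]] = names[i - 1]
            est = ct.score_and_select([parent], cent)
            fracs = ct.clone_fractions(est).drop("normal")
            assert np.allclose(fracs.sum(axis=0), cent.loc[names[0]])

    def test_constraint_lift_to_clusters(self):
        cons = ct.ColonyConstraints(nested={("m1", "m2")},
                                    exclusive={frozenset(("m3", "m4"))})
        lifted = constraints_to_clusters(
            cons, {"m1": "A", "m2": "B", "m3": "A", "m4": "C"})
        assert lifted.nested == {("A", "B")}
        assert lifted.exclusive == {frozenset(("A", "C"))}
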