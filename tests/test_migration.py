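"""Migration-history inference: Sankoff optimality against brute force,
path annotation, consensus histories, and driver-rate comparisons."""

import itertools
import math

import numpy as np
import pytest

from cloneboot import (GenotypeMatrix, MigrationHistory, build_tree,
                       compare_driver_rates, consensus_history, infer_history,
                       map_mutations_to_paths, path_supports, sankoff_labeling)
from cloneboot.migration import AnnotatedPath, _expanded_children
from cloneboot.trees import ClonePhylogeny


def geno(rows, ids=None):
    ids = ids or [f"c{i}" for i in range(len(rows))]
    return GenotypeMatrix(ids, [f"s{j}" for j in range(len(rows[0]))],
                          [[int(ch) for ch in r] for r in rows])


def brute_force_min_migrations(tree, occupancy, primary):
    """Enumerate every site labeling of the expanded tree; root fixed."""
    children, leaf_site = _expanded_children(tree, occupancy)
    sites = sorted({primary} | {s for ss in occupancy.values() for s in ss})
    nodes = [tree.root]
    stack = list(children[tree.root])
    while stack:
        n = stack.pop()
        nodes.append(n)
        stack.extend(children[n])
    free = [n for n in nodes if n != tree.root and n not in leaf_site
            and children[n]] + \
           [n for n in nodes if n != tree.root and not children[n]
            and n not in leaf_site]
    fixed = {tree.root: primary, **leaf_site}
    best = math.inf
    for combo in itertools.product(sites, repeat=len(free)):
        lab = dict(fixed)
        lab.update(zip(free, combo))
        cost = 0
        for n in nodes:
            for k in children[n]:
                if lab[k] != lab[n]:
                    cost += 1
        best = min(best, cost)
    return best


class TestSankoffOptimality:
    def test_all_clones_in_primary_no_paths(self):
        tree = build_tree(geno(["10", "01"]))
        occ = {"c0": {"P"}, "c1": {"P"}}
        history, _ = infer_history(tree, occ, "P")
        assert history.paths == []

    def test_single_metastatic_cherry(self):
        # one clone confined to the liver under a primary-labeled root:
        # exactly one migration, primary -> liver
        tree = build_tree(geno(["10", "01"]))
        occ = {"c0": {"lung"}, "c1": {"liver"}}
        history, labeling = infer_history(tree, occ, "lung")
        assert history.paths == [("lung", "liver")]
        assert labeling.n_migrations == 1

    def test_shared_clone_emits_intermetastatic_path(self):
        # the same clone detected in two metastatic sites: one extra
        # migration between them with no associated mutations
        tree = build_tree(geno(["100", "110", "111"]))
        occ = {"c0": {"P"}, "c1": {"GEJ"}, "c2": {"GEJ", "heart"}}
        history, labeling = infer_history(tree, occ, "P")
        assert ("GEJ", "heart") in history.paths
        annotated = map_mutations_to_paths(tree, labeling, occ)
        gej_heart = [p for p in annotated
                     if (p.source, p.destination) == ("GEJ", "heart")]
        assert gej_heart[0].n_mutations == 0

    def test_matches_brute_force_on_random_small_instances(self, rng):
        # random genotype trees with up to ~6 internal nodes and 4 sites
        sites = ["P", "A", "B", "C"]
        for trial in range(25):
            n = int(rng.integers(2, 7))
            L = n + 2
            state = np.zeros((n, L), dtype=int)
            # random nested/branching gain sets -> valid distinct genotypes
            for i in range(n):
                p = int(rng.integers(0, i + 1)) - 1
                if p >= 0:
                    state[i] = state[p]
                state[i, i] = 1
            g = GenotypeMatrix([f"c{i}" for i in range(n)],
                               [f"s{j}" for j in range(L)], state).dedup()
            tree = build_tree(g)
            occ = {c: set(rng.choice(sites, size=int(rng.integers(1, 3)),
                                     replace=False).tolist())
                   for c in g.clone_ids}
            labeling = sankoff_labeling(tree, occ, "P")
            assert labeling.n_migrations == \
                brute_force_min_migrations(tree, occ, "P"), (trial, occ)

    def test_clone_without_site_rejected(self):
        tree = build_tree(geno(["10", "01"]))
        with pytest.raises(ValueError, match="no tumor site"):
            infer_history(tree, {"c0": {"P"}, "c1": set()}, "P")


class TestMutationMapping:
    def test_driver_and_total_counts_on_migrating_branch(self):
        tree = build_tree(geno(["1110", "1111"]))
        occ = {"c0": {"P"}, "c1": {"M"}}
        _, labeling = infer_history(tree, occ, "P")
        drivers = {"s0": True, "s1": False, "s2": False, "s3": False}
        annotated = map_mutations_to_paths(tree, labeling, occ, drivers)
        path = annotated[0]
        # branch into c0 gains s0,s1,s2 but does not migrate; the P->M
        # branch gains only s3 (not a driver)
        assert (path.source, path.destination) == ("P", "M")
        assert path.n_mutations == 1 and path.n_drivers == 0

    def test_three_gains_one_driver_gives_rate_one_third(self):
        tree = ClonePhylogeny(["s0", "s1", "s2"])
        tree.add_node("c0", "germline", np.array([1, 1, 1]))
        occ = {"c0": {"M"}}
        _, labeling = infer_history(tree, occ, "P")
        annotated = map_mutations_to_paths(tree, labeling, occ, {"s0": True})
        assert annotated[0].n_mutations == 3
        assert annotated[0].n_drivers == 1
        assert annotated[0].driver_rate == pytest.approx(1 / 3)

    def test_zero_gain_migration_excluded_from_rate(self):
        p = AnnotatedPath("A", "B", 0, 0)
        assert p.driver_rate is None


class TestConsensusHistory:
    def test_support_percentages(self):
        h = MigrationHistory([("P", "A")])
        empty = MigrationHistory([])
        supports = path_supports([h] * 27 + [empty] * 3)
        assert supports[("P", "A")] == pytest.approx(90.0)

    def test_greedy_connectivity_rule(self):
        # pooled supports P->A 90%, A->B 50%, P->B 40% at threshold 50:
        # P->B is omitted because B is already reachable through A->B
        hists = []
        for r in range(10):
            paths = [("P", "A")] if r < 9 else []
            if r < 5:
                paths.append(("A", "B"))
            if 5 <= r < 9:
                paths.append(("P", "B"))
            hists.append(MigrationHistory(sorted(paths)))
        cons = consensus_history(hists, threshold=50.0, primary="P")
        assert cons.path_set() == {("P", "A"), ("A", "B")}
        assert cons.tentative == set()

    def test_subthreshold_connector_flagged_tentative(self):
        hists = [MigrationHistory([("P", "A")]) for _ in range(8)]
        hists += [MigrationHistory([("P", "A"), ("A", "B")]) for _ in range(2)]
        cons = consensus_history(hists, threshold=60.0, primary="P")
        assert ("A", "B") in cons.path_set()
        assert ("A", "B") in cons.tentative

    def test_identical_replicates_reproduce_common_history(self):
        h = MigrationHistory([("P", "A"), ("A", "B")])
        cons = consensus_history([h] * 30, threshold=60.0, primary="P")
        assert cons.path_set() == h.path_set()
        assert all(s == 100.0 for s in cons.support.values())

    def test_every_observed_site_reachable(self, rng):
        sites = ["P", "A", "B", "C"]
        hists = []
        for _ in range(20):
            paths = set()
            for dst in sites[1:]:
                src = str(rng.choice([s for s in sites if s != dst]))
                paths.add((src, dst))
            hists.append(MigrationHistory(sorted(paths)))
        cons = consensus_history(hists, threshold=60.0, primary="P")
        reach, frontier = {"P"}, True
        while frontier:
            frontier = False
            for s, d in cons.paths:
                if s in reach and d not in reach:
                    reach.add(d)
                    frontier = True
        assert {"A", "B", "C"} <= reach

    def test_solid_set_monotone_in_threshold(self):
        hists = [MigrationHistory([("P", "A")]) for _ in range(6)]
        hists += [MigrationHistory([("P", "A"), ("P", "B")]) for _ in range(4)]
        solid = {}
        for thr in (30.0, 50.0, 90.0):
            cons = consensus_history(hists, threshold=thr, primary="P")
            solid[thr] = cons.path_set() - cons.tentative
        assert solid[90.0] <= solid[50.0] <= solid[30.0]


class TestCompareDriverRates:
    def make_annotations(self, prim_rate, meta_rate, n=30):
        out = []
        for _ in range(n):
            out.append([AnnotatedPath("P", "A", 10, int(10 * prim_rate)),
                        AnnotatedPath("A", "B", 10, int(10 * meta_rate))])
        return out

    def test_identical_classes_give_t_zero_p_one(self):
        res = compare_driver_rates(self.make_annotations(0.2, 0.2), "P")
        assert res["t_driver_rate"] == 0.0
        assert res["p_driver_rate"] == 1.0

    def test_degenerate_zero_variance_reported_as_infinite_t(self):
        res = compare_driver_rates(self.make_annotations(0.1, 0.0), "P")
        assert math.isinf(res["t_driver_rate"])
        assert res["p_driver_rate"] == 0.0

    def test_matches_welch_formula_on_noisy_classes(self, rng):
        anns = []
        xs, ys = [], []
        for _ in range(30):
            kp = int(rng.integers(0, 5))
            km = int(rng.integers(0, 3))
            anns.append([AnnotatedPath("P", "A", 10, kp),
                         AnnotatedPath("B", "C", 10, km)])
            xs.append(kp)
            ys.append(km)
        res = compare_driver_rates(anns, "P")
        x, y = np.array(xs, float), np.array(ys, float)
        t_hand = (x.mean() - y.mean()) / np.sqrt(
            x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y))
        assert res["t_driver_count"] == pytest.approx(t_hand)

    def test_empty_class_reported_as_nan(self):
        anns = [[AnnotatedPath("P", "A", 5, 1)]]
        res = compare_driver_rates(anns, "P")
        assert math.isnan(res["metastatic_mean_driver_count"])
        assert math.isnan(res["t_driver_count"])
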