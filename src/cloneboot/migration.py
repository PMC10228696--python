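"""Metastatic cell-migration histories from clone phylogenies.

A migration history is inferred by minimum-migration (Sankoff) labeling of
the clone phylogeny with tumor sites: each node receives one site, the
root is fixed to the primary site, every site change along an edge costs
one migration, and each changed edge emits a directed source -> destination
path. Clones occupying several sites are expanded into co-located leaf
copies, so a clone shared between two sites can seed a migration with no
associated mutations.

Per-replicate histories are pooled into a consensus history: a path's
bootstrap support is the percentage of replicates containing it, paths at
or above the support threshold are solid, and lower-support paths are
added greedily (highest support first) only while some observed site is
still unreachable from the primary; those are flagged tentative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import MigrationHistory
from .trees import ClonePhylogeny

logger = logging.getLogger("cloneboot")

_INF = math.inf


@dataclass
class SiteLabeling:
    """Node -> tumor-site assignment over a clone phylogeny.

    Expanded leaf copies for multi-site clones are keyed ``"<node>@<site>"``.
    """

    labels: dict[str, str]
    primary: str
    n_migrations: int


@dataclass
class AnnotatedPath:
    """A migration path with the mutations gained on its emitting branch."""

    source: str
    destination: str
    n_mutations: int
    n_drivers: int

    @property
    def driver_rate(self) -> float | None:
        if self.n_mutations == 0:
            return None
        return self.n_drivers / self.n_mutations


def _expanded_children(tree: ClonePhylogeny, occupancy: dict[str, set[str]]
                       ) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Children map with multi-site tips expanded into leaf copies.

    A tip occupying one site stays a leaf fixed to that site, so mutations
    on its branch stay associated with any migration inferred there; a tip
    occupying k > 1 sites becomes free and gains k fixed leaf copies.
    Returns the children map and the leaf -> fixed-site map.
    """
    children = {n: list(tree.children[n]) for n in tree.nodes()}
    leaf_site: dict[str, str] = {}
    for tip in tree.tips():
        sites = occupancy.get(tip)
        if not sites:
            raise ValueError(f"clone {tip!r} occupies no tumor site")
        if len(sites) == 1:
            leaf_site[tip] = next(iter(sites))
        else:
            children[tip] = [f"{tip}@{s}" for s in sorted(sites)]
            for s in sorted(sites):
                copy = f"{tip}@{s}"
                children[copy] = []
                leaf_site[copy] = s
    return children, leaf_site


def sankoff_labeling(tree: ClonePhylogeny, occupancy: dict[str, set[str]],
                     primary: str) -> SiteLabeling:
    """Minimum-migration site labeling with the root fixed to the primary.

    Unit cost per site change; top-down ties prefer the parent's label
    (favouring fewer distinct sources), then site name order.
    """
    sites = sorted({primary} | {s for ss in occupancy.values() for s in ss})
    idx = {s: i for i, s in enumerate(sites)}
    children, leaf_site = _expanded_children(tree, occupancy)

    post: list[str] = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        post.append(n)
        stack.extend(children[n])
    post.reverse()

    # child contribution to state s is min over t of cost[child][t] + (s != t),
    # which simplifies to min(cost[child][s], min(cost[child]) + 1)
    cost: dict[str, np.ndarray] = {}
    for n in post:
        kids = children[n]
        if not kids:
            c = np.full(len(sites), _INF)
            c[idx[leaf_site[n]]] = 0.0
        else:
            c = np.zeros(len(sites))
            for k in kids:
                kc = cost[k]
                c += np.minimum(kc, kc.min() + 1.0)
        cost[n] = c

    labels: dict[str, str] = {}
    if primary not in idx:
        raise ValueError(f"primary site {primary!r} unknown")
    labels[tree.root] = primary
    order = [tree.root]
    stack = list(children[tree.root])
    while stack:
        n = stack.pop()
        order.append(n)
        stack.extend(children[n])
    parent_of: dict[str, str] = {}
    for n in order:
        for k in children[n]:
            parent_of[k] = n
    for n in order:
        if n == tree.root:
            continue
        p_lab = labels[parent_of[n]]
        kc = cost[n]
        scores = kc + (np.arange(len(sites)) != idx[p_lab])
        best = scores.min()
        if scores[idx[p_lab]] == best:
            labels[n] = p_lab
        else:
            labels[n] = sites[int(np.argmin(scores))]

    n_mig = sum(1 for k, p in parent_of.items() if labels[k] != labels[p])
    return SiteLabeling(labels, primary, n_mig)


def infer_history(tree: ClonePhylogeny, occupancy: dict[str, set[str]],
                  primary: str) -> tuple[MigrationHistory, SiteLabeling]:
    """Infer the minimum-migration history of a clone phylogeny.

    Returns the multiset of migration paths (one per label-changing edge,
    including edges to expanded multi-site leaf copies) and the labeling
    that produced them.
    """
    labeling = sankoff_labeling(tree, occupancy, primary)
    children, _ = _expanded_children(tree, occupancy)
    paths = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        for k in children[n]:
            if labeling.labels[k] != labeling.labels[n]:
                paths.append((labeling.labels[n], labeling.labels[k]))
            stack.append(k)
    return MigrationHistory(sorted(paths)), labeling


def map_mutations_to_paths(tree: ClonePhylogeny, labeling: SiteLabeling,
                           occupancy: dict[str, set[str]],
                           driver_flags: dict[str, bool] | None = None
                           ) -> list[AnnotatedPath]:
    """Attach branch mutation counts to the migration paths they emit.

    SNVs gained on a label-changing branch (parent absent -> child present,
    via the tree's ancestral reconstruction) are counted, with the driver
    subset taken from ``driver_flags`` (default: no drivers). Edges to
    expanded leaf copies gain nothing, so a shared-clone migration is
    annotated (0, 0) and excluded from rate computations.
    """
    driver_flags = driver_flags or {}
    drv = np.array([bool(driver_flags.get(s, False)) for s in tree.snv_ids])
    children, _ = _expanded_children(tree, occupancy)
    out = []
    stack = [tree.root]
    while stack:
        n = stack.pop()
        for k in children[n]:
            stack.append(k)
            if labeling.labels[k] == labeling.labels[n]:
                continue
            if k not in tree.parent:  # expanded leaf copy: no mutations
                n_mut, n_drv = 0, 0
            else:
                gains = tree.branch_gains(k)
                n_mut = int(gains.sum())
                n_drv = int((gains & drv).sum())
            out.append(AnnotatedPath(labeling.labels[n], labeling.labels[k],
                                     n_mut, n_drv))
    return sorted(out, key=lambda p: (p.source, p.destination, p.n_mutations))


def path_supports(histories: list[MigrationHistory]) -> dict[tuple[str, str], float]:
    """Bootstrap support (percent of replicates) of every observed path."""
    if not histories:
        raise ValueError("need at least one history")
    n = len(histories)
    return {path: 100.0 * sum(path in h.path_set() for h in histories) / n
            for path in {p for h in histories for p in h.path_set()}}


def consensus_history(histories: list[MigrationHistory], threshold: float,
                      primary: str) -> MigrationHistory:
    """Pool per-replicate histories into a supported consensus history.

    Support of a path is the percentage of replicates containing it. Paths
    with support >= threshold are solid; further paths are added in
    descending support only while an observed site remains unreachable
    from the primary, and are flagged tentative.
    """
    support = path_supports(histories)

    all_sites = {s for h in histories for s in h.sites()} | {primary}
    ranked = sorted(support, key=lambda p: (-support[p], p))
    chosen = [p for p in ranked if support[p] >= threshold]
    tentative: set[tuple[str, str]] = set()

    def reachable(paths: list[tuple[str, str]]) -> set[str]:
        seen = {primary}
        changed = True
        while changed:
            changed = False
            for src, dst in paths:
                if src in seen and dst not in seen:
                    seen.add(dst)
                    changed = True
        return seen

    while True:
        missing = all_sites - reachable(chosen)
        if not missing:
            break
        added = False
        for p in ranked:
            if p in chosen:
                continue
            if p[1] in missing:
                chosen.append(p)
                tentative.add(p)
                added = True
                break
        if not added:
            logger.warning("sites unreachable from %s in any replicate "
                           "history: %s", primary, sorted(missing))
            break

    chosen.sort(key=lambda p: (-support[p], p))
    return MigrationHistory(chosen, {p: support[p] for p in chosen}, tentative)


def compare_driver_rates(annotations: list[list[AnnotatedPath]],
                         primary: str) -> dict:
    """Compare driver mutation load between primary- and metastasis-sourced
    migration paths across bootstrap replicates.

    Per replicate, the mean driver count and mean driver rate (paths with
    zero mapped mutations excluded from the rate) are computed separately
    for paths whose source is the primary site and for all others; a
    two-sample t-test is run across replicates for each statistic.
    """
    def per_replicate(paths: list[AnnotatedPath], from_primary: bool):
        sel = [p for p in paths if (p.source == primary) == from_primary]
        counts = [p.n_drivers for p in sel]
        rates = [p.driver_rate for p in sel if p.driver_rate is not None]
        return (float(np.mean(counts)) if counts else math.nan,
                float(np.mean(rates)) if rates else math.nan)

    prim = np.array([per_replicate(a, True) for a in annotations])
    meta = np.array([per_replicate(a, False) for a in annotations])

    def ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if len(x) == 0 or len(y) == 0:
            return math.nan, math.nan
        tiny = 1e-18  # variance at float rounding scale counts as zero
        if np.var(x) < tiny and np.var(y) < tiny:
            if abs(np.mean(x) - np.mean(y)) < 1e-12:
                return 0.0, 1.0
            logger.warning("degenerate t-test: zero variance, unequal means")
            return math.inf if np.mean(x) > np.mean(y) else -math.inf, 0.0
        t, p = stats.ttest_ind(x, y, equal_var=False)
        return float(t), float(p)

    t_count, p_count = ttest(prim[:, 0], meta[:, 0])
    t_rate, p_rate = ttest(prim[:, 1], meta[:, 1])
    return {
        "primary_mean_driver_count": float(np.nanmean(prim[:, 0])) if not np.isnan(prim[:, 0]).all() else math.nan,
        "metastatic_mean_driver_count": float(np.nanmean(meta[:, 0])) if not np.isnan(meta[:, 0]).all() else math.nan,
        "primary_mean_driver_rate": float(np.nanmean(prim[:, 1])) if not np.isnan(prim[:, 1]).all() else math.nan,
        "metastatic_mean_driver_rate": float(np.nanmean(meta[:, 1])) if not np.isnan(meta[:, 1]).all() else math.nan,
        "t_driver_count": t_count,
        "p_driver_count": p_count,
        "t_driver_rate": t_rate,
        "p_driver_rate": p_rate,
    }
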