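"""Synthetic tumor-evolution datasets for testing every pipeline stage.

The generator emulates multi-tumor metastasis simulations: a random rooted
clone phylogeny (uniform attachment), SNVs distributed over branches with
at least one per branch (gain-only, so clone genotypes obey a perfect
phylogeny), tumor sites seeded by migrating clone lineages — one founding
lineage per metastatic site under monoclonal seeding, two or more under
polyclonal seeding — Dirichlet clone frequencies within each site, and
binomial read sampling at a negative-binomial (or uniform-range) depth.

One tumor sample is taken per site; the first site is the primary. The
expected VAF of an SNV in a sample is half the summed frequency of the
clones carrying it (times purity), which is exactly the model the
inference engine inverts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import FrequencyMatrix, GenotypeMatrix, MigrationHistory, ReadCountTable
from .trees import ClonePhylogeny, GERMLINE

logger = logging.getLogger("cloneboot")

PRIMARY_SITE = "P"


@dataclass
class SimulationTruth:
    """Ground truth of one simulated patient."""

    tree: ClonePhylogeny
    genotypes: GenotypeMatrix
    frequencies: FrequencyMatrix      # samples (= sites) x clones
    history: MigrationHistory
    occupancy: dict[str, set[str]]    # clone -> sites containing it
    seeding_mode: str
    driver_flags: dict[str, bool]
    primary: str = PRIMARY_SITE

    @property
    def site_ids(self) -> list[str]:
        return self.frequencies.sample_ids


def simulate_truth(n_clones: int, n_snvs: int, n_samples: int,
                   seeding_mode: str = "monoclonal", seed: int = 0,
                   driver_rate: float = 0.1,
                   driver_migration_enrichment: float = 3.0,
                   shared_clone_prob: float = 0.1,
                   polyclonal_max_founders: int = 3) -> SimulationTruth:
    """Simulate a clone phylogeny, site seeding history and frequencies.

    ``seeding_mode`` is ``"monoclonal"`` (one founding lineage per
    metastatic site) or ``"polyclonal"`` (2..polyclonal_max_founders).
    With probability ``shared_clone_prob`` a founding clone also remains
    in its source site, producing a migration with no associated
    mutations. Driver flags are Bernoulli per SNV, with the rate
    multiplied by ``driver_migration_enrichment`` on founding branches.
    """
    if seeding_mode not in ("monoclonal", "polyclonal"):
        raise ValueError(f"unknown seeding mode {seeding_mode!r}")
    if n_clones < 2:
        raise ValueError("need at least two clones")
    if n_samples < 2:
        raise ValueError("need a primary and at least one metastatic site")
    if n_snvs < n_clones:
        raise ValueError(
            f"need n_snvs >= n_clones ({n_clones}) so every branch gains "
            "at least one SNV and all genotypes are distinct")
    n_mets = n_samples - 1
    min_founders = n_mets if seeding_mode == "monoclonal" else 2 * n_mets
    if n_clones - 1 < min_founders:
        raise ValueError(
            f"{seeding_mode} seeding of {n_mets} metastases needs at least "
            f"{min_founders + 1} clones, got {n_clones}")

    rng = np.random.default_rng(seed)
    clone_ids = [f"T{i + 1}" for i in range(n_clones)]
    snv_ids = [f"s{j + 1}" for j in range(n_snvs)]

    # uniform-attachment rooted tree: clone i attaches below a random
    # earlier clone; clone 0 hangs off the germline
    parent_idx = [-1] + [int(rng.integers(0, i)) for i in range(1, n_clones)]

    # >= 1 SNV per branch, remainder multinomial
    extra = rng.multinomial(n_snvs - n_clones, np.full(n_clones, 1.0 / n_clones))
    per_branch = 1 + extra
    branch_snvs: list[list[int]] = []
    cursor = 0
    for b in range(n_clones):
        branch_snvs.append(list(range(cursor, cursor + per_branch[b])))
        cursor += per_branch[b]

    state = np.zeros((n_clones, n_snvs), dtype=np.int8)
    for i in range(n_clones):
        lineage = i
        while lineage != -1:
            state[i, branch_snvs[lineage]] = 1
            lineage = parent_idx[lineage]
    genotypes = GenotypeMatrix(clone_ids, snv_ids, state)

    tree = ClonePhylogeny(snv_ids)
    for i in range(n_clones):
        parent = GERMLINE if parent_idx[i] == -1 else clone_ids[parent_idx[i]]
        tree.add_node(clone_ids[i], parent, state[i])

    # seed metastatic sites with migrating founder lineages; two founders
    # of one site must not lie on one lineage (the deeper one's migration
    # source would equal its destination), so placement is retried with a
    # fresh shuffle when lineage conflicts exhaust the pool
    sites = [PRIMARY_SITE] + [f"M{k + 1}" for k in range(n_mets)]
    min_per_site = 1 if seeding_mode == "monoclonal" else 2

    def ancestors(c: int) -> set[int]:
        out = set()
        while parent_idx[c] != -1:
            c = parent_idx[c]
            out.add(c)
        return out

    founder_of: dict[int, str] = {}
    for _attempt in range(50):
        founder_of = {}
        available = list(range(1, n_clones))
        ok = True
        for m, site in enumerate(sites[1:]):
            reserve = min_per_site * (n_mets - m - 1)
            k = min_per_site if seeding_mode == "monoclonal" else int(
                rng.integers(2, polyclonal_max_founders + 1))
            k = max(min_per_site, min(k, len(available) - reserve))
            chosen: list[int] = []
            pool = list(available)
            rng.shuffle(pool)
            for c in pool:
                if len(chosen) == k:
                    break
                anc = ancestors(c)
                if any(x in anc or c in ancestors(x) for x in chosen):
                    continue
                chosen.append(c)
            if len(chosen) < min_per_site:
                ok = False
                break
            for c in chosen:
                founder_of[c] = site
                available.remove(c)
        if ok:
            break
    else:
        raise ValueError("could not place the requested founders on this "
                         "phylogeny; fewer sites or more clones are needed")

    shared = {c for c in founder_of if rng.random() < shared_clone_prob}
    # homes propagate down the tree (parents precede children by index),
    # overridden at founders
    home = {0: PRIMARY_SITE}
    paths = []
    for i in range(1, n_clones):
        home[i] = founder_of.get(i, home[parent_idx[i]])
    for c, site in founder_of.items():
        src = home[parent_idx[c]] if parent_idx[c] != -1 else PRIMARY_SITE
        paths.append((src, site))

    occupancy = {clone_ids[i]: {home[i]} for i in range(n_clones)}
    for c in shared:
        src = home[parent_idx[c]] if parent_idx[c] != -1 else PRIMARY_SITE
        if src != home[c]:
            occupancy[clone_ids[c]].add(src)

    freqs = np.zeros((n_samples, n_clones))
    for si, site in enumerate(sites):
        present = [i for i in range(n_clones) if site in occupancy[clone_ids[i]]]
        if not present:  # a site must contain its founder lineage
            raise RuntimeError(f"site {site} ended up empty")
        freqs[si, present] = rng.dirichlet(np.ones(len(present)))
    frequencies = FrequencyMatrix(sites, clone_ids, freqs)

    founder_branch_snvs = {j for c in founder_of for j in branch_snvs[c]}
    driver_flags = {}
    for j, s in enumerate(snv_ids):
        rate = driver_rate * (driver_migration_enrichment
                              if j in founder_branch_snvs else 1.0)
        driver_flags[s] = bool(rng.random() < min(rate, 1.0))

    return SimulationTruth(tree, genotypes, frequencies,
                           MigrationHistory(sorted(paths)), occupancy,
                           seeding_mode, driver_flags)


def expected_vafs(truth: SimulationTruth, purity: float = 1.0) -> np.ndarray:
    """Model-expected VAF per (sample, SNV): purity * f @ M / 2."""
    return 0.5 * purity * truth.frequencies.values @ truth.genotypes.state.astype(float)


def simulate_reads(truth: SimulationTruth, seed: int = 0,
                   depth_mean: float = 100.0, depth_dispersion: float = 5.0,
                   depth_range: tuple[int, int] | None = None,
                   purity: float = 1.0) -> ReadCountTable:
    """Sample read counts from the truth's expected VAFs.

    Per (sample, SNV) cell the total depth is negative binomial with the
    given mean and dispersion, or uniform over ``depth_range`` when that is
    provided; the variant count is binomial at the expected VAF.
    """
    rng = np.random.default_rng(seed)
    n_samples = len(truth.site_ids)
    n_snvs = truth.genotypes.n_snvs
    if depth_range is not None:
        lo, hi = depth_range
        depth = rng.integers(lo, hi + 1, size=(n_samples, n_snvs))
    else:
        p = depth_dispersion / (depth_dispersion + depth_mean)
        depth = rng.negative_binomial(depth_dispersion, p,
                                      size=(n_samples, n_snvs))
    vaf = expected_vafs(truth, purity)
    alt = rng.binomial(depth, vaf)
    return ReadCountTable(truth.site_ids, truth.genotypes.snv_ids,
                          depth - alt, alt)
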