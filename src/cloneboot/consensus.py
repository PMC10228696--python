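"""Consensus clones over bootstrap replicates.

Clones inferred from all bootstrap replicates are pooled and grouped:
group seeds are chosen greedily in descending order of exact-genotype
frequency (ties broken lexicographically by genotype string), and a clone
joins the first group whose seed is within the Hamming-distance cutoff.
Bootstrap support of a group is the percentage of replicates contributing
at least one member; a replicate is counted at most once per group.

A group's consensus genotype takes, per SNV, state 1 when strictly more
than the base-threshold proportion of members carry it, state 0 when
strictly more than the threshold lack it, and the ambiguous state
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AMBIGUOUS, GenotypeMatrix

logger = logging.getLogger("cloneboot")


@dataclass
class CloneGroup:
    """Near-identical bootstrap clone genotypes with their support."""

    seed: tuple[int, ...]
    members: list[tuple[int, ...]] = field(default_factory=list)
    replicate_of: list[int] = field(default_factory=list)
    support: float = 0.0

    def n_replicates_contributing(self) -> int:
        return len(set(self.replicate_of))


def group_clones(clones_per_replicate: list[GenotypeMatrix],
                 cutoff: int = 1) -> list[CloneGroup]:
    """Group (nearly) identical clone genotypes across replicates.

    ``clones_per_replicate[r]`` holds the clones inferred from bootstrap
    replicate ``r``; all matrices must share the SNV axis. Every bootstrap
    clone lands in exactly one group.
    """
    if not clones_per_replicate:
        raise ValueError("need at least one replicate")
    snv_ids = clones_per_replicate[0].snv_ids
    for g in clones_per_replicate:
        if g.snv_ids != snv_ids:
            raise ValueError("replicates disagree on the SNV axis")

    entries: list[tuple[tuple[int, ...], int]] = []
    freq: dict[tuple[int, ...], int] = {}
    for r, g in enumerate(clones_per_replicate):
        for row in g.row_tuples():
            entries.append((row, r))
            freq[row] = freq.get(row, 0) + 1

    # distinct genotypes in seed-priority order found their own group or
    # join the first (highest-priority) group whose seed is close enough
    priority = sorted(freq, key=lambda t: (-freq[t], t))
    groups: list[CloneGroup] = []
    group_of: dict[tuple[int, ...], int] = {}
    for row in priority:
        row_arr = np.asarray(row)
        target = None
        for gi, g in enumerate(groups):
            if int(np.sum(np.asarray(g.seed) != row_arr)) <= cutoff:
                target = gi
                break
        if target is None:
            target = len(groups)
            groups.append(CloneGroup(seed=row))
        group_of[row] = target

    for row, r in entries:
        g = groups[group_of[row]]
        g.members.append(row)
        g.replicate_of.append(r)

    n_rep = len(clones_per_replicate)
    for g in groups:
        g.support = 100.0 * g.n_replicates_contributing() / n_rep
    return groups


def consensus_sequence(group: CloneGroup, base_threshold: float = 0.90) -> np.ndarray:
    """Per-position consensus over a group's member genotypes.

    State 1 where the proportion of members carrying the SNV strictly
    exceeds ``base_threshold``; state 0 where the proportion lacking it
    strictly exceeds it; ambiguous otherwise.
    """
    if not group.members:
        raise ValueError("empty clone group")
    arr = np.asarray(group.members, dtype=float)
    prop1 = arr.mean(axis=0)
    out = np.full(arr.shape[1], AMBIGUOUS, dtype=np.int8)
    out[prop1 > base_threshold] = 1
    out[(1.0 - prop1) > base_threshold] = 0
    return out


def consensus_clones(clones_per_replicate: list[GenotypeMatrix],
                     cutoff: int = 1, base_threshold: float = 0.90
                     ) -> tuple[GenotypeMatrix, dict[str, float]]:
    """Group bootstrap clones and emit consensus genotypes with supports.

    Returns a genotype matrix (possibly containing ambiguous states) whose
    clones are ordered by descending support, and a clone-id -> support
    (percent) mapping.
    """
    groups = group_clones(clones_per_replicate, cutoff)
    order = sorted(range(len(groups)),
                   key=lambda i: (-groups[i].support, groups[i].seed))
    snv_ids = clones_per_replicate[0].snv_ids
    rows, ids, support = [], [], {}
    for rank, gi in enumerate(order):
        cid = f"CC{rank + 1}"
        rows.append(consensus_sequence(groups[gi], base_threshold))
        ids.append(cid)
        support[cid] = groups[gi].support
    return GenotypeMatrix(ids, snv_ids, np.vstack(rows)), support
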