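"""Bootstrap resampling of sequencing reads at each variant position.

Reads at a position form a two-class pool (with / without the variant).
Sampling ``n`` reads with replacement from that pool is exactly a binomial
draw with ``n`` trials and success probability ``alt / n``, so resampling
is implemented as one binomial variate per cell: total depth is conserved
exactly while the variant count fluctuates, and a variant can disappear
from a replicate altogether.

One bootstrap replicate resamples every (sample, SNV) cell independently
and bundles all tumor samples of the patient into a single pseudo-multi-
tumor dataset; a replicate set is a list of such datasets with seeds
derived deterministically from a master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import ReadCountTable

logger = logging.getLogger("cloneboot")


@dataclass
class ReplicateSet:
    """Ordered bootstrap replicates of one read-count table."""

    replicates: list[ReadCountTable]
    seeds: list[int]

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self):
        return iter(self.replicates)


def resample_position(ref: int, alt: int, rng: np.random.Generator) -> tuple[int, int]:
    """Resample the reads of one position with replacement.

    Returns ``(ref', alt')`` with ``ref' + alt' = ref + alt``. A
    zero-coverage position is returned unchanged with a warning.
    """
    total = ref + alt
    if total == 0:
        logger.warning("resampling a zero-coverage position; returning (0, 0)")
        return 0, 0
    new_alt = int(rng.binomial(total, alt / total))
    return total - new_alt, new_alt


def make_replicate(table: ReadCountTable, rng: np.random.Generator) -> ReadCountTable:
    """One pseudo-multi-tumor bootstrap replicate of ``table``.

    Every cell is resampled independently; per-cell totals are preserved
    exactly.
    """
    total = table.total
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, table.alt / np.maximum(total, 1), 0.0)
    new_alt = rng.binomial(total, p)
    return ReadCountTable(table.sample_ids, table.snv_ids,
                          total - new_alt, new_alt)


def replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def make_replicate_set(table: ReadCountTable, n: int, seed: int) -> ReplicateSet:
    """Generate ``n`` bootstrap replicates with reproducible seeds.

    Replicate ``r`` depends only on ``(seed, r)``, so individual replicates
    can be regenerated out of order.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    seeds = replicate_seeds(seed, n)
    reps = [make_replicate(table, np.random.default_rng(s)) for s in seeds]
    return ReplicateSet(reps, seeds)
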