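"""Core domain types shared by every pipeline stage.

The containers here are thin, validated wrappers around numpy arrays with
ordered identifier axes. Conventions used throughout the package:

* read-count and VAF arrays are oriented ``samples x SNVs``;
* clone genotype arrays are oriented ``clones x SNVs`` with states
  0 (absent), 1 (present) and :data:`AMBIGUOUS` (consensus-only);
* clone-frequency arrays are oriented ``samples x clones``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger("cloneboot")

#: Sentinel state for an ambiguous base in a consensus genotype.
AMBIGUOUS: int = -1


def _as_id_list(ids: Iterable) -> list[str]:
    out = [str(i) for i in ids]
    if len(set(out)) != len(out):
        dups = sorted({i for i in out if out.count(i) > 1})
        raise ValueError(f"duplicate identifiers: {dups}")
    return out


@dataclass
class ReadCountTable:
    """Per-(sample, SNV) reference and variant read counts.

    This is the substrate of bootstrap resampling: ``ref[i, j]`` and
    ``alt[i, j]`` are the numbers of reads without and with the variant at
    SNV ``j`` in sample ``i``.
    """

    sample_ids: list[str]
    snv_ids: list[str]
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_id_list(self.sample_ids)
        self.snv_ids = _as_id_list(self.snv_ids)
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        shape = (len(self.sample_ids), len(self.snv_ids))
        if self.ref.shape != shape or self.alt.shape != shape:
            raise ValueError(
                f"count arrays must be shaped {shape}; got ref {self.ref.shape},"
                f" alt {self.alt.shape}"
            )
        if (self.ref < 0).any() or (self.alt < 0).any():
            bad = np.argwhere((self.ref < 0) | (self.alt < 0))[0]
            raise ValueError(
                f"negative read count at sample {self.sample_ids[bad[0]]!r},"
                f" SNV {self.snv_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    @property
    def total(self) -> np.ndarray:
        """Per-cell total read depth (ref + alt)."""
        return self.ref + self.alt

    def vaf(self) -> "VAFMatrix":
        """Observed variant allele frequencies, alt / (ref + alt).

        Zero-coverage cells get VAF 0 with a logged warning: bootstrap
        resampling can legitimately empty a cell of reads.
        """
        tot = self.total
        zero = tot == 0
        if zero.any():
            logger.warning(
                "%d zero-coverage cells; their VAF is treated as 0", int(zero.sum())
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(zero, 0.0, self.alt / np.maximum(tot, 1))
        return VAFMatrix(self.sample_ids, self.snv_ids, v)

    def drop_uncovered_snvs(self) -> "ReadCountTable":
        """Drop SNVs whose total depth is zero in every sample (warned)."""
        keep = (self.total > 0).any(axis=0)
        if keep.all():
            return self
        dropped = [s for s, k in zip(self.snv_ids, keep) if not k]
        logger.warning("dropping %d SNVs with zero coverage everywhere: %s",
                       len(dropped), dropped)
        return ReadCountTable(
            self.sample_ids,
            [s for s, k in zip(self.snv_ids, keep) if k],
            self.ref[:, keep],
            self.alt[:, keep],
        )

    def subset_samples(self, samples: Sequence[str]) -> "ReadCountTable":
        idx = [self.sample_ids.index(s) for s in samples]
        return ReadCountTable(list(samples), self.snv_ids,
                              self.ref[idx], self.alt[idx])


@dataclass
class VAFMatrix:
    """Samples x SNVs matrix of variant allele frequencies.

    Model-expected VAFs under the diploid CNA-free model live in [0, 0.5];
    observed VAFs may exceed 0.5 and are accepted with a warning.
    """

    sample_ids: list[str]
    snv_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_id_list(self.sample_ids)
        self.snv_ids = _as_id_list(self.snv_ids)
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.sample_ids), len(self.snv_ids))
        if self.values.shape != shape:
            raise ValueError(f"VAF array must be shaped {shape}")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("VAFs must lie in [0, 1]")
        if (self.values > 0.5).any():
            logger.warning(
                "%d observed VAFs exceed 0.5 (expected only without CNAs)",
                int((self.values > 0.5).sum()),
            )


@dataclass
class GenotypeMatrix:
    """Binary clones x SNVs presence/absence matrix (M).

    ``state[i, j]`` is 1 when clone ``i`` carries SNV ``j``, else 0.
    The :data:`AMBIGUOUS` state appears only in consensus outputs.
    """

    clone_ids: list[str]
    snv_ids: list[str]
    state: np.ndarray

    def __post_init__(self) -> None:
        self.clone_ids = _as_id_list(self.clone_ids)
        self.snv_ids = _as_id_list(self.snv_ids)
        self.state = np.asarray(self.state, dtype=np.int8)
        shape = (len(self.clone_ids), len(self.snv_ids))
        if self.state.shape != shape:
            raise ValueError(f"genotype array must be shaped {shape}")
        ok = np.isin(self.state, (0, 1, AMBIGUOUS))
        if not ok.all():
            raise ValueError("genotype states must be 0, 1 or ambiguous")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_snvs(self) -> int:
        return len(self.snv_ids)

    @property
    def is_binary(self) -> bool:
        return not (self.state == AMBIGUOUS).any()

    def row(self, clone_id: str) -> np.ndarray:
        return self.state[self.clone_ids.index(clone_id)]

    def row_tuples(self) -> list[tuple[int, ...]]:
        return [tuple(int(x) for x in r) for r in self.state]

    def dedup(self) -> "GenotypeMatrix":
        """Remove duplicate genotype rows, keeping first occurrence."""
        seen: dict[tuple, int] = {}
        keep = []
        for i, row in enumerate(self.row_tuples()):
            if row not in seen:
                seen[row] = i
                keep.append(i)
        if len(keep) == self.n_clones:
            return self
        return GenotypeMatrix([self.clone_ids[i] for i in keep],
                              self.snv_ids, self.state[keep])


@dataclass
class FrequencyMatrix:
    """Samples x clones matrix of estimated clone frequencies (f).

    Per-sample sums may be below 1; the remainder is interpretable as
    normal-cell contamination.
    """

    sample_ids: list[str]
    clone_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _as_id_list(self.sample_ids)
        self.clone_ids = _as_id_list(self.clone_ids)
        self.values = np.asarray(self.values, dtype=float)
        shape = (len(self.sample_ids), len(self.clone_ids))
        if self.values.shape != shape:
            raise ValueError(f"frequency array must be shaped {shape}")
        if (self.values < -1e-12).any():
            raise ValueError("clone frequencies must be non-negative")
        self.values = np.clip(self.values, 0.0, None)
        sums = self.values.sum(axis=1)
        if (sums > 1.0 + 1e-6).any():
            raise ValueError(
                f"per-sample clone frequencies sum above 1: max {sums.max():.6f}"
            )


@dataclass
class MigrationHistory:
    """Multiset of directed site-to-site migration paths.

    ``support`` optionally maps a (source, destination) pair to a bootstrap
    support percentage in (0, 100]; ``tentative`` marks sub-threshold paths
    retained only to keep every site reachable from the primary.
    """

    paths: list[tuple[str, str]] = field(default_factory=list)
    support: dict[tuple[str, str], float] = field(default_factory=dict)
    tentative: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for src, dst in self.paths:
            if src == dst:
                raise ValueError(f"self-migration {src!r} -> {dst!r}")

    def path_set(self) -> set[tuple[str, str]]:
        return set(self.paths)

    def sites(self) -> set[str]:
        return {s for p in self.paths for s in p}

    def __len__(self) -> int:
        return len(self.paths)


@dataclass
class RunConfig:
    """Tunable thresholds of the bootstrap clone-inference workflow.

    Defaults follow the published analysis protocol: 30 bootstrap
    replicates, clone grouping allowing at most one base difference, a >90%
    consensus base threshold, <1% frequency pruning, >5% clone-frequency
    reporting for migration inference, and the quality filter requiring at
    least 50 reference and 2 mutant reads.
    """

    n_replicates: int = 30
    group_cutoff: int = 1
    base_threshold: float = 0.90
    prune_freq: float = 0.01
    report_freq: float = 0.05
    qc_min_ref: int = 50
    qc_min_alt: int = 2
    support_threshold_paths: float = 60.0
    hybrid_iter_cap: int = 10
    hybrid_min_separation: float = 0.1
    kmax: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_threshold", "prune_freq", "report_freq"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("group_cutoff", "qc_min_ref", "qc_min_alt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0.0 <= self.support_threshold_paths <= 100.0):
            raise ValueError("support_threshold_paths must be a percentage")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, rng_seed=int(seed))
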