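"""Accuracy metrics: genotype error, migration-path classification, and
support-versus-accuracy summaries.

Genotype error (GE) pairs each simulated clone with its most similar
inferred clone (an inferred clone may serve several simulated clones),
averages the mismatch count over ties, and divides by the sequence
length. An ambiguous inferred state counts as half a mismatch by default
(strict scoring charges a full mismatch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import AMBIGUOUS, GenotypeMatrix, MigrationHistory

logger = logging.getLogger("cloneboot")

DEFAULT_SUPPORT_BINS = (10.0, 50.0)


@dataclass
class GenotypeErrorReport:
    """Per-simulated-clone genotype errors and their dataset mean."""

    per_clone: dict[str, float]
    pairing: dict[str, list[str]]  # simulated -> tied nearest inferred

    @property
    def dataset_ge(self) -> float:
        return float(np.mean(list(self.per_clone.values())))


#: How an ambiguous inferred state is scored against a simulated state:
#: ``half`` charges 0.5 mismatch, ``strict`` a full mismatch, ``ignore``
#: drops ambiguous sites from the comparison (pairwise deletion, as
#: sequence-distance software treats an N).
AMBIGUITY_MODES = ("half", "strict", "ignore")


def _normalised_error(true_row: np.ndarray, inf_row: np.ndarray,
                      ambiguity: str) -> float:
    amb = inf_row == AMBIGUOUS
    hard = float(np.sum((true_row != inf_row) & ~amb))
    if ambiguity == "ignore":
        resolved = int((~amb).sum())
        return hard / resolved if resolved else 1.0
    cost = 0.5 if ambiguity == "half" else 1.0
    return (hard + cost * amb.sum()) / len(true_row)


def genotype_error(true: GenotypeMatrix, inferred: GenotypeMatrix,
                   ambiguity: str = "half") -> GenotypeErrorReport:
    """GE of each simulated clone against its nearest inferred clone(s).

    Both matrices must share the SNV axis. Ties are averaged. An empty
    inferred set scores GE = 1 for every simulated clone (with a warning).
    """
    if true.snv_ids != inferred.snv_ids:
        raise ValueError("SNV axes disagree")
    if ambiguity not in AMBIGUITY_MODES:
        raise ValueError(f"ambiguity must be one of {AMBIGUITY_MODES}")
    per_clone, pairing = {}, {}
    if inferred.n_clones == 0:
        logger.warning("no inferred clones; GE = 1 for all simulated clones")
        return GenotypeErrorReport({c: 1.0 for c in true.clone_ids},
                                   {c: [] for c in true.clone_ids})
    for i, cid in enumerate(true.clone_ids):
        d = np.array([_normalised_error(true.state[i], inferred.state[k], ambiguity)
                      for k in range(inferred.n_clones)])
        best = d.min()
        ties = np.flatnonzero(d == best)
        per_clone[cid] = float(d[ties].mean())
        pairing[cid] = [inferred.clone_ids[k] for k in ties]
    return GenotypeErrorReport(per_clone, pairing)


def nearest_true_ge(inferred: GenotypeMatrix, true: GenotypeMatrix,
                    ambiguity: str = "half") -> dict[str, float]:
    """GE of each *inferred* clone against its nearest simulated clone.

    This is the per-clone error that pairs with a clone's bootstrap
    support in support-accuracy summaries.
    """
    if true.snv_ids != inferred.snv_ids:
        raise ValueError("SNV axes disagree")
    if ambiguity not in AMBIGUITY_MODES:
        raise ValueError(f"ambiguity must be one of {AMBIGUITY_MODES}")
    out = {}
    for k, cid in enumerate(inferred.clone_ids):
        out[cid] = min(_normalised_error(true.state[i], inferred.state[k], ambiguity)
                       for i in range(true.n_clones))
    return out


def classify_paths(true: MigrationHistory, inferred: MigrationHistory) -> dict[str, int]:
    """TP / FP / FN counts on migration paths as presence sets.

    Multiplicity is collapsed: a path either is or is not in a history.
    """
    t, i = true.path_set(), inferred.path_set()
    return {"TP": len(i & t), "FP": len(i - t), "FN": len(t - i)}


def support_accuracy_table(per_clone_ge: dict[str, float],
                           support: dict[str, float],
                           bins: tuple[float, ...] = DEFAULT_SUPPORT_BINS) -> list[dict]:
    """Bin clones by bootstrap support and summarise their GE distribution.

    Default bins: support <= 10%, 10-50%, > 50%. Empty bins are reported
    with ``n = 0`` and no statistics.
    """
    edges = (0.0,) + tuple(bins) + (100.0,)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [cid for cid, s in support.items()
                   if (lo < s <= hi) and cid in per_clone_ge]
        ges = np.array([per_clone_ge[c] for c in members])
        row = {"support_low": lo, "support_high": hi, "n": len(members)}
        if len(members):
            row.update(median_ge=float(np.median(ges)),
                       q1_ge=float(np.quantile(ges, 0.25)),
                       q3_ge=float(np.quantile(ges, 0.75)))
        rows.append(row)
    return rows


def path_support_summary(classified: list[tuple[dict[str, float], set]]) -> dict:
    """Median support of true-positive and false-positive consensus paths.

    ``classified`` holds, per dataset, the consensus path->support map and
    the set of true paths. Supports are pooled across datasets.
    """
    tp, fp = [], []
    for support, true_paths in classified:
        for path, s in support.items():
            (tp if path in true_paths else fp).append(s)
    out = {"n_tp": len(tp), "n_fp": len(fp)}
    if tp:
        out["tp_median_support"] = float(np.median(tp))
    if fp:
        out["fp_median_support"] = float(np.median(fp))
    return out
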