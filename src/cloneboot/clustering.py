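"""Per-sample VAF clustering and candidate-clone construction.

SNVs of one tumor sample are clustered by a one-dimensional binomial
mixture over their observed read counts: component ``k`` has a success
probability (its VAF centre) and a mixing weight, fitted by EM, with the
component count chosen by BIC over ``1..k_max``. Clusters are ordered by
descending mean VAF into a root-to-tip chain; consecutive clusters are
related as ancestor-descendant when the descendant's cancer-cell fraction
(CCF = 2 x VAF) fits under the remaining capacity of its would-be parent,
and as siblings otherwise. A single cluster is labelled monoclonal.

Candidate clones accumulate all SNVs on the path from the root cluster to
a target cluster, so a chain of clusters yields nested genotypes and a
sibling split yields genotypes that share only the ancestral prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .datatypes import GenotypeMatrix

logger = logging.getLogger("cloneboot")

MONOCLONAL = "monoclonal"
ANCESTOR_DESCENDANT = "ancestor-descendant"
SIBLING = "sibling"

#: Slack on CCF comparisons when deciding cluster relationships.
CCF_TOL = 0.05


@dataclass
class VafCluster:
    snv_ids: list[str]
    mean_vaf: float

    @property
    def ccf(self) -> float:
        return min(2.0 * self.mean_vaf, 1.0)


@dataclass
class SnvClusterChain:
    """Root-first ordered clusters of one sample with their relationships.

    ``parent[i]`` is the index of cluster ``i``'s parent (-1 for the root);
    ``relationships[i]`` labels cluster ``i`` relative to cluster ``i - 1``.
    """

    sample_id: str
    clusters: list[VafCluster] = field(default_factory=list)
    parent: list[int] = field(default_factory=list)
    relationships: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)


def _fit_binomial_mixture(alt: np.ndarray, tot: np.ndarray, k: int,
                          max_iter: int = 200, tol: float = 1e-8):
    """EM fit of a k-component binomial mixture; returns (loglik, p, labels)."""
    n = len(alt)
    vaf = alt / tot
    # deterministic quantile initialisation
    qs = (np.arange(k) + 0.5) / k
    p = np.clip(np.quantile(vaf, qs), 1e-4, 1 - 1e-4)
    w = np.full(k, 1.0 / k)
    loglik = -np.inf
    for _ in range(max_iter):
        logpmf = binom.logpmf(alt[:, None], tot[:, None],
                              np.clip(p, 1e-6, 1 - 1e-6)[None, :])
        joint = np.log(np.maximum(w, 1e-300))[None, :] + logpmf
        m = joint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        new_loglik = float(lse.sum())
        resp = np.exp(joint - lse[:, None])
        w = resp.mean(axis=0)
        denom = resp.T @ tot
        p = np.where(denom > 0, (resp.T @ alt) / np.maximum(denom, 1e-12), p)
        if new_loglik - loglik < tol:
            loglik = new_loglik
            break
        loglik = new_loglik
    labels = np.argmax(resp, axis=1)
    return loglik, p, labels


def cluster_sample(sample_id: str, snv_ids: list[str], alt: np.ndarray,
                   ref: np.ndarray, k_max: int = 8) -> SnvClusterChain:
    """Cluster one sample's SNVs by VAF and order clusters into a chain.

    Only SNVs with at least one variant read participate. Returns an empty
    chain (with a warning) when no SNV carries the variant.
    """
    alt = np.asarray(alt, dtype=float)
    tot = np.asarray(ref, dtype=float) + alt
    mask = alt > 0
    if not mask.any():
        logger.warning("sample %s has no variant reads; empty cluster chain",
                       sample_id)
        return SnvClusterChain(sample_id)
    ids = [s for s, m in zip(snv_ids, mask) if m]
    a, t = alt[mask], tot[mask]
    n = len(ids)

    best = None
    for k in range(1, min(k_max, n) + 1):
        loglik, p, labels = _fit_binomial_mixture(a, t, k)
        bic = -2.0 * loglik + (2 * k - 1) * np.log(n)
        if best is None or bic < best[0]:
            best = (bic, p, labels)
    _, p, labels = best

    clusters = []
    for k in sorted(set(labels)):
        members = [ids[i] for i in np.flatnonzero(labels == k)]
        sel = labels == k
        mean_vaf = float(a[sel].sum() / t[sel].sum())
        clusters.append(VafCluster(sorted(members), mean_vaf))
    # root first: descending mean VAF, ties by smallest member SNV id
    clusters.sort(key=lambda c: (-c.mean_vaf, c.snv_ids[0]))

    chain = SnvClusterChain(sample_id, clusters)
    capacities = []
    for i, c in enumerate(clusters):
        if i == 0:
            chain.parent.append(-1)
            chain.relationships.append(MONOCLONAL if len(clusters) == 1 else "root")
            capacities.append(c.ccf)
            continue
        # walk up from the previous cluster to the first node whose
        # remaining CCF capacity accommodates this cluster (pigeonhole)
        node = i - 1
        while node != -1 and capacities[node] < c.ccf - CCF_TOL:
            node = chain.parent[node]
        parent = node if node != -1 else 0
        chain.parent.append(parent)
        chain.relationships.append(
            ANCESTOR_DESCENDANT if parent == i - 1 else SIBLING)
        capacities.append(c.ccf)
        capacities[parent] -= c.ccf
    return chain


def candidates_from_chain(chain: SnvClusterChain,
                          all_snv_ids: list[str]) -> GenotypeMatrix:
    """One candidate clone per cluster: the union of SNVs from root to it.

    SNVs absent from the sample (or the chain) are 0 in every candidate.
    """
    col = {s: j for j, s in enumerate(all_snv_ids)}
    rows, ids = [], []
    for i in range(len(chain)):
        carried: set[str] = set()
        node = i
        while node != -1:
            carried.update(chain.clusters[node].snv_ids)
            node = chain.parent[node]
        row = np.zeros(len(all_snv_ids), dtype=np.int8)
        for s in carried:
            row[col[s]] = 1
        rows.append(row)
        ids.append(f"{chain.sample_id}.c{i}")
    if not rows:
        return GenotypeMatrix([], all_snv_ids,
                              np.zeros((0, len(all_snv_ids)), dtype=np.int8))
    return GenotypeMatrix(ids, all_snv_ids, np.vstack(rows))
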