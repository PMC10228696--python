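"""Clone deconvolution engine: candidate pooling, tree-guided search for
missing ancestral and hybrid clones, and constrained clone-frequency
estimation.

The central model relation is, per tumor sample, ``(1/2) f M = V``: with a
binary clones-x-SNVs genotype matrix ``M`` and clone frequencies ``f``, the
expected variant allele frequency of each SNV in a diploid CNA-free genome
is half the summed frequency of the clones carrying it. Frequencies are
estimated per sample by nonnegative least squares with the per-sample sum
bounded by 1 (the remainder is normal-cell contamination).

The engine iterates: build a clone tree, add parsimony ancestors, estimate
frequencies, prune clones below the frequency threshold, and decompose
potential hybrid genotypes by splitting co-carried SNV groups on their
observed-VAF residuals, until the clone set stops changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.cluster import KMeans

from .clustering import candidates_from_chain, cluster_sample
from .datatypes import (FrequencyMatrix, GenotypeMatrix, ReadCountTable,
                        RunConfig, VAFMatrix)
from .trees import ClonePhylogeny, build_tree, containment_tree

logger = logging.getLogger("cloneboot")


@dataclass
class ClonePrediction:
    """Final output of the engine: genotypes, frequencies and a tree."""

    genotypes: GenotypeMatrix
    frequencies: FrequencyMatrix
    tree: ClonePhylogeny
    provenance: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# candidate pooling and quality filtering
# ---------------------------------------------------------------------------

def qc_snv_mask(counts: ReadCountTable, qc_min_ref: int, qc_min_alt: int) -> np.ndarray:
    """SNVs usable for quality assessment: enough reference and mutant
    reads in at least one sample."""
    ok = (counts.ref >= qc_min_ref) & (counts.alt >= qc_min_alt)
    return ok.any(axis=0)


def pool_and_filter(candidates: list[GenotypeMatrix], counts: ReadCountTable,
                    config: RunConfig) -> GenotypeMatrix:
    """Pool per-sample candidate clones, deduplicate and drop spurious ones.

    A candidate is considered spurious when no quality-passing SNV is
    unique to it *and* its genotype is not an ancestral prefix (subset) of
    another candidate; prefix candidates legitimately share every SNV with
    their descendants. If everything is filtered, the single clone carrying
    all SNVs is returned as a fallback.
    """
    rows, ids = [], []
    for cand in candidates:
        if cand.snv_ids != counts.snv_ids:
            raise ValueError("candidate SNV axis disagrees with counts")
        for cid, row in zip(cand.clone_ids, cand.state):
            if row.any():
                rows.append(row)
                ids.append(cid)
    if not rows:
        raise ValueError("no candidate clones to pool")
    pooled = GenotypeMatrix(ids, counts.snv_ids, np.vstack(rows)).dedup()

    qc = qc_snv_mask(counts, config.qc_min_ref, config.qc_min_alt)
    state = pooled.state
    sets = [frozenset(np.flatnonzero(r)) for r in state]
    keep = []
    for i in range(pooled.n_clones):
        others = state[np.arange(pooled.n_clones) != i]
        unique = (state[i] == 1) & qc
        if len(others):
            unique &= ~(others == 1).any(axis=0)
        is_prefix = any(sets[i] < sets[j] for j in range(len(sets)) if j != i)
        if unique.any() or is_prefix or pooled.n_clones == 1:
            keep.append(i)
        else:
            logger.info("dropping candidate %s: no unique QC-passing SNV",
                        pooled.clone_ids[i])
    if not keep:
        logger.warning("all candidates filtered; falling back to a single "
                       "clone carrying every SNV")
        return GenotypeMatrix(["fallback"], counts.snv_ids,
                              np.ones((1, counts.n_snvs), dtype=np.int8))
    return GenotypeMatrix([pooled.clone_ids[i] for i in keep],
                          counts.snv_ids, state[keep])


# ---------------------------------------------------------------------------
# ancestral clones
# ---------------------------------------------------------------------------

def _fresh_ids(prefix: str, existing: list[str], n: int) -> list[str]:
    out, k = [], 1
    taken = set(existing)
    while len(out) < n:
        cid = f"{prefix}{k}"
        if cid not in taken:
            out.append(cid)
            taken.add(cid)
        k += 1
    return out


def infer_ancestral_clones(tree: ClonePhylogeny, M: GenotypeMatrix) -> GenotypeMatrix:
    """Append parsimony-reconstructed internal-node genotypes missing from M.

    Internal genotypes come from the Fitch pass done at tree construction
    (ties toward absence, i.e. later gain); the all-zero germline genotype
    is never added as a clone.
    """
    have = set(M.row_tuples())
    new_rows = []
    for node in tree.nodes():
        if not tree.children[node] or node not in tree.genotypes:
            continue
        g = tree.genotypes[node]
        t = tuple(int(x) for x in g)
        if any(t) and t not in have:
            have.add(t)
            new_rows.append(np.asarray(g, dtype=np.int8))
    if not new_rows:
        return M
    ids = _fresh_ids("anc", M.clone_ids, len(new_rows))
    return GenotypeMatrix(M.clone_ids + ids, M.snv_ids,
                          np.vstack([M.state, np.vstack(new_rows)]))


# ---------------------------------------------------------------------------
# frequency estimation (Eq. "half f M = V")
# ---------------------------------------------------------------------------

def _bounded_nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A x - b|| s.t. x >= 0 and sum(x) <= 1.

    Plain NNLS is used first; only when its solution violates the sum bound
    is the bound enforced through a slack variable and a heavy penalty row
    (sum(x) + s = 1, s >= 0).
    """
    x, _ = nnls(A, b)
    if x.sum() <= 1.0 + 1e-9:
        return x
    lam = 1e4 * max(1.0, float(np.abs(b).max()))
    n = A.shape[1]
    A_aug = np.zeros((A.shape[0] + 1, n + 1))
    A_aug[:-1, :n] = A
    A_aug[-1, :] = lam
    b_aug = np.concatenate([b, [lam]])
    x, _ = nnls(A_aug, b_aug)
    x = x[:n]
    total = x.sum()
    if total > 1.0:
        x = x / total
    return x


def estimate_frequencies(M: GenotypeMatrix, V: VAFMatrix) -> FrequencyMatrix:
    """Per-sample bounded nonnegative least squares clone frequencies."""
    if not M.is_binary:
        raise ValueError("frequency estimation requires binary genotypes")
    if V.snv_ids != M.snv_ids:
        raise ValueError("VAF and genotype SNV axes disagree")
    A = 0.5 * M.state.T.astype(float)
    if np.linalg.matrix_rank(A) < M.n_clones:
        logger.warning("genotype matrix is rank deficient; frequency "
                       "estimates are a least-norm choice among minimisers")
    f = np.vstack([_bounded_nnls(A, V.values[i]) for i in range(len(V.sample_ids))])
    return FrequencyMatrix(V.sample_ids, M.clone_ids, f)


def eq1_residual(M: GenotypeMatrix, f: FrequencyMatrix, V: VAFMatrix) -> float:
    """Frobenius norm of (1/2) f M - V (the model-fit residual)."""
    pred = 0.5 * f.values @ M.state.astype(float)
    return float(np.linalg.norm(pred - V.values))


def prune_low_frequency(M: GenotypeMatrix, f: FrequencyMatrix, V: VAFMatrix,
                        threshold: float) -> tuple[GenotypeMatrix, FrequencyMatrix]:
    """Zero frequencies strictly below ``threshold``; drop clones absent
    everywhere; re-estimate on the reduced clone set.

    A clone at exactly the threshold is retained. If pruning would remove
    every clone, the single highest-frequency clone is kept with a warning.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    vals = np.where(f.values < threshold, 0.0, f.values)
    present = (vals > 0).any(axis=0)
    if not present.any():
        best = int(np.argmax(f.values.max(axis=0)))
        logger.warning("pruning removed every clone; keeping %s",
                       M.clone_ids[best])
        present[best] = True
    if present.all():
        return M, f
    M2 = GenotypeMatrix([c for c, p in zip(M.clone_ids, present) if p],
                        M.snv_ids, M.state[present])
    return M2, estimate_frequencies(M2, V)


# ---------------------------------------------------------------------------
# hybrid decomposition
# ---------------------------------------------------------------------------

def decompose_hybrids(M: GenotypeMatrix, V: VAFMatrix, f: FrequencyMatrix,
                      prune_threshold: float,
                      min_separation: float = 0.1) -> GenotypeMatrix:
    """Split co-carried SNV groups whose observed VAFs disagree.

    SNVs sharing a carrying-clone set have identical expected VAFs in every
    sample; their observed-VAF residual profiles are split by 2-means, and
    for every carrying clone the two half-genotypes (group A only, group B
    only) are offered as alternate candidates. Alternates that attract at
    least the prune-threshold frequency in some sample are retained.

    A split is attempted only when the two residual centroids are at least
    ``min_separation`` apart (Euclidean over samples): read-sampling noise
    alone produces VAF scatter on the order of sqrt(p(1-p)/depth) per
    sample, and splitting inside that scatter only manufactures spurious
    clones.
    """
    state = M.state
    expected = 0.5 * f.values @ state.astype(float)
    resid = V.values - expected

    patterns: dict[tuple, list[int]] = {}
    for j in range(M.n_snvs):
        pat = tuple(state[:, j])
        if any(pat):
            patterns.setdefault(pat, []).append(j)

    new_rows: list[np.ndarray] = []
    have = set(M.row_tuples())
    for pat, snvs in patterns.items():
        if len(snvs) < 2:
            continue
        profiles = resid[:, snvs].T  # one residual profile per SNV
        if np.ptp(profiles, axis=0).max() < 1e-9:
            continue  # observed VAFs already agree with the model
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(profiles)
        lab = km.labels_
        if len(set(lab)) < 2:
            continue
        sep = float(np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1]))
        if sep < min_separation:
            continue
        group_a = [snvs[i] for i in np.flatnonzero(lab == 0)]
        group_b = [snvs[i] for i in np.flatnonzero(lab == 1)]
        for c in np.flatnonzero(np.asarray(pat)):
            for drop in (group_a, group_b):
                row = state[c].copy()
                row[drop] = 0
                t = tuple(int(x) for x in row)
                if any(t) and t not in have:
                    have.add(t)
                    new_rows.append(row)
    if not new_rows:
        return M

    ids = _fresh_ids("hyb", M.clone_ids, len(new_rows))
    M_aug = GenotypeMatrix(M.clone_ids + ids, M.snv_ids,
                           np.vstack([M.state, np.vstack(new_rows)]))
    f_aug = estimate_frequencies(M_aug, V)
    n_orig = M.n_clones
    appreciable = (f_aug.values[:, n_orig:] >= prune_threshold).any(axis=0)
    keep = np.concatenate([np.ones(n_orig, dtype=bool), appreciable])
    if keep.all():
        return M_aug
    return GenotypeMatrix([c for c, k in zip(M_aug.clone_ids, keep) if k],
                          M.snv_ids, M_aug.state[keep])


# ---------------------------------------------------------------------------
# finalisation
# ---------------------------------------------------------------------------

def finalize(M: GenotypeMatrix, f: FrequencyMatrix, V: VAFMatrix,
             provenance: dict[str, str] | None = None,
             prune_threshold: float | None = None) -> ClonePrediction:
    """Prune, assign leftover SNVs by VAF similarity, and emit the final
    prediction.

    Sub-threshold clones are pruned first so that every surviving clone
    carries at least the reporting-grade frequency somewhere. Then an SNV
    carried by no clone is attached to the clone (and, to keep the
    gain-only tree consistent, its tree descendants) whose carrier-set
    expected-VAF profile is nearest in least squares to the SNV's observed
    VAFs; ties go to the clone with the higher mean frequency. Clones are
    then renamed C1..Cn in canonical genotype order and the tree rebuilt.
    """
    if prune_threshold is not None:
        M, f = prune_low_frequency(M, f, V, prune_threshold)
    state = M.state.copy()
    unassigned = np.flatnonzero(~(state == 1).any(axis=0))
    if unassigned.size:
        # genotype-containment ancestry: descendants of a clone are the
        # clones whose mutation sets strictly contain it
        nest = containment_tree(M)
        desc = {c: [M.clone_ids.index(d) for d in nest.descendants(cid)]
                for c, cid in enumerate(M.clone_ids)}
        mean_freq = f.values.mean(axis=0)
        for j in unassigned:
            obs = V.values[:, j]
            best_c, best_err = None, None
            for c in range(M.n_clones):
                carriers = [c] + desc[c]
                exp = 0.5 * f.values[:, carriers].sum(axis=1)
                err = float(np.sum((obs - exp) ** 2))
                if (best_err is None or err < best_err - 1e-12 or
                        (abs(err - best_err) <= 1e-12 and
                         mean_freq[c] > mean_freq[best_c])):
                    best_c, best_err = c, err
            state[best_c, j] = 1
            for d in desc[best_c]:
                state[d, j] = 1

    final = GenotypeMatrix(M.clone_ids, M.snv_ids, state).dedup()
    order = sorted(range(final.n_clones), key=lambda i: tuple(final.state[i]))
    prov_in = provenance or {}
    names = [f"C{k + 1}" for k in range(final.n_clones)]
    prov = {names[k]: prov_in.get(final.clone_ids[order[k]], "cluster-derived")
            for k in range(final.n_clones)}
    final = GenotypeMatrix(names, final.snv_ids, final.state[order])
    freqs = estimate_frequencies(final, V)
    tree = build_tree(final) if final.n_clones >= 2 else _single_clone_tree(final)
    return ClonePrediction(final, freqs, tree, prov)


def _single_clone_tree(M: GenotypeMatrix) -> ClonePhylogeny:
    tree = ClonePhylogeny(M.snv_ids)
    tree.add_node(M.clone_ids[0], tree.root, M.state[0])
    return tree


# ---------------------------------------------------------------------------
# full engine
# ---------------------------------------------------------------------------

def deconvolve_clones(counts: ReadCountTable,
                         config: RunConfig | None = None) -> ClonePrediction:
    """Run the complete clone-deconvolution engine on one dataset.

    Stages: per-sample VAF clustering -> candidate clones -> pooling and
    quality filtering -> iterated {tree, ancestral search, frequency
    estimation, pruning, hybrid decomposition} to a fixpoint (capped) ->
    final SNV assignment.
    """
    config = config or RunConfig()
    counts = counts.drop_uncovered_snvs()
    V = counts.vaf()

    candidates = []
    for i, s in enumerate(counts.sample_ids):
        chain = cluster_sample(s, counts.snv_ids, counts.alt[i], counts.ref[i],
                               k_max=config.kmax)
        candidates.append(candidates_from_chain(chain, counts.snv_ids))
    M = pool_and_filter(candidates, counts, config)
    provenance = {cid: "cluster-derived" for cid in M.clone_ids}

    for _ in range(config.hybrid_iter_cap):
        before = set(M.row_tuples())
        if M.n_clones >= 2:
            tree = build_tree(M)
            M = infer_ancestral_clones(tree, M)
        f = estimate_frequencies(M, V)
        M, f = prune_low_frequency(M, f, V, config.prune_freq)
        M = decompose_hybrids(M, V, f, config.prune_freq,
                              min_separation=config.hybrid_min_separation)
        for cid in M.clone_ids:
            if cid not in provenance:
                provenance[cid] = "ancestral" if cid.startswith("anc") else "hybrid"
        if set(M.row_tuples()) == before:
            break
    else:
        logger.warning("clone search did not reach a fixpoint within %d "
                       "iterations", config.hybrid_iter_cap)

    f = estimate_frequencies(M, V)
    return finalize(M, f, V, provenance, prune_threshold=config.prune_freq)
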