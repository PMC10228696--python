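"""Rooted clone phylogenies over binary SNV genotypes.

Trees are built by neighbor joining on pairwise Hamming distances between
clone genotype rows, with an all-absent germline genotype appended and used
as the root. Ancestral genotypes at internal nodes are reconstructed by
Fitch parsimony with the root constrained to the germline (all-zero) state
and ties resolved toward absence, which favours later gains.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .datatypes import GenotypeMatrix

logger = logging.getLogger("cloneboot")

GERMLINE = "germline"


class ClonePhylogeny:
    """A rooted tree whose root is the germline (all-absent) genotype.

    Clone genotypes sit at tips; internal-node genotypes are filled in by
    :meth:`reconstruct_ancestors`. Every edge carries the set of SNVs gained
    along it (parent 0 -> child 1); losses violate the gain-only output
    convention and are logged, not fatal.
    """

    def __init__(self, snv_ids: list[str]):
        self.snv_ids = list(snv_ids)
        self.root: str = GERMLINE
        self.parent: dict[str, str | None] = {GERMLINE: None}
        self.children: dict[str, list[str]] = {GERMLINE: []}
        self.genotypes: dict[str, np.ndarray] = {
            GERMLINE: np.zeros(len(snv_ids), dtype=np.int8)
        }

    # -- construction -----------------------------------------------------
    def add_node(self, node: str, parent: str, genotype: np.ndarray | None = None) -> None:
        if node in self.parent:
            raise ValueError(f"duplicate node {node!r}")
        self.parent[node] = parent
        self.children.setdefault(parent, []).append(node)
        self.children.setdefault(node, [])
        if genotype is not None:
            self.genotypes[node] = np.asarray(genotype, dtype=np.int8)

    # -- traversal --------------------------------------------------------
    def nodes(self) -> list[str]:
        """Preorder node list starting at the root."""
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children[n]))
        return out

    def postorder(self) -> list[str]:
        return list(reversed(self.nodes()))

    def edges(self) -> list[tuple[str, str]]:
        return [(self.parent[n], n) for n in self.nodes() if n != self.root]

    def tips(self) -> list[str]:
        return [n for n in self.nodes() if not self.children[n]]

    def descendants(self, node: str) -> list[str]:
        out, stack = [], list(self.children[node])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out

    # -- genotypes --------------------------------------------------------
    def reconstruct_ancestors(self) -> None:
        """Fitch parsimony over all SNV columns, vectorised via bit masks.

        Mask bit 1 encodes state 0, bit 2 encodes state 1. The root is fixed
        to all-zero; on a top-down tie the parent state is kept, and a free
        choice prefers absence.
        """
        L = len(self.snv_ids)
        masks: dict[str, np.ndarray] = {}
        for n in self.postorder():
            kids = self.children[n]
            if not kids:
                g = self.genotypes[n]
                masks[n] = np.where(g == 1, 2, 1).astype(np.uint8)
            else:
                inter = np.full(L, 3, dtype=np.uint8)
                union = np.zeros(L, dtype=np.uint8)
                for k in kids:
                    inter &= masks[k]
                    union |= masks[k]
                masks[n] = np.where(inter > 0, inter, union)
        # top-down assignment
        for n in self.nodes():
            if n == self.root:
                continue
            if not self.children[n]:
                continue  # tip genotype observed
            p_state = self.genotypes[self.parent[n]]
            m = masks[n]
            keep_parent = ((p_state == 0) & (m & 1 > 0)) | ((p_state == 1) & (m & 2 > 0))
            forced_one = (m == 2)
            self.genotypes[n] = np.where(
                keep_parent, p_state, np.where(forced_one, 1, 0)
            ).astype(np.int8)

    def branch_gains(self, node: str) -> np.ndarray:
        """Boolean mask of SNVs gained on the edge into ``node``."""
        p = self.parent[node]
        if p is None:
            return np.zeros(len(self.snv_ids), dtype=bool)
        gp, gn = self.genotypes[p], self.genotypes[node]
        losses = (gp == 1) & (gn == 0)
        if losses.any():
            lost = [self.snv_ids[i] for i in np.flatnonzero(losses)]
            logger.warning("SNVs lost on branch to %s (gain-only model): %s",
                           node, lost)
        return (gp == 0) & (gn == 1)

    def suppress_unary(self) -> None:
        """Collapse genotype-less internal nodes with a single child."""
        for n in list(self.nodes()):
            if n == self.root or n not in self.parent:
                continue
            kids = self.children[n]
            if len(kids) == 1 and n not in self.genotypes:
                p = self.parent[n]
                (k,) = kids
                self.children[p][self.children[p].index(n)] = k
                self.parent[k] = p
                del self.parent[n], self.children[n]

    # -- serialisation ----------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: str) -> str:
            length = ""
            p = self.parent[node]
            if p is not None and node in self.genotypes and p in self.genotypes:
                d = int(np.sum(self.genotypes[p] != self.genotypes[node]))
                length = f":{d}"
            kids = self.children[node]
            if not kids:
                return f"{node}{length}"
            inner = ",".join(fmt(k) for k in kids)
            return f"({inner}){node}{length}"

        return fmt(self.root) + ";"


def hamming_matrix(state: np.ndarray) -> np.ndarray:
    """Pairwise Hamming distances between genotype rows (float)."""
    x = state.astype(np.int16)
    return np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2).astype(float)


def build_tree(genotypes: GenotypeMatrix) -> ClonePhylogeny:
    """Neighbor joining on Hamming distances, rooted at the germline.

    The clone rows are put in a canonical (lexicographic genotype) order
    before NJ so the topology does not depend on input row order. Identical
    rows are rejected: they should have been removed by deduplication.
    """
    if not genotypes.is_binary:
        raise ValueError("tree building requires binary genotypes")
    order = sorted(range(genotypes.n_clones),
                   key=lambda i: tuple(genotypes.state[i]))
    ids = [genotypes.clone_ids[i] for i in order]
    state = genotypes.state[order]
    for (i, a), (j, b) in itertools.combinations(enumerate(ids), 2):
        if (state[i] == state[j]).all():
            raise ValueError(f"identical genotype rows: {a!r} and {b!r}")

    tree = ClonePhylogeny(genotypes.snv_ids)
    if len(ids) == 1:
        tree.add_node(ids[0], GERMLINE, state[0])
        return tree

    full = np.vstack([np.zeros((1, genotypes.n_snvs), dtype=np.int8), state])
    labels = [GERMLINE] + ids
    dm = DistanceMatrix(hamming_matrix(full), labels)
    unrooted = nj(dm)

    # orient the unrooted NJ tree away from the germline tip
    adj: dict[str, list[str]] = {}
    names: dict[int, str] = {}
    counter = itertools.count(1)

    def name_of(tn: TreeNode) -> str:
        key = id(tn)
        if key not in names:
            names[key] = tn.name if tn.name else f"an{next(counter)}"
        return names[key]

    for node in unrooted.traverse():
        for child in node.children:
            a, b = name_of(node), name_of(child)
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)

    geno = {ids[i]: state[i] for i in range(len(ids))}
    seen = {GERMLINE}
    stack = [(GERMLINE, nb) for nb in sorted(adj.get(GERMLINE, []))]
    while stack:
        parent, node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        tree.add_node(node, parent, geno.get(node))
        for nb in sorted(adj[node]):
            if nb not in seen:
                stack.append((node, nb))

    tree.suppress_unary()
    tree.reconstruct_ancestors()
    return tree


def containment_tree(genotypes: GenotypeMatrix) -> ClonePhylogeny:
    """Gain-only tree: each clone's parent is the largest genotype subset.

    Used by the simulator and for attaching clones whose genotypes are
    already nested; complements NJ, which places all clones at tips.
    """
    if not genotypes.is_binary:
        raise ValueError("containment tree requires binary genotypes")
    sets = [frozenset(np.flatnonzero(r)) for r in genotypes.state]
    order = sorted(range(len(sets)), key=lambda i: (len(sets[i]), genotypes.clone_ids[i]))
    tree = ClonePhylogeny(genotypes.snv_ids)
    placed: list[int] = []
    for i in order:
        parent = GERMLINE
        best = -1
        for j in placed:
            if sets[j] < sets[i] or sets[j] == sets[i]:
                if len(sets[j]) > best:
                    best = len(sets[j])
                    parent = genotypes.clone_ids[j]
        tree.add_node(genotypes.clone_ids[i], parent, genotypes.state[i])
        placed.append(i)
    return tree
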