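"""Ancestral sequence reconstruction on a fixed tree and assignment of
substitutions to branches.

Marginal maximum-likelihood reconstruction under JC or K80, via the standard
two-pass (pullback/pushdown) conditional-likelihood algorithm. Ties at equal
marginal posteriors are broken in lexicographic nucleotide order (A<C<G<T)
for determinism. Branch lengths of 0 are floored at 1e-9 in likelihood
computations to avoid degenerate transition matrices. Missing leaf states
(gap/N) are masked per site (likelihood 1 for every state), not deleted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import codon_model
from .genetic_code import BASES, is_transition
from .seqio import CodonAlignment, PhyloTree, ReferenceError_

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_MIN_BRANCH = 1e-9


def _k80_matrix(t: float, kappa: float) -> np.ndarray:
    """K80 transition-probability matrix at distance t (expected subs/site).

    kappa is the transition/transversion *rate* ratio; kappa = 1 gives JC.
    Rates are normalized so t is the expected number of substitutions.
    """
    t = max(t, _MIN_BRANCH)
    alpha = kappa / (kappa + 2.0)
    beta = 1.0 / (kappa + 2.0)
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.empty((4, 4))
    for i, bi in enumerate(BASES):
        for j, bj in enumerate(BASES):
            if i == j:
                P[i, j] = p_same
            elif is_transition(bi, bj):
                P[i, j] = p_ts
            else:
                P[i, j] = p_tv
    return P


def _leaf_partials(seq: str) -> np.ndarray:
    """(L, 4) indicator partials; gap/N/ambiguity rows are all ones (masked)."""
    L = len(seq)
    out = np.zeros((L, 4))
    for i, b in enumerate(seq):
        j = _BASE_INDEX.get(b)
        if j is None:
            out[i, :] = 1.0
        else:
            out[i, j] = 1.0
    return out


@dataclass
class AncestralReconstruction:
    """Inferred sequence and per-site posterior of the chosen state for each
    node; leaf sequences pass through unchanged."""

    sequences: dict[str, str]
    posteriors: dict[str, np.ndarray]
    model: str
    kappa: float
    internal_ids: list[str] = field(default_factory=list)

    def to_table(self):
        """Long-form (node, site, state, posterior) rows for TSV export.

        Sites are reported 1-based for human readability.
        """
        rows = []
        for node in self.internal_ids:
            seq = self.sequences[node]
            post = self.posteriors[node]
            for i, (state, p) in enumerate(zip(seq, post)):
                rows.append((node, i + 1, state, float(p)))
        return rows


@dataclass
class BranchSubstitutions:
    """Substitutions assigned to one parent->child branch, with the
    pathway-averaged nonsynonymous (ns) and synonymous (s) totals."""

    parent: str
    child: str
    events: list[tuple[int, str, str]]  # (0-based site, from, to)
    ns: float
    s: float

    @property
    def branch_id(self) -> str:
        return f"{self.parent}->{self.child}"


def estimate_kappa(alignment: CodonAlignment) -> float:
    """Empirical transition/transversion rate ratio from pairwise counts.

    With one transition partner and two transversion partners per base,
    equal rates give an expected ts:tv count ratio of 1:2, so
    kappa = 2 * (observed ts / observed tv). Falls back to 2.0 when no
    transversions are observed.
    """
    ts = tv = 0
    seqs = alignment.sequences
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            for a, b in zip(seqs[i], seqs[j]):
                if a == b or a not in _BASE_INDEX or b not in _BASE_INDEX:
                    continue
                if is_transition(a, b):
                    ts += 1
                else:
                    tv += 1
    if tv == 0:
        return 2.0
    return 2.0 * ts / tv


def reconstruct_marginal(
    alignment: CodonAlignment,
    tree: PhyloTree,
    model: str = "JC",
    kappa: float | None = None,
) -> AncestralReconstruction:
    """Per-site marginal ML states at every internal node.

    model is "JC" or "K80"; for K80 the rate ratio kappa is estimated from
    the alignment when not supplied.
    """
    model = model.upper()
    if model not in ("JC", "K80"):
        raise ValueError(f"unknown model {model!r}; use JC or K80")
    kap = 1.0 if model == "JC" else (kappa if kappa is not None else estimate_kappa(alignment))

    leaves = set(tree.leaf_labels)
    taxa = set(alignment.taxa)
    if leaves != taxa:
        raise ReferenceError_(
            f"tree/alignment taxon mismatch: only-in-tree {sorted(leaves - taxa)}, "
            f"only-in-alignment {sorted(taxa - leaves)}"
        )

    L = alignment.length
    pi = np.full(4, 0.25)
    down: dict[int, np.ndarray] = {}
    msg: dict[int, np.ndarray] = {}  # message from child edge to its parent
    Pmat: dict[int, np.ndarray] = {}

    for node in tree.postorder():
        key = id(node)
        if node.is_leaf():
            down[key] = _leaf_partials(alignment.sequence(node.taxon.label))
        else:
            d = np.ones((L, 4))
            for child in node.child_nodes():
                d *= msg[id(child)]
            # per-site rescale to avoid underflow; posteriors are scale-free
            scale = d.max(axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            down[key] = d / scale
        if node.parent_node is not None:
            P = _k80_matrix(node.edge.length, kap)
            Pmat[key] = P
            msg[key] = down[key] @ P.T

    up: dict[int, np.ndarray] = {}
    root = tree.tree.seed_node
    up[id(root)] = np.broadcast_to(pi, (L, 4)).copy()
    for node in tree.preorder():
        for child in node.child_nodes():
            outer = up[id(node)].copy()
            for sib in node.child_nodes():
                if sib is not child:
                    outer *= msg[id(sib)]
            u = outer @ Pmat[id(child)]
            scale = u.max(axis=1, keepdims=True)
            scale[scale == 0] = 1.0
            up[id(child)] = u / scale

    sequences: dict[str, str] = {}
    posteriors: dict[str, np.ndarray] = {}
    internal_ids: list[str] = []
    for node in tree.preorder():
        node_id = PhyloTree.node_id(node)
        if node.is_leaf():
            sequences[node_id] = alignment.sequence(node.taxon.label)
            posteriors[node_id] = np.ones(L)
            continue
        internal_ids.append(node_id)
        joint = up[id(node)] * down[id(node)]
        total = joint.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        post = joint / total
        best = post.argmax(axis=1)  # first max == lexicographic A<C<G<T
        sequences[node_id] = "".join(BASES[j] for j in best)
        posteriors[node_id] = post[np.arange(L), best]

    return AncestralReconstruction(
        sequences=sequences,
        posteriors=posteriors,
        model=model,
        kappa=kap,
        internal_ids=internal_ids,
    )


def map_branch_substitutions(
    recon: AncestralReconstruction,
    tree: PhyloTree,
    frame_offset: int = 0,
) -> list[BranchSubstitutions]:
    """Compare parent and child sequences codon-by-codon along every branch.

    Emits fractional ns/s via pathway averaging plus the raw per-site event
    list. Codons that are not unambiguous sense codons in both sequences
    (gap, N, stop) are skipped with a logged count.
    """
    results = []
    some_len = len(next(iter(recon.sequences.values())))
    if (some_len - frame_offset) % 3:
        raise ValueError("frame violation: (length - frame_offset) not divisible by 3")
    for parent_id, child_id, _length in tree.branches():
        pseq = recon.sequences[parent_id]
        cseq = recon.sequences[child_id]
        events = [
            (i, a, b) for i, (a, b) in enumerate(zip(pseq, cseq)) if a != b
        ]
        ns = s = 0.0
        skipped = 0
        for i in range(frame_offset, some_len - 2, 3):
            ca, cb = pseq[i : i + 3], cseq[i : i + 3]
            if ca == cb:
                continue
            if not (codon_model.codon_is_countable(ca) and codon_model.codon_is_countable(cb)):
                skipped += 1
                continue
            d = codon_model.pathway_differences(ca, cb)
            ns += d.Nd
            s += d.Sd
        if skipped:
            logger.info(
                "branch %s->%s: %d uncountable differing codons skipped",
                parent_id,
                child_id,
                skipped,
            )
        results.append(BranchSubstitutions(parent_id, child_id, events, ns, s))
    return results


# ---------------------------------------------------------------------------
# distances and neighbor joining (convenience tree builder)


def _pairwise_distance(a: str, b: str, method: str) -> float:
    """p, JC or K2P distance with pairwise deletion of gap/N sites."""
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _BASE_INDEX or y not in _BASE_INDEX:
            continue
        n += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    p = (ts + tv) / n
    if method == "p":
        return p
    if method == "JC":
        return codon_model.jukes_cantor_correct(p)
    if method == "K2P":
        P, Q = ts / n, tv / n
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if w1 <= 0 or w2 <= 0:
            raise codon_model.SaturationError("K2P distance undefined (saturated)")
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    raise ValueError(f"unknown distance {method!r}")


def distance_matrix(alignment: CodonAlignment, method: str = "p") -> np.ndarray:
    n = len(alignment.taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _pairwise_distance(
                alignment.sequences[i], alignment.sequences[j], method
            )
    return D


def nj_tree(alignment: CodonAlignment, distance: str = "p") -> PhyloTree:
    """Neighbor-joining tree from pairwise distances.

    Deterministic given input order: ties in the Q criterion are broken by
    the lexicographically smallest joined pair. Negative branch-length
    estimates are clipped to 0. The unrooted result is returned with a
    trifurcating (or, for 2 remaining nodes, bifurcating) root.
    """
    if len(alignment.taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = distance_matrix(alignment, distance)
    taxon_ns = dendropy.TaxonNamespace(alignment.taxa)
    nodes: list[dendropy.Node] = []
    for t in alignment.taxa:
        node = dendropy.Node(taxon=taxon_ns.get_taxon(t))
        nodes.append(node)
    names = list(alignment.taxa)
    D = D.copy()

    while len(nodes) > 3:
        m = len(nodes)
        totals = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - totals[i] - totals[j]
                key = (q, min(names[i], names[j]), max(names[i], names[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = max(0.0, 0.5 * D[i, j] + (totals[i] - totals[j]) / (2 * (m - 2)))
        vj = max(0.0, D[i, j] - vi)
        parent = dendropy.Node()
        ni, nj_ = nodes[i], nodes[j]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = vi
        nj_.edge.length = vj
        dnew = np.array(
            [0.5 * (D[i, k] + D[j, k] - D[i, j]) for k in range(m) if k not in (i, j)]
        )
        keep = [k for k in range(m) if k not in (i, j)]
        D = D[np.ix_(keep, keep)]
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = np.maximum(dnew, 0.0)
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    root = dendropy.Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        lens = [
            max(0.0, 0.5 * (d01 + d02 - d12)),
            max(0.0, 0.5 * (d01 + d12 - d02)),
            max(0.0, 0.5 * (d02 + d12 - d01)),
        ]
    else:  # 2 nodes: split the remaining distance
        lens = [D[0, 1] / 2.0, D[0, 1] / 2.0]
    for node, ln in zip(nodes, lens):
        root.add_child(node)
        node.edge.length = ln
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    tree.is_rooted = True
    return PhyloTree(tree)
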