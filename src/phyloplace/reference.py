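"""Reference tree and alignment handling, and the likelihood cache engine.

The reference phylogeny is an unrooted bifurcating tree with fixed branch
lengths.  For traversal it is stored rooted at the internal node adjacent to
the lexicographically smallest leaf (a deterministic anchor), with children
ordered by the smallest leaf label in their subtree, so edge numbering is
reproducible across runs and survives serialization.  Likelihood semantics
remain unrooted: every reported number is invariant to the traversal root.

Edges are numbered 0..2n-4 in preorder; edge ``e`` is the branch above
preorder node ``e + 1``.  Two traversals (postorder, then preorder)
precompute three conditional likelihood vectors per edge — distal, proximal
and center-of-edge — after which every query placement is a three-taxon
tree computation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from scipy.optimize import minimize_scalar

from .models import AA_ORDER, NT_ORDER, SubstModel

__all__ = [
    "ReferenceTree",
    "ReferenceAlignment",
    "EdgeCache",
    "read_reference",
    "parse_newick",
    "compute_caches",
    "tree_loglike",
    "reestimate_branch_lengths",
    "attachment_loglike",
    "attachment_loglike_grid",
]

_NT_AMBIG = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", ".": "ACGT", "?": "ACGT", "X": "ACGT",
}
_AA_AMBIG = {aa: aa for aa in AA_ORDER}
_AA_AMBIG.update({
    "B": "ND", "Z": "QE", "J": "IL", "U": "C", "O": "K",
    "X": AA_ORDER, "-": AA_ORDER, ".": AA_ORDER, "?": AA_ORDER, "*": AA_ORDER,
})
GAP_CHARS = frozenset("-.?")


class ReferenceTree:
    """Edge-numbered unrooted bifurcating phylogeny with branch lengths.

    Array layout: nodes 0..2n-3 in preorder with node 0 the traversal root
    (degree 3); ``parent[v]`` / ``children[v]`` give the rooted structure;
    edge ``e`` corresponds to node ``e + 1`` and has length ``lengths[e]``.
    """

    def __init__(self, parent, children, lengths, leaf_name, node_label=None):
        self.parent = np.asarray(parent, dtype=int)
        self.children = children
        self.lengths = np.asarray(lengths, dtype=float)
        self.leaf_name = dict(leaf_name)          # node -> taxon label
        self.node_label = dict(node_label or {})  # node -> internal label
        self.n_nodes = len(self.parent)
        self._dist = None
        self._leafsets = None

    # -- basic structure ---------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.leaf_name)

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    @property
    def leaf_names(self):
        return sorted(self.leaf_name.values())

    def is_leaf(self, node: int) -> bool:
        return len(self.children[node]) == 0

    def edge_child(self, edge: int) -> int:
        """The distal (away from root) node of an edge."""
        if not 0 <= edge < self.n_edges:
            raise KeyError(f"unknown edge id {edge}")
        return edge + 1

    def postorder(self):
        order = []
        stack = [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def leafset(self, edge: int) -> frozenset:
        """Leaf labels on the distal side of an edge."""
        if self._leafsets is None:
            sets = [None] * self.n_nodes
            for v in self.postorder():
                if self.is_leaf(v):
                    sets[v] = frozenset([self.leaf_name[v]])
                else:
                    acc = frozenset()
                    for c in self.children[v]:
                        acc |= sets[c]
                    sets[v] = acc
            self._leafsets = sets
        return self._leafsets[self.edge_child(edge)]

    # -- construction ------------------------------------------------------
    @classmethod
    def from_adjacency(cls, adj, labels, internal_labels=None):
        """Build from an undirected adjacency map {node: [(nbr, length)]}.

        Suppresses degree-2 nodes, resolves polytomies with zero-length
        edges (warning), anchors the root at the neighbor of the
        lexicographically smallest leaf, and orders children by the
        smallest leaf label in their subtree.
        """
        adj = {k: list(v) for k, v in adj.items()}
        internal_labels = dict(internal_labels or {})

        def _drop(u, v):
            adj[u] = [(w, t) for w, t in adj[u] if w != v]

        # suppress degree-2 nodes (e.g. a rooted input's root)
        changed = True
        while changed:
            changed = False
            for v in list(adj):
                if v not in labels and len(adj[v]) == 2:
                    (a, ta), (b, tb) = adj[v]
                    _drop(a, v), _drop(b, v)
                    adj[a].append((b, ta + tb))
                    adj[b].append((a, ta + tb))
                    del adj[v]
                    changed = True
        # resolve polytomies with zero-length edges
        fresh = 0
        for v in list(adj):
            while len(adj[v]) > 3:
                warnings.warn("non-bifurcating node resolved with a zero-length edge")
                fresh += 1
                z = ("_poly", fresh)
                n1, n2 = adj[v][0], adj[v][1]
                _drop(n1[0], v), _drop(n2[0], v)
                adj[v] = adj[v][2:] + [(z, 0.0)]
                adj[z] = [n1, n2, (v, 0.0)]
                adj[n1[0]].append((z, n1[1]))
                adj[n2[0]].append((z, n2[1]))
        leaves = [v for v in adj if v in labels]
        if len(leaves) < 3:
            raise ValueError("reference tree needs at least 3 leaves")
        if len(set(labels[v] for v in leaves)) != len(leaves):
            raise ValueError("duplicate leaf labels in reference tree")
        for v in adj:
            if v not in labels and len(adj[v]) not in (3,):
                raise ValueError("internal node of unexpected degree")

        anchor = min(leaves, key=lambda v: labels[v])
        root = adj[anchor][0][0]

        # min leaf label per subtree, rooted at `root`
        minleaf = {}

        def _minleaf(v, par):
            if v in labels:
                minleaf[(v, par)] = labels[v]
                return labels[v]
            m = min(_minleaf(w, v) for w, _ in adj[v] if w != par)
            minleaf[(v, par)] = m
            return m

        for w, _ in adj[root]:
            _minleaf(w, root)

        parent, lengths, children, leaf_name, node_label = [-1], [], [[]], {}, {}
        if root in internal_labels:
            node_label[0] = internal_labels[root]
        ids = {root: 0}

        def _walk(v, par, vid):
            kids = sorted(((w, t) for w, t in adj[v] if w != par),
                          key=lambda wt: minleaf[(wt[0], v)])
            for w, t in kids:
                wid = len(parent)
                ids[w] = wid
                parent.append(vid)
                lengths.append(t)
                children.append([])
                children[vid].append(wid)
                if w in labels:
                    leaf_name[wid] = labels[w]
                elif w in internal_labels:
                    node_label[wid] = internal_labels[w]
                _walk(w, v, wid)

        _walk(root, None, 0)
        lengths = np.array([0.0] + lengths)  # slot 0 unused (root)
        if np.any(lengths < 0):
            raise ValueError("negative branch length in reference tree")
        return cls(parent, children, lengths[1:], leaf_name, node_label)

    # edge e has length lengths[e] (= branch above node e+1)

    # -- serialization -----------------------------------------------------
    def newick(self, edge_numbers: bool = False, fmt: str = "%.12g") -> str:
        def _sub(v):
            if self.is_leaf(v):
                base = self.leaf_name[v]
            else:
                base = "(" + ",".join(_sub(c) for c in self.children[v]) + ")"
                base += self.node_label.get(v, "")
            if v == 0:
                return base
            e = v - 1
            s = f"{base}:{fmt % self.lengths[e]}"
            if edge_numbers:
                s += "{%d}" % e
            return s

        return _sub(0) + ";"

    def with_branch_lengths(self, lengths) -> "ReferenceTree":
        t = ReferenceTree(self.parent.copy(), [list(c) for c in self.children],
                          np.asarray(lengths, float).copy(), self.leaf_name,
                          self.node_label)
        return t

    # -- distances ---------------------------------------------------------
    def _depths(self):
        depth = np.zeros(self.n_nodes)
        ndepth = np.zeros(self.n_nodes, dtype=int)
        for v in range(1, self.n_nodes):
            depth[v] = depth[self.parent[v]] + self.lengths[v - 1]
            ndepth[v] = ndepth[self.parent[v]] + 1
        return depth, ndepth

    def node_distance(self, u: int, v: int) -> float:
        if self._dist is None:
            depth, _ = self._depths()
            self._dist = (depth, None)
        depth = self._dist[0]
        return depth[u] + depth[v] - 2 * depth[self._lca(u, v)]

    def _lca(self, u, v):
        seen = set()
        while u != -1:
            seen.add(u)
            u = self.parent[u]
        while v not in seen:
            v = self.parent[v]
        return v

    def attachment_distance(self, e1: int, a1: float, e2: int, a2: float) -> float:
        """Path distance between two attachment points.

        ``a`` is measured from the distal end of the edge toward the root.
        """
        if e1 == e2:
            return abs(a1 - a2)
        v1, p1 = self.edge_child(e1), self.parent[self.edge_child(e1)]
        v2, p2 = self.edge_child(e2), self.parent[self.edge_child(e2)]
        c1 = [(v1, a1), (p1, self.lengths[e1] - a1)]
        c2 = [(v2, a2), (p2, self.lengths[e2] - a2)]
        return min(w1 + self.node_distance(x, y) + w2
                   for x, w1 in c1 for y, w2 in c2)

    def _node_path(self, u, v):
        """Inclusive node path between u and v."""
        _, nd = self._depths()
        pu, pv = [u], [v]
        while nd[pu[-1]] > nd[pv[-1]]:
            pu.append(self.parent[pu[-1]])
        while nd[pv[-1]] > nd[pu[-1]]:
            pv.append(self.parent[pv[-1]])
        while pu[-1] != pv[-1]:
            pu.append(self.parent[pu[-1]])
            pv.append(self.parent[pv[-1]])
        return pu + pv[-2::-1]

    def nodes_between_edges(self, e1: int, e2: int) -> int:
        """Number of nodes strictly on the path connecting two edges.

        Zero for the same edge; one for edges sharing a node (e.g. sister
        pendant edges).
        """
        if e1 == e2:
            return 0
        ends1 = (self.edge_child(e1), self.parent[self.edge_child(e1)])
        ends2 = (self.edge_child(e2), self.parent[self.edge_child(e2)])
        return min(len(self._node_path(x, y)) for x in ends1 for y in ends2)

    # -- pruning -----------------------------------------------------------
    def to_adjacency(self):
        adj = {v: [] for v in range(self.n_nodes)}
        labels = {}
        for v in range(1, self.n_nodes):
            p = self.parent[v]
            adj[p].append((v, self.lengths[v - 1]))
            adj[v].append((p, self.lengths[v - 1]))
        for v, name in self.leaf_name.items():
            labels[v] = name
        return adj, labels

    def prune_leaf(self, name: str):
        """Remove a leaf, suppress the degree-2 node, renumber.

        Returns ``(pruned_tree, true_edge)`` where ``true_edge`` is the id
        in the pruned tree of the edge formed by merging the two branches
        that met the removed leaf's attachment node.
        """
        if self.n_leaves < 4:
            raise ValueError("cannot prune below 3 leaves")
        inv = {v: n for v, n in self.leaf_name.items()}
        node = next((v for v, n in inv.items() if n == name), None)
        if node is None:
            raise KeyError(f"no leaf named {name!r}")
        adj, labels = self.to_adjacency()
        p = adj[node][0][0]
        side_sets = []
        for w, _ in adj[p]:
            if w == node:
                continue
            side_sets.append(self._leafset_from(w, p, adj, labels))
        nbr = adj[node][0][0]
        adj[nbr] = [(w, t) for w, t in adj[nbr] if w != node]
        del adj[node]
        del labels[node]
        pruned = ReferenceTree.from_adjacency(adj, labels)
        target = frozenset(side_sets[0])
        all_leaves = frozenset(pruned.leaf_name.values())
        for e in range(pruned.n_edges):
            ls = pruned.leafset(e)
            if ls == target or ls == all_leaves - target:
                return pruned, e
        raise RuntimeError("merged edge not found after pruning")

    @staticmethod
    def _leafset_from(v, par, adj, labels):
        out = set()
        stack = [(v, par)]
        while stack:
            u, pu = stack.pop()
            if u in labels:
                out.add(labels[u])
            for w, _ in adj[u]:
                if w != pu:
                    stack.append((w, u))
        return out


def parse_newick(newick: str) -> ReferenceTree:
    """Parse Newick text into a validated, deterministically numbered tree."""
    dt = dendropy.Tree.get(data=newick, schema="newick",
                           preserve_underscores=True)
    adj, labels, ilabels = {}, {}, {}
    for nd in dt.preorder_node_iter():
        adj.setdefault(id(nd), [])
        if nd.taxon is not None:
            labels[id(nd)] = nd.taxon.label
        elif nd.label:
            ilabels[id(nd)] = nd.label
        for ch in nd.child_nodes():
            if ch.edge.length is None:
                raise ValueError("reference tree has a missing branch length")
            adj[id(nd)].append((id(ch), float(ch.edge.length)))
            adj.setdefault(id(ch), []).append((id(nd), float(ch.edge.length)))
    return ReferenceTree.from_adjacency(adj, labels, ilabels)


@dataclass
class ReferenceAlignment:
    """Aligned reference sequences, one row per tree leaf."""

    rows: dict
    alphabet: str = "nt"  # 'nt' or 'aa'

    def __post_init__(self):
        lens = {len(s) for s in self.rows.values()}
        if len(lens) > 1:
            raise ValueError("alignment rows have differing lengths")
        self.rows = {k: v.upper() for k, v in self.rows.items()}

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def states(self) -> str:
        return NT_ORDER if self.alphabet == "nt" else AA_ORDER

    def encode(self, name: str) -> np.ndarray:
        """Per-site indicator over states; ambiguity codes spread uniformly
        over their compatible set, gaps and N/X over all states."""
        return encode_sequence(self.rows[name], self.alphabet)

    @classmethod
    def from_fasta(cls, fasta: str, alphabet: str = None) -> "ReferenceAlignment":
        rows = {}
        for rec in SeqIO.parse(io.StringIO(fasta), "fasta"):
            rows[rec.id] = str(rec.seq)
        if not rows:
            raise ValueError("no sequences found in FASTA input")
        if alphabet is None:
            alphabet = guess_alphabet("".join(rows.values()))
        return cls(rows, alphabet)

    def to_fasta(self) -> str:
        return "".join(f">{k}\n{v}\n" for k, v in self.rows.items())


def guess_alphabet(seq: str) -> str:
    informative = [c for c in seq.upper() if c not in GAP_CHARS]
    nt = sum(c in "ACGTUN" for c in informative)
    return "nt" if informative and nt / len(informative) > 0.9 else "aa"


def encode_sequence(seq: str, alphabet: str) -> np.ndarray:
    states = NT_ORDER if alphabet == "nt" else AA_ORDER
    amb = _NT_AMBIG if alphabet == "nt" else _AA_AMBIG
    idx = {c: i for i, c in enumerate(states)}
    out = np.zeros((len(seq), len(states)))
    for s, c in enumerate(seq.upper()):
        for st in amb.get(c, states):
            out[s, idx[st]] = 1.0
    return out


def read_reference(newick: str, fasta: str, alphabet: str = None):
    """Parse and cross-validate the reference tree and alignment."""
    tree = parse_newick(newick)
    aln = ReferenceAlignment.from_fasta(fasta, alphabet)
    missing = set(tree.leaf_names) - set(aln.rows)
    if missing:
        raise ValueError(
            "alignment is missing rows for tree leaves: " + ", ".join(sorted(missing)))
    return tree, aln


# ---------------------------------------------------------------------------
# conditional likelihood caches


@dataclass
class EdgeCache:
    """Distal, proximal and center-of-edge likelihood vectors per edge.

    Arrays are (edges, sites, rate categories, states); per-site log scaling
    factors keep long alignments inside double-precision range.  The distal
    vector conditions on the state at the edge's distal node, the proximal
    vector on the state at its proximal node, and the midpoint vector is the
    product of both sides propagated half the branch length toward the
    center (the quick-evaluation anchor).
    """

    tree: ReferenceTree
    model: SubstModel
    distal: np.ndarray
    distal_scale: np.ndarray
    proximal: np.ndarray
    proximal_scale: np.ndarray
    midpoint: np.ndarray
    midpoint_scale: np.ndarray

    @property
    def n_vectors(self) -> int:
        return 3 * self.tree.n_edges


def _rescale(arr, threshold):
    """Per-site rescaling when the max partial likelihood drops below
    ``threshold``; returns log factors taken out."""
    m = arr.max(axis=(1, 2))
    mask = (m < threshold) & (m > 0)
    factor = np.where(mask, m, 1.0)
    arr /= factor[:, None, None]
    return np.log(factor)


def compute_caches(tree: ReferenceTree, aln: ReferenceAlignment,
                   model: SubstModel, scale_threshold: float = 1e-50) -> EdgeCache:
    """Two tree traversals precomputing every per-edge likelihood vector."""
    if model.alphabet_size != len(aln.states):
        raise ValueError("model alphabet does not match alignment alphabet")
    n_sites = aln.n_columns
    K, S = model.n_rate_cats, model.alphabet_size
    E = tree.n_edges
    P = model.transition_matrices(tree.lengths)       # (E, K, S, S)
    Ph = model.transition_matrices(tree.lengths / 2)  # (E, K, S, S)

    down = [None] * tree.n_nodes
    dscale = [None] * tree.n_nodes
    for v in tree.postorder():
        if tree.is_leaf(v):
            tip = aln.encode(tree.leaf_name[v])       # (sites, S)
            down[v] = np.broadcast_to(tip[:, None, :], (n_sites, K, S)).copy()
            dscale[v] = np.zeros(n_sites)
        else:
            acc = np.ones((n_sites, K, S))
            sc = np.zeros(n_sites)
            for c in tree.children[v]:
                flow = np.einsum("kxy,sky->skx", P[c - 1], down[c], optimize=True)
                acc *= flow
                sc += dscale[c]
            sc += _rescale(acc, scale_threshold)
            down[v], dscale[v] = acc, sc

    distal = np.empty((E, n_sites, K, S))
    distal_scale = np.empty((E, n_sites))
    for e in range(E):
        distal[e] = down[e + 1]
        distal_scale[e] = dscale[e + 1]

    proximal = np.empty((E, n_sites, K, S))
    proximal_scale = np.empty((E, n_sites))
    for v in range(1, tree.n_nodes):  # preorder by construction
        e = v - 1
        p = tree.parent[v]
        acc = np.ones((n_sites, K, S))
        sc = np.zeros(n_sites)
        for s_ in tree.children[p]:
            if s_ == v:
                continue
            acc *= np.einsum("kxy,sky->skx", P[s_ - 1], down[s_], optimize=True)
            sc += dscale[s_]
        if p != 0:
            pe = p - 1
            acc *= np.einsum("kxy,sky->skx", P[pe], proximal[pe], optimize=True)
            sc += proximal_scale[pe]
        sc += _rescale(acc, scale_threshold)
        proximal[e], proximal_scale[e] = acc, sc

    mid = np.einsum("ekxy,esky->eskx", Ph, distal, optimize=True) \
        * np.einsum("ekxy,esky->eskx", Ph, proximal, optimize=True)
    midpoint_scale = distal_scale + proximal_scale
    for e in range(E):
        midpoint_scale[e] += _rescale(mid[e], scale_threshold)

    if not np.all(np.isfinite(distal)) or not np.all(np.isfinite(proximal)):
        raise FloatingPointError("non-finite values in likelihood caches")
    return EdgeCache(tree, model, distal, distal_scale,
                     proximal, proximal_scale, mid, midpoint_scale)


def tree_loglike(cache: EdgeCache, edge: int = 0) -> float:
    """Reference-alignment log-likelihood, joining the caches across an edge.

    The result is the same (within round-off) for every edge.
    """
    tree, model = cache.tree, cache.model
    tree.edge_child(edge)  # raises on unknown edge
    P = model.transition_matrices(float(tree.lengths[edge]))
    flow = np.einsum("kxy,sky->skx", P, cache.distal[edge], optimize=True)
    w = cache.model.rate_categories.weights
    pi = model.stationary_freqs
    site_l = np.einsum("k,x,skx,skx->s", w, pi, cache.proximal[edge], flow,
                       optimize=True)
    if np.any(site_l <= 0):
        raise FloatingPointError("zero site likelihood on the reference tree")
    return float(np.sum(np.log(site_l) + cache.distal_scale[edge]
                        + cache.proximal_scale[edge]))


# ---------------------------------------------------------------------------
# attachment likelihoods (three-taxon computation at a candidate edge)


def attachment_loglike_grid(cache: EdgeCache, edge: int, q_ind: np.ndarray,
                            mask: np.ndarray, a_values, b_values) -> np.ndarray:
    """Log-likelihood of attaching a query on a grid of (a, b) values.

    ``q_ind`` is the query's per-state indicator over the masked-in columns
    (shape ``(len(mask), S)``); ``a`` is the distance from the edge's distal
    end, ``b`` the pendant branch length.  Returns shape ``(len(a), len(b))``.
    Only the masked-in columns enter: the factor from the remaining columns
    is placement-independent and cancels from every confidence ratio.
    """
    tree, model = cache.tree, cache.model
    a_values = np.atleast_1d(np.asarray(a_values, float))
    b_values = np.atleast_1d(np.asarray(b_values, float))
    A = float(tree.lengths[edge])
    d = cache.distal[edge][mask]
    p_ = cache.proximal[edge][mask]
    const = float(np.sum(cache.distal_scale[edge][mask]
                         + cache.proximal_scale[edge][mask]))
    Pa = model.transition_matrices(a_values)                 # (na,K,S,S)
    Pr = model.transition_matrices(np.maximum(A - a_values, 0.0))
    Pb = model.transition_matrices(b_values)                 # (nb,K,S,S)
    G = np.einsum("akxy,sky->askx", Pa, d, optimize=True) \
        * np.einsum("akxy,sky->askx", Pr, p_, optimize=True)  # (na,m,K,S)
    C = np.einsum("bkxy,sy->bskx", Pb, q_ind, optimize=True)  # (nb,m,K,S)
    w = model.rate_categories.weights
    pi = model.stationary_freqs
    site_l = np.einsum("askx,bskx,k,x->abs", G, C, w, pi, optimize=True)
    if np.any(site_l <= 0):
        raise FloatingPointError(f"zero site likelihood at edge {edge}")
    return np.sum(np.log(site_l), axis=2) + const


def attachment_loglike(cache: EdgeCache, edge: int, q_ind: np.ndarray,
                       mask: np.ndarray, a: float, b: float) -> float:
    return float(attachment_loglike_grid(cache, edge, q_ind, mask, [a], [b])[0, 0])


# ---------------------------------------------------------------------------
# fixed-topology branch length re-estimation


def _edge_loglike_fn(cache, edge):
    tree, model = cache.tree, cache.model
    w = model.rate_categories.weights
    pi = model.stationary_freqs
    d, p_ = cache.distal[edge], cache.proximal[edge]
    const = float(np.sum(cache.distal_scale[edge] + cache.proximal_scale[edge]))

    def f(t):
        P = model.transition_matrices(float(t))
        flow = np.einsum("kxy,sky->skx", P, d, optimize=True)
        site_l = np.einsum("k,x,skx,skx->s", w, pi, p_, flow, optimize=True)
        return float(np.sum(np.log(site_l))) + const

    return f


def reestimate_branch_lengths(tree: ReferenceTree, aln: ReferenceAlignment,
                              model: SubstModel, tol: float = 1e-3,
                              max_sweeps: int = 12,
                              bounds=(1e-6, 10.0)) -> ReferenceTree:
    """Optimize branch lengths on the fixed topology by coordinate ascent.

    One derivative-free 1-D search per edge on the log-length scale, swept
    repeatedly until the total log-likelihood gain in a sweep falls below
    ``tol``.  Topology and edge numbering are untouched.
    """
    cur = tree.with_branch_lengths(tree.lengths)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    cache = compute_caches(cur, aln, model)
    best = tree_loglike(cache, 0)
    for _ in range(max_sweeps):
        start = best
        for e in range(cur.n_edges):
            cache = compute_caches(cur, aln, model)
            f = _edge_loglike_fn(cache, e)
            res = minimize_scalar(lambda lt: -f(np.exp(lt)), bounds=(lo, hi),
                                  method="bounded",
                                  options={"xatol": 1e-5})
            t_new = float(np.exp(res.x))
            if f(t_new) >= f(cur.lengths[e]):
                cur.lengths[e] = t_new
        cache = compute_caches(cur, aln, model)
        best = tree_loglike(cache, 0)
        if best - start < tol:
            break
    else:
        warnings.warn("branch length re-estimation hit the sweep cap; "
                      "returning best lengths found")
    return cur
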