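"""Independent reference implementations used to cross-check the package.

Everything here deliberately avoids the package's cached-vector machinery:
likelihoods are computed by direct recursive pruning on a dendropy tree
with transition matrices from scipy's generic matrix exponential, and tree
distances come from networkx shortest paths on an explicit graph.
"""

import dendropy
import networkx as nx
import numpy as np
from scipy.linalg import expm

from phyloplace.reference import encode_sequence


def pruning_loglike(newick, rows, model, alphabet):
    """Single-pass recursive Felsenstein pruning, rooted wherever the
    newick happens to be rooted (the likelihood is root-invariant)."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    q = model.rate_matrix
    rates = model.rate_categories.rates
    weights = model.rate_categories.weights
    pi = model.stationary_freqs
    n_sites = len(next(iter(rows.values())))

    def partial(node, k):
        if node.is_leaf():
            return encode_sequence(rows[node.taxon.label], alphabet)
        out = np.ones((n_sites, len(pi)))
        for ch in node.child_nodes():
            p = expm(q * rates[k] * ch.edge.length)
            out *= partial(ch, k) @ p.T
        return out

    site_l = np.zeros(n_sites)
    for k in range(len(rates)):
        root_partial = partial(tree.seed_node, k)
        site_l += weights[k] * (root_partial @ pi)
    return float(np.sum(np.log(site_l)))


def attach_query_newick(tree, edge, a, b, qname="QUERY"):
    """Newick of the reference tree with a pendant query leaf attached at
    distance ``a`` from the distal end of ``edge``, pendant length ``b``."""
    adj, labels = tree.to_adjacency()
    v = tree.edge_child(edge)
    p = int(tree.parent[v])
    A = float(tree.lengths[edge])
    adj[v] = [(w, t) for w, t in adj[v] if w != p]
    adj[p] = [(w, t) for w, t in adj[p] if w != v]
    x, q = "attach_pt", "query_leaf"
    adj[x] = [(v, a), (p, A - a), (q, b)]
    adj[v].append((x, a))
    adj[p].append((x, A - a))
    adj[q] = [(x, b)]
    labels[q] = qname

    def sub(node, par):
        kids = [(w, t) for w, t in adj[node] if w != par]
        if not kids:
            return labels[node]
        return "(" + ",".join(f"{sub(w, node)}:{t:.12g}" for w, t in kids) + ")"

    root = next(k for k in adj if k not in labels)
    return sub(root, None) + ";"


def placement_loglike(tree, aln, model, read, edge, a, b):
    """Three-part attachment likelihood over the read's masked-in columns,
    by brute-force pruning on the extended tree."""
    nwk = attach_query_newick(tree, edge, a, b)
    mask = read.mask
    rows = {name: "".join(seq[i] for i in mask)
            for name, seq in aln.rows.items()}
    rows["QUERY"] = "".join(read.aligned[i] for i in mask)
    return pruning_loglike(nwk, rows, model, aln.alphabet)


def tree_graph(tree):
    g = nx.Graph()
    for v in range(1, tree.n_nodes):
        g.add_edge(int(tree.parent[v]), v, weight=float(tree.lengths[v - 1]))
    return g


def attachment_distance(tree, e1, a1, e2, a2):
    """Path distance between attachment points via networkx, splitting the
    host edges with explicit intermediate nodes."""
    g = tree_graph(tree)
    for tag, (e, a) in (("P1", (e1, a1)), ("P2", (e2, a2))):
        v = tree.edge_child(e)
        p = int(tree.parent[v])
        if g.has_edge(v, p):
            g.remove_edge(v, p)
        g.add_edge(tag, v, weight=a)
        g.add_edge(tag, p, weight=float(tree.lengths[e]) - a)
    if e1 == e2:
        return abs(a1 - a2)
    return nx.shortest_path_length(g, "P1", "P2", weight="weight")


def nodes_between_edges_bfs(tree, e1, e2):
    """Count of nodes on the shortest inter-edge path, from an explicit
    graph search over the four endpoint pairings."""
    if e1 == e2:
        return 0
    g = tree_graph(tree)
    ends1 = (tree.edge_child(e1), int(tree.parent[tree.edge_child(e1)]))
    ends2 = (tree.edge_child(e2), int(tree.parent[tree.edge_child(e2)]))
    return min(len(nx.shortest_path(g, x, y)) for x in ends1 for y in ends2)


def dense_log_marginal(tree, aln, model, read, edge, prior, n=400, bcap_q=1e-10):
    """Dense-grid oracle for the Bayes marginal on one edge.

    Trapezoid rule over an (n+1) x (n+1) grid with one Richardson
    extrapolation step (combining the full grid with its every-other-point
    subgrid), which removes the h^2 error term that would otherwise
    dominate for sharply peaked integrands.
    """
    from phyloplace.reference import attachment_loglike_grid, compute_caches
    cache = compute_caches(tree, aln, model)
    A = float(tree.lengths[edge])
    a_grid = np.linspace(0.0, A, n + 1) if A > 0 else np.array([0.0])
    if prior.kind == "exponential":
        bcap = -prior.mean * np.log(bcap_q)
    else:
        bcap = prior.upper_bound
    b_grid = np.linspace(0.0, bcap, n + 1)
    ll = attachment_loglike_grid(cache, edge, read.indicator, read.mask,
                                 a_grid, b_grid)
    m = ll.max()
    f = np.exp(ll - m) * prior.pdf(b_grid)[None, :]

    def trap2d(g, a, b):
        inner = np.trapezoid(g, b, axis=1)
        if A > 0:
            return np.trapezoid(inner, a) / A
        return inner[0]

    fine = trap2d(f, a_grid, b_grid)
    coarse = trap2d(f[::2][:, ::2] if A > 0 else f[:, ::2],
                    a_grid[::2] if A > 0 else a_grid, b_grid[::2])
    total = (4 * fine - coarse) / 3
    return float(np.log(total) + m)
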