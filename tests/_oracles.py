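"""Independent brute-force oracles, deliberately decoupled from the
package's streaming implementations."""

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import linprog


def descendants_via_networkx(tree, j):
    """Descendants-or-self of node j from an independently built digraph."""
    g = nx.DiGraph()
    g.add_nodes_from(range(tree.n_nodes))
    for i in range(tree.n_nodes - 1):
        g.add_edge(int(tree.parent[i]), i)
    return {j} | nx.descendants(g, j)


def path_distance_matrix(tree):
    """All-pairs path lengths over the tree's weighted edges."""
    g = nx.Graph()
    g.add_nodes_from(range(tree.n_nodes))
    for i in range(tree.n_nodes - 1):
        g.add_edge(i, int(tree.parent[i]), weight=float(tree.lengths[i]))
    n = tree.n_nodes
    d = np.zeros((n, n))
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="weight"):
        for dst, val in lengths.items():
            d[src, dst] = val
    return d


def min_cost_transport(p, q, cost):
    """1-Wasserstein via an explicit transport linear program."""
    n = len(p)
    c = cost.reshape(-1)
    a_eq = []
    b_eq = []
    for i in range(n):  # row sums = p
        row = np.zeros((n, n))
        row[i, :] = 1.0
        a_eq.append(row.reshape(-1))
        b_eq.append(p[i])
    for j in range(n - 1):  # column sums = q (last constraint redundant)
        col = np.zeros((n, n))
        col[:, j] = 1.0
        a_eq.append(col.reshape(-1))
        b_eq.append(q[j])
    res = linprog(c, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success, res.message
    return res.fun


def fowlkes_mallows_by_pair_enumeration(pred, truth):
    """FM score by explicit enumeration of all sample pairs."""
    samples = sorted(pred)
    tp = fp = fn = 0
    for a, b in itertools.combinations(samples, 2):
        same_pred = pred[a] == pred[b]
        same_true = truth[a] == truth[b]
        if same_pred and same_true:
            tp += 1
        elif same_pred:
            fp += 1
        elif same_true:
            fn += 1
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    return tp / np.sqrt((tp + fp) * (tp + fn))
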