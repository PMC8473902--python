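"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (explicit local polynomial
fits, O(n^3) agglomeration, full dynamic programming) kept separate from
the package implementation paths they validate.
"""

import numpy as np


def sg_second_derivative_bruteforce(wavenumbers, intensities, window, polyorder):
    """Least-squares fit a degree-`polyorder` polynomial to every
    `window`-point neighborhood and evaluate its second derivative at the
    center point.  Returns (trimmed wavenumbers, derivatives)."""
    half = (window - 1) // 2
    wn = np.asarray(wavenumbers, float)
    y = np.asarray(intensities, float)
    out = []
    for c in range(half, wn.size - half):
        x = wn[c - half:c + half + 1] - wn[c]
        coeffs = np.polynomial.polynomial.polyfit(x, y[c - half:c + half + 1],
                                                  polyorder)
        out.append(2.0 * coeffs[2])  # d2/dx2 of sum c_k x^k at x=0
    return wn[half:-half], np.array(out)


def single_linkage_bruteforce(d):
    """Naive O(n^3) single-linkage agglomeration over a full matrix.

    Clusters are frozensets of leaf indices; inter-cluster distance is
    recomputed as the minimum over all member pairs at every step.  Ties
    break toward the pair with the lowest (min leaf, min leaf) indices.
    Returns the list of merge heights and the sequence of merged leaf-set
    pairs."""
    d = np.asarray(d, float)
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    heights, merged = [], []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = min(d[i, j] for i in clusters[a] for j in clusters[b])
                ra, rb = sorted((min(clusters[a]), min(clusters[b])))
                key = (dist, ra, rb)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dist, _, _), a, b = best
        heights.append(dist)
        merged.append((clusters[a], clusters[b]))
        new = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [new]
    return heights, merged


def smith_waterman_full(x, y, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Full affine-gap Smith-Waterman with traceback.

    Gap convention: the first base of a gap costs `gap_open`, each further
    base `gap_extend`.  Returns (score, matches, aligned_length).
    """
    m, n = len(x), len(y)
    NEG = -10**9
    H = np.zeros((m + 1, n + 1), int)
    E = np.full((m + 1, n + 1), NEG, int)
    F = np.full((m + 1, n + 1), NEG, int)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (x[i - 1] == y[j - 1] and x[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
    score = int(H.max())
    if score == 0:
        return 0, 0, 0
    i, j = np.unravel_index(np.argmax(H), H.shape)
    matches = aligned = 0
    state = "H"
    while H[i][j] > 0 or state != "H":
        if state == "H":
            s = match if (x[i - 1] == y[j - 1] and x[i - 1] != "N") else mismatch
            if H[i][j] == E[i][j]:
                state = "E"
            elif H[i][j] == F[i][j]:
                state = "F"
            else:
                assert H[i][j] == H[i - 1][j - 1] + s
                matches += x[i - 1] == y[j - 1] != "N"
                aligned += 1
                i, j = i - 1, j - 1
        elif state == "E":
            aligned += 1
            if E[i][j] == H[i][j - 1] + gap_open:
                state = "H"
            j -= 1
        else:
            aligned += 1
            if F[i][j] == H[i - 1][j] + gap_open:
                state = "H"
            i -= 1
    return score, int(matches), aligned


def random_additive_tree_matrix(n_taxa, rng):
    """Random binary tree with uniform(0.05, 1) edge lengths; returns
    (leaf labels, path-length distance matrix)."""
    import networkx as nx

    G = nx.Graph()
    nodes = [f"L{i}" for i in range(n_taxa)]
    leaves = nodes[:]
    nxt = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        p = f"I{nxt}"
        nxt += 1
        G.add_edge(a, p, w=float(rng.uniform(0.05, 1.0)))
        G.add_edge(b, p, w=float(rng.uniform(0.05, 1.0)))
        nodes = [x for x in nodes if x not in (a, b)] + [p]
    d = dict(nx.all_pairs_dijkstra_path_length(G, weight="w"))
    mat = np.array([[d[x][y] for y in leaves] for x in leaves])
    return leaves, mat
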