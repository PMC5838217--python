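"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized code paths: joint-state
probabilities are exact rationals built by explicit sample loops, and the
con/re decision rule is evaluated literally on those rationals. They exist
so the optimized implementation can be checked against a slow, obviously
correct reference.
"""

from fractions import Fraction

STATES = (-1, 0, 1)


def joint_table(row_i, row_j):
    """Exact joint probabilities {(vi, vj): Fraction} from two state rows."""
    n = len(row_i)
    assert len(row_j) == n
    table = {(a, b): Fraction(0) for a in STATES for b in STATES}
    for vi, vj in zip(row_i, row_j):
        table[(int(vi), int(vj))] += Fraction(1, n)
    return table


def classify(table, theta):
    """Literal evaluation of the con/re decision rule with exact rationals.

    theta (a float) is converted to its exact binary rational so the strict
    comparisons agree bit-for-bit with any correct implementation.
    """
    th = Fraction(theta)
    same = table[(-1, -1)] + table[(1, 1)] + table[(0, 0)]
    opp = table[(-1, 1)] + table[(1, -1)] + table[(0, 0)]
    mixed = (table[(-1, 0)] + table[(0, -1)] + table[(1, 0)]
             + table[(0, 1)] + table[(0, 0)])
    if same - opp > 0 and same - mixed > th:
        return "con", same - mixed
    if opp - same > 0 and opp - mixed > th:
        return "re", opp - mixed
    return "none", None


def detect_all_pairs(states, gene_ids, theta):
    """All-pairs detection by explicit double loop; returns a sorted list of
    (gene_a, gene_b, type, strength-as-Fraction) in canonical order."""
    out = []
    g = len(gene_ids)
    for i in range(g):
        for j in range(i + 1, g):
            label, strength = classify(joint_table(states[i], states[j]), theta)
            if label != "none":
                a, b = sorted((gene_ids[i], gene_ids[j]))
                out.append((a, b, label, strength))
    out.sort(key=lambda r: (r[0], r[1]))
    return out


def shortest_path_lengths(edges, nodes):
    """All-pairs shortest paths by repeated BFS over an adjacency dict."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    dist = {}
    for src in nodes:
        seen = {src: 0}
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in seen:
                        seen[w] = d
                        nxt.append(w)
            frontier = nxt
        dist[src] = seen
    return dist
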