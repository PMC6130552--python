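"""Independent brute-force oracles for graph and communication measures.

Everything here is deliberately naive — exhaustive enumeration of simple
paths, triangles, partitions and neighbor sets — and shares no code with
the package implementation it checks.
"""

from itertools import combinations, permutations

import numpy as np


def enumerate_simple_paths(adj: np.ndarray, s: int, t: int):
    """Yield every simple path s -> t as a node list (DFS)."""
    n = adj.shape[0]
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in range(n):
            if adj[node, nxt] > 0 and nxt not in path:
                stack.append((nxt, path + [nxt]))


def brute_shortest_path_length(w: np.ndarray, s: int, t: int,
                               weighted: bool) -> float:
    best = np.inf
    for path in enumerate_simple_paths(w, s, t):
        if weighted:
            length = sum(1.0 / w[a, b] for a, b in zip(path[:-1], path[1:]))
        else:
            length = len(path) - 1
        best = min(best, length)
    return best


def brute_distance_matrix(w: np.ndarray, weighted: bool) -> np.ndarray:
    n = w.shape[0]
    d = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s != t:
                d[s, t] = brute_shortest_path_length(w, s, t, weighted)
    return d


def brute_char_path_length(w: np.ndarray, weighted: bool) -> float:
    d = brute_distance_matrix(w, weighted)
    off = d[~np.eye(w.shape[0], dtype=bool)]
    return off[np.isfinite(off)].mean()


def brute_global_efficiency(w: np.ndarray, weighted: bool) -> float:
    d = brute_distance_matrix(w, weighted)
    off = d[~np.eye(w.shape[0], dtype=bool)]
    inv = np.where(np.isfinite(off) & (off > 0), 1.0 / off, 0.0)
    return inv.mean()


def brute_clustering(w: np.ndarray, weighted: bool) -> float:
    """Mean nodal clustering; Onnela geometric-mean form for weighted."""
    n = w.shape[0]
    a = (w != 0).astype(float)
    wn = w / w.max() if weighted and w.max() > 0 else a
    per_node = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            per_node.append(0.0)
            continue
        total = 0.0
        for x, y in combinations(nb, 2):
            if a[x, y]:
                total += (wn[i, x] * wn[i, y] * wn[x, y]) ** (1.0 / 3.0) \
                    if weighted else 1.0
        per_node.append(2.0 * total / (k * (k - 1)))
    return float(np.mean(per_node))


def brute_local_efficiency(w: np.ndarray, weighted: bool) -> float:
    n = w.shape[0]
    per_node = []
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            per_node.append(0.0)
            continue
        sub = w[np.ix_(nb, nb)]
        per_node.append(brute_global_efficiency(sub, weighted))
    return float(np.mean(per_node))


def set_partitions(items):
    """All set partitions (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def newman_modularity(w: np.ndarray, partition) -> float:
    two_m = w.sum()
    if two_m == 0:
        return 0.0
    s = w.sum(axis=1)
    q = 0.0
    for block in partition:
        for i in block:
            for j in block:
                q += w[i, j] - s[i] * s[j] / two_m
    return q / two_m


def brute_max_modularity(w: np.ndarray) -> tuple[float, list]:
    best_q, best_p = -np.inf, None
    for part in set_partitions(range(w.shape[0])):
        q = newman_modularity(w, part)
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p


def brute_search_information(w: np.ndarray) -> np.ndarray:
    """-log2 of the walker probability along each (enumerated) shortest path."""
    n = w.shape[0]
    strength = w.sum(axis=1)
    si = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            best, best_path = np.inf, None
            for path in enumerate_simple_paths(w, s, t):
                length = sum(1.0 / w[a, b] for a, b in zip(path[:-1], path[1:]))
                if length < best - 1e-12:
                    best, best_path = length, path
            if best_path is None:
                si[s, t] = np.inf
                continue
            prob = 1.0
            for a, b in zip(best_path[:-1], best_path[1:]):
                prob *= w[a, b] / strength[a]
            si[s, t] = -np.log2(prob)
    return si


def brute_matching_index(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    mi = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            others = [k for k in range(n) if k not in (i, j)]
            shared = [k for k in others if w[i, k] > 0 and w[j, k] > 0]
            any_nb = [k for k in others if w[i, k] > 0 or w[j, k] > 0]
            den = sum(w[i, k] + w[j, k] for k in any_nb)
            if den > 0:
                mi[i, j] = sum(w[i, k] + w[j, k] for k in shared) / den
    return mi


def brute_neighborhood_overlap(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    no = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ni = {k for k in range(n) if w[i, k] > 0 and k not in (i, j)}
            nj = {k for k in range(n) if w[j, k] > 0 and k not in (i, j)}
            union = ni | nj
            if union:
                no[i, j] = len(ni & nj) / len(union)
    return no


def brute_path_transitivity(w: np.ndarray) -> np.ndarray:
    """Mean matching index over node pairs of each enumerated shortest path."""
    n = w.shape[0]
    mi = brute_matching_index(w)
    pt = np.zeros((n, n))
    for s in range(n):
        for t in range(s + 1, n):
            best, best_path = np.inf, None
            for path in enumerate_simple_paths(w, s, t):
                length = sum(1.0 / w[a, b] for a, b in zip(path[:-1], path[1:]))
                if length < best - 1e-12:
                    best, best_path = length, path
            if best_path is None:
                pt[s, t] = pt[t, s] = np.inf
                continue
            omega = len(best_path)
            vals = [mi[best_path[a], best_path[b]]
                    for a, b in combinations(range(omega), 2)]
            pt[s, t] = pt[t, s] = float(np.mean(vals))
    return pt


def absorbing_mfpt(w: np.ndarray) -> np.ndarray:
    """MFPT by solving the absorbing-chain linear system per target."""
    n = w.shape[0]
    p = w / w.sum(axis=1, keepdims=True)
    mfpt = np.zeros((n, n))
    for target in range(n):
        others = [i for i in range(n) if i != target]
        q = p[np.ix_(others, others)]
        m = np.linalg.solve(np.eye(n - 1) - q, np.ones(n - 1))
        for row, i in enumerate(others):
            mfpt[i, target] = m[row]
    return mfpt


def random_connected_graph(rng: np.random.Generator, n: int,
                           weighted: bool, p_edge: float = 0.45) -> np.ndarray:
    """Random connected graph; weights in (0.2, 1.2) when weighted."""
    while True:
        a = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p_edge:
                    a[i, j] = a[j, i] = 1.0
        # connectivity check by BFS
        seen, frontier = {0}, [0]
        while frontier:
            node = frontier.pop()
            for k in range(n):
                if a[node, k] and k not in seen:
                    seen.add(k)
                    frontier.append(k)
        if len(seen) == n:
            break
    if weighted:
        w = rng.uniform(0.2, 1.2, size=(n, n))
        w = (w + w.T) / 2
        return a * w
    return a
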