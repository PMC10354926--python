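"""Independent brute-force oracles used to cross-check the implementation.

Everything here is pure Python over adjacency dictionaries — deliberately
sharing no code path with the package's scipy/networkx-based machinery.
"""

from __future__ import annotations


def floyd_warshall(nodes: list[str], edges: list[tuple[str, str]]) -> dict:
    """All-pairs shortest hop counts by the O(n^3) recurrence."""
    INF = float("inf")
    dist = {u: {v: (0 if u == v else INF) for v in nodes} for u in nodes}
    for u, v in edges:
        dist[u][v] = 1
        dist[v][u] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik == INF:
                continue
            row_k = dist[k]
            row_i = dist[i]
            for j in nodes:
                alt = dik + row_k[j]
                if alt < row_i[j]:
                    row_i[j] = alt
    return dist


def naive_module_distance(sample_nodes, cell_nodes, apsp) -> float:
    """d(S, C): explicit double loop over the all-pairs table."""
    total = 0.0
    for c in cell_nodes:
        total += min(apsp[s][c] for s in sample_nodes)
    return total / len(cell_nodes)


def naive_phenotype_distance(sample_modules, cell_nodes, apsp) -> float:
    """d(P, C): plain mean of the per-sample distances."""
    vals = [naive_module_distance(S, cell_nodes, apsp) for S in sample_modules]
    return sum(vals) / len(vals)


def rank_by_sorting(row: list[float]) -> list[float]:
    """Cross-column midranks divided by N, computed by explicit sorting."""
    n = len(row)
    order = sorted(range(n), key=lambda i: row[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and row[order[j + 1]] == row[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1  # 1-based average of tied positions
        for k in range(i, j + 1):
            ranks[order[k]] = mid / n
        i = j + 1
    return ranks
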