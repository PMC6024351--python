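"""Independent oracles used by the tests.

Deliberately naive implementations (union-find, dense edge-by-edge operator
assembly, BFS path search) kept separate from the package's production code
paths so the two routes stay independent.
"""

from __future__ import annotations

import numpy as np


class UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def union_find_percolates(mask: np.ndarray, axis: int = 0) -> bool:
    """Face-adjacency percolation along ``axis`` via union-find with two
    virtual terminal nodes."""
    mask = np.asarray(mask, dtype=bool)
    nx, ny, nz = mask.shape
    n = mask.size
    flat = mask.ravel()
    uf = UnionFind(n + 2)
    src, snk = n, n + 1
    idx = np.arange(n).reshape(mask.shape)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        a = idx[tuple(sl_a)].ravel()
        b = idx[tuple(sl_b)].ravel()
        both = flat[a] & flat[b]
        for i, j in zip(a[both], b[both]):
            uf.union(int(i), int(j))
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = 0
    hi[axis] = -1
    for i in idx[tuple(lo)].ravel():
        if flat[i]:
            uf.union(src, int(i))
    for i in idx[tuple(hi)].ravel():
        if flat[i]:
            uf.union(snk, int(i))
    return uf.find(src) == uf.find(snk)


def bfs_percolates(mask: np.ndarray, axis: int = 0) -> bool:
    """Breadth-first path search from the low to the high face."""
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    lo = [slice(None)] * 3
    lo[axis] = 0
    frontier = [tuple(p) for p in np.argwhere(np.zeros(shape, bool) | False)]
    start = np.zeros(shape, bool)
    start[tuple(lo)] = True
    frontier = [tuple(p) for p in np.argwhere(start & mask)]
    seen = set(frontier)
    while frontier:
        nxt = []
        for (i, j, k) in frontier:
            if (axis == 0 and i == shape[0] - 1) or \
               (axis == 1 and j == shape[1] - 1) or \
               (axis == 2 and k == shape[2] - 1):
                return True
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                q = (i + di, j + dj, k + dk)
                if (0 <= q[0] < shape[0] and 0 <= q[1] < shape[1]
                        and 0 <= q[2] < shape[2] and q not in seen
                        and mask[q]):
                    seen.add(q)
                    nxt.append(q)
        frontier = nxt
    return False


def dense_face_laplacian(mask: np.ndarray, c: float) -> np.ndarray:
    """Edge-by-edge dense assembly of the face-flux operator over the
    conductive subset (row order = C order of conductive cells)."""
    mask = np.asarray(mask, dtype=bool)
    pos = -np.ones(mask.shape, dtype=int)
    n = int(mask.sum())
    pos[mask] = np.arange(n)
    L = np.zeros((n, n))
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                a = pos[i, j, k]
                for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
                    q = (i + di, j + dj, k + dk)
                    if q[0] < nx and q[1] < ny and q[2] < nz and mask[q]:
                        b = pos[q]
                        L[a, b] += c
                        L[b, a] += c
                        L[a, a] -= c
                        L[b, b] -= c
    return L


def chain_crossing_probability(phi: float, n: int) -> float:
    """A 1 x 1 x n chain percolates iff every cell survives: (1 - phi)^n."""
    return (1.0 - phi) ** n
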