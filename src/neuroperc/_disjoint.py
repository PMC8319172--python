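"""Union-find (disjoint set) used by percolation and spanning-tree code."""

from __future__ import annotations


class DisjointSet:
    """Array-based union-find with union by size and path halving.

    Tracks the number of components and the size of the largest one so the
    percolation sweep can read both in O(1) after every union.
    """

    __slots__ = ("parent", "size", "n_components", "max_size")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n
        self.n_components = n
        self.max_size = 1 if n else 0

    def find(self, x: int) -> int:
        parent = self.parent
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        """Merge the sets of ``a`` and ``b``; return True if they were distinct."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        size = self.size
        if size[ra] < size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        size[ra] += size[rb]
        if size[ra] > self.max_size:
            self.max_size = size[ra]
        self.n_components -= 1
        return True

    def components(self) -> list[list[int]]:
        groups: dict[int, list[int]] = {}
        for x in range(len(self.parent)):
            groups.setdefault(self.find(x), []).append(x)
        return list(groups.values())
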