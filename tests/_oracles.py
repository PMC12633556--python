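"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: union-find over explicit neighbor offsets for 3-D
connected components, and an exhaustive nearest-neighbor scan for
leading-edge distances. They share no code with the package.
"""

from __future__ import annotations

import numpy as np


def _neighbor_offsets(spatial: int = 8, temporal_diagonal: bool = True):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dt in (-1, 0, 1):
                if dx == dy == dt == 0:
                    continue
                if spatial == 4 and abs(dx) + abs(dy) > 1:
                    continue
                if dt != 0 and not temporal_diagonal and (dx or dy):
                    continue
                offs.append((dx, dy, dt))
    return offs


def brute_force_components(
    binary: np.ndarray, spatial: int = 8, temporal_diagonal: bool = True,
    min_pixels: int = 1,
) -> list[frozenset]:
    """Connected components of a binary (x, y, t) array via union-find.

    Returns the partition as a list of frozensets of (x, y, t) tuples,
    dropping components smaller than ``min_pixels``.
    """
    active = set(zip(*np.nonzero(binary)))
    parent: dict = {v: v for v in active}

    def find(v):
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:
            parent[v], v = root, parent[v]
        return root

    offs = _neighbor_offsets(spatial, temporal_diagonal)
    for (x, y, t) in active:
        for dx, dy, dt in offs:
            nb = (x + dx, y + dy, t + dt)
            if nb in parent:
                ra, rb = find((x, y, t)), find(nb)
                if ra != rb:
                    parent[ra] = rb
    groups: dict = {}
    for v in active:
        groups.setdefault(find(v), set()).add(v)
    return [frozenset(g) for g in groups.values() if len(g) >= min_pixels]


def partition_of_labels(labels: np.ndarray) -> set[frozenset]:
    """The label matrix as a set of voxel-tuple frozensets (ID-order agnostic)."""
    out: dict = {}
    xs, ys, ts = np.nonzero(labels)
    for x, y, t, k in zip(xs, ys, ts, labels[xs, ys, ts]):
        out.setdefault(int(k), set()).add((int(x), int(y), int(t)))
    return {frozenset(v) for v in out.values()}


def brute_force_edge_distances(prev: np.ndarray, nxt: np.ndarray) -> list[float]:
    """Distances of newly active pixels to the nearest previously active pixel.

    Exhaustive O(n_new * n_prev) scan; the independent check for the
    EDT-based speed measurement.
    """
    prev_pts = np.argwhere(prev)
    new_pts = np.argwhere(nxt & ~prev)
    out = []
    for p in new_pts:
        d2 = ((prev_pts - p) ** 2).sum(axis=1)
        out.append(float(np.sqrt(d2.min())))
    return out
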