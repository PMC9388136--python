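"""Brute-force oracles shared by the test modules.

These deliberately use naive algorithms (image enumeration, label
propagation) independent of the library's implementations.
"""

import numpy as np


def brute_force_minimum_image(dx, box):
    """Enumerate candidate periodic images, pick the smallest norm,
    breaking ties toward the half-open [-L/2, L/2) convention."""
    best = None
    for ix in range(-3, 4):
        for iy in range(-3, 4):
            cand = np.array([dx[0] + ix * box.size_x,
                             dx[1] + iy * box.size_y, dx[2]])
            key = (round(np.linalg.norm(cand), 12), cand[0], cand[1])
            if best is None or key < best[0]:
                best = (key, cand)
    return best[1]


def label_propagation_components(n, edges):
    """Iterate min-label propagation to a fixed point, then group by
    label; returns component sizes, largest first."""
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            m = min(labels[a], labels[b])
            if labels[a] != m or labels[b] != m:
                labels[a] = labels[b] = m
                changed = True
    sizes = {}
    for l in labels:
        sizes[l] = sizes.get(l, 0) + 1
    return sorted(sizes.values(), reverse=True)
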