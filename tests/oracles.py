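"""Independent brute-force oracles used by the tests.

These deliberately avoid the library calls the implementation uses:
morphological closing is a literal max-then-min window sweep, and
connected components are a breadth-first flood fill.
"""

from collections import deque

import numpy as np


def brute_force_close(values: np.ndarray, window: int) -> np.ndarray:
    """Grayscale closing by explicit neighborhood max then min, with
    replicate (edge-value) padding."""
    r = window // 2
    padded = np.pad(values, r, mode="edge")
    h, w = values.shape
    dil = np.empty_like(values)
    for i in range(h):
        for j in range(w):
            dil[i, j] = padded[i : i + window, j : j + window].max()
    padded = np.pad(dil, r, mode="edge")
    out = np.empty_like(values)
    for i in range(h):
        for j in range(w):
            out[i, j] = padded[i : i + window, j : j + window].min()
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a boolean mask via BFS flood fill.

    Returns a list of sets of (row, col) tuples, one per component.
    """
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    elif connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        raise ValueError(connectivity)
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for si in range(h):
        for sj in range(w):
            if not mask[si, sj] or seen[si, sj]:
                continue
            comp = set()
            q = deque([(si, sj)])
            seen[si, sj] = True
            while q:
                i, j = q.popleft()
                comp.add((i, j))
                for di, dj in nbrs:
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        q.append((ni, nj))
            comps.append(comp)
    return comps
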