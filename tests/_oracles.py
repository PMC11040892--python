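"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's own code paths: erosion/dilation as
explicit sliding-window min/max loops, connected components as BFS flood
fill, and the boundary chain traced counterclockwise (the package traces
clockwise) so the two walks share no orientation convention.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def sliding_erode(mask: np.ndarray, k: int) -> np.ndarray:
    """Per-pixel minimum over a k x k window, zero-padded."""
    h, w = mask.shape
    r = k // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            val = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if not (0 <= ii < h and 0 <= jj < w) or not mask[ii, jj]:
                        val = False
                        break
                if not val:
                    break
            out[i, j] = val
    return out


def sliding_dilate(mask: np.ndarray, k: int) -> np.ndarray:
    """Per-pixel maximum over a k x k window, zero-padded."""
    h, w = mask.shape
    r = k // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            val = False
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < h and 0 <= jj < w and mask[ii, jj]:
                        val = True
                        break
                if val:
                    break
            out[i, j] = val
    return out


def flood_fill_components(mask: np.ndarray) -> list[frozenset]:
    """8-connected components as pixel sets, via BFS flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                queue = deque([(i, j)])
                seen[i, j] = True
                while queue:
                    r, c = queue.popleft()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h
                                and 0 <= cc < w
                                and mask[rr, cc]
                                and not seen[rr, cc]
                            ):
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                components.append(frozenset(comp))
    return components


# counterclockwise Moore neighborhood starting west
_CCW = (
    (0, -1), (1, -1), (1, 0), (1, 1),
    (0, 1), (-1, 1), (-1, 0), (-1, -1),
)


def ccw_chain_length(mask: np.ndarray) -> float:
    """Outer boundary chain length by a counterclockwise Moore walk."""
    pts = np.argwhere(mask)
    if pts.shape[0] == 1:
        return 0.0
    padded = np.pad(np.asarray(mask, dtype=bool), 1)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    start = (int(pts[order[0], 0]) + 1, int(pts[order[0], 1]) + 1)

    def advance(p, backtrack):
        rel = (backtrack[0] - p[0], backtrack[1] - p[1])
        k = _CCW.index(rel)
        for j in range(1, 9):
            off = _CCW[(k + j) % 8]
            q = (p[0] + off[0], p[1] + off[1])
            if padded[q]:
                before = _CCW[(k + j - 1) % 8]
                return q, (p[0] + before[0], p[1] + before[1])
        raise AssertionError("unreachable")

    p, bt = start, (start[0], start[1] - 1)
    q, nbt = advance(p, bt)
    first = (p, q)
    length = 0.0
    for _ in range(8 * pts.shape[0] + 8):
        length += math.sqrt(2.0) if abs(q[0] - p[0]) + abs(q[1] - p[1]) == 2 else 1.0
        p, bt = q, nbt
        q, nbt = advance(p, bt)
        if (p, q) == first:
            return length
    raise AssertionError("walk did not close")


def pooled_t_closed_form(a, b):
    """Textbook pooled two-sample t statistic and one-sided p (a > b)."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, float(t_dist.sf(t, na + nb - 2))
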