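"""Independent reference implementations used only by the tests.

Each oracle recomputes a pipeline quantity by a different route (explicit
breadth-first search, brute-force enumeration, textbook formulas) so the
library code is checked against logic that shares none of its internals.
"""

from collections import deque

import numpy as np
from scipy.stats import t as t_dist


def border_flood_fill(edge_mask: np.ndarray) -> np.ndarray:
    """Fill a binary edge map by explicit BFS from the image border.

    A pixel belongs to the filled set iff it is an edge pixel or it cannot
    be reached from the border through non-edge pixels, moving with
    4-connectivity.
    """
    edges = np.asarray(edge_mask, dtype=bool)
    rows, cols = edges.shape
    reachable = np.zeros_like(edges)
    queue = deque()
    for r in range(rows):
        for c in (0, cols - 1):
            if not edges[r, c] and not reachable[r, c]:
                reachable[r, c] = True
                queue.append((r, c))
    for c in range(cols):
        for r in (0, rows - 1):
            if not edges[r, c] and not reachable[r, c]:
                reachable[r, c] = True
                queue.append((r, c))
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols:
                if not edges[rr, cc] and not reachable[rr, cc]:
                    reachable[rr, cc] = True
                    queue.append((rr, cc))
    return ~reachable


def count_at_or_above(channel: np.ndarray, threshold: float) -> int:
    """Brute-force pixel count with an explicit Python loop."""
    n = 0
    for value in np.asarray(channel, dtype=float).ravel():
        if value >= threshold:
            n += 1
    return n


def pooled_t_formula(a, b):
    """Textbook pooled-variance two-sample t test: (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * t_dist.sf(abs(t), df)
    return t, df, p


def otsu_brute_force(values: np.ndarray, bins: int = 256) -> float:
    """Exhaustive between-class-variance maximization over histogram cuts.

    Returns the bin-center threshold maximizing w0*w1*(mu0-mu1)^2, scanning
    every cutpoint of a 256-bin histogram on [0, 1].
    """
    counts, edges = np.histogram(np.asarray(values).ravel(), bins=bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2
    best_score, best_t = -1.0, None
    for cut in range(1, bins):
        w0 = counts[:cut].sum()
        w1 = counts[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:cut] * centers[:cut]).sum() / w0
        mu1 = (counts[cut:] * centers[cut:]).sum() / w1
        score = w0 * w1 * (mu0 - mu1) ** 2
        if score > best_score:
            best_score, best_t = score, centers[cut - 1]
    return best_t
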