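"""Independent brute-force oracles used across the test suite.

These implement the mathematical definitions directly (explicit sliding
windows, flood fill, enumeration) and deliberately share no code with the
package implementation.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def _pad_reflect(img: np.ndarray, r: int) -> np.ndarray:
    # edge-duplicating reflection (a a b c | c b a): the package's convention
    return np.pad(img, r, mode="symmetric")


def flat_opening(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Grayscale opening with a flat structuring element: min filter then max
    filter over the (symmetric) footprint, reflecting boundaries."""
    r = footprint.shape[0] // 2
    offs = [(i - r, j - r) for i, j in np.argwhere(footprint)]
    h, w = img.shape

    def min_filter(a):
        p = _pad_reflect(a, r)
        out = np.empty_like(a, dtype=float)
        for i in range(h):
            for j in range(w):
                out[i, j] = min(p[i + r + di, j + r + dj] for di, dj in offs)
        return out

    def max_filter(a):
        p = _pad_reflect(a, r)
        out = np.empty_like(a, dtype=float)
        for i in range(h):
            for j in range(w):
                out[i, j] = max(p[i + r - di, j + r - dj] for di, dj in offs)
        return out

    return max_filter(min_filter(img.astype(float)))


def white_top_hat(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return img.astype(float) - flat_opening(img, footprint)


def ball_heights(radius: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    d2 = yy * yy + xx * xx
    fp = d2 <= radius * radius
    h = np.where(fp, np.sqrt(np.maximum(radius * radius - d2, 0.0)), 0.0)
    return h, fp


def nonflat_opening(img: np.ndarray, heights: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Grayscale opening with a non-flat element: erosion (min of f − g) then
    dilation (max of f + g), reflecting boundaries."""
    r = footprint.shape[0] // 2
    offs = [(i - r, j - r) for i, j in np.argwhere(footprint)]
    h, w = img.shape

    def erode(a):
        p = _pad_reflect(a, r)
        out = np.empty((h, w))
        for i in range(h):
            for j in range(w):
                out[i, j] = min(
                    p[i + r + di, j + r + dj] - heights[di + r, dj + r] for di, dj in offs
                )
        return out

    def dilate(a):
        p = _pad_reflect(a, r)
        out = np.empty((h, w))
        for i in range(h):
            for j in range(w):
                out[i, j] = max(
                    p[i + r - di, j + r - dj] + heights[di + r, dj + r] for di, dj in offs
                )
        return out

    return dilate(erode(img.astype(float)))


def rolling_ball_subtract(img: np.ndarray, radius: int) -> np.ndarray:
    h, fp = ball_heights(radius)
    bg = nonflat_opening(img, h, fp)
    return np.clip(img.astype(float) - bg, 0.0, 255.0)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[int]:
    """Connected-component sizes by BFS flood fill; returns sorted sizes."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    sizes = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                q = deque([(i, j)])
                seen[i, j] = True
                size = 0
                while q:
                    a, b = q.popleft()
                    size += 1
                    for di, dj in neigh:
                        x, y = a + di, b + dj
                        if 0 <= x < h and 0 <= y < w and mask[x, y] and not seen[x, y]:
                            seen[x, y] = True
                            q.append((x, y))
                sizes.append(size)
    return sorted(sizes)


def otsu_exhaustive(img: np.ndarray) -> int:
    """Otsu by explicit search over the 255 candidate splits of a 256-bin
    histogram; first (lowest) maximizer wins."""
    vals = np.clip(np.floor(np.asarray(img, dtype=float)), 0, 255).astype(int).ravel()
    hist = [0] * 256
    for v in vals:
        hist[v] += 1
    total = len(vals)
    best_t, best_var = 0, -1.0
    for t in range(255):
        n0 = sum(hist[: t + 1])
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = sum(v * hist[v] for v in range(t + 1)) / n0
        mu1 = sum(v * hist[v] for v in range(t + 1, 256)) / n1
        var = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def midranks(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def mann_whitney_exact_p(a, b) -> float:
    """Two-sided exact Mann–Whitney p by enumerating rank-sum assignments."""
    a, b = list(a), list(b)
    pooled = np.array(a + b, dtype=float)
    ranks = midranks(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    ws = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n_a)]
    ws = np.array(ws)
    eps = 1e-9
    p = 2.0 * min((ws <= w_obs + eps).mean(), (ws >= w_obs - eps).mean())
    return min(float(p), 1.0)


def friedman_permutation_p(data: np.ndarray, n_perm: int, seed: int) -> float:
    """Permutation p for the Friedman statistic: permute within rows."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape

    def statistic(d):
        ranks = np.array([midranks(row) for row in d])
        rj = ranks.sum(axis=0)
        ss = ((rj - n * (k + 1) / 2.0) ** 2).sum()
        chi = 12.0 / (n * k * (k + 1)) * ss
        # tie correction
        c = 0.0
        for row in d:
            _, counts = np.unique(row, return_counts=True)
            c += (counts**3 - counts).sum()
        denom = 1.0 - c / (n * k * (k * k - 1))
        return chi / denom if denom > 0 else 0.0

    obs = statistic(data)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = np.array([row[rng.permutation(k)] for row in data])
        if statistic(perm) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
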