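"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (per-pixel loops, exhaustive
enumeration) and shares no code with the package implementation paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_otsu_threshold(img: np.ndarray) -> int:
    """Exhaustive 0-255 search for the max between-class-variance split."""
    hist = np.bincount(img.astype(np.uint8).ravel(), minlength=256).astype(float)
    total = hist.sum()
    levels = np.arange(256)
    best_var, best_t = -1.0, 0
    for t in range(256):
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (levels[: t + 1] * hist[: t + 1]).sum() / w0
        m1 = (levels[t + 1 :] * hist[t + 1 :]).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def naive_zhang_suen(mask: np.ndarray) -> np.ndarray:
    """Per-pixel loop implementation of parallel two-subiteration thinning."""
    img = mask.astype(np.uint8).copy()
    h, w = img.shape

    def neigh(r, c):
        def g(rr, cc):
            return int(img[rr, cc]) if 0 <= rr < h and 0 <= cc < w else 0

        return [
            g(r - 1, c), g(r - 1, c + 1), g(r, c + 1), g(r + 1, c + 1),
            g(r + 1, c), g(r + 1, c - 1), g(r, c - 1), g(r - 1, c - 1),
        ]

    while True:
        changed = False
        for step in (0, 1):
            to_delete = []
            for r in range(h):
                for c in range(w):
                    if not img[r, c]:
                        continue
                    n = neigh(r, c)
                    b = sum(n)
                    if not 2 <= b <= 6:
                        continue
                    seq = n + [n[0]]
                    a = sum(
                        1 for k in range(8) if seq[k] == 0 and seq[k + 1] == 1
                    )
                    if a != 1:
                        continue
                    p2, p4, p6, p8 = n[0], n[2], n[4], n[6]
                    if step == 0:
                        if p2 * p4 * p6 or p4 * p6 * p8:
                            continue
                    else:
                        if p2 * p4 * p8 or p2 * p6 * p8:
                            continue
                    to_delete.append((r, c))
            for r, c in to_delete:
                img[r, c] = 0
            changed = changed or bool(to_delete)
        if not changed:
            return img.astype(bool)


def brute_ladder(mask: np.ndarray, spacing: int, strip: int) -> np.ndarray:
    """Column-by-column majority vote over the clipped strip."""
    h, w = mask.shape
    half = strip // 2
    out = np.zeros_like(mask, dtype=bool)
    for r in range(spacing, h, spacing):
        for c in range(w):
            votes = 0
            avail = 0
            for dr in range(-half, half + 1):
                if 0 <= r + dr < h:
                    avail += 1
                    votes += int(mask[r + dr, c])
            out[r, c] = votes * 2 > avail
    return out


def auc_pair_counting(scores_pos_class, labels_binary) -> float:
    """AUC as the concordant-pair fraction (ties count 1/2)."""
    s = np.asarray(scores_pos_class, float)
    y = np.asarray(labels_binary, int)  # 1 = positive
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def wilcoxon_enumeration(a, b) -> float:
    """Exact two-sided p over all sign patterns (zeros dropped, midranks)."""
    from scipy.stats import rankdata

    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for s, r in zip(signs, ranks) if s)
        if min(wp, ranks.sum() - wp) <= w_obs + 1e-9:
            count += 1
    return count / 2**n


def draw_capsule_mask(mask: np.ndarray, p0, p1, radius: float) -> None:
    """Set True every pixel within ``radius`` of the segment p0-p1."""
    h, w = mask.shape
    ys, xs = np.mgrid[0:h, 0:w]
    d = (p1[0] - p0[0], p1[1] - p0[1])
    l2 = d[0] ** 2 + d[1] ** 2
    t = np.clip(((ys - p0[0]) * d[0] + (xs - p0[1]) * d[1]) / l2, 0, 1)
    dist = np.hypot(ys - (p0[0] + t * d[0]), xs - (p0[1] + t * d[1]))
    mask[dist <= radius] = True
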