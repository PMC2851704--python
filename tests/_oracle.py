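"""Independent brute-force implementations used as test oracles.

Deliberately written with plain Python loops and no shared code with the
package, so they can serve as an independent check of the inverse-variance
formulas.
"""

from __future__ import annotations

import math


def brute_fixed(ys: list[float], ses: list[float]) -> dict:
    """Fixed-effect pooling by explicit summation."""
    ws = [1.0 / s**2 for s in ses]
    sw = 0.0
    swy = 0.0
    for w, y in zip(ws, ys):
        sw += w
        swy += w * y
    y_pool = swy / sw
    q = 0.0
    for w, y in zip(ws, ys):
        q += w * (y - y_pool) ** 2
    return {
        "y": y_pool,
        "se": 1.0 / math.sqrt(sw),
        "weights": [w / sw for w in ws],
        "Q": q,
    }


def brute_dl(ys: list[float], ses: list[float]) -> dict:
    """DerSimonian-Laird pooling by explicit summation."""
    fixed = brute_fixed(ys, ses)
    k = len(ys)
    ws = [1.0 / s**2 for s in ses]
    sw = sum(ws)
    sw2 = sum(w * w for w in ws)
    c = sw - sw2 / sw
    tau2 = max(0.0, (fixed["Q"] - (k - 1)) / c) if c > 0 else 0.0
    wstar = [1.0 / (s**2 + tau2) for s in ses]
    sws = sum(wstar)
    y_pool = sum(w * y for w, y in zip(wstar, ys)) / sws
    return {
        "y": y_pool,
        "se": 1.0 / math.sqrt(sws),
        "weights": [w / sws for w in wstar],
        "tau2": tau2,
        "Q": fixed["Q"],
        "C": c,
    }


def brute_spearman(xs: list[float], ys: list[float]) -> float:
    """Pearson correlation applied to mid-ranks, coded from scratch."""

    def midranks(values: list[float]) -> list[float]:
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            mid = (i + j) / 2 + 1
            for t in range(i, j + 1):
                ranks[order[t]] = mid
            i = j + 1
        return ranks

    rx, ry = midranks(xs), midranks(ys)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = math.sqrt(sum((a - mx) ** 2 for a in rx))
    dy = math.sqrt(sum((b - my) ** 2 for b in ry))
    return num / (dx * dy)
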