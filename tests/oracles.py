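"""Slow, independent brute-force oracles used by the test suite."""

import numpy as np


def li_oracle(counts):
    """Minimise the full cross-entropy sum over all 256 thresholds."""
    counts = np.asarray(counts, float)
    best_t, best = None, np.inf
    for t in range(256):
        lo = [(g, counts[g]) for g in range(0, t + 1) if counts[g] > 0]
        hi = [(g, counts[g]) for g in range(t + 1, 256) if counts[g] > 0]
        if not lo or not hi:
            continue
        mu0 = sum(g * h for g, h in lo) / sum(h for _, h in lo)
        mu1 = sum(g * h for g, h in hi) / sum(h for _, h in hi)
        eta = 0.0
        for g, h in lo:
            if g > 0:
                eta += h * g * np.log(g / mu0)
        for g, h in hi:
            eta += h * g * np.log(g / mu1)
        if eta < best:
            best, best_t = eta, t
    return best_t


def triangle_oracle(counts):
    """Maximise the point-to-chord distance with explicit 2-D geometry."""
    counts = np.asarray(counts, float)
    nz = np.flatnonzero(counts)
    if nz.size == 0:
        return None
    peak = int(np.argmax(counts))
    first, last = int(nz[0]), int(nz[-1])
    end = last if last > peak else (first if first < peak else None)
    if end is None:
        return None
    span = end - peak
    p1 = np.array([0.0, 1.0])
    p2 = np.array([1.0, counts[end] / counts[peak]])
    seg = p2 - p1
    best_t, best = None, -1.0
    step = 1 if span > 0 else -1
    for b in range(peak, end + step, step):
        q = np.array([(b - peak) / span, counts[b] / counts[peak]])
        cross = abs(seg[0] * (q[1] - p1[1]) - seg[1] * (q[0] - p1[0]))
        d = cross / np.hypot(*seg)
        if d > best + 1e-15:
            best, best_t = d, b
    return best_t


def random_histograms(n, seed):
    """Assorted 256-bin histograms: bimodal, decaying and sparse shapes."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        kind = rng.integers(3)
        if kind == 0:
            h = np.zeros(256)
            for centre, spread, mass in ((rng.integers(5, 80), rng.integers(3, 20),
                                          rng.integers(500, 5000)),
                                         (rng.integers(120, 250), rng.integers(3, 30),
                                          rng.integers(50, 2000))):
                g = np.clip(rng.normal(centre, spread, mass), 0, 255).astype(int)
                h += np.bincount(g, minlength=256)
        elif kind == 1:
            h = rng.poisson(np.maximum(
                1e-9, 2000 * np.exp(-np.arange(256) / rng.uniform(10, 60))))
        else:
            h = np.zeros(256)
            idx = rng.choice(256, size=rng.integers(5, 40), replace=False)
            h[idx] = rng.integers(1, 1000, idx.size)
        out.append(h.astype(float))
    return out
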