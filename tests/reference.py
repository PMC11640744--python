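"""Naive reference implementations used as independent test oracles.

Everything here is written as plain per-timepoint / per-element Python
loops, deliberately sharing no code with the vectorized package paths.
"""

import numpy as np


def naive_bundle(data, distance_mode="absolute", epsilon=1e-10):
    """One-timepoint-at-a-time ChMinMaxPat feature bundle (15 vectors)."""
    data = np.asarray(data, dtype=float)
    L, nc = data.shape
    tts = [np.zeros((nc, nc)) for _ in range(6)]
    maps = [[] for _ in range(6)]
    for i in range(L):
        vec = data[i]
        av = sum(vec) / nc
        dist = [v - av for v in vec]
        if distance_mode == "absolute":
            dist = [abs(d) for d in dist]
        id1 = max(range(nc), key=lambda j: (vec[j], -j)) + 1
        id2 = min(range(nc), key=lambda j: (vec[j], j)) + 1
        id3 = max(range(nc), key=lambda j: (dist[j], -j)) + 1
        id4 = min(range(nc), key=lambda j: (dist[j], j)) + 1
        pairs = [(id1, id2), (id1, id3), (id1, id4), (id2, id3), (id2, id4), (id3, id4)]
        for k, (a, b) in enumerate(pairs):
            tts[k][a - 1, b - 1] += 1
            maps[k].append((a - 1) * nc + (b - 1))
    fvs = []
    for k in range(6):
        rows = []
        for a in range(nc):
            s = sum(tts[k][a])
            rows.extend(tts[k][a, b] / (s + epsilon) for b in range(nc))
        fvs.append(np.array(rows))
    fv7 = np.concatenate(fvs)
    hists = []
    for k in range(6):
        h = np.zeros(nc * nc)
        for v in maps[k]:
            h[v] += 1
        hists.append(h)
    fv14 = np.concatenate(hists)
    fv15 = np.concatenate([fv7, fv14])
    return fvs + [fv7] + hists + [fv14, fv15]


def naive_nca_objective(w, X, y, sigma=1.0, lam=0.0):
    """Leave-one-out NCA objective via explicit loops."""
    n, nfeat = X.shape
    obj = 0.0
    for i in range(n):
        kern = []
        for j in range(n):
            if j == i:
                kern.append(0.0)
                continue
            d = sum(w[f] ** 2 * abs(X[i, f] - X[j, f]) for f in range(nfeat)) / sigma
            kern.append(np.exp(-d))
        denom = sum(kern)
        if denom == 0:
            continue
        obj += sum(kern[j] for j in range(n) if y[j] == y[i] and j != i) / denom
    return obj - lam * sum(v * v for v in w)


def naive_mode_votes(pred_matrix, lo, hi):
    """Per-position majority tally; ties go to the lower label."""
    voters, n = pred_matrix.shape
    out = []
    for pos in range(n):
        c_lo = sum(1 for v in range(voters) if pred_matrix[v, pos] == lo)
        c_hi = voters - c_lo
        out.append(lo if c_lo >= c_hi else hi)
    return np.array(out)
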