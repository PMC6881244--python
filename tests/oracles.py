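"""Independent brute-force reference implementations used as oracles.

Everything here is written as literal, loop-based enumeration of the
defining formulas, deliberately sharing no code path with the package
implementation it checks.
"""

import numpy as np

ANGLE_STEPS = {0: (0, 1), 45: (1, 1), 90: (1, 0), 135: (1, -1)}


def brute_glcm(levels: np.ndarray, G: int, offset: int, angle: int):
    """Symmetric normalized GLCM by enumerating every voxel and its
    displaced partner within the same slice."""
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * offset, dc * offset
    nr, nc, ns = levels.shape
    counts = np.zeros((G, G))
    for z in range(ns):
        for r in range(nr):
            for c in range(nc):
                a = levels[r, c, z]
                if a == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < nr and 0 <= c2 < nc:
                    b = levels[r2, c2, z]
                    if b != 0:
                        counts[a - 1, b - 1] += 1
                        counts[b - 1, a - 1] += 1
    total = counts.sum()
    if total == 0:
        return None
    return counts / total


def brute_glcm_features(P: np.ndarray) -> dict:
    """Literal per-cell summation of the eight base GLCM statistics."""
    G = P.shape[0]
    energy = entropy = inertia = idm = shade = prom = 0.0
    mu = 0.0
    px = P.sum(axis=1)
    for i in range(G):
        mu += (i + 1) * px[i]
    var = 0.0
    for i in range(G):
        var += (i + 1 - mu) ** 2 * px[i]
    cov = 0.0
    for i in range(G):
        for j in range(G):
            p = P[i, j]
            energy += p * p
            if p > 0:
                entropy -= p * np.log2(p)
            inertia += (i - j) ** 2 * p
            idm += p / (1.0 + (i - j) ** 2)
            s = (i + 1) + (j + 1) - 2 * mu
            shade += s**3 * p
            prom += s**4 * p
            cov += (i + 1) * (j + 1) * p
    cov -= mu * mu
    return {
        "GLCMEnergy": energy,
        "GLCMEntropy": entropy,
        "Inertia": inertia,
        "Correlation": cov / var if var > 0 else 0.0,
        "Inverse Difference Moment": idm,
        "Cluster Shade": shade,
        "Cluster Prominence": prom,
        "Haralick Correlation": cov,
    }


def brute_rlm(levels: np.ndarray, G: int, offset: int, angle: int):
    """Run-length counts by finding, for every voxel, the maximal
    stride run that starts at it (a run starts where the predecessor
    at the stride is off-grid, out of mask, or a different level)."""
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * offset, dc * offset
    nr, nc, ns = levels.shape
    runs = {}
    for z in range(ns):
        for r in range(nr):
            for c in range(nc):
                lev = levels[r, c, z]
                if lev == 0:
                    continue
                pr, pc = r - dr, c - dc
                if 0 <= pr < nr and 0 <= pc < nc and levels[pr, pc, z] == lev:
                    continue  # not a run start
                length = 1
                rr, cc = r + dr, c + dc
                while 0 <= rr < nr and 0 <= cc < nc and \
                        levels[rr, cc, z] == lev:
                    length += 1
                    rr += dr
                    cc += dc
                runs[(lev, length)] = runs.get((lev, length), 0) + 1
    if not runs:
        return None, 0
    R = max(ln for _, ln in runs)
    counts = np.zeros((G, R))
    for (lev, ln), k in runs.items():
        counts[lev - 1, ln - 1] = k
    return counts, int(sum(runs.values()))


def brute_rlm_features(counts: np.ndarray, n_runs: int) -> dict:
    """Literal double-sum recomputation of the ten RLM statistics."""
    G, R = counts.shape
    acc = {k: 0.0 for k in [
        "Short Run Emphasis", "Long Run Emphasis",
        "Low Gray Level Run Emphasis", "High Gray Level Run Emphasis",
        "Short Run Low Gray Level Emphasis",
        "Short Run High Gray Level Emphasis",
        "Long Run Low Gray Level Emphasis",
        "Long Run High Gray Level Emphasis"]}
    gln = rln = 0.0
    for i in range(1, G + 1):
        row = 0.0
        for ell in range(1, R + 1):
            r = counts[i - 1, ell - 1]
            row += r
            acc["Short Run Emphasis"] += r / ell**2
            acc["Long Run Emphasis"] += r * ell**2
            acc["Low Gray Level Run Emphasis"] += r / i**2
            acc["High Gray Level Run Emphasis"] += r * i**2
            acc["Short Run Low Gray Level Emphasis"] += r / (i**2 * ell**2)
            acc["Short Run High Gray Level Emphasis"] += r * i**2 / ell**2
            acc["Long Run Low Gray Level Emphasis"] += r * ell**2 / i**2
            acc["Long Run High Gray Level Emphasis"] += r * i**2 * ell**2
        gln += row**2
    for ell in range(1, R + 1):
        col = 0.0
        for i in range(1, G + 1):
            col += counts[i - 1, ell - 1]
        rln += col**2
    out = {k: v / n_runs for k, v in acc.items()}
    out["Gray Level Nonuniformity"] = gln / n_runs
    out["Run Length Nonuniformity"] = rln / n_runs
    return out


def brute_haralick(P: np.ndarray) -> dict:
    """Literal recomputation of the sum/difference statistics."""
    G = P.shape[0]
    psum = {}
    pdiff = {}
    for i in range(1, G + 1):
        for j in range(1, G + 1):
            p = P[i - 1, j - 1]
            psum[i + j] = psum.get(i + j, 0.0) + p
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p
    sa = sum(k * v for k, v in psum.items())
    da = sum(k * v for k, v in pdiff.items())
    se = -sum(v * np.log2(v) for v in psum.values() if v > 0)
    de = -sum(v * np.log2(v) for v in pdiff.values() if v > 0)
    sv = sum((k - sa) ** 2 * v for k, v in psum.items())
    dv = sum((k - da) ** 2 * v for k, v in pdiff.items())
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    hxy = -sum(p * np.log2(p) for p in P.ravel() if p > 0)
    hxy1 = -sum(P[i, j] * np.log2(px[i] * py[j])
                for i in range(G) for j in range(G)
                if P[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * np.log2(px[i] * py[j])
                for i in range(G) for j in range(G) if px[i] * py[j] > 0)
    hx = -sum(p * np.log2(p) for p in px if p > 0)
    ac = sum((i + 1) * (j + 1) * P[i, j]
             for i in range(G) for j in range(G))
    return {
        "Haralick Sum Average": sa,
        "Haralick Sum Entropy": se,
        "Haralick Sum Variance": sv,
        "Haralick Difference Average": da,
        "Haralick Difference Entropy": de,
        "Haralick Difference Variance": dv,
        "Haralick Information Measure 1":
            (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Haralick Information Measure 2":
            float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "Haralick Autocorrelation": ac,
        "Haralick Maximum Probability": float(P.max()),
    }


def brute_uniformity(x: np.ndarray, G: int) -> float:
    """Sum of squared histogram probabilities, by explicit binning."""
    x = np.asarray(x, float).ravel()
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return 1.0
    counts = [0] * G
    for v in x:
        b = int((v - lo) / (hi - lo) * G)
        counts[min(b, G - 1)] += 1
    n = len(x)
    return sum((c / n) ** 2 for c in counts)
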