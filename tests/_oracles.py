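"""Independent brute-force oracles used by the tests.

Everything here is deliberately written from first principles (explicit
loops, closed forms) and must stay independent of the pocketdyn
implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def kabsch_oracle(mobile: np.ndarray, reference: np.ndarray):
    """Textbook Kabsch: optimal proper rotation + translation and RMSD."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    P = mobile - mc
    Q = reference - rc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    fitted = P @ R.T + rc
    rmsd = np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1)))
    return R, rc - R @ mc, float(rmsd)


def rmsd_oracle(a: np.ndarray, b: np.ndarray) -> float:
    total = 0.0
    for p, q in zip(a, b):
        total += sum((p[i] - q[i]) ** 2 for i in range(3))
    return float(np.sqrt(total / len(a)))


def covariance_oracle(X: np.ndarray) -> np.ndarray:
    """Double-loop population covariance."""
    m, d = X.shape
    mean = X.mean(axis=0)
    C = np.zeros((d, d))
    for row in X:
        dev = row - mean
        C += np.outer(dev, dev)
    return C / m


def rmsf_oracle(X: np.ndarray) -> np.ndarray:
    """Per-atom RMSF by explicit loop; X is (M, 3N)."""
    m = len(X)
    n = X.shape[1] // 3
    mean = X.mean(axis=0)
    out = np.zeros(n)
    for a in range(n):
        s = 0.0
        for row in X:
            dx = row[3 * a : 3 * a + 3] - mean[3 * a : 3 * a + 3]
            s += dx @ dx
        out[a] = np.sqrt(s / m)
    return out


def fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def dense_occlusion_fraction(
    point: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    max_length: float = 10.0,
    n_directions: int = 2000,
) -> float:
    """Fraction of dense ray directions whose finite segment passes within
    an atom's vdW radius of that atom's centre."""
    dirs = fibonacci_directions(n_directions)
    hit = 0
    diff = centers - point
    d2_all = (diff * diff).sum(axis=1)
    for u in dirs:
        t = np.clip(diff @ u, 0.0, max_length)
        d2 = d2_all - 2.0 * t * (diff @ u) + t * t
        if np.any(d2 <= radii**2):
            hit += 1
    return hit / n_directions


def neighbor_count_oracle(lattice: np.ndarray, mask: np.ndarray, connectivity=26):
    """Double-loop lattice-neighbour count."""
    counts = np.zeros(len(lattice), dtype=int)
    for i, p in enumerate(lattice):
        for j, q in enumerate(lattice):
            if i == j or not mask[j]:
                continue
            d = np.abs(p - q)
            if connectivity == 26:
                adjacent = d.max() == 1
            else:
                adjacent = d.sum() == 1 and d.max() == 1
            if adjacent:
                counts[i] += 1
    return counts


def hotspot_oracle(lattice, buried, favor, fraction=0.25, support_quota=4):
    """Brute-force quarter-of-best candidate rule + neighbour support."""
    buried = np.asarray(buried, dtype=bool)
    favor = np.asarray(favor, dtype=float)
    if not buried.any():
        z = np.zeros(len(lattice), dtype=bool)
        return z, z
    fmax = favor[buried].max()
    candidate = buried & (favor >= fraction * fmax)
    support = neighbor_count_oracle(np.asarray(lattice), candidate)
    hotspot = candidate & (support > support_quota)
    return candidate, hotspot


def boost_limit_oracle(e_b: float, alpha: float, v: float) -> float:
    """Deep-well asymptote of the boost: dV -> (E_b - V) - alpha."""
    return (e_b - v) - alpha
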