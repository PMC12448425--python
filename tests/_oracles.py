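"""Independent reference implementations used only by the tests.

Each oracle recomputes a quantity by a different route than the package
(brute-force enumeration, closed forms, plain loops) so agreement is a
real check, not a tautology.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def divergence_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of a closed mesh via a plain per-triangle loop of
    the divergence theorem (V = |sum det(a, b, c)| / 6)."""
    total = 0.0
    for i, j, k in faces:
        a, b, c = vertices[i], vertices[j], vertices[k]
        total += (
            a[0] * (b[1] * c[2] - b[2] * c[1])
            - a[1] * (b[0] * c[2] - b[2] * c[0])
            + a[2] * (b[0] * c[1] - b[1] * c[0])
        )
    return abs(total) / 6.0


def triangle_area_sum(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Surface area by per-triangle Heron's formula (no cross products)."""
    total = 0.0
    for i, j, k in faces:
        a = np.linalg.norm(vertices[j] - vertices[i])
        b = np.linalg.norm(vertices[k] - vertices[j])
        c = np.linalg.norm(vertices[i] - vertices[k])
        s = (a + b + c) / 2.0
        total += math.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0))
    return total


def mann_whitney_exact_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments
    of the pooled sample (requires no ties)."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1.0 for x in group_a for y in group_b if x > y) + 0.5 * sum(
            1 for x in group_a for y in group_b if x == y
        )

    u_obs = u_stat(a, b)
    n_ab = n_a * len(b)
    # two-sided: arrangements at least as extreme in either tail
    dev_obs = abs(u_obs - n_ab / 2.0)
    count = 0
    total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, n_a):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        if abs(u_stat(ga, gb) - n_ab / 2.0) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def spearman_no_ties(x, y) -> float:
    """Spearman rho by the classic d^2 formula (valid without ties)."""
    x, y = np.asarray(x), np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = float(((rx - ry) ** 2).sum())
    n = len(x)
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def kruskal_h_no_ties(groups) -> float:
    """Kruskal-Wallis H by direct rank sums (valid without ties)."""
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n_total = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    return 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)


def ols(X, y):
    """Plain least squares via the normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def spheroid_area_quadrature(polar: float, equatorial: float, n: int = 20000) -> float:
    """Spheroid area by surface-of-revolution quadrature in the polar
    angle: A = 2 pi b int_0^pi sin(t) sqrt(a^2 sin^2 t + b^2 cos^2 t) dt."""
    a, b = polar, equatorial
    t = np.linspace(0.0, math.pi, n + 1)
    integrand = 2.0 * math.pi * b * np.sin(t) * np.sqrt(
        a**2 * np.sin(t) ** 2 + b**2 * np.cos(t) ** 2
    )
    return float(np.trapezoid(integrand, t))
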