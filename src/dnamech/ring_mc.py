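"""Monte Carlo of closed wormlike rings: writhe fluctuation statistics.

This is the simulation behind the empirical writhe-variance curve frozen in
:func:`dnamech.wlc_model.writhe_variance`.  A closed ring of N straight
segments with discrete-WLC bending energy E/kT = (P/h) sum_i (1 - cos
theta_i) is sampled by crankshaft Metropolis moves; the writhe of each
polygon is evaluated with the exact pairwise Gauss-integral formula for
straight segments.  Linking-number statistics of small DNA circles need
only the variance of this distribution (mean zero by achirality of the
bending ensemble).

Run ``scripts/calibrate_writhe.py`` to regenerate the calibration grid.
"""
from __future__ import annotations

import numpy as np

__all__ = ["polygon_writhe", "ring_writhe_variance"]


def polygon_writhe(points: np.ndarray) -> float:
    """Exact writhe of a closed polygon from its vertices, shape (N, 3).

    Sums the Gauss integral over all non-adjacent segment pairs using the
    closed-form solid-angle expression for straight segments.
    """
    n = len(points)
    starts = points
    ends = np.roll(points, -1, axis=0)
    ii, jj = np.triu_indices(n, k=2)
    keep = ~((ii == 0) & (jj == n - 1))  # wrap-around adjacency
    ii, jj = ii[keep], jj[keep]
    p1, p2 = starts[ii], ends[ii]
    p3, p4 = starts[jj], ends[jj]
    r13, r14 = p3 - p1, p4 - p1
    r23, r24 = p3 - p2, p4 - p2
    r34, r12 = p4 - p3, p2 - p1

    def unit(v):
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return v / norm

    n1 = unit(np.cross(r13, r14))
    n2 = unit(np.cross(r14, r24))
    n3 = unit(np.cross(r24, r23))
    n4 = unit(np.cross(r23, r13))

    def asin_dot(a, b):
        return np.arcsin(np.clip(np.sum(a * b, axis=1), -1.0, 1.0))

    omega = (asin_dot(n1, n2) + asin_dot(n2, n3)
             + asin_dot(n3, n4) + asin_dot(n4, n1))
    sign = np.sign(np.sum(np.cross(r34, r12) * r13, axis=1))
    return float(np.sum(omega * sign) / (2.0 * np.pi))


def _bend_energy_at(points, k, g):
    n = len(points)
    a = points[k] - points[(k - 1) % n]
    b = points[(k + 1) % n] - points[k]
    c = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return g * (1.0 - c)


def ring_writhe_variance(
    l_over_p: float,
    n_segments: int = 64,
    n_samples: int = 2000,
    seed: int = 0,
    moves_per_sample: int | None = None,
    max_rotation_rad: float = 1.0,
) -> tuple[float, float]:
    """Estimate <Wr^2> (turns^2) for a closed WLC ring of reduced length L/P.

    Crankshaft moves rotate a random sub-chain about the chord through two
    vertices; only the two hinge angles change energy.  Returns the
    variance estimate and a rough standard error (autocorrelation-inflated).
    """
    if l_over_p <= 0:
        raise ValueError("reduced length must be positive")
    rng = np.random.default_rng(seed)
    n = n_segments
    g = n / l_over_p  # P/h with segment length h = 1
    if moves_per_sample is None:
        moves_per_sample = 2 * n
    theta = 2 * np.pi * np.arange(n) / n
    radius = 1.0 / (2 * np.sin(np.pi / n))
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)])

    def crank(pts):
        i = rng.integers(0, n)
        m = rng.integers(2, n - 1)
        j = (i + m) % n
        axis = pts[j] - pts[i]
        axis = axis / np.linalg.norm(axis)
        ang = rng.uniform(-max_rotation_rad, max_rotation_rad)
        idx = [(i + k) % n for k in range(1, m)]
        e_old = _bend_energy_at(pts, i, g) + _bend_energy_at(pts, j, g)
        sub = pts[idx] - pts[i]
        ca, sa = np.cos(ang), np.sin(ang)
        rot = sub * ca + np.cross(axis, sub) * sa + np.outer(sub @ axis, axis) * (1 - ca)
        new = pts.copy()
        new[idx] = rot + pts[i]
        e_new = _bend_energy_at(new, i, g) + _bend_energy_at(new, j, g)
        if e_new - e_old < 0 or rng.random() < np.exp(-(e_new - e_old)):
            return new
        return pts

    for _ in range(40 * n):  # equilibration
        pts = crank(pts)
    wr2 = np.empty(n_samples)
    for s in range(n_samples):
        for _ in range(moves_per_sample):
            pts = crank(pts)
        wr2[s] = polygon_writhe(pts) ** 2
    return float(wr2.mean()), float(wr2.std() / np.sqrt(n_samples / 20.0))
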