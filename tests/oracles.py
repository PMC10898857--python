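"""Independent brute-force oracles used to cross-check the implementation.

Each oracle takes a deliberately different computational route from the code
it checks: numerical quadrature instead of closed-form segment sums for the
Fourier coefficients, covariance eigendecomposition instead of SVD for PCA,
direct vector-space sums of squares instead of distance-matrix partitions
for PERMANOVA.
"""

from __future__ import annotations

import numpy as np


def efa_quadrature(points: np.ndarray, n_harmonics: int,
                   parameterization: str = "chord", gl_order: int = 12):
    """Elliptical Fourier coefficients by per-segment Gauss-Legendre
    quadrature of (2/T) * integral of x(t) {cos, sin}(2 pi n t / T) dt for a
    piecewise-linear closed contour.

    Returns (harmonics (n, 4) as (a, b, c, d), (A0, C0)).
    """
    pts = np.asarray(points, float)
    seg = np.diff(pts, axis=0)
    chord = np.hypot(seg[:, 0], seg[:, 1])
    keep = chord > 0
    seg, pts0 = seg[keep], pts[:-1][keep]
    if parameterization == "chord":
        dt = chord[keep]
    else:
        dt = np.ones(len(seg))
    t1 = np.concatenate([[0.0], np.cumsum(dt)])
    T = t1[-1]

    nodes, weights = np.polynomial.legendre.leggauss(gl_order)
    # map nodes from [-1, 1] into each segment
    t_nodes = t1[:-1, None] + (nodes[None, :] + 1.0) / 2.0 * dt[:, None]
    half_w = weights[None, :] * dt[:, None] / 2.0
    # linear interpolation of x, y at the quadrature nodes
    frac = (t_nodes - t1[:-1, None]) / dt[:, None]
    x_nodes = pts0[:, 0, None] + frac * seg[:, 0, None]
    y_nodes = pts0[:, 1, None] + frac * seg[:, 1, None]

    harmonics = np.zeros((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        ang = 2.0 * np.pi * n * t_nodes / T
        cosv, sinv = np.cos(ang), np.sin(ang)
        harmonics[n - 1, 0] = (2.0 / T) * np.sum(half_w * x_nodes * cosv)
        harmonics[n - 1, 1] = (2.0 / T) * np.sum(half_w * x_nodes * sinv)
        harmonics[n - 1, 2] = (2.0 / T) * np.sum(half_w * y_nodes * cosv)
        harmonics[n - 1, 3] = (2.0 / T) * np.sum(half_w * y_nodes * sinv)
    A0 = np.sum(half_w * x_nodes) / T
    C0 = np.sum(half_w * y_nodes) / T
    return harmonics, (float(A0), float(C0))


def pca_covariance(X: np.ndarray):
    """PCA via eigendecomposition of the population covariance matrix.

    Returns (mean, loadings rows sorted by decreasing eigenvalue,
    eigenvalues)."""
    X = np.asarray(X, float)
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return mean, evecs[:, order].T, np.maximum(evals[order], 0.0)


def oneway_permanova_f(D: np.ndarray, groups) -> float:
    """One-way PERMANOVA pseudo-F from a distance matrix, computed from the
    Gower-centered inner-product matrix trace identities."""
    D = np.asarray(D, float)
    groups = np.asarray(groups)
    N = len(D)
    G = -0.5 * D**2
    J = np.eye(N) - np.ones((N, N)) / N
    Gc = J @ G @ J
    uniq = sorted(set(groups), key=str)
    H = np.zeros((N, N))
    for g in uniq:
        m = groups == g
        H[np.ix_(m, m)] = 1.0 / m.sum()
    ss_total = np.trace(Gc)
    ss_among = np.trace(H @ Gc)
    ss_within = ss_total - ss_among
    a, n = len(uniq), N
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def nested_ss_from_vectors(X: np.ndarray, community, potter):
    """Nested sums of squares computed directly in vector space (valid when
    the distance is Euclidean on X): total / community / potter-within /
    residual from group means."""
    X = np.asarray(X, float)
    community = np.asarray(community)
    potter = np.asarray(potter)
    grand = X.mean(axis=0)
    ss_total = np.sum((X - grand) ** 2)
    ss_comm = 0.0
    ss_resid = 0.0
    for c in set(community):
        mc = community == c
        cm = X[mc].mean(axis=0)
        ss_comm += mc.sum() * np.sum((cm - grand) ** 2)
    for p in set(potter):
        mp = potter == p
        pm = X[mp].mean(axis=0)
        ss_resid += np.sum((X[mp] - pm) ** 2)
    ss_potter = ss_total - ss_comm - ss_resid
    return ss_total, ss_comm, ss_potter, ss_resid


def cross_projection_ratio(XA: np.ndarray, XB: np.ndarray, k: int = 3) -> float:
    """Brute-force V2/V1: project A's centered data onto B's top-k axes and
    take the variance ratio (all steps spelled out independently)."""
    XA = np.asarray(XA, float)
    XB = np.asarray(XB, float)
    Ac = XA - XA.mean(axis=0)
    Bc = XB - XB.mean(axis=0)
    evalsA = np.linalg.eigvalsh((Ac.T @ Ac) / len(XA))
    v1 = float(np.sort(evalsA)[::-1][:k].sum())
    evalsB, evecsB = np.linalg.eigh((Bc.T @ Bc) / len(XB))
    axesB = evecsB[:, np.argsort(evalsB)[::-1][:k]]
    proj = Ac @ axesB
    v2 = float(np.sum(proj**2) / len(XA))
    return v2 / v1


def upgma_cophenetic(labels, merges, heights):
    """Cophenetic distances implied by a merge history (height convention:
    two items in clusters merged at height h are at cophenetic distance
    2 * h)."""
    n = len(labels)
    members = {i: [i] for i in range(n)}
    C = np.zeros((n, n))
    for step, ((a, b), h) in enumerate(zip(merges, heights)):
        ma, mb = members[int(a)], members[int(b)]
        for i in ma:
            for j in mb:
                C[i, j] = C[j, i] = 2.0 * h
        members[n + step] = ma + mb
    return C
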