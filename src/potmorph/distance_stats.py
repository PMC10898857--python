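"""Distance-based statistics: alternative-Gower distances, two-level nested
permutation MANOVA (potters within communities), multivariate dispersion at
morphogenetic stages, and UPGMA dendrograms with Newick export.

The nested PERMANOVA partitions sums of squares directly from a dissimilarity
matrix D.  With within-group sums SS_w(g) = (1/n_g) * sum_{i<j in g} d_ij^2:

    SS_total            = (1/N) * sum_{i<j} d_ij^2
    SS_community        = SS_total - sum_c SS_w(c)
    SS_residual         = sum_p SS_w(p)
    SS_potter(community)= SS_total - SS_community - SS_residual

    F_community  = MS_community / MS_potter(community)   df = C - 1
    F_individual = MS_potter(community) / MS_residual    df = P - C

The community p-value permutes whole potters across communities (the
exchangeable units under the community null); the individual p-value permutes
observations among potters within each community.  Both use the
(b + 1)/(m + 1) Monte-Carlo estimator, which includes the observed statistic
in its own null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .dissimilarity import DissimilarityMatrix
from .errors import DesignError, DomainError, ValidationError

__all__ = [
    "PermutationResult",
    "NestedPermanovaResult",
    "DispersionResult",
    "Dendrogram",
    "alt_gower",
    "distance_matrix",
    "nested_permanova",
    "dispersion_analysis",
    "potter_aggregate",
    "upgma",
]

log = logging.getLogger("potmorph.distance_stats")


# ---------------------------------------------------------------------------
# distances


def alt_gower(x, y) -> float:
    """Alternative-Gower distance: mean absolute difference over the columns
    that are not zero in both observations (double zeros excluded, no range
    standardization).  If every column is a double zero, the distance is 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    nz = ~((x == 0) & (y == 0))
    if not nz.any():
        return 0.0
    return float(np.abs(x - y)[nz].sum() / nz.sum())


def _alt_gower_matrix(X: np.ndarray, block: int = 128) -> np.ndarray:
    n = len(X)
    Z = X == 0
    D = np.empty((n, n))
    for i0 in range(0, n, block):  # row blocks keep memory bounded
        i1 = min(i0 + block, n)
        diff = np.abs(X[i0:i1, None, :] - X[None, :, :]).sum(axis=2)
        dz = (Z[i0:i1, None, :] & Z[None, :, :]).sum(axis=2)
        nz = X.shape[1] - dz
        D[i0:i1] = np.where(nz > 0, diff / np.maximum(nz, 1), 0.0)
    np.fill_diagonal(D, 0.0)
    return D


def distance_matrix(vectors, metric: str = "altGower",
                    labels=None) -> DissimilarityMatrix:
    """Pairwise distance matrix under the requested metric."""
    X = np.vstack([np.asarray(getattr(v, "values", v), float) for v in vectors])
    if not np.isfinite(X).all():
        raise ValidationError("distance_matrix requires finite input")
    if len(X) < 2:
        raise ValidationError("need at least 2 vectors")
    if metric == "altGower":
        D = _alt_gower_matrix(X)
    elif metric == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    else:
        raise DomainError(f"unknown metric {metric!r}")
    if labels is None:
        labels = list(range(len(X)))
    return DissimilarityMatrix(labels=list(labels), values=D)


# ---------------------------------------------------------------------------
# nested PERMANOVA


@dataclass
class PermutationResult:
    factor: str
    df: int
    F: float
    p: float
    n_perm: int
    seed: int
    df_denom: int = 0


@dataclass
class NestedPermanovaResult:
    community: PermutationResult | None
    individual: PermutationResult
    ss: dict = field(default_factory=dict)


def _within_ss(G: np.ndarray, members: np.ndarray) -> float:
    """(1/n_g) sum_{i<j in g} d^2 for one group given the squared matrix G."""
    sub = G[np.ix_(members, members)]
    return float(sub.sum() / (2.0 * len(members)))


def nested_permanova(D: DissimilarityMatrix, community, potter,
                     n_perm: int = 10000, seed: int = 0) -> NestedPermanovaResult:
    """Two-level nested permutation MANOVA on a dissimilarity matrix.

    ``community`` and ``potter`` are per-observation label sequences aligned
    with ``D.labels``.  Unbalanced designs are allowed.  A community with a
    single potter aborts the community test only (result ``None``) with a
    logged message; a potter with a single observation is a design error.
    """
    community = np.asarray(community)
    potter = np.asarray(potter)
    N = D.n
    if len(community) != N or len(potter) != N:
        raise ValidationError("label lengths must match the matrix size")

    # each potter maps to exactly one community
    pot_comm = {}
    for c, p in zip(community, potter):
        if p in pot_comm and pot_comm[p] != c:
            raise DesignError(f"potter {p!r} appears in more than one community")
        pot_comm[p] = c
    potters = sorted(pot_comm, key=str)
    comms = sorted(set(community), key=str)
    P, C = len(potters), len(comms)
    if P - C < 1:
        raise DesignError("no potter-level degrees of freedom in this design")

    pot_members = {p: np.flatnonzero(potter == p) for p in potters}
    for p, m in pot_members.items():
        if len(m) < 2:
            raise DesignError(f"potter {p!r} has a single observation")
    comm_potters = {c: [p for p in potters if pot_comm[p] == c] for c in comms}
    singleton = [c for c, ps in comm_potters.items() if len(ps) < 2]

    G = D.values**2
    ss_total = float(G.sum() / (2.0 * N))
    ss_resid = sum(_within_ss(G, pot_members[p]) for p in potters)
    comm_members = {c: np.flatnonzero(community == c) for c in comms}
    ss_comm = ss_total - sum(_within_ss(G, m) for m in comm_members.values())
    ss_potter = ss_total - ss_comm - ss_resid

    df_comm, df_potter, df_resid = C - 1, P - C, N - P
    ms_potter = ss_potter / df_potter
    ms_resid = ss_resid / df_resid
    f_comm = (ss_comm / df_comm) / ms_potter if df_comm > 0 else np.nan
    f_ind = ms_potter / ms_resid

    rng = np.random.default_rng(seed)

    # potter-level aggregated squared distances for the community test:
    # Gp[p, q] = sum_{i in p, j in q} d_ij^2
    Z = np.zeros((N, P))
    for k, p in enumerate(potters):
        Z[pot_members[p], k] = 1.0
    Gp = Z.T @ G @ Z
    pot_sizes = Z.sum(axis=0)
    pot_comm_codes = np.array([comms.index(pot_comm[p]) for p in potters])

    community_result = None
    if C < 2:
        log.warning("community test skipped: only one community in the design")
    elif singleton:
        log.warning(
            "community test skipped: community/ies %s have a single potter",
            singleton,
        )
    else:
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(P)
            codes = pot_comm_codes[perm]
            ss_c = ss_total
            for c in range(C):
                sel = codes == c
                n_c = pot_sizes[sel].sum()
                ss_c -= Gp[np.ix_(sel, sel)].sum() / (2.0 * n_c)
            ss_p = ss_total - ss_c - ss_resid
            f = (ss_c / df_comm) / (ss_p / df_potter)
            if f >= f_comm - 1e-12:
                exceed += 1
        p_comm = (exceed + 1) / (n_perm + 1)
        community_result = PermutationResult(
            factor="community", df=df_comm, F=f_comm, p=p_comm,
            n_perm=n_perm, seed=seed, df_denom=df_potter)

    # individual test: permute observations among potters within communities
    pot_codes = np.array([potters.index(p) for p in potter])
    exceed = 0
    for _ in range(n_perm):
        perm_codes = pot_codes.copy()
        for c in comms:
            m = comm_members[c]
            perm_codes[m] = perm_codes[m[rng.permutation(len(m))]]
        ss_r = 0.0
        for k in range(P):
            members = np.flatnonzero(perm_codes == k)
            ss_r += G[np.ix_(members, members)].sum() / (2.0 * len(members))
        ss_p = ss_total - ss_comm - ss_r
        f = (ss_p / df_potter) / (ss_r / df_resid)
        if f >= f_ind - 1e-12:
            exceed += 1
    p_ind = (exceed + 1) / (n_perm + 1)
    individual_result = PermutationResult(
        factor="individual", df=df_potter, F=f_ind, p=p_ind,
        n_perm=n_perm, seed=seed, df_denom=df_resid)

    ss = {"total": ss_total, "community": ss_comm, "potter": ss_potter,
          "residual": ss_resid}
    return NestedPermanovaResult(community=community_result,
                                 individual=individual_result, ss=ss)


# ---------------------------------------------------------------------------
# multivariate dispersion (betadisper-style)


@dataclass
class DispersionResult:
    groups: list
    group_of: np.ndarray
    distances: np.ndarray
    group_means: dict
    group_medians: dict
    F: float
    p: float
    df: tuple
    n_perm: int
    seed: int


def dispersion_analysis(data, groups, metric: str = "altGower",
                        n_perm: int = 999, seed: int = 0,
                        centroid_type: str = "centroid") -> DispersionResult:
    """Distance of each observation to its group centroid in principal
    coordinates, with a one-way permutation F test for homogeneity.

    ``data`` is either a vector set (rows = observations) or a precomputed
    :class:`DissimilarityMatrix`.  Negative eigenvalue (imaginary) axes of the
    principal-coordinates embedding subtract from the squared distances;
    negative squared distances are clipped to zero with a logged diagnostic.
    """
    if centroid_type != "centroid":
        raise DomainError("only centroid_type='centroid' is implemented")
    groups = np.asarray(groups)
    if isinstance(data, DissimilarityMatrix):
        D = data.values
    else:
        D = distance_matrix(data, metric=metric).values
    N = len(D)
    if len(groups) != N:
        raise ValidationError("group labels must match the number of observations")
    uniq = sorted(set(groups), key=str)
    if len(uniq) < 2:
        raise DesignError("need at least 2 groups")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise DesignError(f"group {g!r} has fewer than 2 observations")

    # principal coordinates: double-centering of -0.5 * D^2
    A = -0.5 * D**2
    J = np.eye(N) - np.ones((N, N)) / N
    B = J @ A @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = np.max(np.abs(evals)) * 1e-10 if len(evals) else 0.0
    pos = evals > tol
    neg = evals < -tol
    Xr = evecs[:, pos] * np.sqrt(evals[pos])
    Xi = evecs[:, neg] * np.sqrt(-evals[neg])

    z2 = np.zeros(N)
    for g in uniq:
        m = groups == g
        cr = Xr[m].mean(axis=0)
        ci = Xi[m].mean(axis=0) if Xi.size else np.zeros(0)
        d2 = ((Xr[m] - cr) ** 2).sum(axis=1)
        if Xi.size:
            d2 = d2 - ((Xi[m] - ci) ** 2).sum(axis=1)
        z2[m] = d2
    if np.any(z2 < 0):
        log.info("clipping %d negative squared distances to 0", int((z2 < 0).sum()))
        z2 = np.maximum(z2, 0.0)
    z = np.sqrt(z2)

    def anova_f(vals: np.ndarray, labels: np.ndarray) -> float:
        grand = vals.mean()
        ss_b = sum((labels == g).sum() * (vals[labels == g].mean() - grand) ** 2
                   for g in uniq)
        ss_w = sum(((vals[labels == g] - vals[labels == g].mean()) ** 2).sum()
                   for g in uniq)
        dfb, dfw = len(uniq) - 1, N - len(uniq)
        return (ss_b / dfb) / (ss_w / dfw) if ss_w > 0 else np.inf

    f_obs = anova_f(z, groups)
    rng = np.random.default_rng(seed)
    exceed = sum(anova_f(z[rng.permutation(N)], groups) >= f_obs - 1e-12
                 for _ in range(n_perm))
    p = (exceed + 1) / (n_perm + 1)

    return DispersionResult(
        groups=uniq, group_of=groups, distances=z,
        group_means={g: float(z[groups == g].mean()) for g in uniq},
        group_medians={g: float(np.median(z[groups == g])) for g in uniq},
        F=f_obs, p=p, df=(len(uniq) - 1, N - len(uniq)),
        n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# potter-level aggregation and UPGMA


def potter_aggregate(D_trials: DissimilarityMatrix, potters,
                     mode: str = "mean_pairwise") -> DissimilarityMatrix:
    """Potter-level matrix: mean dissimilarity over all cross pairs of the two
    potters' trials; zero diagonal by definition."""
    if mode != "mean_pairwise":
        raise DomainError(f"unknown aggregation mode {mode!r}")
    potters = np.asarray(potters)
    if len(potters) != D_trials.n:
        raise ValidationError("potter labels must match the trial matrix")
    uniq = sorted(set(potters), key=str)
    usable = [p for p in uniq if (potters == p).sum() > 0]
    if len(usable) < 2:
        raise ValidationError("need at least 2 potters")
    n = len(usable)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            block = D_trials.values[np.ix_(np.flatnonzero(potters == usable[i]),
                                           np.flatnonzero(potters == usable[j]))]
            M[i, j] = M[j, i] = float(block.mean())
    return DissimilarityMatrix(labels=usable, values=M)


@dataclass
class Dendrogram:
    """UPGMA merge history.  ``heights`` are ultrametric node heights
    (cophenetic distance / 2, so two leaves at distance d merge at d/2)."""

    labels: list
    merges: np.ndarray   # (n-1, 2) merged cluster ids, scipy convention
    heights: np.ndarray  # (n-1,) node heights
    linkage: np.ndarray  # full scipy linkage matrix (heights = cophenetic)

    def to_newick(self) -> str:
        n = len(self.labels)

        def node(i: int) -> tuple[str, float]:
            if i < n:
                return str(self.labels[i]), 0.0
            a, b = self.merges[i - n]
            h = self.heights[i - n]
            sa, ha = node(int(a))
            sb, hb = node(int(b))
            return f"({sa}:{h - ha:.10g},{sb}:{h - hb:.10g})", h

        s, _ = node(2 * n - 2)
        return s + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster_a": self.merges[:, 0].astype(int),
            "cluster_b": self.merges[:, 1].astype(int),
            "height": self.heights,
        })

    def cophenetic(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.linkage))


def upgma(D: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix."""
    if D.n < 2:
        raise ValidationError("need at least 2 items to cluster")
    Z = hierarchy.linkage(squareform(D.values, checks=False), method="average")
    heights = Z[:, 2] / 2.0
    return Dendrogram(labels=list(D.labels), merges=Z[:, :2].copy(),
                      heights=heights, linkage=Z)
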