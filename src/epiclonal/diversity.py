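"""Epigenetic diversity and structure statistics on binary epilocus matrices.

Implements Shannon's diversity index per epilocus, matching of shared
epigenotypes (missing-tolerant), Euclidean epigenetic distances with
missing-data rescaling, great-circle geographic distances, principal
coordinate analysis (Gower double-centering), one-level AMOVA with a
permutation test of Phi_ST, and the Mantel permutation test.

Permutation p-values follow the (count + 1) / (n_perm + 1) convention for
"p(rand >= data)", so p is never zero and never below 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "shannon_index",
    "match_epigenotypes",
    "epi_distance",
    "geo_distance",
    "pcoa",
    "amova",
    "mantel",
    "PcoaResult",
    "AmovaResult",
    "MantelResult",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088


# ----------------------------------------------------------------- diversity
def shannon_index(states: pd.DataFrame) -> tuple[pd.Series, float, float]:
    """Per-locus Shannon diversity I = -[p ln p + (1-p) ln(1-p)] with the
    band frequency p computed among non-missing entries, plus the mean and
    SD over loci.  All-missing loci are skipped."""
    vals = {}
    for locus in states.columns:
        col = states[locus].dropna()
        if col.empty:
            continue
        p = float(col.mean())
        terms = [q * np.log(q) for q in (p, 1.0 - p) if q > 0.0]
        vals[locus] = -sum(terms)
    per_locus = pd.Series(vals, name="shannon")
    if per_locus.empty:
        raise ValueError("no scorable loci")
    return per_locus, float(per_locus.mean()), float(per_locus.std(ddof=1))


def match_epigenotypes(states: pd.DataFrame) -> pd.Series:
    """Group samples with matching epigenotypes, missing entries matching
    anything.

    Two samples match iff at every locus both are non-missing and equal, or
    at least one is missing.  The relation is not transitive, so groups are
    built greedily in sample order: a sample joins the first existing group
    whose every member it matches, else founds a new group.  Returns a
    group id per sample.
    """
    X = states.to_numpy(float)
    groups: list[list[int]] = []
    assign = {}

    def matches(i: int, j: int) -> bool:
        a, b = X[i], X[j]
        both = ~np.isnan(a) & ~np.isnan(b)
        return bool(np.all(a[both] == b[both]))

    for i in range(len(X)):
        for gid, members in enumerate(groups):
            if all(matches(i, j) for j in members):
                members.append(i)
                assign[i] = gid
                break
        else:
            groups.append([i])
            assign[i] = len(groups) - 1
    return pd.Series([f"E{assign[i] + 1:02d}" for i in range(len(X))],
                     index=states.index, name="epigenotype_group")


# ----------------------------------------------------------------- distances
def epi_distance(states: pd.DataFrame, squared: bool = False) -> pd.DataFrame:
    """Pairwise Euclidean epigenetic distances with missing-data rescaling.

    For each pair the squared distance over loci where both samples are
    scored is multiplied by L / L_complete(pair), keeping pairs with
    different amounts of missing data comparable.  ``squared=True`` returns
    squared distances (AMOVA input); otherwise their square roots.
    """
    if len(states) < 2:
        raise ValueError("need at least 2 samples")
    X = states.to_numpy(float)
    L = X.shape[1]
    obs = ~np.isnan(X)
    Xz = np.where(obs, X, 0.0)
    O = obs.astype(float)
    # complete loci per pair and mismatches on them (binary states)
    complete = O @ O.T
    cross = Xz @ Xz.T
    ones = (Xz * O) @ O.T  # count of 1s of i on loci observed in both
    d2 = ones + ones.T - 2.0 * cross
    if np.any(complete[~np.eye(len(X), dtype=bool)] == 0):
        i, j = np.argwhere((complete == 0)
                           & ~np.eye(len(X), dtype=bool))[0]
        raise ValueError("no complete loci for pair "
                         f"({states.index[i]!r}, {states.index[j]!r})")
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(complete > 0, d2 * (L / complete), 0.0)
    np.fill_diagonal(d2, 0.0)
    d2 = 0.5 * (d2 + d2.T)
    out = d2 if squared else np.sqrt(np.maximum(d2, 0.0))
    return pd.DataFrame(out, index=states.index, columns=states.index)


def geo_distance(table: pd.DataFrame, id_col: str | None = None) -> pd.DataFrame:
    """Great-circle (haversine) distance matrix in km between rows with
    ``latitude`` / ``longitude`` columns (Earth radius 6371.0088 km)."""
    lat = table["latitude"].to_numpy(float)
    lon = table["longitude"].to_numpy(float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinates out of range")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2.0) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    ids = table[id_col] if id_col else table.index
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------- PCoA
@dataclass
class PcoaResult:
    coordinates: pd.DataFrame   # samples x retained axes
    eigenvalues: np.ndarray     # all eigenvalues, descending
    pct_variance: np.ndarray    # per retained (positive) axis


def pcoa(dist: pd.DataFrame) -> PcoaResult:
    """Principal coordinate analysis of a distance matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition; axes
    are eigenvectors scaled by the square root of their (positive)
    eigenvalues.  Each axis's sign is fixed so its largest-magnitude loading
    is positive, making the output deterministic across backends.
    """
    D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square symmetric")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    evals, evecs = np.linalg.eigh(0.5 * (B + B.T))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    tol = max(1e-8 * max(abs(evals[0]), 1.0), 0.0)
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        j = np.argmax(np.abs(coords[:, k]))
        if coords[j, k] < 0:
            coords[:, k] = -coords[:, k]
    pct = 100.0 * evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(pd.DataFrame(coords, index=dist.index, columns=cols),
                      evals, pct)


# --------------------------------------------------------------------- AMOVA
@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _phi_st(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Variance components from a squared-distance matrix and group codes."""
    N = len(codes)
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    sizes = np.bincount(codes, minlength=n_groups)
    for g in range(n_groups):
        m = codes == g
        ng = sizes[g]
        if ng > 1:
            sub = d2[np.ix_(m, m)]
            ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = N - n_groups
    sigma2_within = ss_within / df_within
    n0 = (N - np.sum(sizes**2) / N) / df_among
    sigma2_among = (ss_among / df_among - sigma2_within) / n0
    denom = sigma2_among + sigma2_within
    phi = sigma2_among / denom if denom != 0 else 0.0
    return ss_among, ss_within, sigma2_among, sigma2_within, phi


def amova(dist_sq: pd.DataFrame, groups: pd.Series, n_perm: int = 999,
          seed: int | None = None, min_group_size: int = 2) -> AmovaResult:
    """One-level AMOVA on squared distances with a permutation test of
    Phi_ST.

    Groups smaller than ``min_group_size`` are dropped (singleton groups
    cannot contribute within-group variance).  The permutation null shuffles
    individuals among the remaining groups, keeping group sizes fixed; the
    p-value is (# permuted Phi_ST >= observed + 1) / (n_perm + 1).
    """
    groups = pd.Series(groups).reindex(dist_sq.index)
    if groups.isna().any():
        raise ValueError("group labels missing for some samples")
    sizes = groups.value_counts()
    eligible = sizes[sizes >= min_group_size].index
    if len(eligible) < 2:
        raise ValueError("need at least 2 groups with >= "
                         f"{min_group_size} members")
    keep = groups.isin(eligible)
    sub = dist_sq.loc[keep, keep]
    labels = groups[keep]
    cats = sorted(labels.unique())
    codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()
    d2 = np.asarray(sub, dtype=float)

    ss_a, ss_w, s2_a, s2_w, phi = _phi_st(d2, codes, len(cats))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        count += _phi_st(d2, perm, len(cats))[4] >= phi
    p = (count + 1) / (n_perm + 1)
    return AmovaResult(len(cats) - 1, len(codes) - len(cats), ss_a, ss_w,
                       s2_a, s2_w, phi, p, n_perm)


# -------------------------------------------------------------------- Mantel
@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def mantel(d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 999,
           seed: int | None = None) -> MantelResult:
    """Mantel permutation test of the correlation between two distance
    matrices over the same samples in the same order.

    r is the Pearson correlation of the lower-triangle entries; the
    one-tailed p permutes rows and columns of ``d2`` jointly and counts
    permuted r >= observed, with the +1 convention.
    """
    if not d1.index.equals(d2.index):
        raise ValueError("distance matrices must share ids in the same order")
    A = np.asarray(d1, dtype=float)
    B = np.asarray(d2, dtype=float)
    n = A.shape[0]
    tri = np.tril_indices(n, -1)
    a = A[tri]
    r = float(stats.pearsonr(a, B[tri])[0])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += stats.pearsonr(a, B[np.ix_(perm, perm)][tri])[0] >= r
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r, r * r, p, n_perm)
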