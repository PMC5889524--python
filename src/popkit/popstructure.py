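"""Population structure: F_ST, allele-sharing distances, NJ trees, PCA,
K-means clustering.

F_ST uses the Weir–Cockerham (1984) unbiased two-population estimator
with ratio-of-sums aggregation over SNPs.  PCA follows the smartpca
convention: columns centered and scaled by sqrt(p*(1-p)) with an
add-one-shrunk frequency estimate, missing cells zeroed after centering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "FstMatrix", "DistanceMatrix", "PcaResult", "KMeansResult",
    "pairwise_fst", "per_snp_fst", "fst_matrix", "asd_matrix",
    "nj_tree", "pca", "kmeans_on_pcs",
]


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(panel: GenotypePanel, popA: str, popB: str
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir–Cockerham variance components (a, b, c) for two pops.

    Returns (a, a+b+c, usable-mask).  A SNP is usable when both
    populations have at least two genotyped samples and the pooled pair is
    polymorphic.
    """
    stats = []
    for pop in (popA, popB):
        rows = panel.sample_indices(panel.samples_of(pop))
        d = panel.dosages[rows]
        n = (~np.isnan(d)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(d, axis=0) / (2 * np.maximum(n, 1))
            h = np.nansum(d == 1, axis=0) / np.maximum(n, 1)
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2.0
    nsum = n1 + n2
    usable = (n1 >= 2) & (n2 >= 2)
    nsum_s = np.where(usable, nsum, 4.0)  # safe placeholders off-mask
    nbar = nsum_s / r
    nc = (nsum_s - (n1 ** 2 + n2 ** 2) / nsum_s) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / nsum_s
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / nsum_s
    usable &= (pbar > 0) & (pbar < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    return a, a + b + c, usable


def pairwise_fst(panel: GenotypePanel, popA: str, popB: str
                 ) -> tuple[float, int]:
    """Weir–Cockerham F_ST between two populations (ratio of sums).

    Returns (F_ST, number of SNPs used).  SNPs monomorphic across the
    pooled pair, or with fewer than two genotyped samples in either
    population, are skipped.
    """
    for pop in (popA, popB):
        if len(panel.samples_of(pop)) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 samples")
    a, total, usable = _wc_components(panel, popA, popB)
    if not usable.any():
        raise ValueError(f"no usable SNPs for pair ({popA}, {popB})")
    return float(a[usable].sum() / total[usable].sum()), int(usable.sum())


def per_snp_fst(panel: GenotypePanel, popA: str, popB: str) -> np.ndarray:
    """Per-SNP WC F_ST (a / (a+b+c)); NaN where the SNP is unusable."""
    a, total, usable = _wc_components(panel, popA, popB)
    out = np.full(panel.n_snps, np.nan)
    ok = usable & (total != 0)
    out[ok] = a[ok] / total[ok]
    return out


@dataclass
class FstMatrix:
    populations: list[str]
    values: pd.DataFrame
    n_snps: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def fst_matrix(panel: GenotypePanel) -> FstMatrix:
    pops = panel.populations
    vals = pd.DataFrame(0.0, index=pops, columns=pops)
    counts = pd.DataFrame(0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            f, n = pairwise_fst(panel, a, b)
            vals.loc[a, b] = vals.loc[b, a] = f
            counts.loc[a, b] = counts.loc[b, a] = n
    return FstMatrix(populations=pops, values=vals, n_snps=counts)


# ---------------------------------------------------------------------------
# Allele-sharing distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


def asd_matrix(panel: GenotypePanel) -> DistanceMatrix:
    """Allele-sharing distance between individuals.

    d(i, j) = mean over SNPs genotyped in both of |g_i - g_j| / 2, i.e.
    one minus the shared-allele fraction; SNPs missing in either member
    of a pair are excluded pairwise.
    """
    if panel.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = panel.dosages
    n = panel.n_samples
    finite = ~np.isnan(d)
    filled = np.nan_to_num(d)
    out = np.zeros((n, n))
    for i in range(n):
        shared = finite[i] & finite[i + 1:]
        counts = shared.sum(axis=1)
        if (counts == 0).any():
            j = i + 1 + int(np.argmax(counts == 0))
            raise ValueError("no shared genotyped SNPs for pair "
                             f"({panel.sample_ids[i]}, {panel.sample_ids[j]})")
        diff = np.abs(filled[i] - filled[i + 1:]) * shared
        out[i, i + 1:] = out[i + 1:, i] = diff.sum(axis=1) / (2 * counts)
    return DistanceMatrix(ids=list(panel.sample_ids),
                          values=pd.DataFrame(out, index=panel.sample_ids,
                                              columns=panel.sample_ids))


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------

def _newick_escape(name: str) -> str:
    if any(ch in name for ch in " (),:;'\t"):
        return "'" + name.replace("'", "''") + "'"
    return name


def nj_tree(dist: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns an unrooted newick string.

    Deterministic: Q-matrix ties are broken by the lowest (row, column)
    index pair.  Negative branch lengths are clamped to zero with the
    deficit transferred to the sister branch, preserving path lengths.
    """
    D = dist.values.to_numpy(dtype=float).copy()
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need >= 3 taxa")
    # nodes hold partial newick strings
    nodes = [_newick_escape(str(x)) for x in dist.ids]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsum = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = divmod(int(np.argmin(Q)), r)  # argmin scans row-major: lowest pair
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        ai, aj = active[i], active[j]
        new_d = 0.5 * (D[ai, :] + D[aj, :] - dij)
        # reuse slot ai for the merged node
        D[ai, :] = new_d
        D[:, ai] = new_d
        D[ai, ai] = 0.0
        nodes[ai] = f"({nodes[ai]}:{li:.10g},{nodes[aj]}:{lj:.10g})"
        active.pop(j)

    a, b, c = active
    # three-point formulas for the final trifurcation
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb = clamp(la, lb)
    lb, lc = clamp(lb, lc)
    la, lc = clamp(la, lc)
    return (f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},"
            f"{nodes[c]}:{lc:.10g});")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    sample_ids: list[str]
    coordinates: np.ndarray        # (n_samples, n_components)
    eigenvalues: np.ndarray        # all positive eigenvalues, non-increasing
    var_frac_total: np.ndarray     # eigenvalue / total variance
    var_frac_top10: np.ndarray     # eigenvalue / sum of ten largest

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates, index=self.sample_ids,
                          columns=[f"PC{i+1}" for i in range(k)])
        return df


def pca(panel: GenotypePanel, n_components: int = 10) -> PcaResult:
    """Individual-level PCA with allele-frequency normalization.

    Each SNP column is centered on its mean dosage and scaled by
    sqrt(p*(1-p)) where p = (1 + sum dosages) / (2 + 2*n_genotyped), a
    shrunk frequency estimate that cannot reach 0 or 1; missing cells are
    set to zero after centering.  Eigenvalues are those of the sample
    covariance of the normalized matrix.
    """
    if panel.n_samples < 2 or panel.n_snps < 1:
        raise ValueError("need >= 2 samples and >= 1 SNP")
    d = panel.dosages
    finite = ~np.isnan(d)
    n_obs = finite.sum(axis=0)
    sums = np.nansum(d, axis=0)
    keep = n_obs > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / np.maximum(2 * n_obs, 1) * 2
        p_shrunk = (1 + sums) / (2 + 2 * n_obs)
        col_ok = keep & (np.nanstd(np.where(finite, d, np.nan), axis=0) > 0)
    if not col_ok.any():
        raise ValueError("no polymorphic SNPs for PCA")
    X = (np.nan_to_num(d[:, col_ok] - mean[col_ok])
         / np.sqrt(p_shrunk[col_ok] * (1 - p_shrunk[col_ok])))
    X[~finite[:, col_ok]] = 0.0
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s ** 2 / (panel.n_samples - 1)
    pos = eig > eig[0] * 1e-12 if eig.size else eig > 0
    eig = eig[pos]
    k = min(n_components, eig.size)
    scores = u[:, :k] * s[:k]
    top10 = eig[:10].sum()
    return PcaResult(sample_ids=list(panel.sample_ids),
                     coordinates=scores,
                     eigenvalues=eig,
                     var_frac_total=eig / eig.sum(),
                     var_frac_top10=eig / top10)


# ---------------------------------------------------------------------------
# K-means on top PCs
# ---------------------------------------------------------------------------

@dataclass
class KMeansResult:
    K: int
    assignments: pd.Series          # sample -> cluster id
    fractions: pd.DataFrame         # populations x clusters, rows sum to 1
    seed: int


def kmeans_on_pcs(pca_result: PcaResult, panel: GenotypePanel, K: int,
                  n_pcs: int = 10, seed: int = 0) -> KMeansResult:
    """K-means (k-means++, 25 restarts) on the top ``n_pcs`` PC scores.

    ``fractions`` gives, for each population, the share of its samples
    assigned to each cluster.
    """
    from sklearn.cluster import KMeans

    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(pca_result.sample_ids):
        raise ValueError("K exceeds the number of samples")
    n_pcs = min(n_pcs, pca_result.coordinates.shape[1])
    X = pca_result.coordinates[:, :n_pcs]
    km = KMeans(n_clusters=K, init="k-means++", n_init=25, random_state=seed)
    labels = km.fit_predict(X)
    assignments = pd.Series(labels, index=pca_result.sample_ids, name="cluster")
    pops = [panel.pop_of[s] for s in pca_result.sample_ids]
    tab = pd.crosstab(pd.Series(pops, name="pop"),
                      pd.Series(labels, name="cluster"))
    tab = tab.reindex(columns=range(K), fill_value=0)
    fractions = tab.div(tab.sum(axis=1), axis=0)
    return KMeansResult(K=K, assignments=assignments,
                        fractions=fractions, seed=seed)
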