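"""LD-decay effective population size and divergence dating.

Pairwise haplotype r^2 is binned by genetic distance c (Morgans).  Under
drift–recombination balance E[r^2] ~ 1/(2 + 4*N_e*c), and r^2 at distance
c is informative about N_e around t = 1/(2c) generations ago, so each
distance class yields one (t, N_e) point:

    N_e(c) = [(1 / r2_adj) - 2] / (4c),   r2_adj = mean r^2 - 1/n

where n is the number of sampled chromosomes (the 1/n term removes the
finite-sample floor of r^2).  An inter-population N_e for dating is the
average of the two populations' harmonic-mean N_e over the 0.01–0.25 cM
classes, and the divergence time is T_F = 2 * N_e * F_ST generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel

log = logging.getLogger(__name__)

__all__ = ["LdBin", "NeTrajectory", "DivergenceEstimate",
           "pairwise_r2", "bin_r2", "ne_trajectory", "interpop_ne",
           "divergence_time", "time_generations"]


def time_generations(c_morgans: float) -> float:
    """Generations ago probed by LD at genetic distance c: t = 1/(2c)."""
    if c_morgans <= 0:
        raise ValueError("genetic distance must be positive")
    return 1.0 / (2.0 * c_morgans)


def pairwise_r2(haplotypes: np.ndarray, snp_i: int, snp_j: int) -> float:
    """Haplotype r^2 between two loci.

    r^2 = D^2 / (p_i (1-p_i) p_j (1-p_j)) with D the coupling-gamete
    excess, computed over haplotypes non-missing at both loci.  NaN when
    either locus is monomorphic among the usable haplotypes.
    """
    hi = haplotypes[:, snp_i]
    hj = haplotypes[:, snp_j]
    m = (hi >= 0) & (hj >= 0)
    x, y = hi[m].astype(float), hj[m].astype(float)
    if x.size == 0:
        return np.nan
    p, q = x.mean(), y.mean()
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        return np.nan
    D = (x * y).mean() - p * q
    return float(D * D / (p * (1 - p) * q * (1 - q)))


@dataclass(frozen=True)
class LdBin:
    """One genetic-distance class (bounds in Morgans, half-open)."""
    c_lo: float
    c_hi: float
    n_pairs: int
    mean_r2_adj: float
    n_hap: int

    @property
    def c_mid(self) -> float:
        return 0.5 * (self.c_lo + self.c_hi)

    @property
    def c_mid_cM(self) -> float:
        return self.c_mid * 100.0


def bin_r2(panel: GenotypePanel, population: str,
           c_min_cM: float = 0.001, c_max_cM: float = 2.5,
           width_cM: float = 0.001, min_maf: float = 0.05) -> list[LdBin]:
    """Mean adjusted r^2 per genetic-distance class for one population.

    All same-chromosome locus pairs with distance in [c_min, c_max) are
    assigned to half-open classes of ``width_cM``; each class reports
    mean(r^2) - 1/n with n the number of chromosomes.  Loci below the
    minor-allele-frequency floor are excluded before pairing (array
    panels are ascertained for common variants, and rare alleles make
    r^2 a poor N_e estimator).
    """
    if not panel.phased:
        raise ValueError("LD operations require a phased panel")
    haps = panel.haplotypes_of(population)
    n_hap = haps.shape[0]
    with np.errstate(invalid="ignore"):
        p = np.where((haps >= 0).sum(0) > 0,
                     np.where(haps >= 0, haps, 0).sum(0)
                     / np.maximum((haps >= 0).sum(0), 1), np.nan)
    maf = np.minimum(p, 1 - p)
    usable = np.flatnonzero(maf >= max(min_maf, np.nextafter(0, 1)))
    pos_m = panel.pos_morgans()
    chroms = panel.chroms()
    c_min, c_max, width = (c_min_cM / 100, c_max_cM / 100, width_cM / 100)
    n_bins = int(round((c_max - c_min) / width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)

    complete = not (haps[:, usable] < 0).any()
    for chrom in pd.unique(chroms):
        loc = usable[chroms[usable] == chrom]
        if len(loc) < 2:
            continue
        if complete:
            sub = haps[:, loc].astype(float)
            r2 = np.corrcoef(sub.T) ** 2
            iu, ju = np.triu_indices(len(loc), 1)
            d = pos_m[loc[ju]] - pos_m[loc[iu]]
            r2v = r2[iu, ju]
        else:
            pairs = [(i, j) for k, i in enumerate(loc) for j in loc[k + 1:]]
            d = np.array([pos_m[j] - pos_m[i] for i, j in pairs])
            r2v = np.array([pairwise_r2(haps, i, j) for i, j in pairs])
        inside = (d >= c_min) & (d < c_max) & np.isfinite(r2v)
        b = ((d[inside] - c_min) / width).astype(int)
        b = np.clip(b, 0, n_bins - 1)
        np.add.at(sums, b, r2v[inside])
        np.add.at(counts, b, 1)

    bins = []
    for k in range(n_bins):
        mean_adj = (sums[k] / counts[k] - 1.0 / n_hap) if counts[k] else np.nan
        bins.append(LdBin(c_lo=c_min + k * width, c_hi=c_min + (k + 1) * width,
                          n_pairs=int(counts[k]), mean_r2_adj=mean_adj,
                          n_hap=n_hap))
    return bins


@dataclass
class NeTrajectory:
    """Per-distance-class (c, t = 1/(2c), mean adjusted r^2, N_e) records."""
    population: str
    table: pd.DataFrame   # columns: c_mid_morgan, c_mid_cM, t_generations,
                          #          mean_r2_adj, n_pairs, Ne
    n_hap: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ne_trajectory(bins: list[LdBin], population: str,
                  min_pairs: int = 10) -> NeTrajectory:
    """Invert each distance class: N_e = [(1/r2_adj) - 2] / (4c).

    Classes with fewer than ``min_pairs`` pairs or non-positive adjusted
    r^2 yield a missing N_e rather than an error.
    """
    rows = []
    n_hap = bins[0].n_hap if bins else 0
    for b in bins:
        c = b.c_mid
        t = time_generations(c)
        ne = np.nan
        if (b.n_pairs >= min_pairs and np.isfinite(b.mean_r2_adj)
                and b.mean_r2_adj > 0):
            ne = (1.0 / b.mean_r2_adj - 2.0) / (4.0 * c)
        rows.append((c, b.c_mid_cM, t, b.mean_r2_adj, b.n_pairs, ne))
    table = pd.DataFrame(rows, columns=["c_mid_morgan", "c_mid_cM",
                                        "t_generations", "mean_r2_adj",
                                        "n_pairs", "Ne"])
    return NeTrajectory(population=population, table=table, n_hap=n_hap)


def _harmonic_mean(values: np.ndarray) -> float:
    return len(values) / np.sum(1.0 / values)


def interpop_ne(trajA: NeTrajectory, trajB: NeTrajectory,
                c_range_cM: tuple[float, float] = (0.01, 0.25),
                mode: str = "mean_of_harmonic") -> float:
    """Inter-population N_e over a genetic-distance window.

    ``mean_of_harmonic`` (default): harmonic mean of each population's
    per-class N_e over classes inside the window, then the arithmetic
    mean of the two.  ``pooled``: one harmonic mean over both
    populations' in-window classes.  Classes with missing or non-positive
    N_e are excluded (logged).
    """
    lo, hi = c_range_cM
    per_pop = []
    pooled: list[np.ndarray] = []
    for traj in (trajA, trajB):
        t = traj.table
        sel = (t["c_mid_cM"] >= lo) & (t["c_mid_cM"] <= hi)
        ne = t.loc[sel, "Ne"].to_numpy()
        good = ne[np.isfinite(ne) & (ne > 0)]
        dropped = int(sel.sum()) - len(good)
        if dropped:
            log.info("interpop_ne: excluded %d classes for %s",
                     dropped, traj.population)
        if len(good) == 0:
            raise ValueError(f"no usable distance classes for {traj.population} "
                             f"in {lo}-{hi} cM")
        per_pop.append(_harmonic_mean(good))
        pooled.append(good)
    if mode == "mean_of_harmonic":
        return float(np.mean(per_pop))
    if mode == "pooled":
        return float(_harmonic_mean(np.concatenate(pooled)))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class DivergenceEstimate:
    pair: tuple[str, str]
    fst: float
    ne_interpop: float
    t_generations: float
    t_years: float
    years_per_generation: float


def divergence_time(pair: tuple[str, str], fst: float, ne_interpop: float,
                    years_per_generation: float = 25.0) -> DivergenceEstimate:
    """Date a population split: T_F = 2 * N_e * F_ST generations.

    Negative F_ST estimates (possible for very close pairs) are clamped
    to zero with a warning.
    """
    if fst < 0:
        log.warning("negative F_ST %.3g clamped to 0 for pair %s", fst, pair)
        fst = 0.0
    t_gen = 2.0 * ne_interpop * fst
    return DivergenceEstimate(pair=tuple(sorted(pair)), fst=fst,
                              ne_interpop=ne_interpop,
                              t_generations=t_gen,
                              t_years=t_gen * years_per_generation,
                              years_per_generation=years_per_generation)
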