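"""D and f-statistics with delete-m block jackknife, and F4-regression
admixture proportions.

All statistics are functions of per-population sample allele frequencies
(w, x, y, z for D; a', b', c', d' for f2/f3/f4):

    D(W, X; Y, Z)  = sum (w-x)(y-z) / sum (w+x-2wx)(y+z-2yz)
    f2(A, B)       = mean (a'-b')^2
    f3(C; A, B)    = mean (c'-a')(c'-b')
    f4(A, B; C, D) = mean (a'-b')(c'-d')

Standard errors come from a delete-m jackknife over contiguous blocks of
SNPs (a proxy for linkage blocks); a statistic is called significant when
|Z| exceeds the two-sided 1% normal critical value (2.58).  A
significantly negative f3 signals that the target C is admixed; D != 0
signals gene flow involving W or X.

When a series of targets X share the same donors A and B, the two
statistics y = F4(A,O; X,B) = alpha*l and x = F4(B,O; X,A) = (1-alpha)*m
lie on a line y = l - (l/m) x across targets, so an ordinary
least-squares fit eliminates the unknown drift lengths l and m and gives
each target's mixing proportion alpha = y / l.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import AlleleFrequencyTable

log = logging.getLogger(__name__)

__all__ = [
    "JackknifeConfig", "FStatResult", "AdmixtureRegression",
    "two_sided_critical_value", "Z_CRITICAL",
    "block_jackknife", "d_stat", "f2", "f3", "f4",
    "f4_ratio_regression", "three_way_proportions",
]


def two_sided_critical_value(p: float = 0.01) -> float:
    """Standard-normal two-sided critical value, e.g. 2.58 at p = 0.01."""
    return float(sps.norm.ppf(1 - p / 2))


#: significance threshold used for all D/f-statistic calls (p < 0.01)
Z_CRITICAL = round(two_sided_critical_value(0.01), 2)


@dataclass(frozen=True)
class JackknifeConfig:
    """Contiguous-block delete-m jackknife settings.

    Either a block count (``n_blocks``) or an explicit block size in SNPs
    (``block_size_snps``) may be given; blocks are contiguous runs in SNP
    order so that linked SNPs tend to leave the sample together.
    """
    n_blocks: int = 500
    block_size_snps: int | None = None

    def __post_init__(self) -> None:
        if self.block_size_snps is None and self.n_blocks < 10:
            raise ValueError("n_blocks must be >= 10")
        if self.block_size_snps is not None and self.block_size_snps < 1:
            raise ValueError("block_size_snps must be >= 1")

    def blocks(self, n_snps: int) -> np.ndarray:
        """Block id per SNP (0..g-1), contiguous, covering every SNP once."""
        if self.block_size_snps is not None:
            # explicit block size: any block count is allowed (small worked
            # examples use one SNP per block)
            return np.arange(n_snps) // self.block_size_snps
        if n_snps < self.n_blocks:
            raise ValueError(f"{n_snps} SNPs < {self.n_blocks} blocks; "
                             "use a smaller n_blocks")
        return (np.arange(n_snps) * self.n_blocks) // n_snps


@dataclass(frozen=True)
class FStatResult:
    statistic: str
    pops: tuple[str, ...]
    value: float
    jackknife_se: float
    z: float
    n_blocks: int
    n_snps: int

    @property
    def significant(self) -> bool:
        return abs(self.z) > Z_CRITICAL


def block_jackknife(num: np.ndarray, den: np.ndarray, block_ids: np.ndarray
                    ) -> tuple[float, float, float]:
    """Delete-m jackknife for a ratio-of-sums statistic.

    ``num`` and ``den`` are per-SNP contributions; the estimate is
    sum(num)/sum(den) and each leave-one-block-out replicate removes one
    contiguous block.  Uses the weighted delete-m variance (blocks may
    differ in size).  Returns (estimate, se, z).
    """
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    g = int(block_ids.max()) + 1
    n = len(num)
    tn, td = num.sum(), den.sum()
    if td == 0:
        raise ValueError("no informative SNPs (zero denominator)")
    theta = tn / td
    bn = np.bincount(block_ids, weights=num, minlength=g)
    bd = np.bincount(block_ids, weights=den, minlength=g)
    m = np.bincount(block_ids, minlength=g).astype(float)
    keep = m > 0
    bn, bd, m = bn[keep], bd[keep], m[keep]
    g = len(m)
    if g < 2:  # a single block: no resampling variance available
        return theta, 0.0, np.inf if theta != 0 else 0.0
    loo_d = td - bd
    if (loo_d == 0).any():
        raise ValueError("a leave-one-block-out replicate has zero denominator")
    loo = (tn - bn) / loo_d
    if g < 2 or np.allclose(loo, theta):
        return theta, 0.0, np.inf if theta != 0 else 0.0
    h = n / m
    theta_j = g * theta - ((1 - m / n) * loo).sum()
    tau = h * theta - (h - 1) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1)) / g
    se = float(np.sqrt(var))
    z = theta / se if se > 0 else (np.inf if theta != 0 else 0.0)
    return float(theta), se, float(z)


def _freq_matrix(freqs: AlleleFrequencyTable, pops: tuple[str, ...]
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(n_snps, n_pops) frequency array and the all-defined SNP mask."""
    for p in pops:
        if p not in freqs.freq.columns:
            raise KeyError(f"unknown population: {p!r}")
    f = freqs.freq.loc[:, list(pops)].to_numpy(dtype=float)
    return f, np.isfinite(f).all(axis=1)


def _run(statistic: str, pops: tuple[str, ...], num: np.ndarray,
         den: np.ndarray, valid: np.ndarray, jk: JackknifeConfig
         ) -> FStatResult:
    n_skip = int((~valid).sum())
    if n_skip:
        log.info("%s%s: skipped %d SNPs with undefined input",
                 statistic, pops, n_skip)
    num, den = num[valid], den[valid]
    if len(num) == 0 or den.sum() == 0:
        raise ValueError("no informative SNPs")
    ids = jk.blocks(len(num))
    value, se, z = block_jackknife(num, den, ids)
    return FStatResult(statistic=statistic, pops=pops, value=value,
                       jackknife_se=se, z=z,
                       n_blocks=int(ids.max()) + 1, n_snps=len(num))


def d_stat(freqs: AlleleFrequencyTable, W: str, X: str, Y: str, Z: str,
           jk: JackknifeConfig = JackknifeConfig(),
           per_snp_mean: bool = False) -> FStatResult:
    """ABBA-BABA D statistic for (W, X; Y, Z), ratio-of-sums by default.

    ``per_snp_mean`` switches to the mean of per-SNP Num_i/Den_i ratios
    (a sensitivity alternative; SNPs with zero denominator are skipped in
    both modes).
    """
    f, valid = _freq_matrix(freqs, (W, X, Y, Z))
    w, x, y, z = f.T
    num = (w - x) * (y - z)
    den = (w + x - 2 * w * x) * (y + z - 2 * y * z)
    valid = valid & (den != 0) & np.isfinite(den)
    if per_snp_mean:
        with np.errstate(invalid="ignore", divide="ignore"):
            num = np.where(valid, num / den, 0.0)
        den = np.ones_like(num)
    return _run("D", (W, X, Y, Z), num, den, valid, jk)


def f2(freqs: AlleleFrequencyTable, A: str, B: str,
       jk: JackknifeConfig = JackknifeConfig()) -> FStatResult:
    """f2(A, B) = mean (a'-b')^2: drift separating A and B."""
    f, valid = _freq_matrix(freqs, (A, B))
    a, b = f.T
    return _run("f2", (A, B), (a - b) ** 2, np.ones(len(a)), valid, jk)


def f3(freqs: AlleleFrequencyTable, C: str, A: str, B: str,
       jk: JackknifeConfig = JackknifeConfig()) -> FStatResult:
    """f3(C; A, B) = mean (c'-a')(c'-b'); significantly negative values
    indicate that C is admixed between sources related to A and B."""
    f, valid = _freq_matrix(freqs, (C, A, B))
    c, a, b = f.T
    return _run("f3", (C, A, B), (c - a) * (c - b), np.ones(len(a)), valid, jk)


def f4(freqs: AlleleFrequencyTable, A: str, B: str, C: str, D: str,
       jk: JackknifeConfig = JackknifeConfig()) -> FStatResult:
    """f4(A, B; C, D) = mean (a'-b')(c'-d'): shared drift of the two pairs."""
    f, valid = _freq_matrix(freqs, (A, B, C, D))
    a, b, c, d = f.T
    return _run("f4", (A, B, C, D), (a - b) * (c - d), np.ones(len(a)), valid, jk)


# ---------------------------------------------------------------------------
# F4 regression for admixture proportions
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureRegression:
    outgroup: str
    donors: tuple[str, str]
    targets: list[str]
    points: pd.DataFrame        # per target: x = F4(B,O;X,A), y = F4(A,O;X,B)
    intercept_l: float
    slope: float
    m_edge: float
    r_squared: float
    alphas: pd.DataFrame        # per target: alpha, se, clamped
    warnings: list[str]


def _f4_points(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP contributions to (x, y) for one target.

    Columns of ``f``: O, A, B, X.  y = (a-o)(x-b), x_pt = (b-o)(x-a).
    """
    o, a, b, xf = f.T
    return (b - o) * (xf - a), (a - o) * (xf - b)


def _fit_line(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
    vx = xs.var()
    if vx == 0:
        raise ValueError("degenerate regression: targets do not spread in "
                         "F4(B,O;X,A); check the donor/outgroup choice")
    slope = ((xs - xs.mean()) * (ys - ys.mean())).mean() / vx
    return float(ys.mean() - slope * xs.mean()), float(slope)


def f4_ratio_regression(freqs: AlleleFrequencyTable, outgroup: str,
                        donorA: str, donorB: str, targets: list[str],
                        jk: JackknifeConfig = JackknifeConfig()
                        ) -> AdmixtureRegression:
    """Estimate each target's mixing proportion from two donors.

    For every target X the pair (x, y) = (F4(B,O;X,A), F4(A,O;X,B)) is
    computed on the SNPs defined in all involved populations; the OLS line
    through the targets has intercept l and slope -l/m, and
    alpha_X = y_X / l (clamped to [0, 1]).  Per-target standard errors
    come from a delete-m jackknife of the whole procedure over SNP blocks.
    """
    warnings: list[str] = []
    if len(targets) < 2:
        raise ValueError("need at least two targets for the regression")
    if len(targets) < 3:
        warnings.append("fewer than 3 targets: regression is exactly "
                        "determined and uncertainty is optimistic")
    pops = (outgroup, donorA, donorB, *targets)
    f, valid = _freq_matrix(freqs, pops)
    f = f[valid]
    n = f.shape[0]
    if n == 0:
        raise ValueError("no SNPs defined in all populations")
    ids = jk.blocks(n)
    g = int(ids.max()) + 1

    per_target_num = []   # (x contributions, y contributions) per target
    for k, tgt in enumerate(targets):
        cols = f[:, [0, 1, 2, 3 + k]]
        per_target_num.append(_f4_points(cols))

    def regression(mask: np.ndarray | None) -> tuple[float, float, np.ndarray,
                                                     np.ndarray, np.ndarray]:
        xs, ys = [], []
        for xc, yc in per_target_num:
            if mask is None:
                xs.append(xc.mean()); ys.append(yc.mean())
            else:
                xs.append(xc[mask].mean()); ys.append(yc[mask].mean())
        xs, ys = np.asarray(xs), np.asarray(ys)
        intercept, slope = _fit_line(xs, ys)
        alphas = ys / intercept
        return intercept, slope, alphas, xs, ys

    intercept, slope, alphas_raw, xs, ys = regression(None)
    if intercept <= 0:
        raise ValueError("non-positive intercept: the regression geometry "
                         "does not match an admixture model")
    if slope >= 0:
        warnings.append("model geometry violated: slope >= 0 "
                        "(donors likely misspecified)")
    resid = ys - (intercept + slope * xs)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r_sq = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
    m_edge = -intercept / slope if slope != 0 else np.nan

    # jackknife the whole procedure over SNP blocks
    loo_alphas = np.empty((g, len(targets)))
    for b in range(g):
        mask = ids != b
        try:
            loo_alphas[b] = regression(mask)[2]
        except Exception:
            loo_alphas[b] = np.nan
    m_sizes = np.bincount(ids, minlength=g).astype(float)
    h = n / m_sizes
    se = np.empty(len(targets))
    for k in range(len(targets)):
        loo = loo_alphas[:, k]
        ok = np.isfinite(loo)
        if ok.sum() < 2:
            se[k] = np.nan
            continue
        hj = h[ok]
        theta_j = ok.sum() * alphas_raw[k] - ((1 - m_sizes[ok] / n) * loo[ok]).sum()
        tau = hj * alphas_raw[k] - (hj - 1) * loo[ok]
        se[k] = np.sqrt(np.sum((tau - theta_j) ** 2 / (hj - 1)) / ok.sum())

    clamped = (alphas_raw < 0) | (alphas_raw > 1)
    if clamped.any():
        warnings.append(f"{int(clamped.sum())} alpha value(s) clamped to [0, 1]")
    alphas = pd.DataFrame({"alpha": np.clip(alphas_raw, 0, 1),
                           "alpha_raw": alphas_raw,
                           "se": se, "clamped": clamped},
                          index=pd.Index(targets, name="target"))
    points = pd.DataFrame({"x_f4_B_O_X_A": xs, "y_f4_A_O_X_B": ys},
                          index=pd.Index(targets, name="target"))
    return AdmixtureRegression(outgroup=outgroup, donors=(donorA, donorB),
                               targets=list(targets), points=points,
                               intercept_l=intercept, slope=slope,
                               m_edge=float(m_edge), r_squared=r_sq,
                               alphas=alphas, warnings=warnings)


def three_way_proportions(freqs: AlleleFrequencyTable, outgroup: str,
                          donors: tuple[str, str, str], targets: list[str],
                          jk: JackknifeConfig = JackknifeConfig()
                          ) -> pd.DataFrame:
    """Three-donor ancestry shares from the three pairwise F4 regressions.

    Each donor pair (i, j) yields a pairwise proportion alpha_ij per
    target; a donor's raw share is the mean of its two pairwise
    proportions, and the three raw shares are renormalized to sum to one.
    This combination rule is a package choice (the pairwise regressions
    themselves are model-derived); it compresses very uneven mixtures
    toward the interior but degrades gracefully when a pairwise
    regression is poorly determined.
    """
    d1, d2, d3 = donors
    pairs = [(d1, d2), (d1, d3), (d2, d3)]
    alpha = {}
    for a, b in pairs:
        reg = f4_ratio_regression(freqs, outgroup, a, b, targets, jk)
        alpha[(a, b)] = reg.alphas["alpha"]
    rows = []
    for tgt in targets:
        share = {
            d1: (alpha[(d1, d2)][tgt] + alpha[(d1, d3)][tgt]) / 2,
            d2: ((1 - alpha[(d1, d2)][tgt]) + alpha[(d2, d3)][tgt]) / 2,
            d3: ((1 - alpha[(d1, d3)][tgt]) + (1 - alpha[(d2, d3)][tgt])) / 2,
        }
        total = sum(share.values())
        rows.append([share[d] / total for d in donors])
    return pd.DataFrame(rows, index=pd.Index(targets, name="target"),
                        columns=list(donors))
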