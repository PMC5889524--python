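"""Read/write genotype panels and apply marker filters.

Input formats are the field's plain-text staples: VCF (via cyvcf2), a
two-column sample-to-population TSV, and an optional three-column genetic
map TSV (chrom, pos_bp, cM).  Filters implement the QC rules used for
multi-population array panels: autosomes only, per-SNP missing-call rate
strictly below a threshold, greedy physical-distance thinning, and
sliding-window LD pruning on genotype correlations.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import (AlleleFrequencyTable, GenotypePanel, SnpRecord,
                    is_autosome, normalize_chrom)

log = logging.getLogger(__name__)

__all__ = [
    "read_pop_table", "read_genetic_map", "read_vcf", "write_vcf",
    "qc_missingness", "thin_by_distance", "ld_prune",
    "allele_frequencies", "write_frequencies", "apply_genetic_map",
]


def read_pop_table(path: str | Path) -> dict[str, str]:
    """Read `sample_id<TAB>population` (no header) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "pop"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id in population table: {dup}")
    return dict(zip(df["sample"], df["pop"]))


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """Read `chrom<TAB>pos_bp<TAB>cM` (no header); cM must be non-decreasing."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos_bp", "cM"],
                     dtype={"chrom": str}, comment="#")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df = df.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        if (np.diff(grp["cM"].to_numpy()) < 0).any():
            raise ValueError(f"genetic map cM decreases on chromosome {chrom}")
    return df


def apply_genetic_map(panel: GenotypePanel, gmap: pd.DataFrame) -> GenotypePanel:
    """Interpolate per-SNP cM positions from a genetic map (linear in bp)."""
    cm = np.empty(panel.n_snps)
    chroms = panel.chroms()
    pos = panel.pos_bp().astype(float)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        grp = gmap[gmap["chrom"] == chrom]
        if grp.empty:
            cm[sel] = pos[sel] * 1e-6  # fallback: uniform 1 cM/Mb
            continue
        cm[sel] = np.interp(pos[sel], grp["pos_bp"].to_numpy(float),
                            grp["cM"].to_numpy(float))
    return panel.with_genetic_positions(cm)


# ---------------------------------------------------------------------------
# VCF input/output
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, pop_table_path: str | Path,
             genetic_map_path: str | Path | None = None) -> GenotypePanel:
    """Load a VCF with GT fields into a :class:`GenotypePanel`.

    Samples absent from the population table are dropped (count logged);
    non-autosomal records are dropped.  The panel is phased iff every
    genotype call in the retained records is phased.
    """
    from cyvcf2 import VCF

    pop_of = read_pop_table(pop_table_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample id in VCF header")
    keep = [i for i, s in enumerate(samples) if s in pop_of]
    dropped = len(samples) - len(keep)
    if dropped:
        log.info("dropping %d VCF samples absent from population table", dropped)
    if not keep:
        raise ValueError("no VCF sample appears in the population table")
    kept_samples = [samples[i] for i in keep]
    keep_arr = np.asarray(keep)

    snps: list[SnpRecord] = []
    dos_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    for var in vcf:
        if not is_autosome(var.CHROM):
            continue
        # genotypes: per sample [allele1, allele2, phased]; -1 = missing
        g = np.asarray(var.genotype.array())[keep_arr]
        a1, a2 = g[:, 0].astype(np.int8), g[:, 1].astype(np.int8)
        phased = g[:, 2].astype(bool)
        miss = (a1 < 0) | (a2 < 0)
        dos = np.where(miss, np.nan, a1.clip(0).astype(float) + a2.clip(0))
        dos_cols.append(dos)
        if not phased.all():
            all_phased = False
        a1 = np.where(a1 < 0, -1, a1)
        a2 = np.where(a2 < 0, -1, a2)
        hap_cols.append(np.ravel(np.column_stack([a1, a2])))
        alt = var.ALT[0] if var.ALT else "."
        snps.append(SnpRecord(chrom=normalize_chrom(var.CHROM), pos_bp=var.POS,
                              ref_allele=var.REF, alt_allele=alt,
                              snp_id=var.ID or None))
    if not snps:
        raise ValueError(f"no autosomal records in {path}")

    order = np.lexsort((np.array([s.pos_bp for s in snps]),
                        np.array([s.chrom for s in snps])))
    snps = [snps[i] for i in order]
    dosages = np.column_stack([dos_cols[i] for i in order])
    haplotypes = (np.column_stack([hap_cols[i] for i in order])
                  if all_phased else None)
    panel = GenotypePanel(sample_ids=kept_samples,
                          pop_of={s: pop_of[s] for s in kept_samples},
                          snps=snps, dosages=dosages,
                          phased=all_phased, haplotypes=haplotypes)
    if genetic_map_path is not None:
        panel = apply_genetic_map(panel, read_genetic_map(genetic_map_path))
    return panel


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal VCF 4.2 text file."""
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in panel.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j, snp in enumerate(panel.snps):
            if panel.phased and panel.haplotypes is not None:
                a1 = panel.haplotypes[0::2, j]
                a2 = panel.haplotypes[1::2, j]
                gts = [f"{'.' if x < 0 else x}{sep}{'.' if y < 0 else y}"
                       for x, y in zip(a1, a2)]
            else:
                gt_of = {0.0: f"0{sep}0", 1.0: f"0{sep}1", 2.0: f"1{sep}1"}
                gts = [gt_of.get(d, f".{sep}.") for d in panel.dosages[:, j]]
            fh.write(f"{snp.chrom}\t{snp.pos_bp}\t{snp.snp_id}\t"
                     f"{snp.ref_allele}\t{snp.alt_allele}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_pop_table(panel: GenotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in panel.sample_ids:
            fh.write(f"{s}\t{panel.pop_of[s]}\n")


# ---------------------------------------------------------------------------
# Marker filters
# ---------------------------------------------------------------------------

def qc_missingness(panel: GenotypePanel, max_missing: float = 0.05) -> GenotypePanel:
    """Drop SNPs whose missing-call fraction is >= ``max_missing``.

    The threshold is applied strictly ("missing rate less than 0.05"
    retains a SNP), so a SNP exactly at the threshold is removed.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    miss = np.isnan(panel.dosages).mean(axis=0)
    keep = miss < max_missing
    log.info("qc_missingness: %d of %d SNPs kept", int(keep.sum()), panel.n_snps)
    return panel.subset(snp_mask=keep)


def thin_by_distance(panel: GenotypePanel, min_gap_bp: int = 500_000) -> GenotypePanel:
    """Greedy left-to-right thinning: keep a SNP iff it lies more than
    ``min_gap_bp`` beyond the last kept SNP on the same chromosome."""
    chroms = panel.chroms()
    pos = panel.pos_bp()
    keep = np.zeros(panel.n_snps, dtype=bool)
    last_chrom, last_pos = None, None
    for j in range(panel.n_snps):
        if chroms[j] != last_chrom or pos[j] - last_pos > min_gap_bp:
            keep[j] = True
            last_chrom, last_pos = chroms[j], pos[j]
    return panel.subset(snp_mask=keep)


def _pairwise_genotype_r2(d: np.ndarray) -> np.ndarray:
    """Squared genotype correlation between columns, pairwise-complete."""
    L = d.shape[1]
    out = np.zeros((L, L))
    finite = ~np.isnan(d)
    for i in range(L):
        for j in range(i + 1, L):
            m = finite[:, i] & finite[:, j]
            if m.sum() < 2:
                continue
            x, y = d[m, i], d[m, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
            out[i, j] = out[j, i] = r * r
    return out


def ld_prune(panel: GenotypePanel, r2_threshold: float = 0.8,
             window_snps: int = 50, step_snps: int = 5) -> GenotypePanel:
    """Sliding-window LD pruning on genotype correlation.

    Within each window, while any remaining pair has r^2 > threshold the
    member with the higher missing rate is removed (tie: the later SNP).
    Deterministic; chromosome boundaries are respected.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    if not 1 <= step_snps <= window_snps:
        raise ValueError("need window_snps >= step_snps >= 1")
    removed = np.zeros(panel.n_snps, dtype=bool)
    missing_rate = np.isnan(panel.dosages).mean(axis=0)
    chroms = panel.chroms()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for start in range(0, len(idx), step_snps):
            win = idx[start:start + window_snps]
            win = win[~removed[win]]
            if len(win) < 2:
                continue
            r2 = _pairwise_genotype_r2(panel.dosages[:, win])
            alive = np.ones(len(win), dtype=bool)
            while True:
                sub = r2[np.ix_(alive, alive)]
                # >= so that threshold 1.0 still removes perfect duplicates
                ii, jj = np.nonzero(np.triu(sub >= r2_threshold - 1e-12, k=1))
                if len(ii) == 0:
                    break
                a_idx = np.flatnonzero(alive)
                i, j = a_idx[ii[0]], a_idx[jj[0]]
                gi, gj = win[i], win[j]
                # drop the member with more missing data; tie -> later position
                drop = i if missing_rate[gi] > missing_rate[gj] else j
                alive[drop] = False
                removed[win[drop]] = True
            if start + window_snps >= len(idx):
                break
    log.info("ld_prune: removed %d of %d SNPs", int(removed.sum()), panel.n_snps)
    return panel.subset(snp_mask=~removed)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(panel: GenotypePanel,
                       populations: Sequence[str] | None = None
                       ) -> AlleleFrequencyTable:
    """Sample alt-allele frequency and haploid sample size per (SNP, pop).

    freq = sum(non-missing dosages) / n_hap with n_hap = 2 * non-missing
    sample count; freq is NaN where n_hap = 0.
    """
    pops = list(populations) if populations is not None else panel.populations
    freq = {}
    n_hap = {}
    for pop in pops:
        rows = panel.sample_indices(panel.samples_of(pop))
        d = panel.dosages[rows]
        n = 2 * (~np.isnan(d)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, np.nansum(d, axis=0) / np.maximum(n, 1), np.nan)
        freq[pop] = f
        n_hap[pop] = n
    idx = pd.Index(panel.snp_ids(), name="snp_id")
    return AlleleFrequencyTable(freq=pd.DataFrame(freq, index=idx),
                                n_hap=pd.DataFrame(n_hap, index=idx))


def write_frequencies(table: AlleleFrequencyTable, path: str | Path) -> None:
    table.to_long().to_csv(path, sep="\t", index=False)
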