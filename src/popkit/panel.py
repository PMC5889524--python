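"""Core genotype containers.

A :class:`GenotypePanel` holds diploid alt-allele dosages for a set of
samples at a set of SNPs, together with population labels and, when the
source data were phased, the underlying haplotypes.  Every analysis stage
in the package consumes and returns panels, so the invariants enforced
here (dosages in {0, 1, 2, missing}, SNPs sorted by genome coordinate,
haplotype pairs summing to the dosage) are checked once and relied on
everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SnpRecord", "GenotypePanel", "AlleleFrequencyTable"]

#: Sentinel for a missing haplotype allele in the int8 haplotype matrix.
HAP_MISSING = -1


@dataclass(frozen=True)
class SnpRecord:
    """A single autosomal SNP: coordinates, alleles and genetic-map position.

    ``pos_cM`` is optional; when no genetic map is supplied the package
    falls back to a uniform 1 cM/Mb rate (``pos_bp * 1e-6``).
    """

    chrom: str
    pos_bp: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    snp_id: str | None = None
    pos_cM: float | None = None

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"pos_bp must be >= 1, got {self.pos_bp}")
        if self.snp_id is None:
            object.__setattr__(self, "snp_id", f"{self.chrom}:{self.pos_bp}")

    @property
    def pos_morgans(self) -> float:
        cm = self.pos_cM if self.pos_cM is not None else self.pos_bp * 1e-6
        return cm / 100.0


def normalize_chrom(label: str) -> str:
    """Strip a leading 'chr' prefix; chromosome labels are compared bare."""
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


AUTOSOMES = {str(i) for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


@dataclass
class GenotypePanel:
    """Samples x SNPs dosage matrix with population labels.

    Parameters
    ----------
    sample_ids:
        Unique sample identifiers, one per dosage row.
    pop_of:
        Mapping of every sample id to its population name.
    snps:
        SNP metadata, strictly ordered by (chromosome, position).
    dosages:
        float array (n_samples, n_snps) of alt-allele counts; missing
        genotypes are ``numpy.nan``.
    phased:
        True iff every genotype in the source was phased, in which case
        ``haplotypes`` holds a (2*n_samples, n_snps) int8 matrix with
        rows 2i, 2i+1 belonging to sample i (alt allele = 1, missing = -1).
    """

    sample_ids: list[str]
    pop_of: dict[str, str]
    snps: list[SnpRecord]
    dosages: np.ndarray
    phased: bool = False
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, L = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.snps) != L:
            raise ValueError("snps length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        missing_labels = [s for s in self.sample_ids if s not in self.pop_of]
        if missing_labels:
            raise ValueError(f"samples without population label: {missing_labels[:5]}")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        keys = [(normalize_chrom(s.chrom), s.pos_bp) for s in self.snps]
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
            raise ValueError("snps must be strictly ordered by (chrom, pos)")
        if self.phased:
            if self.haplotypes is None:
                raise ValueError("phased panel requires haplotypes")
            if self.haplotypes.shape != (2 * n, L):
                raise ValueError("haplotypes must be (2*n_samples, n_snps)")
            h = self.haplotypes
            pair = np.where((h[0::2] >= 0) & (h[1::2] >= 0),
                            h[0::2].astype(float) + h[1::2], np.nan)
            d = self.dosages
            ok = np.isnan(pair) == np.isnan(d)
            ok &= np.isnan(pair) | (pair == np.nan_to_num(d))
            if not ok.all():
                raise ValueError("haplotype pair sums disagree with dosages")
        elif self.haplotypes is not None:
            raise ValueError("haplotypes present on unphased panel")

    # -- convenience -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_of[s], None)
        return list(seen)

    def samples_of(self, population: str) -> list[str]:
        out = [s for s in self.sample_ids if self.pop_of[s] == population]
        if not out:
            raise KeyError(f"unknown population: {population!r}")
        return out

    def sample_indices(self, samples: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([index[s] for s in samples], dtype=int)

    def pos_bp(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.snps], dtype=int)

    def pos_morgans(self) -> np.ndarray:
        return np.array([s.pos_morgans for s in self.snps], dtype=float)

    def chroms(self) -> np.ndarray:
        return np.array([normalize_chrom(s.chrom) for s in self.snps])

    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]  # type: ignore[misc]

    def subset(self,
               samples: Sequence[str] | None = None,
               snp_mask: np.ndarray | None = None) -> "GenotypePanel":
        """Return a new panel restricted to the given samples and/or SNP mask."""
        rows = (self.sample_indices(samples) if samples is not None
                else np.arange(self.n_samples))
        cols = (np.flatnonzero(np.asarray(snp_mask)) if snp_mask is not None
                else np.arange(self.n_snps))
        sample_ids = [self.sample_ids[i] for i in rows]
        haps = None
        if self.phased and self.haplotypes is not None:
            hap_rows = np.ravel(np.column_stack([2 * rows, 2 * rows + 1]))
            haps = self.haplotypes[np.ix_(hap_rows, cols)].copy()
        return GenotypePanel(
            sample_ids=sample_ids,
            pop_of={s: self.pop_of[s] for s in sample_ids},
            snps=[self.snps[j] for j in cols],
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
            phased=self.phased,
            haplotypes=haps,
        )

    def haplotypes_of(self, population: str) -> np.ndarray:
        """Haplotype matrix (rows = chromosomes) of one population."""
        if not self.phased or self.haplotypes is None:
            raise ValueError("panel is not phased")
        rows = self.sample_indices(self.samples_of(population))
        hap_rows = np.ravel(np.column_stack([2 * rows, 2 * rows + 1]))
        return self.haplotypes[hap_rows]

    def with_genetic_positions(self, cm: Sequence[float]) -> "GenotypePanel":
        snps = [replace(s, pos_cM=float(c)) for s, c in zip(self.snps, cm)]
        return GenotypePanel(self.sample_ids, dict(self.pop_of), snps,
                             self.dosages.copy(), self.phased,
                             None if self.haplotypes is None else self.haplotypes.copy())


@dataclass
class AlleleFrequencyTable:
    """Per-population sample allele frequencies with haploid sample sizes.

    ``freq`` and ``n_hap`` are DataFrames indexed by SNP id with one column
    per population; a frequency is NaN wherever ``n_hap`` is zero.
    """

    freq: pd.DataFrame
    n_hap: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.freq.index.equals(self.n_hap.index):
            raise ValueError("freq and n_hap index mismatch")
        if list(self.freq.columns) != list(self.n_hap.columns):
            raise ValueError("freq and n_hap column mismatch")
        vals = self.freq.to_numpy()
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 1:
                raise ValueError("frequencies outside [0, 1]")
        if (self.n_hap.to_numpy() < 0).any():
            raise ValueError("negative n_hap")
        if np.isnan(vals[self.n_hap.to_numpy() > 0]).any():
            raise ValueError("NaN frequency with positive n_hap")

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    def to_long(self) -> pd.DataFrame:
        long = self.freq.stack(future_stack=True).rename("freq").reset_index()
        long.columns = ["snp_id", "pop", "freq"]
        long["n_hap"] = self.n_hap.stack(future_stack=True).to_numpy()
        return long
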