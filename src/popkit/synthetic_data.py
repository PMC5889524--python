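"""Synthetic genotype panels with known truth.

Three generators cover the quantities the analysis stages estimate, so
each stage has a recovery test against a known parameter:

* :func:`simulate_divergence` — Balding–Nichols drift on a star tree.
  Each population's per-SNP allele frequency is Beta-distributed around a
  shared ancestral frequency with drift parameter F, which sets the
  expected allele-frequency variance F*p*(1-p) and hence the F_ST scale.
* :func:`simulate_admixed_targets` — target individuals whose alleles are
  drawn from donor population A's frequency with probability alpha, else
  donor B's, so the true mixing proportion of every target is known.
* :func:`simulate_wright_fisher_haplotypes` — a forward-time
  Wright–Fisher population of 2*N_e recombining haplotypes, producing
  phased samples whose r^2-vs-distance decay is governed by a known N_e.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel, SnpRecord

__all__ = [
    "DivergenceModel", "AdmixtureScenario", "WrightFisherConfig",
    "simulate_divergence", "simulate_admixed_targets",
    "simulate_wright_fisher_haplotypes",
]


def _snp_grid(n_snps: int, chrom: str = "1", spacing_bp: int = 100_000
              ) -> list[SnpRecord]:
    return [SnpRecord(chrom=chrom, pos_bp=(j + 1) * spacing_bp,
                      snp_id=f"snp{j}") for j in range(n_snps)]


@dataclass
class DivergenceModel:
    """Star-tree drift model: (name, drift_F, n_samples) per population.

    ``drift_F`` is the Balding–Nichols drift of the branch leading to the
    population: 0 means the population sits at the ancestral frequency,
    values approaching 1 mean near-fixation of one allele.  Ancestral
    frequencies are Uniform(lo, hi); the default (0.05, 0.95) avoids
    monomorphic SNPs, mimicking array-SNP ascertainment.
    """

    pop_specs: list[tuple[str, float, int]]
    n_snps: int = 10_000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, F, n in self.pop_specs:
            if not 0 <= F < 1:
                raise ValueError(f"drift_F must be in [0, 1), got {F} for {name}")
            if n < 1:
                raise ValueError(f"n_samples must be >= 1 for {name}")


def simulate_divergence(model: DivergenceModel,
                        return_truth: bool = False):
    """Draw a multi-population panel under the Balding–Nichols model.

    With drift F, a population's frequency at a SNP with ancestral
    frequency p is Beta(p(1-F)/F, (1-p)(1-F)/F) (mean p, variance
    F*p*(1-p)); F = 0 leaves the frequency exactly at p.  Genotypes are
    Binomial(2, pop frequency).

    When ``return_truth`` is set, also returns a dict with the ancestral
    and per-population true frequencies.
    """
    rng = np.random.default_rng(model.seed)
    lo, hi = model.ancestral_freq_range
    p = rng.uniform(lo, hi, model.n_snps)
    sample_ids: list[str] = []
    pop_of: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    pop_freqs: dict[str, np.ndarray] = {}
    for name, F, n in model.pop_specs:
        if F == 0:
            q = p.copy()
        else:
            q = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        pop_freqs[name] = q
        blocks.append(rng.binomial(2, q, size=(n, model.n_snps)).astype(float))
        ids = [f"{name}_{i}" for i in range(n)]
        sample_ids.extend(ids)
        pop_of.update({s: name for s in ids})
    panel = GenotypePanel(sample_ids=sample_ids, pop_of=pop_of,
                          snps=_snp_grid(model.n_snps),
                          dosages=np.vstack(blocks))
    if return_truth:
        return panel, {"ancestral_freq": p, "pop_freqs": pop_freqs}
    return panel


@dataclass
class AdmixtureScenario:
    """Targets mixed from two source populations with known proportions.

    ``alphas`` lists, per target population, the probability that any one
    allele of a target individual descends from source A (the rest come
    from source B).
    """

    source_pops: tuple[str, str]
    alphas: list[float]
    n_samples: int = 50
    target_prefix: str = "MIX"
    seed: int = 0

    def __post_init__(self) -> None:
        for a in self.alphas:
            if not 0 <= a <= 1:
                raise ValueError(f"alpha must be in [0, 1], got {a}")


def simulate_admixed_targets(scenario: AdmixtureScenario,
                             source_panel: GenotypePanel) -> GenotypePanel:
    """Append admixed target populations to a copy of ``source_panel``.

    Each of the two alleles of a target individual at a SNP is drawn as a
    Bernoulli from source A's sample frequency with probability alpha and
    from source B's otherwise, so E[target frequency] =
    alpha*p_A + (1-alpha)*p_B.  Target populations are labelled
    ``{prefix}_a{alpha}`` and the true alpha is returned in the label map.
    """
    from .genotype_io import allele_frequencies

    a_pop, b_pop = scenario.source_pops
    freqs = allele_frequencies(source_panel, [a_pop, b_pop])
    p_a = freqs.freq[a_pop].to_numpy()
    p_b = freqs.freq[b_pop].to_numpy()
    if np.isnan(p_a).any() or np.isnan(p_b).any():
        raise ValueError("source populations have SNPs with no data")
    rng = np.random.default_rng(scenario.seed)
    L = source_panel.n_snps
    sample_ids = list(source_panel.sample_ids)
    pop_of = dict(source_panel.pop_of)
    blocks = [source_panel.dosages]
    for alpha in scenario.alphas:
        name = f"{scenario.target_prefix}_a{alpha:g}"
        dos = np.zeros((scenario.n_samples, L))
        for _ in range(2):  # two independent allele draws per individual
            from_a = rng.random((scenario.n_samples, L)) < alpha
            p = np.where(from_a, p_a, p_b)
            dos += rng.random((scenario.n_samples, L)) < p
        blocks.append(dos)
        ids = [f"{name}_{i}" for i in range(scenario.n_samples)]
        sample_ids.extend(ids)
        pop_of.update({s: name for s in ids})
    return GenotypePanel(sample_ids=sample_ids, pop_of=pop_of,
                         snps=list(source_panel.snps),
                         dosages=np.vstack(blocks))


@dataclass
class WrightFisherConfig:
    """Forward Wright–Fisher simulation of recombining haplotypes.

    ``n_loci`` loci are equally spaced along ``chrom_length_cM``.  The
    population holds 2*N_e haplotypes; each offspring haplotype is a
    recombinant of two uniformly chosen parental haplotypes with a
    Poisson(length in Morgans) number of crossovers at uniform positions.
    The run starts from linkage equilibrium with locus frequencies drawn
    from ``init_freq_range`` and lasts ``n_generations`` (default: N_e
    generations, the horizon at which the r^2 = 1/(2 + 4*N_e*c) inversion
    used downstream is approximately unbiased for this mutation-free
    model; see the methods note).
    """

    N_e: int = 500
    n_generations: int | None = None
    n_loci: int = 100
    chrom_length_cM: float = 6.0
    init_freq_range: tuple[float, float] = (0.2, 0.8)
    sample_haplotypes: int = 200
    pop_name: str = "WF"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_e < 2:
            raise ValueError("N_e must be >= 2")
        if self.n_loci < 2:
            raise ValueError("n_loci must be >= 2")
        if self.chrom_length_cM <= 0:
            raise ValueError("chrom_length_cM must be positive")
        if self.n_generations is None:
            self.n_generations = self.N_e
        if self.sample_haplotypes > 2 * self.N_e:
            raise ValueError("cannot sample more haplotypes than 2*N_e")
        if self.sample_haplotypes % 2:
            raise ValueError("sample_haplotypes must be even (diploid samples)")


def simulate_wright_fisher_haplotypes(config: WrightFisherConfig) -> GenotypePanel:
    """Run the forward simulation and return a phased panel.

    Sampled haplotypes are paired into diploid individuals; locus
    positions are encoded so that the default 1 cM/Mb fallback reproduces
    the simulated genetic distances exactly (pos_cM is set explicitly).
    """
    rng = np.random.default_rng(config.seed)
    H = 2 * config.N_e
    L_mor = config.chrom_length_cM / 100.0
    pos_mor = np.linspace(0.0, L_mor, config.n_loci)
    lo, hi = config.init_freq_range
    init_p = rng.uniform(lo, hi, config.n_loci)
    pop = (rng.random((H, config.n_loci)) < init_p).astype(np.uint8)

    for _ in range(int(config.n_generations)):
        parent1 = rng.integers(0, H, H)
        parent2 = rng.integers(0, H, H)
        n_cross = rng.poisson(L_mor, H)
        new = pop[parent1].copy()
        for i in np.flatnonzero(n_cross):
            cuts = np.sort(rng.uniform(0.0, L_mor, n_cross[i]))
            # odd number of cuts to the left of a locus -> copy from parent 2
            from_p2 = (np.searchsorted(cuts, pos_mor, side="right") % 2).astype(bool)
            new[i, from_p2] = pop[parent2[i], from_p2]
        pop = new

    sel = rng.choice(H, config.sample_haplotypes, replace=False)
    haps = pop[sel].astype(np.int8)
    n_samples = config.sample_haplotypes // 2
    dosages = (haps[0::2].astype(float) + haps[1::2]).astype(float)
    snps = [SnpRecord(chrom="1", pos_bp=j + 1, snp_id=f"wf{j}",
                      pos_cM=float(pos_mor[j] * 100.0))
            for j in range(config.n_loci)]
    ids = [f"{config.pop_name}_{i}" for i in range(n_samples)]
    return GenotypePanel(sample_ids=ids,
                         pop_of={s: config.pop_name for s in ids},
                         snps=snps, dosages=dosages,
                         phased=True, haplotypes=haps)
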