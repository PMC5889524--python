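import numpy as np
import pandas as pd
import pytest

from popkit import DivergenceModel, GenotypePanel, SnpRecord, simulate_divergence


def make_panel(dosages, pops, positions=None, chroms=None, phased=False,
               haplotypes=None):
    """Build a small panel from a dosage matrix and per-sample pop labels."""
    dosages = np.asarray(dosages, dtype=float)
    n, L = dosages.shape
    ids = [f"s{i}" for i in range(n)]
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(L)]
    if chroms is None:
        chroms = ["1"] * L
    snps = [SnpRecord(chrom=c, pos_bp=int(p), snp_id=f"m{j}")
            for j, (c, p) in enumerate(zip(chroms, positions))]
    return GenotypePanel(sample_ids=ids,
                         pop_of={s: p for s, p in zip(ids, pops)},
                         snps=snps, dosages=dosages, phased=phased,
                         haplotypes=haplotypes)


@pytest.fixture(scope="session")
def two_pop_panel():
    """Two moderately drifted populations, fixed seed."""
    return simulate_divergence(DivergenceModel(
        pop_specs=[("P1", 0.05, 40), ("P2", 0.05, 40)],
        n_snps=3000, seed=101))


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)
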