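"""Ancestry-informative-marker (AIM) panel selection.

A panel for a population pair is grown greedily: SNPs are ranked by
per-SNP Weir–Cockerham F_ST, the highest-ranked SNP that keeps all
pairwise inter-marker distances above the 500 kb floor is added, and the
panel's classification quality is scored after every addition as the
Matthews correlation coefficient of a PC1 midpoint classifier.  Selection
stops when the MCC reaches its target (1.0 = perfect separation) or the
panel hits its size cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import GenotypePanel
from .popstructure import pca, per_snp_fst

__all__ = ["ConfusionCounts", "AimPanel", "mcc", "classify_by_pc1",
           "select_aims"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); defined as 0
    when any factor of the denominator is zero.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def classify_by_pc1(panel: GenotypePanel, popA: str, popB: str
                    ) -> ConfusionCounts:
    """Classify the two populations' samples by thresholding PC1.

    PCA is run on the given (AIM-restricted) panel limited to the two
    populations; the threshold is the midpoint of the two population mean
    PC1 scores and orientation is chosen so that population A lies on the
    positive side.  Population A is the "positive" class.
    """
    samples = panel.samples_of(popA) + panel.samples_of(popB)
    sub = panel.subset(samples=samples)
    res = pca(sub, n_components=1)
    pc1 = res.coordinates[:, 0]
    labels = np.array([sub.pop_of[s] == popA for s in sub.sample_ids])
    mean_a = pc1[labels].mean()
    mean_b = pc1[~labels].mean()
    if mean_a < mean_b:
        pc1 = -pc1
        mean_a, mean_b = -mean_a, -mean_b
    thr = 0.5 * (mean_a + mean_b)
    pred_a = pc1 > thr
    return ConfusionCounts(
        TP=int((pred_a & labels).sum()),
        TN=int((~pred_a & ~labels).sum()),
        FP=int((pred_a & ~labels).sum()),
        FN=int((~pred_a & labels).sum()),
    )


@dataclass
class AimPanel:
    pair: tuple[str, str]
    snp_ids: list[str]
    snp_indices: list[int]
    mcc_trajectory: list[float]
    final_mcc: float
    min_gap_bp: int
    reached_target: bool

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def select_aims(panel: GenotypePanel, popA: str, popB: str,
                min_gap_bp: int = 500_000, target_mcc: float = 1.0,
                max_snps: int = 200) -> AimPanel:
    """Greedy AIM selection for one population pair.

    SNPs are ranked by per-SNP F_ST (descending, ties broken by panel
    order); a candidate is admitted only if its distance to every
    already-selected SNP on the same chromosome exceeds ``min_gap_bp``.
    After each admission the MCC of the PC1 classifier on the current
    panel is recorded; selection stops at ``target_mcc`` or ``max_snps``.
    When the target is unreachable the best panel found is returned with
    ``reached_target=False``.
    """
    if popA == popB:
        raise ValueError("populations must be distinct")
    fst = per_snp_fst(panel, popA, popB)
    order = np.argsort(-np.nan_to_num(fst, nan=-np.inf), kind="stable")
    chroms = panel.chroms()
    pos = panel.pos_bp()
    selected: list[int] = []
    trajectory: list[float] = []
    current = 0.0
    for j in order:
        if np.isnan(fst[j]):
            break  # ranked below every informative SNP
        ok = all(chroms[j] != chroms[k] or abs(pos[j] - pos[k]) > min_gap_bp
                 for k in selected)
        if not ok:
            continue
        selected.append(int(j))
        mask = np.zeros(panel.n_snps, dtype=bool)
        mask[selected] = True
        counts = classify_by_pc1(panel.subset(snp_mask=mask), popA, popB)
        current = mcc(counts)
        trajectory.append(current)
        if current >= target_mcc or len(selected) >= max_snps:
            break
    selected_sorted = sorted(selected)
    # trajectory order matches addition order; ids reported in genome order
    ids = [panel.snps[k].snp_id for k in selected_sorted]
    return AimPanel(pair=(popA, popB), snp_ids=ids,  # type: ignore[arg-type]
                    snp_indices=selected_sorted,
                    mcc_trajectory=trajectory,
                    final_mcc=current,
                    min_gap_bp=min_gap_bp,
                    reached_target=current >= target_mcc)
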