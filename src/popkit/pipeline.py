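"""Config-driven orchestration of the full analysis flow.

A run takes a JSON config describing either input files (VCF + population
TSV, optional genetic map) or a synthetic-panel spec, and executes the
enabled stages in dependency order:

    qc -> structure (F_ST / ASD / NJ / PCA / K-means)
       -> aims
       -> ld (r^2 classes, N_e trajectories, divergence times)
       -> fstats (D / f3 / f4)
       -> f4_regression

Each stage writes TSV (or newick) outputs into the output directory and
the run finishes with a ``manifest.json`` recording inputs, parameters,
seeds and per-stage SNP/sample bookkeeping.  A stage failure aborts its
dependents but not independent stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import (AdmixtureScenario, DivergenceModel, JackknifeConfig,
               WrightFisherConfig, allele_frequencies, apply_genetic_map,
               asd_matrix, bin_r2, d_stat, divergence_time, f3, f4,
               f4_ratio_regression, fst_matrix, interpop_ne, kmeans_on_pcs,
               ld_prune, ne_trajectory, nj_tree, pairwise_fst, pca,
               qc_missingness, read_genetic_map, read_vcf, select_aims,
               simulate_admixed_targets, simulate_divergence,
               simulate_wright_fisher_haplotypes, thin_by_distance)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """Parsed run configuration; see :func:`RunConfig.from_dict`."""

    raw: dict[str, Any]
    out_dir: Path
    seed: int = 0

    @classmethod
    def from_dict(cls, cfg: dict[str, Any], out_dir: str | Path) -> "RunConfig":
        if "input" not in cfg and "simulate" not in cfg:
            raise ValueError("config needs an 'input' or 'simulate' section")
        return cls(raw=cfg, out_dir=Path(out_dir), seed=int(cfg.get("seed", 0)))

    @classmethod
    def from_json(cls, path: str | Path, out_dir: str | Path | None = None
                  ) -> "RunConfig":
        cfg = json.loads(Path(path).read_text())
        return cls.from_dict(cfg, out_dir or cfg.get("out_dir", "popkit_out"))


def _build_panel(cfg: RunConfig, manifest: dict[str, Any]):
    raw = cfg.raw
    if "input" in raw:
        inp = raw["input"]
        panel = read_vcf(inp["vcf"], inp["pop_table"],
                         inp.get("genetic_map"))
        manifest["input"] = {k: str(v) for k, v in inp.items()}
    else:
        sim = raw["simulate"]
        kind = sim["kind"]
        seed = int(sim.get("seed", cfg.seed))
        if kind == "divergence":
            model = DivergenceModel(
                pop_specs=[tuple(s) for s in sim["pop_specs"]],
                n_snps=int(sim.get("n_snps", 10_000)), seed=seed)
            panel = simulate_divergence(model)
        elif kind == "admixture":
            src = DivergenceModel(
                pop_specs=[tuple(s) for s in sim["pop_specs"]],
                n_snps=int(sim.get("n_snps", 10_000)), seed=seed)
            panel = simulate_divergence(src)
            scen = AdmixtureScenario(
                source_pops=tuple(sim["source_pops"]),
                alphas=[float(a) for a in sim["alphas"]],
                n_samples=int(sim.get("n_samples", 50)), seed=seed + 1)
            panel = simulate_admixed_targets(scen, panel)
        elif kind == "wright_fisher":
            wf = WrightFisherConfig(
                N_e=int(sim.get("N_e", 500)),
                n_loci=int(sim.get("n_loci", 100)),
                chrom_length_cM=float(sim.get("chrom_length_cM", 6.0)),
                sample_haplotypes=int(sim.get("sample_haplotypes", 200)),
                seed=seed)
            panel = simulate_wright_fisher_haplotypes(wf)
        else:
            raise ValueError(f"unknown simulation kind {kind!r}")
        manifest["simulate"] = sim
    manifest["panel"] = {"n_samples": panel.n_samples, "n_snps": panel.n_snps,
                         "populations": panel.populations,
                         "phased": panel.phased}
    return panel


def run(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest dict."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stages = config.raw.get("stages", {})
    jk_cfg = config.raw.get("jackknife", {})
    jk = JackknifeConfig(n_blocks=int(jk_cfg.get("n_blocks", 500)))
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {},
                                "outputs": [], "errors": {}}

    def record(stage: str, **info: Any) -> None:
        manifest["stages"][stage] = info

    def emit(name: str) -> Path:
        path = out / name
        manifest["outputs"].append(name)
        return path

    panel = _build_panel(config, manifest)

    # ---- qc --------------------------------------------------------------
    qc = stages.get("qc", {})
    if qc.get("enabled", True):
        before = panel.n_snps
        panel = qc_missingness(panel, float(qc.get("max_missing", 0.05)))
        record("qc", snps_in=before, snps_out=panel.n_snps,
               removed=before - panel.n_snps)

    freqs = allele_frequencies(panel)

    # ---- structure --------------------------------------------------------
    st = stages.get("structure", {})
    structure_panel = panel
    if st.get("enabled", True):
        try:
            info: dict[str, Any] = {"snps_in": panel.n_snps}
            if st.get("ld_prune", False):
                lp = st["ld_prune"] if isinstance(st["ld_prune"], dict) else {}
                structure_panel = ld_prune(
                    structure_panel,
                    r2_threshold=float(lp.get("r2_threshold", 0.8)),
                    window_snps=int(lp.get("window_snps", 50)),
                    step_snps=int(lp.get("step_snps", 5)))
                info["snps_after_ld_prune"] = structure_panel.n_snps
            if st.get("thin_gap_bp"):
                structure_panel = thin_by_distance(structure_panel,
                                                   int(st["thin_gap_bp"]))
                info["snps_after_thinning"] = structure_panel.n_snps
            fm = fst_matrix(structure_panel)
            fm.to_tsv(emit("fst_matrix.tsv"))
            dm = asd_matrix(structure_panel)
            dm.to_tsv(emit("asd_matrix.tsv"))
            emit("nj_individuals.nwk").write_text(nj_tree(dm) + "\n")
            p = pca(structure_panel, n_components=int(st.get("n_pcs", 10)))
            df = p.to_frame()
            k = df.shape[1]
            df.loc["var_frac_total"] = list(p.var_frac_total[:k])
            df.loc["var_frac_top10"] = list(p.var_frac_top10[:k])
            df.to_csv(emit("pca.tsv"), sep="\t")
            K = int(st.get("kmeans_k", len(structure_panel.populations)))
            km = kmeans_on_pcs(p, structure_panel, K=K,
                               n_pcs=int(st.get("n_pcs", 10)),
                               seed=config.seed)
            km.fractions.to_csv(emit("kmeans_fractions.tsv"), sep="\t")
            info["snps_analyzed"] = structure_panel.n_snps
            record("structure", **info)
        except Exception as exc:  # independent stages continue
            manifest["errors"]["structure"] = str(exc)
            log.exception("structure stage failed")

    # ---- aims -------------------------------------------------------------
    am = stages.get("aims", {})
    if am.get("enabled", False):
        try:
            rows = []
            for pair in am["pairs"]:
                a, b = pair
                res = select_aims(panel, a, b,
                                  min_gap_bp=int(am.get("min_gap_bp", 500_000)),
                                  target_mcc=float(am.get("target_mcc", 1.0)),
                                  max_snps=int(am.get("max_snps", 200)))
                rows.append({"popA": a, "popB": b, "panel_size": res.size,
                             "final_mcc": res.final_mcc,
                             "reached_target": res.reached_target})
                traj = emit(f"aims_{a}_{b}_trajectory.tsv")
                with open(traj, "w") as fh:
                    fh.write("n_snps\tmcc\n")
                    for i, v in enumerate(res.mcc_trajectory, 1):
                        fh.write(f"{i}\t{v:.6g}\n")
            import pandas as pd
            pd.DataFrame(rows).to_csv(emit("aims_summary.tsv"),
                                      sep="\t", index=False)
            record("aims", pairs=len(rows))
        except Exception as exc:
            manifest["errors"]["aims"] = str(exc)
            log.exception("aims stage failed")

    # ---- ld / demography ----------------------------------------------
    ld = stages.get("ld", {})
    if ld.get("enabled", False):
        if not panel.phased:
            record("ld", skipped="panel is not phased")
        else:
            try:
                import pandas as pd
                pops = ld.get("populations", panel.populations)
                c_lo = float(ld.get("c_min_cM", 0.001))
                c_hi = float(ld.get("c_max_cM", 2.5))
                width = float(ld.get("width_cM", 0.001))
                trajs = {}
                for pop in pops:
                    bins = bin_r2(panel, pop, c_lo, c_hi, width,
                                  min_maf=float(ld.get("min_maf", 0.05)))
                    traj = ne_trajectory(bins, pop)
                    trajs[pop] = traj
                    traj.to_tsv(emit(f"ne_trajectory_{pop}.tsv"))
                rng = tuple(ld.get("interpop_range_cM", (0.01, 0.25)))
                rows = []
                for i, a in enumerate(pops):
                    for b in pops[i + 1:]:
                        ne = interpop_ne(trajs[a], trajs[b], c_range_cM=rng)
                        fst, _ = pairwise_fst(panel, a, b)
                        est = divergence_time(
                            (a, b), fst, ne,
                            years_per_generation=float(
                                ld.get("years_per_generation", 25.0)))
                        rows.append({"popA": a, "popB": b, "fst": est.fst,
                                     "ne_interpop": est.ne_interpop,
                                     "t_generations": est.t_generations,
                                     "t_years": est.t_years})
                if rows:
                    pd.DataFrame(rows).to_csv(emit("divergence_times.tsv"),
                                              sep="\t", index=False)
                record("ld", populations=list(pops), n_pairs=len(rows))
            except Exception as exc:
                manifest["errors"]["ld"] = str(exc)
                log.exception("ld stage failed")

    # ---- fstats ---------------------------------------------------------
    fs = stages.get("fstats", {})
    if fs.get("enabled", False):
        try:
            import pandas as pd
            rows = []
            for quad in fs.get("dstat", []):
                r = d_stat(freqs, *quad, jk=jk)
                rows.append(r)
            for tri in fs.get("f3", []):
                rows.append(f3(freqs, *tri, jk=jk))
            for quad in fs.get("f4", []):
                rows.append(f4(freqs, *quad, jk=jk))
            pd.DataFrame([{"statistic": r.statistic,
                           "pops": ",".join(r.pops), "value": r.value,
                           "se": r.jackknife_se, "Z": r.z,
                           "significant": r.significant,
                           "n_snps": r.n_snps} for r in rows]
                         ).to_csv(emit("fstats.tsv"), sep="\t", index=False)
            record("fstats", n_tests=len(rows))
        except Exception as exc:
            manifest["errors"]["fstats"] = str(exc)
            log.exception("fstats stage failed")

    # ---- f4 regression --------------------------------------------------
    fr = stages.get("f4_regression", {})
    if fr.get("enabled", False):
        try:
            reg = f4_ratio_regression(freqs, fr["outgroup"], fr["donorA"],
                                      fr["donorB"], list(fr["targets"]), jk=jk)
            tab = reg.points.join(reg.alphas)
            tab.to_csv(emit("f4_regression.tsv"), sep="\t")
            record("f4_regression", intercept_l=reg.intercept_l,
                   slope=reg.slope, m_edge=reg.m_edge,
                   r_squared=reg.r_squared, warnings=reg.warnings)
        except Exception as exc:
            manifest["errors"]["f4_regression"] = str(exc)
            log.exception("f4_regression stage failed")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    manifest["outputs"].append("manifest.json")
    return manifest
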