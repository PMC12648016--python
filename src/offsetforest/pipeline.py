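"""End-to-end pipeline: simulate -> filter -> popgen -> GEA ->
introgression -> gradient forest -> offsets, driven by one YAML config
with a single global seed and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (SimConfig, assign_regions, compare_groups, compute_mem,
               diversity_stats, filter_snps, fit_gradient_forest,
               forward_offset, intersect_candidates, ld_prune, lfmm_associate,
               local_offset, make_landscape, offset_decline_curve, patterson_d,
               pca, rda_associate, reverse_offset, select_uncorrelated_vars,
               simulate_genotypes, transform_climate, window_fdm, write_vcf,
               write_metadata, call_introgressed_windows)

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "popgen", "gea", "introgression",
          "gradient_forest", "offsets"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds, at the workflow's standard defaults."""

    seed: int = 0
    out_dir: str = "run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # filtering
    maf_min: float = 0.01
    max_missing: float = 0.4
    # LD pruning
    ld_window: int = 100
    ld_step: int = 10
    ld_r2_max: float = 0.2
    # popgen
    covered_bases: int = 6_973_000
    mem_k: int = 5
    # GEA
    k_latent: int = 3
    alpha: float = 0.05
    sd_mult: float = 3.0
    r_max: float = 0.7
    # introgression
    window_snps: int = 50
    step_snps: int = 25
    fdm_min: float = 0.15
    trios: list[list[str]] = field(default_factory=lambda: [
        ["West", "Wmix", "South", "East"],
        ["East", "Emix", "South", "West"]])
    # gradient forest
    n_trees: int = 500
    # offsets
    distance_caps: list[float] = field(default_factory=lambda: [
        50.0, 100.0, 250.0, 500.0, float("inf")])
    max_km: float | None = None
    # simulation block
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["max_km"] = self.max_km
        Path(path).write_text(yaml.safe_dump(d))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order.

    Writes per-stage artifacts plus ``manifest.json`` (seed, per-stage
    parameters, artifact hashes) into ``config.out_dir`` and returns
    the manifest.  Raises when a stage needs an artifact of a disabled
    upstream stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in config.stages]
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    state: dict = {}

    def need(stage: str, key: str):
        if key not in state:
            raise RuntimeError(
                f"stage {stage!r} needs output {key!r}; enable the stage "
                "that produces it")
        return state[key]

    for stage in enabled:
        params: dict = {}
        if stage == "simulate":
            sim_cfg = SimConfig(seed=config.seed, **config.sim)
            current, future = make_landscape(sim_cfg)
            G, truth = simulate_genotypes(sim_cfg, current)
            state.update(G=G, truth=truth, current=current, future=future)
            write_vcf(G, out / "genotypes.vcf")
            write_metadata(G.samples, out / "samples.tsv")
            truth.to_json(out / "ground_truth.json")
            current.to_dir(out / "climate_current")
            future.to_dir(out / "climate_future")
            params = {"n_loci": G.n_loci, "n_samples": G.n_samples}
        elif stage == "filter":
            G = need(stage, "G")
            Gf = filter_snps(G, config.maf_min, config.max_missing)
            state["Gf"] = Gf
            write_vcf(Gf, out / "genotypes.filtered.vcf")
            params = {"maf_min": config.maf_min,
                      "max_missing": config.max_missing,
                      "n_retained": Gf.n_loci}
        elif stage == "popgen":
            Gf = need(stage, "Gf")
            kept = ld_prune(Gf, config.ld_window, config.ld_step,
                            config.ld_r2_max)
            np.savetxt(out / "ld_pruned.ids", kept, fmt="%d")
            div = diversity_stats(Gf, config.covered_bases)
            div.to_tsv(out / "diversity.tsv", out / "fst.tsv")
            scores, ev = pca(Gf.take_loci(kept), n_components=4)
            pd.DataFrame(scores,
                         index=Gf.samples["sample_id"]).to_csv(
                out / "pca_scores.tsv", sep="\t")
            sites = Gf.samples.drop_duplicates("population")
            mem, _, _ = compute_mem(sites["lon"], sites["lat"], k=config.mem_k)
            mem_df = pd.DataFrame(
                mem, index=sites["population"],
                columns=[f"MEM{i + 1}" for i in range(mem.shape[1])])
            state.update(ld_kept=kept, mem=mem_df, pca_ev=ev)
            mem_df.to_csv(out / "mem.tsv", sep="\t")
            params = {"n_pruned": len(kept), "pca_ev": list(map(float, ev))}
        elif stage == "gea":
            Gf = need(stage, "Gf")
            current = need(stage, "current")
            mem_df = need(stage, "mem")
            env_site = current.values_at(Gf.samples["lon"].to_numpy(),
                                         Gf.samples["lat"].to_numpy())
            env = pd.DataFrame(env_site, columns=current.names)
            kept_vars, _ = select_uncorrelated_vars(env, config.r_max)
            mem_rows = mem_df.loc[Gf.samples["population"]].reset_index(
                drop=True)
            lf = lfmm_associate(Gf, env, K=config.k_latent,
                                alpha=config.alpha)
            rd = rda_associate(
                Gf, pd.concat([env[kept_vars], mem_rows], axis=1),
                sd_mult=config.sd_mult)
            shared, venn = intersect_candidates(lf.lfmm_candidates,
                                                rd.rda_candidates)
            state.update(env=env, kept_vars=kept_vars,
                         candidates=sorted(shared), lfmm=lf, rda=rd)
            (out / "venn.json").write_text(json.dumps(venn))
            lf.lfmm.to_csv(out / "lfmm.tsv", sep="\t", index=False)
            np.savetxt(out / "candidates.ids", sorted(shared), fmt="%d")
            params = {"kept_vars": kept_vars, "venn": venn}
        elif stage == "introgression":
            Gf = need(stage, "Gf")
            trio_rows = []
            scans = {}
            for trio in config.trios:
                res = patterson_d(Gf, trio, f4_seed=config.seed)
                trio_rows.append({
                    "P1": trio[0], "P2": trio[1], "P3": trio[2],
                    "O": trio[3], "D": res.d, "Z": res.z,
                    "f4_ratio": res.f4_ratio, "BBAA": res.bbaa,
                    "ABBA": res.abba, "BABA": res.baba})
                scan = window_fdm(Gf, trio, config.window_snps,
                                  config.step_snps, fdm_min=config.fdm_min)
                scans[trio[1]] = scan
                scan.to_tsv(out / f"fdm_{trio[1]}.tsv")
            pd.DataFrame(trio_rows).to_csv(out / "dstats.tsv", sep="\t",
                                           index=False)
            state["scans"] = scans
            params = {"n_trios": len(config.trios)}
        elif stage == "gradient_forest":
            Gf = need(stage, "Gf")
            candidates = need(stage, "candidates")
            env = need(stage, "env")
            mem_df = need(stage, "mem")
            if not candidates:
                raise RuntimeError("gradient_forest: no candidate SNPs from "
                                   "the gea stage")
            Gc = Gf.take_loci(candidates)
            freqs = Gc.group_freqs(by="population")
            freqs.columns = [f"snp{c}" for c in candidates]
            env_pop = env.groupby(Gf.samples["population"].to_numpy()).mean()
            env_pop = env_pop.loc[freqs.index]
            preds = pd.concat([env_pop, mem_df.loc[freqs.index]], axis=1)
            model = fit_gradient_forest(freqs.fillna(freqs.mean()), preds,
                                        n_trees=config.n_trees,
                                        seed=config.seed)
            model.to_json(out / "turnover_model.json")
            state["model"] = model
            params = {"n_positive": len(model.positive_snps)}
        elif stage == "offsets":
            model = need(stage, "model")
            current = need(stage, "current")
            future = need(stage, "future")
            t_cur = transform_climate(model, current)
            t_fut = transform_climate(model, future)
            maps = forward_offset(t_cur, t_fut, max_km=config.max_km)
            rev = reverse_offset(t_cur, t_fut, max_km=config.max_km)
            decline = offset_decline_curve(t_cur, t_fut,
                                           config.distance_caps)
            Gf = need(stage, "Gf")
            regions = assign_regions(current,
                                     Gf.samples.drop_duplicates("population"))
            summary, tests = compare_groups(maps.local, regions)
            np.savetxt(out / "local_offset.grd", maps.local, fmt="%.8g")
            np.savetxt(out / "forward_offset.grd", maps.forward, fmt="%.8g")
            np.savetxt(out / "reverse_offset.grd", rev, fmt="%.8g")
            np.savetxt(out / "migration_km.grd", maps.migration_km,
                       fmt="%.8g")
            np.savetxt(out / "bearing_deg.grd", maps.bearing_deg, fmt="%.8g")
            decline.to_csv(out / "decline_curve.tsv", sep="\t", index=False)
            summary.to_csv(out / "offset_groups.tsv", sep="\t", index=False)
            tests.to_csv(out / "offset_tests.tsv", sep="\t", index=False)
            state.update(offset_maps=maps, reverse=rev, decline=decline,
                         group_summary=summary)
            params = {"mean_local": float(np.nanmean(maps.local)),
                      "mean_forward": float(np.nanmean(maps.forward))}
        logger.info("stage %s done", stage)
        manifest["stages"][stage] = params

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["artifacts"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    state["manifest"] = manifest
    return state
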