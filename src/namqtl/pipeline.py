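"""End-to-end orchestration: simulate (or load), QC, cluster, scan, validate.

The pipeline mirrors a three-panel NAM study: the NAM itself for QTL
discovery (GLM scan across all lines plus composite interval mapping
within each subfamily), haplotype-class investigation at the top stable
QTL peaks, and a simulated independent panel for marker validation.
Every stage writes its table under the output directory with a
provenance header; re-running with the same config reproduces the
outputs bit-exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import ammi as ammi_mod
from . import assoc, envclim, genodata, io, pyramid, simdata, traits, valmetrics

log = logging.getLogger("namqtl")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    # simulation
    n_markers: int = simdata.N_MARKERS_DEFAULT
    n_rils_per_cross: tuple[int, ...] = (146, 138, 142)
    inbreeding_generations: int = 4
    missing_rate: float = 0.005
    genotyping_error_rate: float = 0.001
    n_stressed: int = 5
    n_non_stressed: int = 3
    # QC
    max_missing: float = 0.01
    min_maf: float = 0.10
    # structure / clustering
    k_subpop: int = 3
    k_env: int = 2
    # scan
    traits_to_scan: tuple[str, ...] = ("TKW", "GY")
    walk_cM: float = 4.0
    cofactor_alpha: float = 0.001
    genomewide_alpha: float = 0.01
    lod_threshold_override: float | None = None
    # QTL calling
    min_envs: int = 2
    require_both_methods: bool = True
    # pyramiding / validation
    n_haplotype_loci: int = 3
    validation_panel_size: int = 80

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def plot_error_variance(plot_table: pd.DataFrame, trait: str) -> float:
    """Pooled within-(env, entry) plot variance from replicated checks."""
    reps = plot_table[plot_table["is_check"]]
    groups = reps.groupby(["env_id", "entry_id"])[trait]
    ss, df = 0.0, 0
    for _, v in groups:
        v = v.dropna()
        if len(v) >= 2:
            ss += float(((v - v.mean()) ** 2).sum())
            df += len(v) - 1
    if df == 0:
        return 0.0
    return ss / df


def run_pipeline(config: PipelineConfig, study: simdata.NamStudy | None = None
                 ) -> dict:
    """Execute every stage; return a results bundle (dict of tables/values)."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    digest_src = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    meta = {"config_digest": io.config_digest(digest_src), "seed": config.seed}
    out = Path(config.out_dir) if config.out_dir else None

    # -- stage 1: data ------------------------------------------------------
    log.info("stage simulate: NAM genotypes and trials")
    if study is None:
        study = simdata.simulate_study(
            seed=config.seed,
            n_markers=config.n_markers,
            config=simdata.SimConfig(
                n_rils_per_cross=config.n_rils_per_cross,
                inbreeding_generations=config.inbreeding_generations,
                missing_rate=config.missing_rate,
                genotyping_error_rate=config.genotyping_error_rate,
                seed=config.seed),
            n_stressed=config.n_stressed,
            n_non_stressed=config.n_non_stressed)
    results: dict = {"study": study, "meta": meta}

    # -- stage 2: genotype QC and structure ---------------------------------
    log.info("stage qc: SNP filtering, kinship, subpopulations")
    geno, qc_report = genodata.filter_snps(
        study.sim.genotypes, config.max_missing, config.min_maf)
    is_parent = study.sim.pedigree["is_parent"].to_numpy()
    geno_prog = geno.subset_lines(~is_parent)
    kin = genodata.kinship(geno_prog)
    ped_labels = study.sim.pedigree.set_index("line_id")["subfamily"]
    subpops = genodata.assign_subpopulations(
        kin, k=config.k_subpop,
        pedigree_labels=ped_labels[~is_parent])
    results.update(qc_report=qc_report, kinship=kin, subpopulations=subpops,
                   genotypes=geno)

    # -- stage 3: traits ----------------------------------------------------
    log.info("stage traits: derivation and spatial adjustment")
    plots = traits.derive_traits(study.plots)
    scan_traits = list(config.traits_to_scan)
    entry_means = pd.concat(
        [traits.adjust_spatial(plots, t) for t in scan_traits + ["DtH"]],
        ignore_index=True)
    results["entry_means"] = entry_means

    # -- stage 4: environment clustering ------------------------------------
    log.info("stage cluster-envs: climate matrix and Ward clustering")
    climate = envclim.build_climate_matrix(study.climate, study.stage_dates)
    site_means = {t: entry_means[entry_means["trait"] == t]
                  .groupby("env_id")["adjusted_value"].mean()
                  for t in scan_traits}
    screens = pd.concat(
        [envclim.screen_factors(climate, m).assign(trait=t)
         for t, m in site_means.items()], ignore_index=True)
    sig_factors = sorted(set(screens.loc[screens["significant"], "factor"]))
    if not sig_factors:
        sig_factors = [c for c in climate.columns if c.endswith("rain_total")]
    env_labels, linkage = envclim.cluster_environments(
        climate[sig_factors], k=config.k_env)
    gf_rain = climate["grain_fill_rain_total"]
    cluster_rain = gf_rain.groupby(env_labels).mean()
    stressed_cluster = cluster_rain.idxmin()
    stressed_envs = sorted(env_labels.index[env_labels == stressed_cluster])
    nonstressed_envs = sorted(env_labels.index[env_labels != stressed_cluster])
    results.update(climate_matrix=climate, factor_screens=screens,
                   env_clusters=env_labels, stressed_envs=stressed_envs,
                   nonstressed_envs=nonstressed_envs,
                   env_dendrogram=envclim.linkage_to_newick(
                       linkage, sorted(env_labels.index)))

    # -- stage 5: combined analysis, heritability, AMMI/AWAI ----------------
    log.info("stage ammi: combined analysis, heritability, AWAI")
    heritabilities, combined, awai_scores = {}, {}, {}
    all_envs = sorted(env_labels.index)
    for t in scan_traits:
        em_t = entry_means[entry_means["trait"] == t]
        s2e = plot_error_variance(plots, t)
        for label, subset in (("stressed", stressed_envs),
                              ("non_stressed", nonstressed_envs),
                              ("all", all_envs)):
            if len(subset) >= 2:
                tbl, comp = traits.combine_environments(em_t, subset, sigma2_e=s2e)
                combined[(t, label)] = (tbl, comp)
        _, comp_all = combined[(t, "all")]
        heritabilities[t] = traits.heritability(comp_all)
        ge = em_t.pivot_table(index="entry_id", columns="env_id",
                              values="adjusted_value")
        ge = ge.dropna()
        dec = ammi_mod.fit_ammi(ge)
        n_axes = ammi_mod.significant_ipca(dec, error_ms=s2e if s2e > 0 else None,
                                           error_df=1e5)
        awai_scores[t] = ammi_mod.awai(dec, n_axes).set_index("entry_id")["awai"]
    results.update(heritability=heritabilities, combined=combined,
                   awai=awai_scores)

    # -- stage 6: LD and thresholds ------------------------------------------
    log.info("stage thresholds: LD decay and LD-protected Bonferroni")
    ld_fit = genodata.ld_decay(geno_prog, study.gmap)
    decay = ld_fit.decay_distance_cM or ld_fit.decay_distance_ma_cM
    if decay is None or decay <= 0:
        raise RuntimeError("LD decay crossing undefined; cannot set thresholds")
    m_eff = assoc.effective_tests(study.gmap.length_cM(), decay)
    thresholds = assoc.significance_thresholds(
        m_eff, config.genomewide_alpha, n_lines=geno_prog.n_lines)
    if config.lod_threshold_override is not None:
        thresholds["lod_threshold"] = config.lod_threshold_override
        thresholds["p_threshold"] = 10 ** (-config.lod_threshold_override)
    results.update(ld_decay=decay, effective_tests=m_eff, thresholds=thresholds,
                   ld_fit=ld_fit)

    # -- stage 7: association scans ------------------------------------------
    log.info("stage scan: GLM and interval scans")
    q_dummies = pd.get_dummies(subpops, prefix="Q", drop_first=True).astype(float)
    dth = entry_means[entry_means["trait"] == "DtH"].pivot_table(
        index="entry_id", columns="env_id", values="adjusted_value").mean(axis=1)
    mtas = []
    for t in scan_traits:
        em_t = entry_means[entry_means["trait"] == t]
        wide = em_t.pivot_table(index="entry_id", columns="env_id",
                                values="adjusted_value")
        ctxs: list[tuple[str, tuple[str, ...], pd.Series]] = [
            (f"env:{e}", (e,), wide[e]) for e in all_envs]
        for label, subset in (("stressed-combined", stressed_envs),
                              ("non_stressed-combined", nonstressed_envs),
                              ("all-combined", all_envs)):
            key = label.replace("-combined", "")
            if (t, key) in combined:
                ctxs.append((label, (), combined[(t, key)][0]
                             .set_index("entry_id")["shrunk_value"]))
        ctxs.append(("AWAI", (), awai_scores[t]))
        for ctx_name, envs, values in ctxs:
            scan = assoc.glm_scan(geno_prog, values, q_dummies, dth)
            mtas.append(assoc.scan_to_mtas(
                scan, study.gmap, t, ctx_name, envs, "glm",
                thresholds["p_threshold"], thresholds.get("r2_threshold", 0.0)))
        # interval scans per subfamily, single environments only
        for fam in sorted(set(subpops)):
            fam_mask = (subpops.reindex(geno_prog.line_ids) == fam).to_numpy()
            sub_geno = geno_prog.subset_lines(fam_mask)
            for e in all_envs:
                profile, _cof = assoc.interval_scan(
                    sub_geno, study.gmap, wide[e],
                    walk_cM=config.walk_cM,
                    cofactor_alpha=config.cofactor_alpha)
                peaks = assoc.profile_peaks(profile, thresholds["lod_threshold"])
                if peaks.empty:
                    continue
                rec = peaks.rename(columns={"nearest_marker": "marker_id"})
                rec["trait"] = t
                rec["env_context"] = f"env:{e}"
                rec["environments"] = [(e,)] * len(rec)
                rec["method"] = "interval"
                mtas.append(rec[["trait", "env_context", "environments",
                                 "marker_id", "chromosome", "position_cM",
                                 "lod", "p_value", "effect", "r2", "method"]])
    mta_table = pd.concat([m for m in mtas if not m.empty], ignore_index=True) \
        if any(not m.empty for m in mtas) else pd.DataFrame(
            columns=["trait", "env_context", "environments", "marker_id",
                     "chromosome", "position_cM", "lod", "p_value", "effect",
                     "r2", "method"])
    results["mtas"] = mta_table

    # -- stage 8: QTL merging and stability ----------------------------------
    log.info("stage merge: MTA chaining into QTLs")
    qtls = assoc.merge_mtas(mta_table, decay)
    qtls = assoc.classify_stable(qtls, config.min_envs,
                                 config.require_both_methods)
    results["qtls"] = qtls

    # -- stage 9: haplotype pyramiding ----------------------------------------
    log.info("stage pyramid: haplotype classes at top stable TKW QTLs")
    stable_tkw = qtls[qtls["stable"] & qtls["traits"].map(lambda ts: "TKW" in ts)]
    stable_tkw = stable_tkw.sort_values("peak_lod", ascending=False)
    peak_markers = list(dict.fromkeys(stable_tkw["peak_marker"]))[
        : config.n_haplotype_loci]
    results["peak_markers"] = peak_markers
    if len(peak_markers) >= 2 and ("TKW", "stressed") in combined:
        classes = pyramid.build_haplotype_classes(geno_prog, peak_markers)
        tkw_stress = combined[("TKW", "stressed")][0].set_index(
            "entry_id")["shrunk_value"]
        values = tkw_stress.reindex(classes["line_id"])
        values.index = classes["line_id"]
        try:
            lsd = pyramid.class_anova_lsd(classes, values)
            adv = pyramid.pyramiding_advantage(lsd["mean"].max(),
                                               lsd["mean"].min())
            results.update(haplotype_classes=classes, class_lsd=lsd,
                           pyramiding_advantage=adv)
        except ValueError as exc:
            log.warning("pyramid stage degenerate: %s", exc)

    # -- stage 10: marker validation ------------------------------------------
    log.info("stage validate: independent simulated panel")
    if peak_markers:
        val = _simulate_validation_panel(study, config, rng, peak_markers)
        results["validation"] = val

    if out is not None:
        _write_outputs(results, out, meta)
    return results


def _simulate_validation_panel(
    study: simdata.NamStudy, config: PipelineConfig,
    rng: np.random.Generator, peak_markers: list[str],
) -> pd.DataFrame:
    """Fresh RIL panel from the same parents, scored at the peak markers."""
    n = config.validation_panel_size
    per_cross = [n // 3, n // 3, n - 2 * (n // 3)]
    sim = simdata.simulate_nam(
        study.parents, study.gmap,
        simdata.SimConfig(n_rils_per_cross=tuple(per_cross),
                          inbreeding_generations=config.inbreeding_generations,
                          missing_rate=0.0, genotyping_error_rate=0.0,
                          seed=config.seed + 77))
    is_parent = sim.pedigree["is_parent"].to_numpy()
    panel = sim.true_genotypes.subset_lines(~is_parent)
    gv = simdata.genetic_values(panel, [q for q in study.planted_qtl
                                        if q.trait == "TKW"], study.gmap)
    tkw = pd.Series(gv["TKW"].to_numpy() + 43.0
                    + rng.normal(0, 1.0, size=panel.n_lines),
                    index=panel.line_ids, name="TKW")
    calls = pd.DataFrame(
        {m: (panel.calls[:, panel.marker_index(m)] >= 1).astype(float)
         for m in peak_markers}, index=panel.line_ids)
    return valmetrics.validate_markers(calls, tkw,
                                       n=min(20, panel.n_lines // 2 - 1))


def _write_outputs(results: dict, out: Path, meta: dict) -> None:
    out.mkdir(parents=True, exist_ok=True)
    io.write_table(results["qc_report"], out / "qc_report.csv", meta)
    io.write_table(results["entry_means"], out / "entry_means.csv", meta)
    io.write_table(results["climate_matrix"].reset_index(),
                   out / "climate_matrix.csv", meta)
    io.write_json({"clusters": results["env_clusters"].to_dict(),
                   "stressed": results["stressed_envs"]},
                  out / "env_clusters.json")
    (out / "env_dendrogram.nwk").write_text(results["env_dendrogram"] + "\n")
    io.write_json({"heritability": results["heritability"],
                   "ld_decay_cM": results["ld_decay"],
                   "effective_tests": results["effective_tests"],
                   **results["thresholds"], **meta},
                  out / "thresholds.json")
    mta = results["mtas"].copy()
    mta["environments"] = mta["environments"].map(lambda e: ";".join(e))
    io.write_table(mta, out / "mtas.tsv", meta, sep="\t")
    qtls = results["qtls"].copy()
    for col in ("traits", "environments", "env_contexts", "methods"):
        qtls[col] = qtls[col].map(lambda v: ";".join(v))
    io.write_table(qtls, out / "qtls.tsv", meta, sep="\t")
    if "class_lsd" in results:
        io.write_table(results["class_lsd"], out / "haplotype_classes.csv", meta)
    if "validation" in results:
        io.write_table(results["validation"], out / "validation.csv", meta)


def recovered_planted_qtl(
    qtl_table: pd.DataFrame,
    planted: Sequence[simdata.PlantedQtl],
    trait: str = "TKW",
    tol_cM: float = 15.0,
    require_stable: bool = True,
) -> int:
    """How many planted QTL of `trait` have a (stable) QTL within tol_cM."""
    q = qtl_table
    if require_stable and "stable" in q.columns:
        q = q[q["stable"]]
    hits = 0
    for pq in planted:
        if pq.trait != trait:
            continue
        sub = q[(q["chromosome"] == pq.chromosome)
                & (q["start_cM"] - tol_cM <= pq.position_cM)
                & (q["end_cM"] + tol_cM >= pq.position_cM)]
        if len(sub):
            hits += 1
    return hits
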