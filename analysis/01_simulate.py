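"""Simulate the default NAM study and write its raw data files.

426 F5 RILs in three subfamilies (146/138/142) from one recurrent
parent, ~1,678 SNPs on 14 chromosomes (~1,723 cM), eight environments
(five terminal-drought, three irrigated) in augmented 10x48 designs
with the four parents as replicated checks.
"""

from pathlib import Path

from namqtl import io, simdata

SEED = 7
OUT = Path("results/study")

study = simdata.simulate_study(seed=SEED)
meta = {"seed": SEED}
io.write_hapmap(study.sim.genotypes, study.gmap, OUT / "genotypes.hmp.txt",
                meta=meta)
io.write_wide_csv(study.sim.genotypes, OUT / "genotypes_wide.csv", meta=meta)
io.write_map(study.gmap, OUT / "map.csv", meta=meta)
io.write_table(study.plots, OUT / "plots.csv", meta=meta)
io.write_table(study.climate, OUT / "climate_daily.csv", meta=meta)
io.write_table(study.stage_dates, OUT / "stage_dates.csv", meta=meta)
io.write_yaml({"seed": SEED, "n_markers": study.gmap.n_markers,
               "map_length_cM": study.gmap.length_cM(),
               "planted_qtl": [vars(q) for q in study.planted_qtl]},
              OUT / "sim_config.yaml")

ped = study.sim.pedigree
print(f"simulated {int((~ped['is_parent']).sum())} RILs + "
      f"{int(ped['is_parent'].sum())} parents; "
      f"{study.gmap.n_markers} markers spanning "
      f"{study.gmap.length_cM():.0f} cM on {len(study.gmap.chromosomes)} "
      "chromosomes")
print(f"plot table: {len(study.plots)} plots across "
      f"{study.plots['env_id'].nunique()} environments -> {OUT}")
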