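"""Run the full discovery pipeline: QC, structure, LD-protected thresholds,
GLM + composite-interval scans, and write the MTA table.

This is the orchestrated end-to-end run; the remaining drivers read its
outputs from results/pipeline/.
"""

from pathlib import Path

from namqtl.pipeline import PipelineConfig, run_pipeline

SEED = 7
OUT = Path("results/pipeline")

cfg = PipelineConfig(seed=SEED, out_dir=str(OUT))
res = run_pipeline(cfg)

thr = res["thresholds"]
print(f"QC kept {res['genotypes'].n_markers} markers; "
      f"LD decay {res['ld_decay']:.2f} cM; "
      f"effective tests M={res['effective_tests']}; "
      f"LOD threshold {thr['lod_threshold']:.2f} "
      f"(p<{thr['p_threshold']:.2e}), r2 threshold "
      f"{thr.get('r2_threshold', float('nan')):.3f}")
mta = res["mtas"]
print(f"{len(mta)} significant MTAs "
      f"({(mta['method'] == 'glm').sum()} GLM, "
      f"{(mta['method'] == 'interval').sum()} interval) -> {OUT/'mtas.tsv'}")
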