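"""Overlay somatic mutations and copy-number changes on the module map.

Finds recurrently point-mutated genes, focal recurrent amplifications,
flags CNA-enriched modules, and tracks how the planted amplified driver
genes move from the periphery of their normal module to the hub of a
tumor-specific module (centrality shift > 0).
"""

import coexage as cx
from coexage.mutations import (
    centrality,
    centrality_shift,
    focal_gene_calls,
    recurrent_cna,
    recurrent_point_mutated,
)
from coexage.network import extract_module_network
from coexage.pipeline import RunConfig, build_condition_modules, preprocess

cohort = cx.simulate_cohort(cx.SyntheticConfig(seed=7))
cfg = RunConfig(seed=7)
expr, tumor_ids, normal_ids = preprocess(cohort.expression, cfg)
tumor_mods, tumor_tom = build_condition_modules(expr, tumor_ids, cfg, "tumor")
normal_mods, normal_tom = build_condition_modules(expr, normal_ids, cfg, "normal")

rec_point = recurrent_point_mutated(cohort.mutations)
print(f"recurrent point-mutated genes: {sorted(rec_point)} "
      f"(planted: {sorted(map(str, cohort.recurrent_point_genes))})")

focal = focal_gene_calls(cohort.cna_segments, cohort.gene_coords)
amp, dele = recurrent_cna(focal, n_patients=len(tumor_ids))
print(f"recurrently amplified genes: {sorted(amp)} "
      f"(planted drivers: {cohort.amp_driver_genes})")

tumor_tables = [
    centrality(extract_module_network(tumor_tom, genes))
    for genes in tumor_mods.modules.values()
]
normal_tables = [
    centrality(extract_module_network(normal_tom, genes))
    for genes in normal_mods.modules.values()
]
print("\ncentrality shift (tumor - normal) of the amplified drivers:")
for gene in cohort.amp_driver_genes:
    try:
        shift = centrality_shift(gene, tumor_tables, normal_tables)
        print(f"  {gene}: {shift:+.3f}")
    except ValueError as err:
        print(f"  {gene}: undefined ({err})")
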