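"""Classify modules by evolutionary gene age and score tumor-module novelty.

Every module is tested for over-representation of unicellular (UC) versus
multicellular (MC) genes; tumor modules are then scored for novelty — the
number of normal modules needed to cover half their genes, over module size.
"""

import coexage as cx
from coexage.novelty import novelty_table, score_modules
from coexage.pipeline import (
    RunConfig,
    build_condition_modules,
    classify_ages,
    preprocess,
)

cohort = cx.simulate_cohort(cx.SyntheticConfig(seed=7))
cfg = RunConfig(seed=7)
expr, tumor_ids, normal_ids = preprocess(cohort.expression, cfg)
tumor_mods, _ = build_condition_modules(expr, tumor_ids, cfg, "tumor")
normal_mods, _ = build_condition_modules(expr, normal_ids, cfg, "normal")

background = set(expr.genes)
results = classify_ages(tumor_mods, cohort.age_table, background, alpha=0.05)
print("tumor module age classes:")
for r in results:
    print(f"  {r.module}: {r.n_uc} UC / {r.n_mc} MC genes -> {r.category} "
          f"(adj p UC={r.adj_p_uc:.3g}, MC={r.adj_p_mc:.3g})")

print("\ntumor module novelty vs normal modules:")
print(novelty_table(score_modules(tumor_mods, normal_mods)).to_string(index=False))
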