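"""Per-sample module activity via single-sample GSEA.

Scores every tumor module in every tumor sample, then asks which novelty
tertile is over-represented in the top quartile of module activity.
"""

import coexage as cx
from coexage.novelty import score_modules
from coexage.pipeline import RunConfig, build_condition_modules, preprocess
from coexage.scoring import ssgsea_matrix, upper_quartile_share

cohort = cx.simulate_cohort(cx.SyntheticConfig(seed=7))
cfg = RunConfig(seed=7)
expr, tumor_ids, normal_ids = preprocess(cohort.expression, cfg)
tumor_mods, _ = build_condition_modules(expr, tumor_ids, cfg, "tumor")
normal_mods, _ = build_condition_modules(expr, normal_ids, cfg, "normal")

scores = ssgsea_matrix(expr.subset_samples(tumor_ids), tumor_mods)
print("module x sample activity (first 4 samples):")
print(scores.scores.iloc[:, :4].round(3).to_string())

tertiles = {r.module: r.tertile for r in score_modules(tumor_mods, normal_mods)}
share = upper_quartile_share(scores, tertiles)
print("\nfraction of each novelty tertile in the top activity quartile:")
print(share.round(3).to_string())
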