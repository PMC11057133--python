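"""End-to-end cohort and progression runs with manifest-driven I/O.

``run_cohort`` realizes the three-step design — assign gene ages, build
tumor and normal co-expression modules, classify modules by age — and layers
novelty scoring, per-sample activity, and the somatic mutation overlay on
top, writing every stage's table plus a machine-readable summary.
``run_progression`` drives the stage-chain comparison and the grade
classifier.  One master seed deterministically derives every stage seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io, module_age, mutations as mut, network as net
from .gene_age import GeneAgeTable, load_phylostrata
from .novelty import novelty_table, score_modules
from .progression import build_stage_chain, rf_grade_classifier
from .scoring import ssgsea_matrix, upper_quartile_share

log = logging.getLogger("coexage")


@dataclass
class RunConfig:
    """Resolved parameters for a pipeline run; round-trips through YAML."""

    expression: str = ""
    manifest: str = ""
    ages: str = ""
    mutations: str | None = None
    segments: str | None = None
    gene_coords: str | None = None
    drivers: str | None = None
    tumor_type: str = "SYNTH"
    out_dir: str = "results"

    beta: float = 6.0
    min_module_size: int = 30
    cpm_threshold: float = 1.0
    log_transform: bool = True
    outlier_k: float = 2.5
    remove_outliers: bool = True
    alpha: float = 0.05
    novelty_coverage: float = 0.5
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    cna_min_fraction: float = 0.10
    focal_fraction: float = 0.25
    mutation_min_patients: int = 3
    rf_iterations: int = 100
    rf_trees: int = 500
    rf_train_frac: float = 0.7
    gini_threshold: float = 5.0
    stages: list[str] = field(default_factory=list)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        digest = np.random.SeedSequence(
            [self.seed, int.from_bytes(stage.encode()[:8].ljust(8, b"\0"), "big")]
        )
        return int(digest.generate_state(1)[0] % (2**31 - 1))


def _log2_cpm(expr: net.ExpressionMatrix) -> net.ExpressionMatrix:
    vals = np.log2(net.cpm(expr.values) + 1.0)
    return net.ExpressionMatrix(vals, expr.sample_meta)


def preprocess(
    counts: net.ExpressionMatrix, config: RunConfig
) -> tuple[net.ExpressionMatrix, list[str], list[str]]:
    """CPM filter, optional log2(CPM+1) transform, outlier and bad-gene removal."""
    tumor = counts.samples_where(condition="tumor")
    normal = counts.samples_where(condition="normal")
    keep = net.cpm_filter(counts, tumor, normal, threshold=config.cpm_threshold)
    expr = counts.subset_genes(keep)
    if config.log_transform:
        expr = _log2_cpm(expr)
    if config.remove_outliers:
        expr = net.remove_outlier_samples(expr, k=config.outlier_k)
    expr = net.drop_bad_genes(expr)
    tumor = expr.samples_where(condition="tumor")
    normal = expr.samples_where(condition="normal")
    return expr, tumor, normal


def build_condition_modules(
    expr: net.ExpressionMatrix, samples: list[str], config: RunConfig, tag: str
) -> tuple[net.ModuleSet, net.CoexpressionNetwork]:
    sub = net.drop_bad_genes(expr.subset_samples(samples))
    adj = net.adjacency(sub, beta=config.beta)
    tom_net = net.tom(adj)
    modset = net.detect_modules(tom_net, min_size=config.min_module_size, provenance=tag)
    return modset, tom_net


def classify_ages(
    modset: net.ModuleSet, ages: GeneAgeTable, background: set[str], alpha: float
) -> list[module_age.AgeEnrichmentResult]:
    raw = [
        module_age.classify_module_age(label, genes, ages, background)
        for label, genes in modset.modules.items()
    ]
    return module_age.adjust_and_categorize(raw, alpha=alpha)


def run_cohort(config: RunConfig) -> dict:
    """Full tumor-vs-normal cohort analysis; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log.info("run_cohort: resolved config %s (seed=%d)", asdict(config), config.seed)

    stage = "load"
    try:
        counts = io.read_expression(config.expression, config.manifest)
        ages = load_phylostrata(config.ages)

        stage = "preprocess"
        expr, tumor_ids, normal_ids = preprocess(counts, config)
        background = set(expr.genes)

        stage = "modules"
        results: dict[str, object] = {}
        modsets: dict[str, net.ModuleSet] = {}
        networks: dict[str, net.CoexpressionNetwork] = {}
        for tag, samples in (("tumor", tumor_ids), ("normal", normal_ids)):
            modset, tom_net = build_condition_modules(expr, samples, config, tag)
            modsets[tag], networks[tag] = modset, tom_net
            io.write_modules(modset, out / f"modules_{tag}.tsv")
            if not modset.modules:
                log.warning("no %s module reached min size %d; all grey", tag, config.min_module_size)

        stage = "age"
        age_results = {
            tag: classify_ages(modsets[tag], ages, background, config.alpha)
            for tag in ("tumor", "normal")
        }
        for tag, res in age_results.items():
            module_age.age_enrichment_table(res).to_csv(
                out / f"age_enrichment_{tag}.tsv", sep="\t", index=False
            )

        stage = "novelty"
        nov = score_modules(modsets["tumor"], modsets["normal"], config.novelty_coverage)
        novelty_table(nov).to_csv(out / "novelty.tsv", sep="\t", index=False)

        stage = "scoring"
        quartile_share = {}
        if modsets["tumor"].modules:
            tumor_expr = expr.subset_samples(tumor_ids)
            scores = ssgsea_matrix(
                tumor_expr,
                modsets["tumor"],
                alpha=config.ssgsea_alpha,
                normalize=config.ssgsea_normalize,
            )
            scores.scores.to_csv(out / "scores_tumor.tsv", sep="\t", index_label="module")
            tertiles = {r.module: r.tertile for r in nov}
            quartile_share = upper_quartile_share(scores, tertiles).to_dict()

        stage = "mutations"
        overlay = _mutation_overlay(config, modsets, networks, out)

        stage = "summary"
        summary = {
            "seed": config.seed,
            "n_genes_analyzed": len(background),
            "n_samples": {"tumor": len(tumor_ids), "normal": len(normal_ids)},
            "modules": {
                tag: {
                    "n_modules": len(modsets[tag].modules),
                    "n_grey": len(modsets[tag].grey),
                    "age_categories": _category_counts(age_results[tag]),
                }
                for tag in ("tumor", "normal")
            },
            "novelty_tertiles": _tertile_counts(nov),
            "upper_quartile_share": quartile_share,
        }
        summary.update(overlay)
        summary = _jsonable(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        _summary_tsv(summary, out / "summary.tsv")
        return summary
    except Exception:
        log.error("run_cohort failed at stage %r", stage)
        raise


def _jsonable(obj):
    """Recursively coerce numpy scalars and non-finite floats for JSON output."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    return obj


def _category_counts(results) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in results:
        counts[r.category] = counts.get(r.category, 0) + 1
    return counts


def _tertile_counts(nov) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in nov:
        counts[r.tertile] = counts.get(r.tertile, 0) + 1
    return counts


def _summary_tsv(summary: dict, path: Path) -> None:
    rows = []

    def flatten(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for k, v in obj.items():
                flatten(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            rows.append((prefix, obj))

    flatten("", summary)
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(path, sep="\t", index=False)


def _mutation_overlay(config: RunConfig, modsets, networks, out: Path) -> dict:
    overlay: dict[str, object] = {}
    if config.mutations:
        muts = io.read_mutations(config.mutations)
        recurrent_point = mut.recurrent_point_mutated(
            muts, min_patients=config.mutation_min_patients
        )
        overlay["recurrent_point_genes"] = sorted(recurrent_point)
    if config.segments and config.gene_coords:
        seg = io.read_segments(config.segments)
        coords = io.read_gene_coords(config.gene_coords)
        focal = mut.focal_gene_calls(seg, coords, focal_fraction=config.focal_fraction)
        n_patients = seg["patient"].nunique()
        amp, dele = mut.recurrent_cna(focal, n_patients, config.cna_min_fraction)
        flags = {}
        rows = []
        for tag in ("tumor", "normal"):
            for state, rec in (("amp", amp), ("del", dele)):
                for label, genes in modsets[tag].modules.items():
                    flag, frac = mut.module_cna_flag(genes, rec, config.cna_min_fraction)
                    rows.append((tag, label, state, flag, frac))
                flags[(tag, state)] = [
                    mut.module_cna_flag(genes, rec, config.cna_min_fraction)[0]
                    for genes in modsets[tag].modules.values()
                ]
        pd.DataFrame(
            rows, columns=["condition", "module", "state", "flagged", "fraction"]
        ).to_csv(out / "module_cna_flags.tsv", sep="\t", index=False)
        enrichment = {}
        for state in ("amp", "del"):
            nf, tf = flags[("normal", state)], flags[("tumor", state)]
            if nf and tf:
                res, _ = mut.cna_module_enrichment(nf, tf)
                enrichment[state] = {"odds_ratio": res.odds_ratio, "p": res.p_value}
        overlay["cna_module_enrichment"] = enrichment
        overlay["n_recurrent_amp_genes"] = len(amp)
        overlay["n_recurrent_del_genes"] = len(dele)
    if config.drivers:
        drivers = io.read_drivers(config.drivers)
        rows = []
        for label, genes in modsets["tumor"].modules.items():
            pct, excluded = mut.driver_fraction(genes, drivers, config.tumor_type)
            rows.append((label, pct, excluded))
        pd.DataFrame(rows, columns=["module", "driver_pct", "excluded"]).to_csv(
            out / "driver_fractions.tsv", sep="\t", index=False
        )
    return overlay


def run_progression(config: RunConfig) -> dict:
    """Stage-chain novelty plus the random-forest grade classifier."""
    if len(config.stages) < 2:
        raise ValueError("progression run needs >= 2 stages in config.stages")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log.info("run_progression: stages=%s seed=%d", config.stages, config.seed)

    counts = io.read_expression(config.expression, config.manifest)
    if "stage" not in counts.sample_meta.columns:
        raise ValueError("manifest lacks the 'stage' column required for progression")
    tumor = counts.samples_where(condition="tumor")
    normal = counts.samples_where(condition="normal")
    keep = net.cpm_filter(counts, tumor, normal, threshold=config.cpm_threshold)
    expr = counts.subset_genes(keep)
    if config.log_transform:
        expr = _log2_cpm(expr)

    chain = build_stage_chain(
        expr, config.stages, beta=config.beta, min_size=config.min_module_size
    )
    for link in chain.links:
        novelty_table(link.results).to_csv(
            out / f"novelty_{link.reference_stage}_to_{link.target_stage}.tsv",
            sep="\t",
            index=False,
        )
    for stage_name, modset in chain.module_sets.items():
        io.write_modules(modset, out / f"modules_{stage_name}.tsv")

    # grade classifier on the final two stages, scored with the last stage's modules
    report_info: dict[str, object] = {}
    lo, hi = config.stages[-2], config.stages[-1]
    final_modules = chain.module_sets[hi]
    if final_modules.modules:
        samples = expr.samples_where(stage=lo) + expr.samples_where(stage=hi)
        sub = expr.subset_samples(samples)
        scores = ssgsea_matrix(sub, final_modules, alpha=config.ssgsea_alpha)
        labels = sub.sample_meta["stage"]
        report = rf_grade_classifier(
            scores,
            labels,
            n_iter=config.rf_iterations,
            train_frac=config.rf_train_frac,
            seed=config.stage_seed("rf"),
            n_trees=config.rf_trees,
            importance_threshold=config.gini_threshold,
        )
        pd.DataFrame({"auc": report.aucs}).to_csv(out / "rf_aucs.tsv", sep="\t", index=False)
        pd.DataFrame(
            {"gini": report.gini, "important": report.important}
        ).to_csv(out / "rf_importance.tsv", sep="\t", index_label="module")
        report_info = {
            "median_auc": report.median_auc,
            "n_important_modules": int(report.important.sum()),
        }

    summary = {
        "stages": config.stages,
        "links": [
            {
                "reference": link.reference_stage,
                "target": link.target_stage,
                "tertiles": _tertile_counts(link.results),
            }
            for link in chain.links
        ],
        "classifier": report_info,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
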