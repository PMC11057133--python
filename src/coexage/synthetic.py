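"""Synthetic paired tumor/normal cohorts with known ground truth.

Counts follow a latent-factor negative-binomial model: each planted module
has a per-sample factor (active only in the module's conditions) that shifts
the log-mean of its member genes, producing block-correlated expression; all
other variation is independent gene-level noise.  The generator also plants
gene ages at controlled unicellular fractions, tumor grades, a focally
amplified driver locus with carrier patients, recurrent and non-recurrent
point mutations, and a driver list, emitting every table in the exact format
the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .gene_age import GeneAgeTable
from .network import ExpressionMatrix, ModuleSet

TUMOR, NORMAL = "tumor", "normal"
LOW_GRADE, HIGH_GRADE = "low", "high"
ACTIVITIES = ("both", "tumor_only", "normal_only", "high_grade_only")


@dataclass(frozen=True)
class PlantedModule:
    name: str
    size: int
    uc_fraction: float
    activity: str = "both"
    loading: float = 1.0

    def __post_init__(self) -> None:
        if self.activity not in ACTIVITIES:
            raise ValueError(f"activity must be one of {ACTIVITIES}")
        if not 0.0 <= self.uc_fraction <= 1.0:
            raise ValueError("uc_fraction must be in [0, 1]")


@dataclass(frozen=True)
class AmpDriverSpec:
    """Recurrently amplified driver genes and the rewiring they cause.

    In normal samples the drivers are ordinary members of *normal_host_module*;
    in tumors they instead load (with *hub_loading*, making them hubs) on the
    tumor-only *host_module*'s factor, and carrier patients additionally gain a
    *log2_fc* expression shift plus a focal amplification segment over the
    locus — amplification pulling genes out of their normal co-expression
    context into the center of a tumor-specific module.
    """

    n_genes: int = 5
    carrier_fraction: float = 0.3
    log2_fc: float = 2.0
    hub_loading: float = 2.0
    host_module: str = "tumor_mixed_1"
    normal_host_module: str = "preserved_mixed"


@dataclass(frozen=True)
class PointMutationSpec:
    n_recurrent: int = 3  # damaging in >= 3 patients, NS/S < 1
    n_nonrecurrent: int = 3  # fail either the patient floor or the ratio


def default_modules() -> list[PlantedModule]:
    return [
        PlantedModule("preserved_uc", 50, 0.9, "both"),
        PlantedModule("preserved_mc", 50, 0.1, "both"),
        PlantedModule("preserved_mixed", 60, 0.5, "both"),
        PlantedModule("tumor_mixed_1", 46, 0.5, "tumor_only"),
        PlantedModule("tumor_mixed_2", 40, 0.5, "tumor_only"),
        PlantedModule("grade_mixed", 50, 0.5, "high_grade_only"),
    ]


@dataclass
class SyntheticConfig:
    """Generative settings for one paired tumor/normal cohort.

    Defaults are sized so a full module-detection run completes quickly on a
    single CPU while planted structure is recoverable: 600 genes, 60 sample
    pairs, six planted modules of 40-60 genes with log-scale factor loading
    1.0 against gene noise sd 0.4, negative-binomial dispersion 0.2, and
    library sizes near one million so counts are roughly CPM-scaled.
    """

    n_genes: int = 600
    n_pairs: int = 60
    modules: list[PlantedModule] = field(default_factory=default_modules)
    factor_sd: float = 1.0
    noise_sd: float = 0.4
    dispersion: float = 0.2
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    base_log_cpm_range: tuple[float, float] = (np.log(5.0), np.log(400.0))
    background_uc_fraction: float = 0.45
    high_grade_fraction: float = 0.5
    amp_driver: AmpDriverSpec = field(default_factory=AmpDriverSpec)
    point_mutations: PointMutationSpec = field(default_factory=PointMutationSpec)
    n_chromosomes: int = 4
    gene_spacing: int = 10_000
    gene_length: int = 1_000
    tumor_type: str = "SYNTH"
    seed: int = 0

    def validate(self) -> None:
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ValueError(
                f"planted module sizes ({total}) exceed n_genes ({self.n_genes})"
            )
        if len({m.name for m in self.modules}) != len(self.modules):
            raise ValueError("planted module names must be unique")
        if not 0.0 <= self.amp_driver.carrier_fraction <= 1.0:
            raise ValueError("carrier fraction must be in [0, 1]")
        by_name = {m.name: m for m in self.modules}
        if self.amp_driver.n_genes:
            host = by_name.get(self.amp_driver.host_module)
            if host is None:
                raise ValueError(
                    f"amp driver host module {self.amp_driver.host_module!r} not planted"
                )
            nhost = by_name.get(self.amp_driver.normal_host_module)
            if nhost is None or nhost.activity not in ("both", "normal_only"):
                raise ValueError(
                    "amp driver normal host module must be planted and active in normals"
                )


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix  # counts, tumor + normal columns, manifest attached
    age_table: GeneAgeTable
    truth: dict[str, dict[str, str]]  # condition -> gene -> planted module
    mutations: pd.DataFrame  # gene, patient, consequence
    cna_segments: pd.DataFrame  # patient, chrom, start, end, state
    gene_coords: pd.DataFrame  # gene, chrom, start, end
    drivers: pd.DataFrame  # gene, tumor_type
    amp_driver_genes: list[str]
    recurrent_point_genes: list[str]
    config: SyntheticConfig

    @property
    def tumor_samples(self) -> list[str]:
        return self.expression.samples_where(condition=TUMOR)

    @property
    def normal_samples(self) -> list[str]:
        return self.expression.samples_where(condition=NORMAL)

    def truth_moduleset(self, condition: str) -> ModuleSet:
        members: dict[str, set[str]] = {}
        for gene, mod in self.truth[condition].items():
            members.setdefault(mod, set()).add(gene)
        all_genes = set(self.expression.genes)
        return ModuleSet(
            members, all_genes - set(self.truth[condition]), f"truth:{condition}"
        )


def _active_mask(activity: str, condition: np.ndarray, grade: np.ndarray) -> np.ndarray:
    if activity == "both":
        return np.ones(len(condition), dtype=bool)
    if activity == "tumor_only":
        return condition == TUMOR
    if activity == "normal_only":
        return condition == NORMAL
    return (condition == TUMOR) & (grade == HIGH_GRADE)


def simulate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw one cohort from the generative model; reproducible given the seed."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_genes, n_pairs = cfg.n_genes, cfg.n_pairs
    width = len(str(n_genes))
    genes = [f"G{str(i + 1).zfill(width)}" for i in range(n_genes)]
    tumor_ids = [f"T{i + 1:03d}" for i in range(n_pairs)]
    normal_ids = [f"N{i + 1:03d}" for i in range(n_pairs)]
    samples = tumor_ids + normal_ids
    condition = np.array([TUMOR] * n_pairs + [NORMAL] * n_pairs)

    n_high = int(round(cfg.high_grade_fraction * n_pairs))
    grade_t = np.array([HIGH_GRADE] * n_high + [LOW_GRADE] * (n_pairs - n_high))
    rng.shuffle(grade_t)
    grade = np.concatenate([grade_t, np.array([""] * n_pairs)])

    # module membership: contiguous gene blocks, background after
    membership: dict[str, list[int]] = {}
    cursor = 0
    for m in cfg.modules:
        membership[m.name] = list(range(cursor, cursor + m.size))
        cursor += m.size
    background = list(range(cursor, n_genes))

    # gene ages at the requested UC fractions (exact per module)
    strata: dict[str, int] = {}
    uc_strata, mc_strata = (1, 2, 3), tuple(range(4, 17))
    for m in cfg.modules:
        idx = membership[m.name]
        n_uc = int(round(m.uc_fraction * len(idx)))
        flags = np.array([True] * n_uc + [False] * (len(idx) - n_uc))
        rng.shuffle(flags)
        for i, is_uc in zip(idx, flags):
            strata[genes[i]] = int(rng.choice(uc_strata if is_uc else mc_strata))
    n_bg_uc = int(round(cfg.background_uc_fraction * len(background)))
    flags = np.array([True] * n_bg_uc + [False] * (len(background) - n_bg_uc))
    rng.shuffle(flags)
    for i, is_uc in zip(background, flags):
        strata[genes[i]] = int(rng.choice(uc_strata if is_uc else mc_strata))
    age_table = GeneAgeTable(strata)

    # log-scale means
    lo, hi = cfg.base_log_cpm_range
    base = rng.uniform(lo, hi, size=n_genes)
    log_mu = np.tile(base[:, None], (1, len(samples)))
    loadings = np.zeros(n_genes)
    for m in cfg.modules:
        idx = membership[m.name]
        loadings[idx] = m.loading

    amp = cfg.amp_driver
    driver_genes: list[str] = []
    carriers: list[str] = []
    if amp.n_genes > 0:
        host_idx = membership[amp.host_module]
        driver_idx = host_idx[: amp.n_genes]
        driver_genes = [genes[i] for i in driver_idx]
        loadings[driver_idx] = amp.hub_loading
        n_carriers = int(round(amp.carrier_fraction * n_pairs))
        carrier_pos = rng.choice(n_pairs, size=n_carriers, replace=False)
        carriers = [tumor_ids[i] for i in sorted(carrier_pos)]
        carrier_cols = np.where(np.isin(np.array(samples), carriers))[0]
        log_mu[np.ix_(driver_idx, carrier_cols)] += amp.log2_fc * np.log(2.0)

    factors: dict[str, np.ndarray] = {}
    for m in cfg.modules:
        active = _active_mask(m.activity, condition, grade)
        f = np.zeros(len(samples))
        f[active] = rng.normal(0.0, cfg.factor_sd, size=int(active.sum()))
        factors[m.name] = f
        idx = membership[m.name]
        log_mu[idx, :] += np.outer(loadings[idx], f)

    # in normals, drivers behave as ordinary members of their normal host module
    if driver_genes:
        driver_idx = [genes.index(g) for g in driver_genes]
        normal_cols = condition == NORMAL
        f_host = factors[amp.normal_host_module] * normal_cols
        log_mu[driver_idx, :] += np.outer(np.ones(len(driver_idx)), f_host)

    log_mu += rng.normal(0.0, cfg.noise_sd, size=log_mu.shape)

    lib = rng.uniform(*cfg.lib_size_range, size=len(samples))
    mu = np.exp(log_mu) * (lib / 1e6)
    if cfg.dispersion > 0:
        r = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    values = pd.DataFrame(counts, index=genes, columns=samples)

    manifest = pd.DataFrame(
        {
            "sample": samples,
            "condition": condition,
            "pair_id": [f"P{i + 1:03d}" for i in range(n_pairs)] * 2,
            "stage": [
                grade[j] if condition[j] == TUMOR else NORMAL
                for j in range(len(samples))
            ],
        }
    ).set_index("sample")
    expression = ExpressionMatrix(values, manifest)

    # ground truth per condition
    truth: dict[str, dict[str, str]] = {TUMOR: {}, NORMAL: {}}
    for m in cfg.modules:
        for i in membership[m.name]:
            if m.activity in ("both", "tumor_only", "high_grade_only"):
                truth[TUMOR][genes[i]] = m.name
            if m.activity in ("both", "normal_only"):
                truth[NORMAL][genes[i]] = m.name
    for g in driver_genes:  # rewired: normal-host members in normals, tumor hubs
        truth[NORMAL][g] = amp.normal_host_module

    # gene coordinates on synthetic chromosomes, preserving gene order
    per_chrom = int(np.ceil(n_genes / cfg.n_chromosomes))
    coords = []
    for i, g in enumerate(genes):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * cfg.gene_spacing
        coords.append((g, chrom, start, start + cfg.gene_length))
    gene_coords = pd.DataFrame(coords, columns=["gene", "chrom", "start", "end"])
    chrom_len = per_chrom * cfg.gene_spacing

    # CNA segments: a focal amplification covering the driver locus in carriers,
    # plus a whole-chromosome gain elsewhere to exercise the focality rule
    seg_rows = []
    if driver_genes:
        span = gene_coords[gene_coords["gene"].isin(driver_genes)]
        chrom = span["chrom"].iloc[0]
        lo_c, hi_c = int(span["start"].min()), int(span["end"].max())
        pad = cfg.gene_spacing
        for patient in carriers:
            seg_rows.append(
                (patient, chrom, max(0, lo_c - pad), min(chrom_len, hi_c + pad), "amp")
            )
    broad_chrom = f"chr{cfg.n_chromosomes}"
    for patient in tumor_ids[: max(2, n_pairs // 20)]:
        seg_rows.append((patient, broad_chrom, 0, chrom_len, "amp"))
    cna_segments = pd.DataFrame(
        seg_rows, columns=["patient", "chrom", "start", "end", "state"]
    )

    # point mutations
    pm = cfg.point_mutations
    mut_rows = []
    bg_genes = [genes[i] for i in background]
    rec_point = list(rng.choice(bg_genes, size=pm.n_recurrent, replace=False))
    remaining = [g for g in bg_genes if g not in set(rec_point)]
    nonrec = list(rng.choice(remaining, size=pm.n_nonrecurrent, replace=False))
    for g in rec_point:  # 3 damaging carriers, NS/S = 3/4 < 1
        pats = rng.choice(tumor_ids, size=7, replace=False)
        for p in pats[:3]:
            mut_rows.append((g, p, "missense"))
        for p in pats[3:]:
            mut_rows.append((g, p, "synonymous"))
    for j, g in enumerate(nonrec):
        if j % 2 == 0:  # too few carriers
            for p in rng.choice(tumor_ids, size=2, replace=False):
                mut_rows.append((g, p, "missense"))
        else:  # enough carriers but NS/S >= 1
            pats = rng.choice(tumor_ids, size=4, replace=False)
            for p in pats[:3]:
                mut_rows.append((g, p, "LoF"))
            mut_rows.append((g, pats[3], "synonymous"))
    mutations = pd.DataFrame(mut_rows, columns=["gene", "patient", "consequence"])

    drivers = pd.DataFrame(
        {"gene": driver_genes + rec_point, "tumor_type": cfg.tumor_type}
    )

    return SyntheticCohort(
        expression=expression,
        age_table=age_table,
        truth=truth,
        mutations=mutations,
        cna_segments=cna_segments,
        gene_coords=gene_coords,
        drivers=drivers,
        amp_driver_genes=driver_genes,
        recurrent_point_genes=rec_point,
        config=cfg,
    )


def truth_recovery(detected: ModuleSet, truth: Mapping[str, str]) -> float:
    """Adjusted Rand index between detected and planted module partitions.

    Grey genes are excluded (they carry no detected label); remaining genes
    are labeled by their planted module, with genes outside any planted
    module pooled into a single background label so spurious assignments are
    penalized.  1.0 means perfect recovery, ~0 chance agreement.
    """
    assigned = detected.membership(include_grey=False)
    genes = sorted(assigned)
    if not genes:
        return 0.0
    pred = [assigned[g] for g in genes]
    true = [truth.get(g, "__background__") for g in genes]
    return float(adjusted_rand_score(true, pred))


def match_detected_to_planted(
    detected: ModuleSet, truth: Mapping[str, str], min_jaccard: float = 0.25
) -> dict[str, str]:
    """Map each planted module to its best-matching detected module by Jaccard.

    Planted modules with no detected counterpart above *min_jaccard* are
    omitted.
    """
    planted: dict[str, set[str]] = {}
    for gene, mod in truth.items():
        planted.setdefault(mod, set()).add(gene)
    out: dict[str, str] = {}
    for name, members in planted.items():
        best_label, best_j = None, min_jaccard
        for label, genes in detected.modules.items():
            j = len(members & genes) / len(members | genes)
            if j >= best_j:
                best_label, best_j = label, j
        if best_label is not None:
            out[name] = best_label
    return out
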