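"""Somatic mutation overlay on co-expression modules.

Recurrence filters for point mutations and focal copy-number alterations,
module-level CNA flags and their tumor-vs-normal Fisher enrichment, driver
gene content, and the within-module gene centrality statistic used to track
whether a gene moves toward the hub or the periphery between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .module_age import FisherResult, fisher_2x2

MISSENSE = "missense"
LOF = "LoF"
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = {MISSENSE, LOF}  # "other" (non-coding etc.) counts toward neither side


# ---------------------------------------------------------------------------
# point mutations


def recurrent_point_mutated(
    mutations: pd.DataFrame,
    min_patients: int = 3,
    max_ns_s: float = 1.0,
) -> set[str]:
    """Genes with missense/LoF hits in >= *min_patients* patients and NS/S < *max_ns_s*.

    *mutations* needs columns gene, patient, consequence.  A gene with zero
    synonymous mutations has an infinite NS/S ratio and fails the filter.
    """
    required = {"gene", "patient", "consequence"}
    if not required <= set(mutations.columns):
        raise ValueError(f"mutation table needs columns {sorted(required)}")
    out = set()
    for gene, grp in mutations.groupby("gene"):
        damaging = grp[grp["consequence"].isin((MISSENSE, LOF))]
        if damaging["patient"].nunique() < min_patients:
            continue
        n_syn = int((grp["consequence"] == SYNONYMOUS).sum())
        n_ns = int(grp["consequence"].isin(NONSYNONYMOUS).sum())
        if n_syn == 0:
            continue  # ratio = +inf, fails "< max_ns_s"
        if n_ns / n_syn < max_ns_s:
            out.add(str(gene))
    return out


# ---------------------------------------------------------------------------
# copy number


def _normalize_chrom(c: str) -> str:
    c = str(c)
    return c if c.startswith("chr") else f"chr{c}"


def focal_gene_calls(
    segments: pd.DataFrame,
    gene_coords: pd.DataFrame,
    focal_fraction: float = 0.25,
    chrom_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene per-patient focal amplification/deletion calls.

    *segments*: patient, chrom, start, end, state (amp/del/neutral), 0-based
    half-open coordinates.  *gene_coords*: gene, chrom, start, end.  A gene's
    call in a patient is the state of the segment overlapping the gene's
    midpoint; the call is focal when that segment spans at most
    *focal_fraction* of the chromosome length (non-strict).  Chromosome
    lengths default to the maximum end coordinate observed per chromosome.
    Only focal amp/del calls are returned (gene, patient, state).
    """
    import warnings

    seg = segments.copy()
    seg["chrom"] = seg["chrom"].map(_normalize_chrom)
    genes = gene_coords.copy()
    genes["chrom"] = genes["chrom"].map(_normalize_chrom)
    if (seg["start"] >= seg["end"]).any() or (genes["start"] >= genes["end"]).any():
        raise ValueError("coordinates must satisfy start < end (0-based half-open)")

    if chrom_sizes is None:
        sizes = (
            pd.concat([seg.groupby("chrom")["end"].max(), genes.groupby("chrom")["end"].max()])
            .groupby(level=0)
            .max()
            .to_dict()
        )
    else:
        sizes = {_normalize_chrom(c): s for c, s in chrom_sizes.items()}

    missing = set(genes["chrom"]) - set(sizes)
    if missing:
        warnings.warn(f"no length for chromosome(s) {sorted(missing)}; genes skipped")

    rows = []
    seg_by_chrom = dict(tuple(seg.groupby("chrom")))
    for gene, chrom, gstart, gend in genes[["gene", "chrom", "start", "end"]].itertuples(index=False):
        if chrom not in sizes:
            continue
        mid = (gstart + gend) // 2
        chrom_seg = seg_by_chrom.get(chrom)
        if chrom_seg is None:
            continue
        hit = chrom_seg[(chrom_seg["start"] <= mid) & (mid < chrom_seg["end"])]
        for patient, sstart, send, state in hit[["patient", "start", "end", "state"]].itertuples(index=False):
            if state not in ("amp", "del"):
                continue
            if (send - sstart) <= focal_fraction * sizes[chrom]:
                rows.append((gene, patient, state))
    return pd.DataFrame(rows, columns=["gene", "patient", "state"]).drop_duplicates()


def recurrent_cna(
    focal_calls: pd.DataFrame,
    n_patients: int,
    min_fraction: float = 0.10,
) -> tuple[set[str], set[str]]:
    """Genes focally amplified / deleted in >= *min_fraction* of patients."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    floor = min_fraction * n_patients
    amp: set[str] = set()
    dele: set[str] = set()
    if len(focal_calls):
        counts = focal_calls.groupby(["gene", "state"])["patient"].nunique()
        for (gene, state), n in counts.items():
            if n >= floor:
                (amp if state == "amp" else dele).add(str(gene))
    return amp, dele


def module_cna_flag(
    module: Iterable[str], recurrent: Iterable[str], min_fraction: float = 0.10
) -> tuple[bool, float]:
    """Whether >= *min_fraction* of the module's genes are recurrently altered."""
    module = set(module)
    if not module:
        raise ValueError("module must be non-empty")
    frac = len(module & set(recurrent)) / len(module)
    return frac >= min_fraction, frac


def cna_module_enrichment(
    normal_flags: Sequence[bool],
    tumor_flags: Sequence[bool],
) -> tuple[FisherResult, np.ndarray]:
    """One-sided Fisher test comparing CNA-flagged module rates, normal vs tumor.

    Table rows are (normal, tumor), columns (flagged, not flagged); the
    alternative is that normal modules are flagged less often (odds ratio
    below one when tumors are enriched).  Returns the result and the table.
    """
    if len(normal_flags) == 0 or len(tumor_flags) == 0:
        raise ValueError("both module collections must be non-empty")
    n_f = int(np.sum(normal_flags))
    t_f = int(np.sum(tumor_flags))
    table = np.array(
        [[n_f, len(normal_flags) - n_f], [t_f, len(tumor_flags) - t_f]], dtype=int
    )
    return fisher_2x2(table, alternative="less"), table


# ---------------------------------------------------------------------------
# drivers


def driver_fraction(
    module: Iterable[str],
    drivers: pd.DataFrame,
    tumor_type: str,
) -> tuple[float, bool]:
    """Percentage of module genes that are known drivers of *tumor_type*.

    *drivers* needs columns gene, tumor_type (Cancer-Census-shaped).  Returns
    (percentage, excluded) where ``excluded`` marks modules with no driver
    overlap, which downstream driver analyses leave out.
    """
    module = set(module)
    if not module:
        raise ValueError("module must be non-empty")
    known = set(drivers["tumor_type"].unique())
    if tumor_type not in known:
        raise ValueError(f"unknown tumor type {tumor_type!r}; known: {sorted(known)}")
    pool = set(drivers.loc[drivers["tumor_type"] == tumor_type, "gene"])
    pct = 100.0 * len(module & pool) / len(module)
    return pct, pct == 0.0


# ---------------------------------------------------------------------------
# centrality


def centrality(module_net: pd.DataFrame) -> pd.DataFrame:
    """Within-module gene centrality from the intra-module weighted network.

    degree = summed edge weights to the other module genes; norm_degree =
    degree over the module's median degree; genes are ranked ascending with
    average ties, the rank divided by the module size S, and 1 subtracted, so
    centrality lies in (-1, 0] with the hub at 0 (absent a top tie).
    """
    import warnings

    if module_net.shape[0] != module_net.shape[1] or module_net.shape[0] < 2:
        raise ValueError("need a square intra-module network of size >= 2")
    w = module_net.to_numpy(dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    degree = w.sum(axis=1)
    if (degree == 0).all():
        warnings.warn("all-zero edge weights; centralities degenerate to ties")
    med = float(np.median(degree))
    norm_degree = degree / med if med > 0 else np.full_like(degree, np.nan)
    s = len(degree)
    rel_rank = rankdata(degree, method="average") / s
    return pd.DataFrame(
        {
            "degree": degree,
            "norm_degree": norm_degree,
            "rel_rank": rel_rank,
            "centrality": rel_rank - 1.0,
        },
        index=module_net.index,
    )


def centrality_shift(
    gene: str,
    tumor_tables: Iterable[pd.DataFrame],
    normal_tables: Iterable[pd.DataFrame],
) -> float:
    """Change in centrality of *gene* from its normal module to its tumor module.

    Each argument is the collection of per-module centrality tables for one
    condition; the gene must appear in exactly one module per condition (grey
    genes have no table).  Returns tumor - normal centrality in (-1, 1);
    raises when the gene is unplaced in either condition.
    """

    def find(tables: Iterable[pd.DataFrame]) -> float:
        hits = [t.loc[gene, "centrality"] for t in tables if gene in t.index]
        if len(hits) != 1:
            raise ValueError(
                f"gene {gene!r} found in {len(hits)} modules; centrality shift undefined"
            )
        return float(hits[0])

    return find(tumor_tables) - find(normal_tables)
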