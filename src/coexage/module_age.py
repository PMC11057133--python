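"""Module age classification and generic over-representation analysis.

Each module is tested for over-representation of unicellular (UC) and of
multicellular (MC) genes against the expressed background with one-sided
Fisher exact tests; after Benjamini-Hochberg adjustment across the cohort's
modules, a module is UC-enriched, MC-enriched, or — when neither direction is
significant — mixed UC-MC, the class where ancient and metazoan programs meet.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_age import GeneAgeTable

UC_ENRICHED = "UC-enriched"
MC_ENRICHED = "MC-enriched"
MIXED = "mixed"


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p_value: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell
    undefined: bool = False  # a zero marginal makes the odds ratio meaningless


def fisher_2x2(
    table: Sequence[Sequence[int]] | np.ndarray,
    alternative: str = "two-sided",
    conditional_or: bool = False,
) -> FisherResult:
    """Exact Fisher test on a 2x2 table of non-negative counts.

    The odds ratio is the unconditional cross-product estimate ``ad / bc``;
    when a cell is zero the Haldane-Anscombe 0.5 correction is applied and the
    result flagged.  ``conditional_or=True`` returns scipy's conditional-MLE
    estimate instead.  A zero row or column marginal leaves the odds ratio
    undefined (NaN, flagged) while the p-value is still exact (trivially 1).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if t.sum() == 0:
        raise ValueError("table grand total must be positive")
    a, b, c, d = t.ravel()
    p = stats.fisher_exact(t.astype(int), alternative=alternative).pvalue

    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        return FisherResult(float("nan"), p, undefined=True)
    if conditional_or:
        odds = stats.contingency.odds_ratio(t.astype(int), kind="conditional").statistic
        return FisherResult(float(odds), p)
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    return FisherResult((a * d) / (b * c), p, corrected=corrected)


@dataclass
class AgeEnrichmentResult:
    """One module's UC/MC over-representation test outcome."""

    module: str
    n_uc: int
    n_mc: int
    bg_uc: int
    bg_mc: int
    p_uc: float
    p_mc: float
    adj_p_uc: float = float("nan")
    adj_p_mc: float = float("nan")
    category: str = MIXED
    classifiable: bool = True


def classify_module_age(
    module: str,
    genes: Iterable[str],
    ages: GeneAgeTable,
    background: Iterable[str],
) -> AgeEnrichmentResult:
    """Raw one-sided Fisher p-values for UC and MC over-representation.

    Counts only age-classified genes, both in the module and in the
    background.  The category is assigned later, after cohort-wide BH
    adjustment (:func:`adjust_and_categorize`).
    """
    genes = set(genes)
    background = set(background)
    if not genes <= background:
        raise ValueError("module genes must be a subset of the background")
    m_uc, m_mc = ages.counts(genes)
    b_uc, b_mc = ages.counts(background)
    if m_uc + m_mc == 0:
        return AgeEnrichmentResult(
            module, 0, 0, b_uc, b_mc, float("nan"), float("nan"), classifiable=False
        )
    # module vs rest-of-background, UC vs MC
    rest_uc, rest_mc = b_uc - m_uc, b_mc - m_mc
    p_uc = fisher_2x2([[m_uc, m_mc], [rest_uc, rest_mc]], alternative="greater").p_value
    p_mc = fisher_2x2([[m_mc, m_uc], [rest_mc, rest_uc]], alternative="greater").p_value
    return AgeEnrichmentResult(module, m_uc, m_mc, b_uc, b_mc, p_uc, p_mc)


def adjust_and_categorize(
    results: Sequence[AgeEnrichmentResult],
    alpha: float = 0.05,
    pooled_family: bool = False,
) -> list[AgeEnrichmentResult]:
    """BH-adjust the Fisher p-values across modules and set categories.

    By default the UC and MC test directions form separate BH families across
    the cohort's modules; ``pooled_family=True`` pools both directions into
    one family.  UC-enriched iff the adjusted UC p is below *alpha*; likewise
    for MC; otherwise mixed.  A two-class labeling cannot be one-sidedly
    enriched in both directions at once.
    """
    if not results:
        return []
    testable = [r for r in results if r.classifiable]
    out = {r.module: replace(r) for r in results}
    if testable:
        p_uc = np.array([r.p_uc for r in testable])
        p_mc = np.array([r.p_mc for r in testable])
        if pooled_family:
            adj = multipletests(np.concatenate([p_uc, p_mc]), method="fdr_bh")[1]
            adj_uc, adj_mc = adj[: len(testable)], adj[len(testable):]
        else:
            adj_uc = multipletests(p_uc, method="fdr_bh")[1]
            adj_mc = multipletests(p_mc, method="fdr_bh")[1]
        for r, au, am in zip(testable, adj_uc, adj_mc):
            res = out[r.module]
            res.adj_p_uc, res.adj_p_mc = float(au), float(am)
            if au < alpha:
                res.category = UC_ENRICHED
            elif am < alpha:
                res.category = MC_ENRICHED
            else:
                res.category = MIXED
    return [out[r.module] for r in results]


def age_enrichment_table(results: Sequence[AgeEnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module,
                "n_uc": r.n_uc,
                "n_mc": r.n_mc,
                "bg_uc": r.bg_uc,
                "bg_mc": r.bg_mc,
                "p_uc": r.p_uc,
                "p_mc": r.p_mc,
                "adj_p_uc": r.adj_p_uc,
                "adj_p_mc": r.adj_p_mc,
                "category": r.category,
                "classifiable": r.classifiable,
            }
            for r in results
        ]
    )


def ora(
    module: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    exclude_terms: Iterable[str] = (),
) -> pd.DataFrame:
    """Hypergeometric over-representation of *module* in each gene set.

    Gene sets are intersected with the background before testing; sets with
    no background overlap are skipped with a warning.  BH adjustment across
    the tested sets; rows sorted by adjusted p.  *exclude_terms* is applied as
    a post-filter on set names (case-insensitive).
    """
    import warnings

    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    module = set(module) & background
    excluded = {t.strip().lower() for t in exclude_terms}
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & background
        if not members:
            warnings.warn(f"gene set {name!r} has no overlap with background; skipped")
            continue
        overlap = len(module & members)
        # P(X >= overlap) drawing |module| genes from the background
        p = stats.hypergeom.sf(overlap - 1, len(background), len(members), len(module))
        rows.append({"set": name, "set_size": len(members), "overlap": overlap, "p": float(p)})
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    if len(df):
        df["adj_p"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df[~df["set"].str.strip().str.lower().isin(excluded)]
        df = df.sort_values(["adj_p", "p", "set"]).reset_index(drop=True)
    else:
        df["adj_p"] = pd.Series(dtype=float)
    return df
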