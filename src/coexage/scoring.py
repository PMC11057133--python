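"""Per-sample module activity via single-sample GSEA.

For each sample, genes are ranked by expression; a running sum walks the
ranked list, rising by a rank-weighted increment at in-set genes and falling
by a uniform increment at out-of-set genes.  The enrichment score is the sum
of the running differences, so modules whose genes sit consistently near the
top of a sample's expression profile score high.  Scores depend only on
within-sample ranks, hence are invariant to any strictly increasing
transform of the expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import ExpressionMatrix, ModuleSet


@dataclass
class ModuleScoreMatrix:
    """Modules x samples enrichment scores."""

    scores: pd.DataFrame
    normalized: bool
    alpha: float

    def summary(self, how: str = "mean") -> pd.Series:
        """Per-module summary over samples (mean by default, median by flag)."""
        if how == "mean":
            return self.scores.mean(axis=1)
        if how == "median":
            return self.scores.median(axis=1)
        raise ValueError(f"unknown summary: {how}")


def ssgsea_sample(
    expr_col: pd.Series,
    gene_set: Iterable[str],
    alpha: float = 0.25,
) -> float:
    """Enrichment score of *gene_set* in one sample's expression profile.

    Genes are ordered by decreasing expression, ties broken by gene id so the
    score is deterministic.  The gene at ascending-rank r (top gene r = n)
    contributes weight ``r**alpha`` when in the set; out-of-set genes each
    contribute 1/(n - |set|) to the penalty term.  ES is the sum over
    positions of the running in-set fraction minus the running out-of-set
    fraction.
    """
    genes = expr_col.index
    in_set = genes.isin(set(gene_set))
    n = len(genes)
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set has no genes in the expression profile")
    if n_in == n:
        raise ValueError("gene set covers every gene; score undefined")
    # decreasing expression, ties by gene id
    order = np.lexsort((np.asarray(genes), -expr_col.to_numpy(dtype=float)))
    in_sorted = in_set[order]
    ranks = np.arange(n, 0, -1, dtype=float)  # ascending rank, top gene = n
    w = np.where(in_sorted, ranks**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    modset: ModuleSet | Mapping[str, Iterable[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> ModuleScoreMatrix:
    """ssGSEA score of every module in every sample.

    Modules with no expressed genes are dropped with a warning.  With
    ``normalize=True`` the whole matrix is divided by its global max - min
    range (so the spread of scores is 1 across the matrix).
    """
    modules = modset.modules if isinstance(modset, ModuleSet) else dict(modset)
    genes = set(expr.genes)
    usable: dict[str, set[str]] = {}
    for label, members in modules.items():
        members = set(members) & genes
        if not members:
            warnings.warn(f"module {label!r} has no expressed genes; dropped")
            continue
        usable[label] = members
    if not usable:
        raise ValueError("no module overlaps the expression matrix")

    vals = expr.values
    n = len(vals.index)
    gene_arr = np.asarray(vals.index)
    masks = {lab: vals.index.isin(members) for lab, members in usable.items()}
    out = np.empty((len(usable), vals.shape[1]))
    ranks_desc = np.arange(n, 0, -1, dtype=float)
    for j, sample in enumerate(vals.columns):
        col = vals[sample].to_numpy(dtype=float)
        order = np.lexsort((gene_arr, -col))
        rank_w = ranks_desc**alpha
        for i, (lab, mask) in enumerate(masks.items()):
            in_sorted = mask[order]
            n_in = in_sorted.sum()
            if n_in == n:
                raise ValueError(f"module {lab!r} covers every expressed gene")
            w = np.where(in_sorted, rank_w, 0.0)
            p_in = np.cumsum(w) / w.sum()
            p_out = np.cumsum(~in_sorted) / (n - n_in)
            out[i, j] = np.sum(p_in - p_out)
    scores = pd.DataFrame(out, index=list(usable), columns=vals.columns)
    if normalize:
        span = float(scores.to_numpy().max() - scores.to_numpy().min())
        if span > 0:
            scores = scores / span
    return ModuleScoreMatrix(scores, normalized=normalize, alpha=alpha)


def upper_quartile_share(
    scores: ModuleScoreMatrix,
    classes: Mapping[str, str],
    summary: str = "mean",
) -> pd.Series:
    """Fraction of each novelty tertile's modules in the top score quartile.

    Modules are summarized over samples, the cohort's 75th-percentile summary
    score defines the upper quartile (non-strict >=), and per tertile the
    fraction of member modules reaching it is returned.
    """
    summ = scores.summary(summary)
    missing = set(summ.index) - set(classes)
    if missing:
        raise ValueError(f"novelty class missing for module(s): {sorted(missing)[:5]}")
    q3 = summ.quantile(0.75)
    top = summ >= q3
    by_class: dict[str, list[bool]] = {}
    for module, val in top.items():
        by_class.setdefault(classes[module], []).append(bool(val))
    return pd.Series({c: float(np.mean(v)) for c, v in sorted(by_class.items())})
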