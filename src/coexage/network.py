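"""Weighted gene co-expression networks and module detection.

The core WGCNA-style sequence: filter low/unreliable expression, drop outlier
samples, raise the absolute Pearson correlation to a soft power to obtain an
unsigned adjacency, convert to the topological overlap matrix (TOM), cluster
genes by average linkage on 1 - TOM, and cut the dendrogram into modules of a
minimum size; unassigned genes form the grey pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

GREY = "grey"


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample metadata.

    ``values`` is a DataFrame indexed by gene id with sample-id columns.
    ``sample_meta`` is indexed by sample id and may carry ``condition``
    (tumor/normal), ``pair_id``, and ``stage`` columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if self.sample_meta is not None:
            missing = self.values.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(f"samples missing from manifest: {list(missing)[:5]}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN comparisons
            if (self.values.to_numpy() < 0).any():
                raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in self.genes if g in set(genes)]
        return replace(self, values=self.values.loc[genes])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[list(samples)]
        return ExpressionMatrix(self.values[list(samples)], meta)

    def samples_where(self, **conditions: object) -> list[str]:
        """Sample ids whose manifest row matches all keyword conditions."""
        if self.sample_meta is None:
            raise ValueError("no sample manifest attached")
        mask = pd.Series(True, index=self.sample_meta.index)
        for col, val in conditions.items():
            mask &= self.sample_meta[col] == val
        return [s for s in self.samples if mask.get(s, False)]


@dataclass
class CoexpressionNetwork:
    """Symmetric gene-gene weight matrix (adjacency or TOM), weights in [0,1]."""

    genes: list[str]
    weights: np.ndarray
    kind: str  # "adjacency" | "tom"
    beta: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.genes)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape does not match gene list")
        self.weights = w

    def validate(self) -> None:
        w = self.weights
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix is not symmetric")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("weights outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.genes, columns=self.genes)


@dataclass
class ModuleSet:
    """Disjoint gene modules plus the grey pool of unassigned genes."""

    modules: dict[str, set[str]]
    grey: set[str] = field(default_factory=set)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, genes in self.modules.items():
            overlap = seen & genes
            if overlap:
                raise ValueError(f"module {label} overlaps earlier modules: {sorted(overlap)[:3]}")
            seen |= genes
        if seen & self.grey:
            raise ValueError("grey pool overlaps assigned modules")

    @property
    def labels(self) -> list[str]:
        return list(self.modules)

    @property
    def assigned_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.modules.values():
            out |= genes
        return out

    def membership(self, include_grey: bool = True) -> dict[str, str]:
        out = {g: label for label, genes in self.modules.items() for g in genes}
        if include_grey:
            out.update({g: GREY for g in self.grey})
        return out

    def to_frame(self, include_grey: bool = True) -> pd.DataFrame:
        rows = [(g, lab) for g, lab in sorted(self.membership(include_grey).items())]
        return pd.DataFrame(rows, columns=["gene", "module"])

    @classmethod
    def from_membership(cls, membership: Mapping[str, str], provenance: str = "") -> "ModuleSet":
        modules: dict[str, set[str]] = {}
        grey: set[str] = set()
        for gene, label in membership.items():
            if label == GREY:
                grey.add(gene)
            else:
                modules.setdefault(label, set()).add(gene)
        return cls(modules, grey, provenance)


# ---------------------------------------------------------------------------
# preprocessing


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million per sample column."""
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise ValueError(f"non-positive library size for sample(s): {bad[:5]}")
    return counts.div(libsize, axis=1) * 1e6


def cpm_filter(
    counts: ExpressionMatrix,
    tumor_ids: Sequence[str],
    normal_ids: Sequence[str],
    threshold: float = 1.0,
) -> set[str]:
    """Genes with CPM above *threshold* in every tumor OR every normal sample.

    Expression estimates for genes below ~1 CPM are unreliable; a gene is kept
    only when it clears the threshold consistently within at least one of the
    two conditions.
    """
    if len(tumor_ids) == 0 or len(normal_ids) == 0:
        raise ValueError("tumor and normal sample groups must both be non-empty")
    unknown = (set(tumor_ids) | set(normal_ids)) - set(counts.samples)
    if unknown:
        raise ValueError(f"sample ids not in expression matrix: {sorted(unknown)[:5]}")
    c = cpm(counts.values)
    keep_t = (c[list(tumor_ids)] > threshold).all(axis=1)
    keep_n = (c[list(normal_ids)] > threshold).all(axis=1)
    return set(counts.genes[keep_t | keep_n])


def remove_outlier_samples(
    expr: ExpressionMatrix, k: float = 2.5
) -> ExpressionMatrix:
    """Drop samples that cluster apart from the rest.

    Samples are clustered by average linkage on Euclidean distance; the tree
    is cut at ``mean + k*sd`` of the merge heights and only the largest
    resulting cluster is retained.  When pair ids are present, dropping a
    sample also drops its partner so the design stays paired.
    """
    X = expr.values.T.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples for outlier screening")
    Z = linkage(X, method="average", metric="euclidean")
    heights = Z[:, 2]
    cut = heights.mean() + k * heights.std(ddof=0)
    from scipy.cluster.hierarchy import fcluster

    labels = fcluster(Z, t=cut, criterion="distance")
    counts = np.bincount(labels)
    main = counts.argmax()
    keep = {expr.samples[i] for i in range(n) if labels[i] == main}
    dropped = set(expr.samples) - keep

    if expr.sample_meta is not None and "pair_id" in expr.sample_meta.columns:
        pairs = expr.sample_meta["pair_id"]
        dropped_pairs = set(pairs.reindex(list(dropped)).dropna())
        keep = {s for s in keep if pairs.get(s) not in dropped_pairs}
    if not keep:
        raise ValueError("all samples flagged as outliers")
    return expr.subset_samples([s for s in expr.samples if s in keep])


def drop_bad_genes(expr: ExpressionMatrix, max_missing: float = 0.5) -> ExpressionMatrix:
    """Remove zero-variance genes and genes missing in > *max_missing* of samples."""
    vals = expr.values
    frac_missing = vals.isna().mean(axis=1)
    variance = vals.var(axis=1, ddof=0)
    keep = (frac_missing <= max_missing) & (variance > 0) & variance.notna()
    return replace(expr, values=vals.loc[keep])


# ---------------------------------------------------------------------------
# network construction


def adjacency(expr: ExpressionMatrix, beta: float = 6.0) -> CoexpressionNetwork:
    """Unsigned soft-threshold adjacency: ``a_ij = |pearson(x_i, x_j)|**beta``.

    The diagonal is set to 1.  Correlations use pairwise-complete observations
    when missing values are present.
    """
    vals = expr.values
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    variance = vals.var(axis=1, ddof=0)
    zero_var = variance[variance == 0]
    if len(zero_var):
        raise ValueError(f"zero-variance gene(s): {list(zero_var.index)[:5]}")
    if vals.isna().any().any():
        corr = vals.T.corr(method="pearson").to_numpy()
    else:
        corr = np.corrcoef(vals.to_numpy(dtype=float))
    a = np.abs(corr) ** beta
    np.clip(a, 0.0, 1.0, out=a)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return CoexpressionNetwork(list(vals.index), a, kind="adjacency", beta=beta)


def tom(adj: CoexpressionNetwork) -> CoexpressionNetwork:
    """Topological overlap matrix from an unsigned adjacency.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_u a_iu * a_uj`` (u != i, j) and ``k_i`` the connectivity of
    gene i excluding the diagonal.  Genes sharing many strong neighbors get
    high overlap even when their direct edge is modest.
    """
    if adj.kind != "adjacency":
        raise ValueError("tom() expects an adjacency network")
    adj.validate()
    a = adj.weights.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a  # zero diagonal removes the u=i and u=j terms
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (l + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip((t + t.T) / 2.0, 0.0, 1.0)
    return CoexpressionNetwork(list(adj.genes), t, kind="tom", beta=adj.beta)


def extract_module_network(
    net: CoexpressionNetwork, module: Iterable[str]
) -> pd.DataFrame:
    """Sub-matrix of *net* over the module's genes (the intra-module network)."""
    module = list(dict.fromkeys(module))
    unknown = set(module) - set(net.genes)
    if unknown:
        raise ValueError(f"gene(s) not in network: {sorted(unknown)[:5]}")
    frame = net.to_frame()
    return frame.loc[module, module]


# ---------------------------------------------------------------------------
# module detection


def _cut_recursive(node, cut_height: float, gap: float, min_size: int, clusters, grey):
    if node.is_leaf():
        grey.append(node.id)
        return
    left, right = node.get_left(), node.get_right()
    tall_child = max(left.dist, right.dist)
    split = node.dist > cut_height or (
        min(left.get_count(), right.get_count()) >= min_size
        and node.dist - tall_child >= gap
    )
    if split:
        _cut_recursive(left, cut_height, gap, min_size, clusters, grey)
        _cut_recursive(right, cut_height, gap, min_size, clusters, grey)
    elif node.get_count() >= min_size:
        clusters.append(node.pre_order(lambda leaf: leaf.id))
    else:
        grey.extend(node.pre_order(lambda leaf: leaf.id))


def detect_modules(
    net: CoexpressionNetwork,
    min_size: int = 30,
    cut_height: float | None = None,
    gap: float = 0.1,
    method: str = "tree",
    provenance: str = "",
) -> ModuleSet:
    """Partition genes into co-expression modules by cutting the TOM dendrogram.

    Average-linkage clustering on the dissimilarity ``1 - TOM`` followed by a
    deterministic recursive tree cut: a branch is split when its merge height
    exceeds *cut_height* (default: 0.99 of the tallest merge) or when both
    children hold at least *min_size* genes and sit at least *gap* below the
    merge.  Surviving branches of >= *min_size* genes become modules, labeled
    "M1", "M2", ... by decreasing size; everything else lands in grey.
    ``method="static"`` uses a plain height cut instead.
    """
    if net.kind != "tom":
        raise ValueError("detect_modules expects a TOM network")
    genes = net.genes
    n = len(genes)
    if n < 2:
        return ModuleSet({}, set(genes), provenance)
    diss = 1.0 - net.weights
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    max_h = Z[:, 2].max() if len(Z) else 0.0
    if cut_height is None:
        cut_height = 0.99 * max_h

    clusters: list[list[int]] = []
    grey_idx: list[int] = []
    if method == "tree":
        root = to_tree(Z)
        _cut_recursive(root, cut_height, gap, min_size, clusters, grey_idx)
    elif method == "static":
        from scipy.cluster.hierarchy import fcluster

        flat = fcluster(Z, t=cut_height, criterion="distance")
        for lab in np.unique(flat):
            idx = list(np.where(flat == lab)[0])
            if len(idx) >= min_size:
                clusters.append(idx)
            else:
                grey_idx.extend(idx)
    else:
        raise ValueError(f"unknown cut method: {method}")

    # order: decreasing size, then by smallest member gene id for determinism
    named = [sorted(genes[i] for i in idx) for idx in clusters]
    named.sort(key=lambda gs: (-len(gs), gs[0]))
    modules = {f"M{i + 1}": set(gs) for i, gs in enumerate(named)}
    grey = {genes[i] for i in grey_idx}
    return ModuleSet(modules, grey, provenance)
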